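"""Collicular projection algebra and saccade decoding."""

import numpy as np
import pytest

from whatwhere.colliculus import (CollicularMap, build_projection,
                                  cell_log_polar_response, decode_saccade,
                                  ground_truth_map, project_map)


@pytest.fixture(scope="module")
def kernel_norms(grid):
    """Pixel-grid normalization constant of every cell kernel."""
    yy, xx = np.mgrid[:128, :128]
    rows = (yy - 64).astype(float).ravel()
    cols = (xx - 64).astype(float).ravel()
    return np.array([cell_log_polar_response(grid, k // 24, k % 24, rows, cols).sum()
                     for k in range(240)])


class TestProjection:
    def test_240_kernels(self, projection):
        assert projection.shape == (240, 128 * 128)

    def test_constant_map_returns_constant(self, projection, grid):
        vals = projection @ np.full(128 * 128, 0.42)
        assert np.abs(vals - 0.42).max() < 1e-12

    def test_delta_at_cell_center_argmaxes_that_cell(self, grid, kernel_norms):
        # brute-force oracle: evaluate every cell's (normalized) kernel
        # at the exact continuous center of cell k
        for k in range(240):
            i, j = divmod(k, 24)
            dr, dc = grid.cell_center(i, j)
            resp = np.array([
                cell_log_polar_response(grid, m // 24, m % 24,
                                        np.array([dr]), np.array([dc]))[0]
                for m in range(240)]) / kernel_norms
            assert int(np.argmax(resp)) == k

    def test_rotation_equivariance_of_kernels(self, grid):
        # the kernel depends on (log r, delta azimuth) only: rotating the
        # evaluation points by one azimuth step and shifting the cell
        # index by one must give identical values
        rng = np.random.default_rng(0)
        r = rng.uniform(3, 50, size=200)
        phi = rng.uniform(0, 2 * np.pi, size=200)
        step = 2 * np.pi / grid.n_azimuth
        for i_az in [0, 5, 23]:
            v1 = cell_log_polar_response(grid, 4, i_az,
                                         r * np.sin(phi), r * np.cos(phi))
            v2 = cell_log_polar_response(grid, 4, (i_az + 1) % 24,
                                         r * np.sin(phi + step),
                                         r * np.cos(phi + step))
            assert np.abs(v1 - v2).max() < 1e-9


class TestGroundTruthMap:
    def test_argmax_at_target_cell(self, projection, grid, synthetic_shift_map):
        cm = ground_truth_map((13, 0), synthetic_shift_map, projection, grid)
        i, j = cm.argmax_cell()
        assert grid.eccentricities[i] == 13.0
        assert j == 6  # azimuth pi/2: straight down in (row, col) convention

    def test_far_target_leaves_padding_level(self, projection, grid,
                                             synthetic_shift_map):
        cm = ground_truth_map((120, 120), synthetic_shift_map, projection, grid)
        pad = synthetic_shift_map.border_level
        assert np.abs(cm.values - pad).max() < 0.02

    def test_values_within_shift_map_range(self, projection, grid,
                                           synthetic_shift_map):
        for offset in [(0, 0), (9, -4), (-20, 15), (40, 0)]:
            cm = ground_truth_map(offset, synthetic_shift_map, projection, grid)
            assert cm.values.min() >= synthetic_shift_map.values.min() - 1e-9
            assert cm.values.max() <= synthetic_shift_map.values.max() + 1e-9

    def test_mirror_symmetric_offsets_permute_cells(self, grid,
                                                    synthetic_shift_map):
        # reflection row -> -row maps azimuth j to -j (mod 24); checked
        # on an odd-sized (point-symmetric) pixel grid, where the
        # construction is exactly equivariant
        proj = build_projection(grid, display_size=127)
        m1 = ground_truth_map((18, 0), synthetic_shift_map, proj, grid,
                              display_size=127)
        m2 = ground_truth_map((-18, 0), synthetic_shift_map, proj, grid,
                              display_size=127)
        g1, g2 = m1.as_grid(), m2.as_grid()
        permuted = g2[:, (-np.arange(24)) % 24]
        assert np.abs(g1 - permuted).max() < 1e-9

    def test_missing_shift_map_rejected(self, projection, grid):
        with pytest.raises(ValueError):
            ground_truth_map((0, 0), None, projection, grid)


class TestDecodeSaccade:
    def test_cardinal_cells(self, grid):
        cmd = decode_saccade((5, 0), grid)  # radius 13, azimuth 0
        assert cmd.displacement == (0, 13)
        cmd = decode_saccade((0, 6), grid)  # radius 2, azimuth 90 deg
        assert cmd.displacement == (2, 0)

    def test_no_cell_decodes_to_zero(self, grid):
        for k in range(grid.map_dim):
            assert decode_saccade(k, grid).displacement != (0, 0)

    def test_invalid_cell_rejected(self, grid):
        with pytest.raises(IndexError):
            decode_saccade((10, 0), grid)

    def test_decode_groundtruth_consistency(self, grid, projection,
                                            synthetic_shift_map):
        # saccading to any cell and asking "where is the target now"
        # with a perfect transfer curve must argmax back at that cell;
        # checked on rings whose cell spacing exceeds the integer-pixel
        # rounding of the decoder (inner rings are sub-pixel apart and
        # alias under rounding by construction)
        for k in range(5 * grid.n_azimuth, 240, 7):
            cmd = decode_saccade(k, grid)
            cm = ground_truth_map(cmd.displacement, synthetic_shift_map,
                                  projection, grid)
            i, j = cm.argmax_cell()
            assert (i, j) == cmd.cell


def test_argmax_tie_breaks_toward_low_eccentricity(grid):
    vals = np.zeros(240)
    vals[[5, 30, 200]] = 1.0  # same value at three cells
    cm = CollicularMap(values=vals, grid=grid)
    assert cm.argmax_cell() == (0, 5)
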