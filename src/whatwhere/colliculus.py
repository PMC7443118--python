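"""Collicular accuracy maps: log-polar projection and saccade decoding.

The action space of the agent is the 240-cell (10 eccentricities x 24
azimuths) retinotopic motor map, by analogy with the superior
colliculus.  A pixel-space accuracy map (probability of a correct
foveal classification after saccading to each pixel) is projected onto
the cells with Gaussian kernels defined in log-polar coordinates; each
kernel is normalized to sum to one so a cell's value is a spatial
*average* of the accuracies it integrates, keeping values in [0, 1].
Cell values are interpreted as independent Bernoulli accuracies, not as
a distribution over cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .retina import LogPolarGrid


@dataclass
class CollicularMap:
    """Per-cell predicted/true accuracy in [0, 1] (the 'Where' output)."""

    values: np.ndarray  # (map_dim,)
    grid: LogPolarGrid

    def __post_init__(self):
        if self.values.shape != (self.grid.map_dim,):
            raise ValueError("map length does not match the grid")

    def argmax_cell(self) -> tuple[int, int]:
        """Highest-accuracy cell; ties broken toward the lowest
        eccentricity ring, then the lowest azimuth index (favoring the
        shortest saccade)."""
        flat = int(np.argmax(self.values))  # np.argmax returns first max:
        # flat index order is (ecc-major, azimuth-minor), which realizes
        # the tie-break rule directly.
        return divmod(flat, self.grid.n_azimuth)

    def as_grid(self) -> np.ndarray:
        return self.values.reshape(self.grid.n_eccentricity, self.grid.n_azimuth)


@dataclass(frozen=True)
class SaccadeCommand:
    cell: tuple[int, int]  # (eccentricity index, azimuth index)
    displacement: tuple[int, int]  # (drow, dcol), integer pixels


def _log_sigma_per_ring(grid: LogPolarGrid) -> np.ndarray:
    """Radial kernel width: half the local log-spacing between rings."""
    log_ecc = np.log(np.asarray(grid.eccentricities))
    gaps = np.diff(log_ecc)
    local = np.empty(len(log_ecc))
    local[0] = gaps[0]
    local[-1] = gaps[-1]
    local[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
    return 0.5 * local


def cell_log_polar_response(grid: LogPolarGrid, i_ecc: int, i_az: int,
                            rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Unnormalized Gaussian kernel of one cell evaluated at continuous
    (row, col) displacements from fixation.  The kernel is a function of
    (log r, azimuth) only, which makes the projection rotation-
    equivariant in the continuous limit."""
    r = np.hypot(rows, cols)
    phi = np.arctan2(rows, cols)
    sigma_log = _log_sigma_per_ring(grid)[i_ecc]
    sigma_phi = 0.5 * (2 * np.pi / grid.n_azimuth)
    with np.errstate(divide="ignore"):
        dlog = np.log(r / grid.eccentricities[i_ecc])
    dphi = np.angle(np.exp(1j * (phi - grid.azimuths()[i_az])))
    out = np.exp(-0.5 * (dlog / sigma_log) ** 2 - 0.5 * (dphi / sigma_phi) ** 2)
    return np.where(r > 0, out, 0.0)


def build_projection(grid: LogPolarGrid, display_size: int = 128) -> np.ndarray:
    """Dense (map_dim x display_size**2) averaging projection matrix."""
    center = display_size // 2
    yy, xx = np.mgrid[:display_size, :display_size]
    rows = (yy - center).astype(float).ravel()
    cols = (xx - center).astype(float).ravel()
    P = np.empty((grid.map_dim, display_size * display_size))
    k = 0
    for i_ecc in range(grid.n_eccentricity):
        for i_az in range(grid.n_azimuth):
            w = cell_log_polar_response(grid, i_ecc, i_az, rows, cols)
            P[k] = w / w.sum()
            k += 1
    return P


def project_map(projection: np.ndarray, pixel_map: np.ndarray,
                grid: LogPolarGrid) -> CollicularMap:
    values = projection @ pixel_map.ravel()
    return CollicularMap(values=np.clip(values, 0.0, 1.0), grid=grid)


def ground_truth_map(target_offset: tuple[float, float],
                     shift_map, projection: np.ndarray,
                     grid: LogPolarGrid,
                     display_size: int = 128) -> CollicularMap:
    """Assemble the true accuracy map for a target at ``target_offset``
    (row, col displacement from the current gaze) by centering the
    measured shift-accuracy map there, padding elsewhere with the map's
    border mean (~ chance accuracy), then projecting to the cells.

    This is the 'computational shortcut': since classification accuracy
    depends only on the target's offset from fixation, the full-display
    accuracy map is the central shift map translated to the target.
    """
    if shift_map is None:
        raise ValueError("a ShiftAccuracyMap is required")
    sm = shift_map.values
    half = sm.shape[0] // 2
    pad = shift_map.border_level
    full = np.full((display_size, display_size), pad, dtype=np.float64)
    center = display_size // 2
    tr = center + int(np.rint(target_offset[0]))
    tc = center + int(np.rint(target_offset[1]))
    r0, c0 = tr - half, tc - half
    rs, re = max(0, r0), min(display_size, r0 + sm.shape[0])
    cs, ce = max(0, c0), min(display_size, c0 + sm.shape[1])
    if rs < re and cs < ce:
        full[rs:re, cs:ce] = sm[rs - r0:re - r0, cs - c0:ce - c0]
    return project_map(projection, full, grid)


def decode_saccade(cell: tuple[int, int] | int, grid: LogPolarGrid) -> SaccadeCommand:
    """Polar-to-Cartesian conversion of a cell center, rounded to integer
    pixels.  The innermost ring (radius 2) sets the minimum saccade
    amplitude; no cell decodes to (0, 0)."""
    if isinstance(cell, (int, np.integer)):
        cell = divmod(int(cell), grid.n_azimuth)
    i_ecc, i_az = cell
    if not (0 <= i_ecc < grid.n_eccentricity and 0 <= i_az < grid.n_azimuth):
        raise IndexError(f"invalid cell {cell}")
    drow, dcol = grid.cell_center(i_ecc, i_az)
    return SaccadeCommand(cell=(i_ecc, i_az),
                          displacement=(int(np.rint(drow)), int(np.rint(dcol))))
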