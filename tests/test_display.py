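"""Generative display model: clutter spectrum, placement, blending, mask."""

import numpy as np
import pytest
from scipy import stats

from whatwhere.display import (Display, NoiseParams, TargetSpec, embed_target,
                               generate_noise, make_trial,
                               max_admissible_eccentricity,
                               sample_target_position)
from whatwhere.glyphs import make_glyph_dataset


def radial_amplitude_median(texture):
    """Median frequency of the radially averaged amplitude spectrum."""
    F = np.abs(np.fft.fft2(texture - texture.mean()))
    n = texture.shape[0]
    f = np.hypot(np.fft.fftfreq(n)[:, None], np.fft.fftfreq(n)[None, :]).ravel()
    bins = np.linspace(0, 0.5, n // 2 + 1)
    idx = np.digitize(f, bins)
    prof = np.array([F.ravel()[idx == i].mean() if (idx == i).any() else 0.0
                     for i in range(1, len(bins))])
    centers = 0.5 * (bins[:-1] + bins[1:])
    cum = np.cumsum(prof)
    return centers[np.searchsorted(cum, cum[-1] / 2)]


class TestNoise:
    def test_spectral_median_matches_sf0(self):
        meds = [radial_amplitude_median(
            generate_noise(NoiseParams(sf0=0.1, b_sf=1.0, seed=s), 128))
            for s in range(5)]
        assert 0.08 <= np.mean(meds) <= 0.12

    def test_narrow_bandwidth_concentrates_spectrum(self):
        # b_sf -> 0: quasi-sinusoidal rings, energy in a vanishing annulus
        tex = generate_noise(NoiseParams(sf0=0.1, b_sf=0.05, seed=0), 128)
        F = np.abs(np.fft.fft2(tex - tex.mean())) ** 2
        f = np.hypot(np.fft.fftfreq(128)[:, None], np.fft.fftfreq(128)[None, :])
        inside = F[(f > 0.08) & (f < 0.12)].sum()
        assert inside / F.sum() > 0.99

    @pytest.mark.parametrize("seed", [0, 1, 12345])
    def test_normalized_to_unit_range(self, seed):
        tex = generate_noise(NoiseParams(seed=seed), 64)
        assert tex.min() == 0.0 and tex.max() == 1.0

    @pytest.mark.parametrize("sf0", [-0.1, 0.0, 0.5, 0.9])
    def test_invalid_sf0_rejected(self, sf0):
        with pytest.raises(ValueError):
            NoiseParams(sf0=sf0)

    def test_too_small_size_rejected(self):
        with pytest.raises(ValueError):
            generate_noise(NoiseParams(), 16)


class TestTargetPosition:
    def test_zero_eccentricity_is_center(self):
        assert sample_target_position(np.random.default_rng(0), 0) == (0, 0)

    def test_azimuth_isotropy(self):
        rng = np.random.default_rng(42)
        phis = []
        for _ in range(10_000):
            r, c = sample_target_position(rng, 40)
            phis.append(np.arctan2(r, c) % (2 * np.pi))
        counts, _ = np.histogram(phis, bins=12, range=(0, 2 * np.pi))
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_infeasible_eccentricity_rejected(self):
        with pytest.raises(ValueError):
            sample_target_position(np.random.default_rng(0), 63)

    def test_max_admissible_radius(self):
        # 28x28 footprint corner at r + 14*sqrt(2) must stay inside 64
        assert max_admissible_eccentricity() == pytest.approx(64 - 14 * np.sqrt(2))


class TestEmbedding:
    def _texture(self):
        return generate_noise(NoiseParams(seed=3), 128)

    def test_zero_contrast_is_identity_inside_mask(self):
        tex = self._texture()
        disp = embed_target(tex, np.ones((28, 28)),
                            TargetSpec(label=0, position=(5, -7), contrast=0.0))
        yy, xx = np.ogrid[:128, :128]
        inside = np.hypot(yy - 64, xx - 64) <= 64
        assert np.array_equal(disp.pixels[inside], tex[inside])

    def test_opaque_blend_takes_pixel_max(self):
        tex = np.full((128, 128), 0.3)
        disp = embed_target(tex, np.ones((28, 28)),
                            TargetSpec(label=0, position=(0, 0), contrast=0.7))
        assert disp.pixels[64, 64] == pytest.approx(0.7)

    def test_transparent_blend_takes_pixel_mean(self):
        tex = np.full((128, 128), 0.3)
        disp = embed_target(tex, np.ones((28, 28)),
                            TargetSpec(label=0, position=(0, 0), contrast=0.7,
                                       blend="transparent"))
        assert disp.pixels[64, 64] == pytest.approx(0.5)

    def test_opaque_blend_idempotent_and_commutative(self):
        rng = np.random.default_rng(0)
        a, b = rng.random((128, 128)), np.zeros((128, 128))
        spec = TargetSpec(label=0, position=(0, 0), contrast=1.0)
        tgt = rng.random((28, 28))
        once = embed_target(a, tgt, spec).pixels
        twice = embed_target(once, tgt, spec).pixels
        assert np.array_equal(once, twice)

    def test_mask_zeroes_outside_radius(self):
        disp = embed_target(self._texture(), np.ones((28, 28)),
                            TargetSpec(label=0, position=(10, 10), contrast=0.5))
        yy, xx = np.ogrid[:128, :128]
        assert (disp.pixels[np.hypot(yy - 64, xx - 64) > 64] == 0).all()

    def test_footprint_outside_mask_rejected(self):
        with pytest.raises(ValueError):
            embed_target(self._texture(), np.ones((28, 28)),
                         TargetSpec(label=0, position=(60, 0), contrast=0.5))


class TestMakeTrial:
    @pytest.fixture(scope="class")
    def bank(self):
        return make_glyph_dataset(5, seed=0)

    def test_deterministic_under_seed(self, bank):
        d1 = make_trial(np.random.default_rng(7), bank)
        d2 = make_trial(np.random.default_rng(7), bank)
        assert np.array_equal(d1.pixels, d2.pixels)
        assert d1.target == d2.target

    def test_degenerate_contrast_range(self, bank):
        rng = np.random.default_rng(0)
        contrasts = {make_trial(rng, bank, (0.7, 0.7)).target.contrast
                     for _ in range(50)}
        assert contrasts == {0.7}

    def test_eccentricity_choice_policy_uniform(self, bank):
        rng = np.random.default_rng(1)
        eccs = [4.0, 16.0, 28.0, 40.0]
        drawn = [make_trial(rng, bank, (0.5, 0.5), eccs).target.eccentricity
                 for _ in range(2000)]
        # each requested ring hit about equally often (rounding tolerance 1px)
        counts = [sum(abs(d - e) <= 1.5 for d in drawn) for e in eccs]
        assert stats.chisquare(counts).pvalue > 1e-3

    def test_empty_bank_rejected(self, bank):
        from whatwhere.glyphs import TargetBank

        empty = TargetBank(images=np.empty((0, 28, 28)), labels=np.empty(0, int))
        with pytest.raises(ValueError):
            make_trial(np.random.default_rng(0), empty)


def test_display_roundtrip_png_json(tmp_path):
    bank = make_glyph_dataset(2, seed=0)
    disp = make_trial(np.random.default_rng(0), bank)
    from whatwhere.display import load_display, save_display

    save_display(disp, tmp_path / "trial")
    back = load_display(tmp_path / "trial")
    assert back.target == disp.target
    assert np.abs(back.pixels - disp.pixels).max() <= 1 / 255 + 1e-9
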