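"""Generative model of the visual display.

A trial display is a 128x128 grayscale scene: an isotropic band-pass
noise texture ("clutter"), one 28x28 target embedded at a random
position, and a circular mask of radius 64 px outside of which every
pixel is exactly zero.  The clutter emulates natural-image statistics
and is controlled by two parameters: the median spatial frequency
``sf0`` (cycles/pixel) of its amplitude spectrum and the bandwidth
``b_sf`` (octaves) around it.

Coordinate convention: 0-based row/col indexing; the display center is
pixel ``(size//2, size//2)``; a target *position* is the (row, col)
displacement of the target's center pixel (index 14 of the 28x28
footprint) from the display center; eccentricity is the Euclidean pixel
distance of that displacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

TARGET_SIZE = 28
TARGET_HALF = TARGET_SIZE // 2  # center pixel index within the footprint
DISPLAY_SIZE = 128
MASK_RADIUS = 64


@dataclass(frozen=True)
class NoiseParams:
    """Band-pass clutter parameters.

    sf0   -- median spatial frequency, cycles/pixel, in (0, 0.5)
    b_sf  -- bandwidth (std of log2-frequency), octaves, > 0
    seed  -- RNG seed for the white-noise draw
    """

    sf0: float = 0.1
    b_sf: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.sf0 < 0.5:
            raise ValueError(f"sf0 must lie in (0, 0.5), got {self.sf0}")
        if self.b_sf <= 0:
            raise ValueError(f"b_sf must be positive, got {self.b_sf}")


@dataclass(frozen=True)
class TargetSpec:
    """Ground truth of the embedded target (hidden from the agent)."""

    label: int
    position: tuple[int, int]  # (row, col) displacement from display center
    contrast: float = 1.0
    blend: str = "opaque"  # or "transparent"

    def __post_init__(self):
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in [0, 1], got {self.contrast}")
        if self.blend not in ("opaque", "transparent"):
            raise ValueError(f"unknown blend mode {self.blend!r}")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(*self.position))


@dataclass
class Display:
    """One generated scene with its hidden ground truth."""

    pixels: np.ndarray  # (size, size) float in [0, 1]
    target: TargetSpec
    mask_radius: int = MASK_RADIUS

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    @property
    def center(self) -> tuple[int, int]:
        return (self.size // 2, self.size // 2)


def _radial_frequency_grid(size: int) -> np.ndarray:
    fr = np.fft.fftfreq(size)[:, None]
    fc = np.fft.rfftfreq(size)[None, :]
    return np.hypot(fr, fc)


def noise_envelope(f: np.ndarray, sf0: float, b_sf: float) -> np.ndarray:
    """Radial amplitude envelope: log-normal in frequency with a 1/f
    prefactor so that ``sf0`` is the median of the ring-averaged
    amplitude spectrum (the natural-image-like 1/f trend makes the
    log-normal symmetric in log-frequency under a d(log f) measure)."""
    sigma = b_sf * np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.log(f / sf0)
        env = (sf0 / f) * np.exp(-0.5 * (logr / sigma) ** 2)
    env[f == 0] = 0.0
    return env


def generate_noise(params: NoiseParams, size: int = DISPLAY_SIZE,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Band-pass filtered white noise, min-max rescaled to fill [0, 1]."""
    if size < 32:
        raise ValueError("size must be >= 32")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    white = rng.standard_normal((size, size))
    spectrum = np.fft.rfft2(white) * noise_envelope(
        _radial_frequency_grid(size), params.sf0, params.b_sf)
    tex = np.fft.irfft2(spectrum, s=(size, size))
    lo, hi = tex.min(), tex.max()
    if hi - lo < 1e-12:  # degenerate (e.g. zero-variance draw)
        return np.zeros_like(tex)
    return (tex - lo) / (hi - lo)


def max_admissible_eccentricity(size: int = DISPLAY_SIZE,
                                mask_radius: int = MASK_RADIUS) -> float:
    """Largest eccentricity feasible at every azimuth (worst case is the
    diagonal, where the footprint corner sits at r + 14*sqrt(2))."""
    return mask_radius - TARGET_HALF * np.sqrt(2.0)


def _position_admissible(row: int, col: int, mask_radius: int = MASK_RADIUS) -> bool:
    return np.hypot(abs(row) + TARGET_HALF, abs(col) + TARGET_HALF) <= mask_radius


def sample_target_position(rng: np.random.Generator,
                           eccentricity: float | str = "uniform",
                           mask_radius: int = MASK_RADIUS) -> tuple[int, int]:
    """Draw a target position.

    With a numeric ``eccentricity`` the azimuth is uniform in [0, 2pi)
    (isotropic generation); with ``"uniform"`` the position is uniform
    over all admissible integer positions inside the mask.
    """
    if isinstance(eccentricity, str):
        if eccentricity != "uniform":
            raise ValueError(f"unknown eccentricity policy {eccentricity!r}")
        lim = int(max_admissible_eccentricity(mask_radius=mask_radius)) + 1
        while True:
            row, col = (int(v) for v in rng.integers(-lim, lim + 1, size=2))
            if _position_admissible(row, col, mask_radius):
                return (row, col)
    ecc = float(eccentricity)
    if ecc == 0:
        return (0, 0)
    if ecc > max_admissible_eccentricity(mask_radius=mask_radius):
        raise ValueError(
            f"eccentricity {ecc} leaves no room for the 28x28 footprint "
            f"inside the radius-{mask_radius} mask at every azimuth")
    phi = rng.uniform(0.0, 2 * np.pi)
    return (int(np.rint(ecc * np.sin(phi))), int(np.rint(ecc * np.cos(phi))))


def rectify_target(target_image: np.ndarray, contrast: float) -> np.ndarray:
    """Clamp to [0, 1] then scale by the contrast factor."""
    return np.clip(target_image, 0.0, 1.0) * contrast


def embed_target(texture: np.ndarray, target_image: np.ndarray,
                 spec: TargetSpec, mask_radius: int = MASK_RADIUS) -> Display:
    """Merge target and clutter, then apply the circular mask.

    Opaque blend takes the per-pixel max over the footprint; transparent
    takes the per-pixel mean (50/50).  Outside the footprint the texture
    is untouched; outside the mask every pixel is set to 0.
    """
    size = texture.shape[0]
    if target_image.shape != (TARGET_SIZE, TARGET_SIZE):
        raise ValueError("target image must be 28x28")
    row, col = spec.position
    if not _position_admissible(row, col, mask_radius):
        raise ValueError(f"target footprint at {spec.position} exits the mask")
    center = size // 2
    r0 = center + row - TARGET_HALF
    c0 = center + col - TARGET_HALF
    pixels = texture.astype(np.float64).copy()
    patch = pixels[r0:r0 + TARGET_SIZE, c0:c0 + TARGET_SIZE]
    tgt = rectify_target(target_image, spec.contrast)
    if spec.blend == "opaque":
        np.maximum(patch, tgt, out=patch)
    else:
        patch[...] = 0.5 * (patch + tgt)
    yy, xx = np.ogrid[:size, :size]
    outside = np.hypot(yy - center, xx - center) > mask_radius
    pixels[outside] = 0.0
    return Display(pixels=np.clip(pixels, 0.0, 1.0), target=spec,
                   mask_radius=mask_radius)


def make_trial(rng: np.random.Generator,
               target_bank,
               contrast_range: tuple[float, float] = (0.3, 0.7),
               eccentricity_policy: float | str | list | tuple = "uniform",
               noise: NoiseParams = NoiseParams(),
               blend: str = "opaque",
               noise_gain: float = 1.0) -> Display:
    """Generate one full trial display.

    ``target_bank`` exposes ``images`` (n, 28, 28) and ``labels`` (n,).
    ``eccentricity_policy`` is ``"uniform"`` (uniform over admissible
    positions), a number (fixed eccentricity, uniform azimuth), a
    sequence of eccentricities to choose from uniformly, or
    ``("gaussian", std)`` (bivariate Gaussian offset, redrawn until
    admissible).  ``noise_gain`` scales the clutter amplitude.
    """
    if len(target_bank.images) == 0:
        raise ValueError("empty target bank")
    idx = int(rng.integers(len(target_bank.images)))
    contrast = float(rng.uniform(*contrast_range))
    policy = eccentricity_policy
    if isinstance(policy, tuple) and len(policy) == 2 and policy[0] == "gaussian":
        std = float(policy[1])
        while True:
            row, col = (int(v) for v in np.rint(rng.normal(0.0, std, size=2)))
            if _position_admissible(row, col):
                position = (row, col)
                break
    else:
        if isinstance(policy, (list, tuple, np.ndarray)):
            policy = float(rng.choice(np.asarray(policy, dtype=float)))
        position = sample_target_position(rng, policy)
    spec = TargetSpec(label=int(target_bank.labels[idx]), position=position,
                      contrast=contrast, blend=blend)
    texture = generate_noise(noise, rng=rng) * noise_gain
    return embed_target(texture, target_bank.images[idx], spec)


# -- persistence ----------------------------------------------------------

def save_display(display: Display, path: str | Path):
    """8-bit grayscale PNG plus a JSON sidecar with the ground truth."""
    from PIL import Image

    path = Path(path)
    img = Image.fromarray((display.pixels * 255).round().astype(np.uint8))
    img.save(path.with_suffix(".png"))
    meta = {"label": display.target.label,
            "position": list(display.target.position),
            "contrast": display.target.contrast,
            "blend": display.target.blend,
            "mask_radius": display.mask_radius}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_display(path: str | Path) -> Display:
    from PIL import Image

    path = Path(path)
    pixels = np.asarray(Image.open(path.with_suffix(".png")), dtype=np.float64) / 255.0
    meta = json.loads(path.with_suffix(".json").read_text())
    spec = TargetSpec(label=meta["label"], position=tuple(meta["position"]),
                      contrast=meta["contrast"], blend=meta["blend"])
    return Display(pixels=pixels, target=spec, mask_radius=meta["mask_radius"])
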