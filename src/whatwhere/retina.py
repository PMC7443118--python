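"""Log-polar retinal encoding.

The peripheral observation is produced by a fixed bank of oriented
log-Gabor filters whose centers sit on a log-polar grid: 10 eccentricity
rings (at ~2 .. 51.3 px from fixation) x 24 azimuths x 6 orientations x
2 phases (even "symmetric" and odd "antisymmetric"), i.e. 2,880
coefficients for a 128x128 display — a compression of ~83% relative to
the 16,384 input pixels, with high spatial frequencies preserved only
near the center.  Filter size grows proportionally to eccentricity
(constant-octave log-Gabors do this by construction), emulating the
cortical magnification of primate V1.

Before filtering, images are whitened (amplitude-spectrum flattening)
so that coefficient magnitudes are balanced across eccentricity scales.

The bank is one dense matrix ``T`` (features x pixels); encoding a
batch is a single matrix product, and a Moore-Penrose pseudo-inverse of
``T`` provides least-squares image reconstructions for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .display import Display, TARGET_SIZE, TARGET_HALF

DEFAULT_ECCENTRICITIES = (2.0, 3.0, 4.5, 6.5, 9.0, 13.0, 18.0, 26.0, 36.5, 51.3)


@dataclass(frozen=True)
class LogPolarGrid:
    """Retinotopic coordinate system shared by the feature vector and the
    collicular map.

    eccentricities -- ring radii in pixels, strictly increasing
    n_azimuth      -- azimuth samples per ring
    n_theta        -- edge orientations per node
    n_phase        -- phases per orientation (even/odd)
    size_ratio     -- filter spatial extent / eccentricity
    """

    eccentricities: tuple[float, ...] = DEFAULT_ECCENTRICITIES
    n_azimuth: int = 24
    n_theta: int = 6
    n_phase: int = 2
    size_ratio: float = 0.8

    def __post_init__(self):
        ecc = np.asarray(self.eccentricities)
        if not (np.diff(ecc) > 0).all():
            raise ValueError("eccentricities must be strictly increasing")

    @property
    def n_eccentricity(self) -> int:
        return len(self.eccentricities)

    @property
    def feature_dim(self) -> int:
        return self.n_eccentricity * self.n_azimuth * self.n_theta * self.n_phase

    @property
    def map_dim(self) -> int:
        return self.n_eccentricity * self.n_azimuth

    def azimuths(self) -> np.ndarray:
        return 2 * np.pi * np.arange(self.n_azimuth) / self.n_azimuth

    def cell_center(self, i_ecc: int, i_az: int) -> tuple[float, float]:
        """(row, col) displacement of a grid node from fixation."""
        r = self.eccentricities[i_ecc]
        phi = 2 * np.pi * i_az / self.n_azimuth
        return (r * np.sin(phi), r * np.cos(phi))


@dataclass
class RetinalFeatures:
    """The agent's peripheral observation x."""

    coefficients: np.ndarray
    grid: LogPolarGrid

    def __post_init__(self):
        if self.coefficients.shape != (self.grid.feature_dim,):
            raise ValueError("coefficient length does not match the grid")


# -- whitening ------------------------------------------------------------

def _radial_frequency_grid(size: int) -> np.ndarray:
    fr = np.fft.fftfreq(size)[:, None]
    fc = np.fft.rfftfreq(size)[None, :]
    return np.hypot(fr, fc)


def whitening_filter(f: np.ndarray, f_cutoff: float = 0.4) -> np.ndarray:
    """Isotropic retina-like amplitude ramp f * exp(-(f/f_c)^4)."""
    return f * np.exp(-((f / f_cutoff) ** 4))


def whiten(image: np.ndarray, f_cutoff: float = 0.4) -> np.ndarray:
    """Flatten the amplitude spectrum of a grayscale image.

    Linear and translation-equivariant (a pure convolution); a constant
    image maps to zero since the DC gain is zero.
    """
    size = image.shape[0]
    spectrum = np.fft.rfft2(image)
    spectrum *= whitening_filter(_radial_frequency_grid(size), f_cutoff)
    return np.fft.irfft2(spectrum, s=image.shape)


# -- filter bank ----------------------------------------------------------

def _log_gabor_spectrum(size: int, f_peak: float, theta: float,
                        sigma_log: float, sigma_theta: float) -> np.ndarray:
    """Complex half-plane log-Gabor in the Fourier domain (full fft grid)."""
    fr = np.fft.fftfreq(size)[:, None]
    fc = np.fft.fftfreq(size)[None, :]
    f = np.hypot(fr, fc)
    with np.errstate(divide="ignore"):
        radial = np.exp(-0.5 * (np.log(f / f_peak) / sigma_log) ** 2)
    radial[f == 0] = 0.0
    ang = np.arctan2(fr, fc)
    dtheta = np.angle(np.exp(1j * (ang - theta)))  # wrapped difference
    angular = np.exp(-0.5 * (dtheta / sigma_theta) ** 2)
    return radial * angular


def build_filterbank(grid: LogPolarGrid, image_size: int = 128,
                     dtype=np.float32) -> np.ndarray:
    """Dense linear transform (feature_dim x image_size**2).

    Each row is one oriented log-Gabor centered at a grid node; the even
    and odd phases are the real and imaginary parts of the analytic
    filter.  Each row is normalized so that its composition with the
    whitening front end has unit L2 norm: coefficient magnitudes are
    then balanced across eccentricity scales on white-noise input, which
    is the purpose of whitening before this bank.

    Emits a warning in the build log (returned array's metadata is not
    carried; a UserWarning is raised) if the outermost filters extend
    substantially beyond the image.
    """
    import warnings

    outer = grid.eccentricities[-1] * (1 + grid.size_ratio)
    if outer > 1.5 * image_size / 2:
        warnings.warn("outermost filters are clipped by more than 50%")

    n_px = image_size * image_size
    rows = np.empty((grid.feature_dim, n_px), dtype=dtype)
    center = image_size // 2
    sigma_log = 0.55 / grid.size_ratio  # constant-octave bandwidth
    sigma_theta = np.pi / grid.n_theta
    fr = np.fft.fftfreq(image_size)[:, None]
    fc = np.fft.fftfreq(image_size)[None, :]
    wfreq = whitening_filter(np.hypot(fr, fc))
    k = 0
    for i_ecc, ecc in enumerate(grid.eccentricities):
        f_peak = min(0.45, 1.0 / (2.0 * grid.size_ratio * ecc))
        for i_az in range(grid.n_azimuth):
            drow, dcol = grid.cell_center(i_ecc, i_az)
            # phase ramp shifts the filter to its (sub-pixel) node
            ramp = np.exp(-2j * np.pi * (fr * (center + drow) + fc * (center + dcol)))
            for i_theta in range(grid.n_theta):
                theta = np.pi * i_theta / grid.n_theta
                spec = _log_gabor_spectrum(image_size, f_peak, theta,
                                           sigma_log, sigma_theta)
                kernel = np.fft.ifft2(spec * ramp)
                whitened = np.fft.ifft2(spec * ramp * wfreq)
                for part, wpart in (((kernel.real, whitened.real),
                                     (kernel.imag, whitened.imag))[:grid.n_phase]):
                    norm = np.linalg.norm(wpart)
                    rows[k] = part.ravel() / norm if norm > 0 else part.ravel()
                    k += 1
    assert k == grid.feature_dim
    return rows


def pseudo_inverse(transform: np.ndarray, rcond: float = 1e-7) -> np.ndarray:
    """Truncated-SVD Moore-Penrose pseudo-inverse of the filter bank.

    The bank's singular spectrum decays continuously (the code is
    overcomplete per pixel area at the center, undercomplete at the
    periphery), so the cutoff trades reconstruction stability against
    fidelity of the Moore-Penrose identity T T+ T = T; the truncated
    directions bound the identity error at ``rcond`` relative.
    """
    return np.linalg.pinv(transform.astype(np.float64), rcond=rcond)


# -- encoder --------------------------------------------------------------

class RetinalEncoder:
    """Caches the filter bank (and lazily its pseudo-inverse) for a grid."""

    def __init__(self, grid: LogPolarGrid = LogPolarGrid(), image_size: int = 128):
        self.grid = grid
        self.image_size = image_size
        self.transform = build_filterbank(grid, image_size)
        self._pinv = None

    @property
    def pinv(self) -> np.ndarray:
        if self._pinv is None:
            self._pinv = pseudo_inverse(self.transform)
        return self._pinv

    def recenter(self, pixels: np.ndarray, gaze: tuple[int, int]) -> np.ndarray:
        """Integer-pixel translation putting the gaze at the grid origin,
        zero-padding what falls outside the frame."""
        size = self.image_size
        gr, gc = int(gaze[0]), int(gaze[1])
        if not (0 <= gr < size and 0 <= gc < size):
            raise ValueError(f"gaze {gaze} outside the display")
        center = size // 2
        out = np.zeros((size, size), dtype=np.float64)
        dr, dc = center - gr, center - gc
        rs, re = max(0, dr), min(size, size + dr)
        cs, ce = max(0, dc), min(size, size + dc)
        out[rs:re, cs:ce] = pixels[rs - dr:re - dr, cs - dc:ce - dc]
        return out

    def encode(self, display: Display, gaze: tuple[int, int] | None = None) -> RetinalFeatures:
        gaze = display.center if gaze is None else gaze
        img = whiten(self.recenter(display.pixels, gaze))
        coeffs = self.transform @ img.ravel().astype(self.transform.dtype)
        return RetinalFeatures(coefficients=np.asarray(coeffs, dtype=np.float64),
                               grid=self.grid)

    def encode_batch(self, images: np.ndarray) -> np.ndarray:
        """Encode pre-centered whitened images (n, size, size) -> (n, dim)."""
        flat = images.reshape(len(images), -1).astype(self.transform.dtype)
        return flat @ self.transform.T

    def reconstruct(self, features: RetinalFeatures) -> np.ndarray:
        """Least-squares estimate of the whitened image (diagnostics)."""
        if features.grid != self.grid:
            raise ValueError("features come from a different grid")
        img = self.pinv @ features.coefficients
        return img.reshape(self.image_size, self.image_size)


def crop_fovea(display: Display, gaze: tuple[int, int]) -> np.ndarray:
    """28x28 axis-aligned crop centered on gaze, zero-padded at borders."""
    size = display.size
    gr, gc = int(gaze[0]), int(gaze[1])
    patch = np.zeros((TARGET_SIZE, TARGET_SIZE), dtype=np.float64)
    r0, c0 = gr - TARGET_HALF, gc - TARGET_HALF
    rs, re = max(0, r0), min(size, r0 + TARGET_SIZE)
    cs, ce = max(0, c0), min(size, c0 + TARGET_SIZE)
    if rs < re and cs < ce:
        patch[rs - r0:re - r0, cs - c0:ce - c0] = display.pixels[rs:re, cs:ce]
    return patch
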