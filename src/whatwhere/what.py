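"""The "What" pathway: foveal classification and its transfer curve.

A LeNet-style convolutional classifier reads the 28x28 foveal patch and
outputs, through a sigmoid on each of 10 units, the per-class detection
likelihood.  The maximum likelihood is the *foveal accuracy* — the
critic signal of the architecture.  Training is in two stages: first on
centered targets, then on a curriculum of cluttered patches whose
random shifts grow progressively (std +1 every 5 epochs up to 15,
shifts clipped at 27 px) with contrast drawn from U[0.3, 0.7].

After training, accuracy is measured on a grid of target shifts within
+-27 px to form the 55x55 shift-dependent accuracy map — the empirical
transfer curve used to build ground-truth collicular maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .display import NoiseParams, generate_noise, rectify_target, TARGET_SIZE, TARGET_HALF
from .glyphs import TargetBank, N_CLASSES

MAX_SHIFT = 27
SHIFT_MAP_SIDE = 2 * MAX_SHIFT + 1  # 55


@dataclass
class ClassPosterior:
    """Per-class detection likelihoods p(y|x) at the fovea."""

    likelihoods: np.ndarray  # (10,) in [0, 1]

    @property
    def foveal_accuracy(self) -> float:
        return float(self.likelihoods.max())

    @property
    def label(self) -> int:
        return int(self.likelihoods.argmax())


@dataclass
class ShiftAccuracyMap:
    """Empirical accuracy vs. target shift on a (2*max_shift+1)^2 grid."""

    values: np.ndarray  # (55, 55) in [0, 1]
    n_samples: int
    max_shift: int = MAX_SHIFT

    def __post_init__(self):
        side = 2 * self.max_shift + 1
        if self.values.shape != (side, side):
            raise ValueError(f"expected {side}x{side} map, got {self.values.shape}")

    @property
    def border_level(self) -> float:
        """Mean accuracy on the outermost ring of the grid (~ chance);
        used as the padding level beyond the measured support."""
        v = self.values
        border = np.concatenate([v[0], v[-1], v[1:-1, 0], v[1:-1, -1]])
        return float(border.mean())

    def at(self, shift: tuple[int, int]) -> float:
        r = int(shift[0]) + self.max_shift
        c = int(shift[1]) + self.max_shift
        return float(self.values[r, c])


@dataclass(frozen=True)
class CurriculumSchedule:
    """Stepwise growth of the shift variability across epochs."""

    n_epochs: int = 75
    samples_per_epoch: int = 60_000
    epochs_per_step: int = 5
    std_increment: float = 1.0
    std_max: float = 15.0
    max_shift: int = MAX_SHIFT
    contrast_range: tuple[float, float] = (0.3, 0.7)

    def shift_std(self, epoch: int) -> float:
        return min((epoch // self.epochs_per_step) * self.std_increment,
                   self.std_max)

    def sample_shifts(self, epoch: int, n: int,
                      rng: np.random.Generator) -> np.ndarray:
        std = self.shift_std(epoch)
        shifts = np.rint(rng.normal(0.0, std, size=(n, 2)))
        return np.clip(shifts, -self.max_shift, self.max_shift).astype(int)


def build_classifier(rng: np.random.Generator | None = None) -> nn.Sequential:
    """Three conv layers each followed by max-pooling, then two fully
    connected layers; ReLU throughout, 10 sigmoid outputs.  The pooling
    cascade (28 -> 14 -> 7 -> 3) is what buys the classifier its partial
    shift tolerance."""
    rng = np.random.default_rng(0) if rng is None else rng
    return nn.Sequential([
        nn.Conv2d(1, 8, 5, rng), nn.ReLU(), nn.MaxPool2d(2),    # 28 -> 14
        nn.Conv2d(8, 16, 3, rng), nn.ReLU(), nn.MaxPool2d(2),   # 14 -> 7
        nn.Conv2d(16, 32, 3, rng), nn.ReLU(), nn.MaxPool2d(2),  # 7 -> 3
        nn.Flatten(),
        nn.Linear(32 * 3 * 3, 128, rng), nn.ReLU(),
        nn.Linear(128, N_CLASSES, rng),
    ])


def predict(model: nn.Sequential, patch: np.ndarray) -> ClassPosterior:
    if patch.shape != (TARGET_SIZE, TARGET_SIZE):
        raise ValueError(f"patch must be 28x28, got {patch.shape}")
    probs = model.predict(patch[None, None, :, :])[0]
    return ClassPosterior(likelihoods=probs.astype(np.float64))


def predict_batch(model: nn.Sequential, patches: np.ndarray) -> np.ndarray:
    """(n, 28, 28) -> (n, 10) likelihoods."""
    return model.predict(patches[:, None, :, :])


# -- cluttered patch generation ------------------------------------------

def make_cluttered_patch(rng: np.random.Generator, target_image: np.ndarray,
                         shift: tuple[int, int], contrast: float,
                         noise: NoiseParams, blend: str = "opaque",
                         noise_size: int = 128) -> np.ndarray:
    """A 28x28 foveal patch: band-pass clutter with the target placed at
    ``shift`` from the patch center (pixels leaving the patch are cut).

    Equivalent to generating a full display and cropping the fovea at a
    gaze offset of -shift from the target, at a fraction of the cost.
    The clutter is normalized at full display size before cropping so
    its local contrast statistics match the display crops.
    """
    m = noise_size // 2 - TARGET_HALF
    tex = generate_noise(noise, size=noise_size, rng=rng)[m:m + TARGET_SIZE,
                                                          m:m + TARGET_SIZE]
    tgt = rectify_target(target_image, contrast)
    out = tex.copy()
    r0, c0 = int(shift[0]), int(shift[1])
    rs, re = max(0, r0), min(TARGET_SIZE, r0 + TARGET_SIZE)
    cs, ce = max(0, c0), min(TARGET_SIZE, c0 + TARGET_SIZE)
    if rs < re and cs < ce:
        sub = out[rs:re, cs:ce]
        tsub = tgt[rs - r0:re - r0, cs - c0:ce - c0]
        if blend == "opaque":
            np.maximum(sub, tsub, out=sub)
        else:
            sub[...] = 0.5 * (sub + tsub)
    return out


def _patch_batch(rng, bank: TargetBank, shifts, contrasts, noise: NoiseParams):
    patches = np.empty((len(shifts), TARGET_SIZE, TARGET_SIZE), dtype=np.float32)
    idx = rng.integers(len(bank), size=len(shifts))
    for i, (j, sh, ct) in enumerate(zip(idx, shifts, contrasts)):
        patches[i] = make_cluttered_patch(rng, bank.images[j], sh, ct, noise)
    return patches, bank.labels[np.asarray(idx)]


# -- training -------------------------------------------------------------

def _train_epochs(model, sample_batch, n_epochs, samples_per_epoch,
                  batch_size, lr, rng):
    opt = nn.Adam(model.params(), lr=lr)
    for epoch in range(n_epochs):
        for _ in range(max(1, samples_per_epoch // batch_size)):
            x, y = sample_batch(epoch, batch_size)
            onehot = np.eye(N_CLASSES, dtype=np.float32)[y]
            logits = model.forward(x[:, None, :, :].astype(np.float32), train=True)
            _, grad = nn.sigmoid_bce_with_logits(logits, onehot)
            model.zero_grad()
            model.backward(grad)
            opt.step()
    return model


def train_centered(model: nn.Sequential, bank: TargetBank,
                   n_epochs: int = 20, batch_size: int = 64,
                   lr: float = 1e-3, samples_per_epoch: int | None = None,
                   rng: np.random.Generator | None = None) -> nn.Sequential:
    """Stage 1: clean, centered targets (no clutter, full contrast)."""
    if len(bank) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(0) if rng is None else rng
    if samples_per_epoch is None:
        samples_per_epoch = len(bank)

    def sample(_epoch, n):
        idx = rng.integers(len(bank), size=n)
        return bank.images[idx].astype(np.float32), bank.labels[idx]

    return _train_epochs(model, sample, n_epochs, samples_per_epoch,
                         batch_size, lr, rng)


def train_curriculum(model: nn.Sequential, bank: TargetBank,
                     schedule: CurriculumSchedule = CurriculumSchedule(),
                     noise: NoiseParams = NoiseParams(),
                     batch_size: int = 64, lr: float = 1e-3,
                     rng: np.random.Generator | None = None) -> nn.Sequential:
    """Stage 2: freshly generated shifted, cluttered patches each epoch."""
    rng = np.random.default_rng(0) if rng is None else rng

    def sample(epoch, n):
        shifts = schedule.sample_shifts(epoch, n, rng)
        contrasts = rng.uniform(*schedule.contrast_range, size=n)
        return _patch_batch(rng, bank, shifts, contrasts, noise)

    return _train_epochs(model, sample, schedule.n_epochs,
                         schedule.samples_per_epoch, batch_size, lr, rng)


def evaluate_accuracy(model: nn.Sequential, patches: np.ndarray,
                      labels: np.ndarray, batch_size: int = 512) -> float:
    correct = 0
    for i in range(0, len(patches), batch_size):
        probs = predict_batch(model, patches[i:i + batch_size])
        correct += int((probs.argmax(axis=1) == labels[i:i + batch_size]).sum())
    return correct / len(patches)


def centered_validation_accuracy(model, bank: TargetBank) -> float:
    return evaluate_accuracy(model, bank.images.astype(np.float32), bank.labels)


def estimate_shift_accuracy_map(model: nn.Sequential, bank: TargetBank,
                                n_per_shift: int = 1000,
                                noise: NoiseParams = NoiseParams(),
                                contrast_range: tuple[float, float] = (0.3, 0.7),
                                shift_step: int = 1,
                                rng: np.random.Generator | None = None) -> ShiftAccuracyMap:
    """Measure accuracy on every (subsampled) target shift within
    +-27 px, ``n_per_shift`` cluttered samples per shift.  With
    ``shift_step > 1`` the grid is measured coarsely and bilinearly
    interpolated back onto the full 55x55 support."""
    if n_per_shift < 1:
        raise ValueError("n_per_shift must be >= 1")
    rng = np.random.default_rng(0) if rng is None else rng
    axis = np.arange(-MAX_SHIFT, MAX_SHIFT + 1, shift_step)
    if axis[-1] != MAX_SHIFT:
        axis = np.append(axis, MAX_SHIFT)
    acc = np.empty((len(axis), len(axis)))
    for a, dr in enumerate(axis):
        for b, dc in enumerate(axis):
            contrasts = rng.uniform(*contrast_range, size=n_per_shift)
            shifts = [(dr, dc)] * n_per_shift
            patches, labels = _patch_batch(rng, bank, shifts, contrasts, noise)
            acc[a, b] = evaluate_accuracy(model, patches, labels)
    if len(axis) < SHIFT_MAP_SIDE:
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((axis, axis), acc, method="linear")
        full = np.arange(-MAX_SHIFT, MAX_SHIFT + 1)
        rr, cc = np.meshgrid(full, full, indexing="ij")
        acc = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(
            SHIFT_MAP_SIDE, SHIFT_MAP_SIDE)
    return ShiftAccuracyMap(values=np.clip(acc, 0.0, 1.0), n_samples=n_per_shift)
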