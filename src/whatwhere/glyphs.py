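"""Target banks: a deterministic synthetic glyph set and an MNIST reader.

The glyph bank is a download-free stand-in for the handwritten-digit
set: ten programmatically rendered 28x28 stroke/curve classes with
small random affine jitter (rotation, translation, scale) providing
within-class variability.  It is easier (more separable) than real
handwriting by design; glyph-based runs exercise every code path and
support property tests, not published-scale accuracy reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

N_CLASSES = 10
SIZE = 28


@dataclass
class TargetBank:
    """Images (n, 28, 28) in [0, 1] with integer class labels (n,)."""

    images: np.ndarray
    labels: np.ndarray
    seed: int | None = None

    def __len__(self):
        return len(self.images)


@dataclass
class GlyphBank(TargetBank):
    def split(self, val_fraction: float = 0.2) -> tuple[TargetBank, TargetBank]:
        """Deterministic stratified train/validation split."""
        rng = np.random.default_rng(0 if self.seed is None else self.seed + 1)
        train_idx, val_idx = [], []
        for c in range(N_CLASSES):
            idx = np.flatnonzero(self.labels == c)
            rng.shuffle(idx)
            n_val = max(1, int(len(idx) * val_fraction)) if len(idx) > 1 else 0
            val_idx.extend(idx[:n_val])
            train_idx.extend(idx[n_val:])
        tr, va = np.sort(train_idx), np.sort(val_idx)
        return (TargetBank(self.images[tr], self.labels[tr], self.seed),
                TargetBank(self.images[va], self.labels[va], self.seed))


def _canvas():
    return np.zeros((SIZE, SIZE))


def _line(img, p0, p1, width=2.5):
    n = 60
    t = np.linspace(0, 1, n)
    pts_r = p0[0] + t * (p1[0] - p0[0])
    pts_c = p0[1] + t * (p1[1] - p0[1])
    yy, xx = np.mgrid[:SIZE, :SIZE]
    for r, c in zip(pts_r, pts_c):
        img[np.hypot(yy - r, xx - c) <= width / 2 + 0.5] = 1.0
    return img


def _ring(img, radius, width=2.5):
    yy, xx = np.mgrid[:SIZE, :SIZE]
    d = np.hypot(yy - 13.5, xx - 13.5)
    img[np.abs(d - radius) <= width / 2 + 0.3] = 1.0
    return img


def glyph_prototype(label: int) -> np.ndarray:
    """Render the noise-free prototype of one glyph class.

    Strokes are deliberately thick and shapes near full-footprint: the
    bank is meant to be an easy, well-separated surrogate target set, so
    reduced-scale training runs retain headroom under heavy clutter."""
    img = _canvas()
    c, lo, hi, w = 13.5, 4.0, 23.0, 4.0
    yy, xx = np.mgrid[:SIZE, :SIZE]
    if label == 0:      # ring
        _ring(img, 9.0, 4.0)
    elif label == 1:    # vertical bar
        _line(img, (lo, c), (hi, c), w)
    elif label == 2:    # horizontal bar
        _line(img, (c, lo), (c, hi), w)
    elif label == 3:    # plus
        _line(img, (lo, c), (hi, c), w)
        _line(img, (c, lo), (c, hi), w)
    elif label == 4:    # X
        _line(img, (lo, lo), (hi, hi), w)
        _line(img, (lo, hi), (hi, lo), w)
    elif label == 5:    # filled disk
        img[np.hypot(yy - c, xx - c) <= 8.0] = 1.0
    elif label == 6:    # square outline
        for p0, p1 in [((lo, lo), (lo, hi)), ((lo, hi), (hi, hi)),
                       ((hi, hi), (hi, lo)), ((hi, lo), (lo, lo))]:
            _line(img, p0, p1, w)
    elif label == 7:    # triangle outline
        a, b, d = (hi, lo), (hi, hi), (lo, c)
        for p0, p1 in [(a, b), (b, d), (d, a)]:
            _line(img, p0, p1, w)
    elif label == 8:    # two horizontal bars
        _line(img, (c - 6, lo), (c - 6, hi), w)
        _line(img, (c + 6, lo), (c + 6, hi), w)
    elif label == 9:    # one diagonal stroke
        _line(img, (hi, lo), (lo, hi), w)
    else:
        raise ValueError(f"label must be in 0..9, got {label}")
    return np.clip(ndimage.gaussian_filter(img, 0.4), 0.0, 1.0)


def _jitter(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    angle = rng.uniform(-12, 12)
    scale = rng.uniform(0.9, 1.1)
    shift = rng.uniform(-1.5, 1.5, size=2)
    a = np.deg2rad(angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]]) / scale
    center = np.array([13.5, 13.5])
    offset = center - rot @ (center + shift)
    out = ndimage.affine_transform(img, rot, offset=offset, order=1, mode="constant")
    return np.clip(out, 0.0, 1.0)


def make_glyph_dataset(n_per_class: int, seed: int = 0) -> GlyphBank:
    """Deterministic jittered glyph bank with ``n_per_class`` images per
    class; the first image of each class is the unjittered prototype."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for label in range(N_CLASSES):
        proto = glyph_prototype(label)
        images.append(proto)
        labels.append(label)
        for _ in range(n_per_class - 1):
            images.append(_jitter(proto, rng))
            labels.append(label)
    return GlyphBank(images=np.stack(images), labels=np.asarray(labels), seed=seed)


def export_glyphs(bank: GlyphBank, out_dir: str | Path):
    """Write the bank as PNGs plus a labels CSV."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["filename,label"]
    for i, (img, label) in enumerate(zip(bank.images, bank.labels)):
        name = f"glyph_{i:05d}.png"
        Image.fromarray((img * 255).round().astype(np.uint8)).save(out / name)
        lines.append(f"{name},{label}")
    (out / "labels.csv").write_text("\n".join(lines) + "\n")


def load_mnist_idx(directory: str | Path, kind: str = "train") -> TargetBank:
    """Read the classic IDX-format handwritten-digit files from a local
    directory (``train-images-idx3-ubyte`` etc., optionally gzipped).
    Only needed for full-scale runs reproducing published accuracies;
    never used by the test suite."""
    import gzip

    directory = Path(directory)
    prefix = "train" if kind == "train" else "t10k"

    def _read(name):
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                opener = gzip.open if cand.suffix == ".gz" else open
                with opener(cand, "rb") as fh:
                    return fh.read()
        raise FileNotFoundError(f"{name}[.gz] not found in {directory}")

    raw = _read(f"{prefix}-images-idx3-ubyte")
    n = int.from_bytes(raw[4:8], "big")
    images = np.frombuffer(raw, np.uint8, offset=16).reshape(n, 28, 28) / 255.0
    raw = _read(f"{prefix}-labels-idx1-ubyte")
    labels = np.frombuffer(raw, np.uint8, offset=8).astype(np.int64)
    return TargetBank(images=images, labels=labels)
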