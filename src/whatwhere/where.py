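"""The "Where" pathway: retinal features -> predicted collicular map.

A fully connected network (2,880 -> 1,000 -> 1,000 -> 240 in the
reference configuration) with ReLU hidden layers, batch normalization
and a sigmoid output maps the log-polar feature vector to a predicted
accuracy for every saccade cell.  It is trained against ground-truth
maps built from the What pathway's shift-accuracy transfer curve, with
per-cell binary cross-entropy averaged over cells — the cells are
independent Bernoulli accuracies, not a normalized distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .colliculus import CollicularMap, ground_truth_map
from .display import NoiseParams, make_trial
from .retina import LogPolarGrid, RetinalEncoder, RetinalFeatures, whiten


@dataclass(frozen=True)
class WhereConfig:
    hidden_sizes: tuple[int, int] = (1000, 1000)
    lr: float = 1e-4
    n_epochs: int = 60
    samples_per_epoch: int = 60_000
    batch_size: int = 256
    batch_norm: bool = True

    def __post_init__(self):
        if min(self.hidden_sizes) <= 0 or self.lr <= 0:
            raise ValueError("sizes and learning rate must be positive")


def build_where_net(config: WhereConfig, grid: LogPolarGrid,
                    rng: np.random.Generator | None = None) -> nn.Sequential:
    rng = np.random.default_rng(0) if rng is None else rng
    h1, h2 = config.hidden_sizes
    layers: list[nn.Layer] = [nn.Linear(grid.feature_dim, h1, rng)]
    if config.batch_norm:
        layers.append(nn.BatchNorm1d(h1))
    layers.append(nn.ReLU())
    layers.append(nn.Linear(h1, h2, rng))
    if config.batch_norm:
        layers.append(nn.BatchNorm1d(h2))
    layers.append(nn.ReLU())
    out = nn.Linear(h2, grid.map_dim, rng)
    # start from the chance prior: most cells sit near the 10% baseline,
    # so initializing the output bias at logit(0.1) removes a long
    # "learn the base rate" transient from training
    out.b.value[:] = np.log(0.1 / 0.9)
    layers.append(out)
    return nn.Sequential(layers)


def predict_map(model: nn.Sequential, features: RetinalFeatures) -> CollicularMap:
    x = features.coefficients[None, :].astype(np.float32)
    if x.shape[1] != model.layers[0].W.value.shape[0]:
        raise ValueError("feature length does not match the network input")
    values = model.predict(x)[0].astype(np.float64)
    return CollicularMap(values=values, grid=features.grid)


def make_where_dataset(n: int, bank, shift_map, projection,
                       encoder: RetinalEncoder,
                       noise: NoiseParams = NoiseParams(),
                       contrast_range: tuple[float, float] = (0.3, 0.7),
                       eccentricity_policy="uniform",
                       rng: np.random.Generator | None = None):
    """Generate ``n`` (features, ground-truth map) training pairs.

    Displays are generated fresh, encoded at central fixation; the
    target ground truth is converted to a collicular map on the fly (the
    computational shortcut justified by the position-independence of the
    categorical performance).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    grid = encoder.grid
    X = np.empty((n, grid.feature_dim), dtype=np.float32)
    Y = np.empty((n, grid.map_dim), dtype=np.float32)
    batch_imgs = []
    batch_rows = []
    for i in range(n):
        disp = make_trial(rng, bank, contrast_range, eccentricity_policy, noise)
        batch_imgs.append(whiten(disp.pixels))
        batch_rows.append(i)
        Y[i] = ground_truth_map(disp.target.position, shift_map, projection,
                                grid, display_size=disp.size).values
        if len(batch_imgs) == 256 or i == n - 1:
            X[batch_rows] = encoder.encode_batch(np.stack(batch_imgs))
            batch_imgs, batch_rows = [], []
    return X, Y


def train_where(model: nn.Sequential, X: np.ndarray, Y: np.ndarray,
                config: WhereConfig,
                rng: np.random.Generator | None = None,
                n_epochs: int | None = None) -> list[float]:
    """Train on pre-generated pairs; returns the per-epoch mean BCE."""
    rng = np.random.default_rng(0) if rng is None else rng
    opt = nn.Adam(model.params(), lr=config.lr)
    n_epochs = config.n_epochs if n_epochs is None else n_epochs
    losses = []
    for _ in range(n_epochs):
        order = rng.permutation(len(X))
        epoch_loss, n_batches = 0.0, 0
        for s in range(0, len(X), config.batch_size):
            idx = order[s:s + config.batch_size]
            if len(idx) < 2:  # batch-norm needs at least two samples
                continue
            logits = model.forward(X[idx], train=True)
            loss, grad = nn.sigmoid_bce_with_logits(logits, Y[idx])
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(1, n_batches))
    return losses


def validation_bce(model: nn.Sequential, X: np.ndarray, Y: np.ndarray) -> float:
    logits = model.forward(X.astype(np.float32), train=False)
    loss, _ = nn.sigmoid_bce_with_logits(logits, Y)
    return loss


def bce_entropy_floor(Y: np.ndarray) -> float:
    """BCE of the ground-truth maps against themselves: the per-cell
    Bernoulli entropy, the irreducible floor of the training loss."""
    return float(nn.bernoulli_entropy(Y).mean())
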