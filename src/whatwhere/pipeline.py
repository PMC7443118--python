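"""End-to-end training pipeline and system persistence.

Order matters: the What classifier (the critic) is trained first, its
shift-accuracy transfer curve is measured, and only then is the Where
network (the actor) trained against ground-truth collicular maps built
from that curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import what as what_mod
from . import where as where_mod
from .agent import SaccadeAgent
from .colliculus import build_projection
from .config import Profile, ci_profile
from .glyphs import TargetBank, make_glyph_dataset
from .retina import RetinalEncoder
from .what import ShiftAccuracyMap


@dataclass
class TrainedSystem:
    what_model: object
    shift_map: ShiftAccuracyMap
    where_model: object
    encoder: RetinalEncoder
    projection: np.ndarray
    profile: Profile
    seed: int
    where_losses: list | None = None
    centered_val_accuracy: float | None = None  # after stage 1, clean targets

    @property
    def grid(self):
        return self.encoder.grid

    def agent(self) -> SaccadeAgent:
        return SaccadeAgent(self.what_model, self.where_model, self.encoder)


def child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Fan one master seed out to independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def train_what(profile: Profile, train_bank: TargetBank, seed: int,
               val_bank: TargetBank | None = None):
    """Returns (model, clean validation accuracy after the centered stage)."""
    rng_init, rng_centered, rng_curr = child_rngs(seed, 3)
    model = what_mod.build_classifier(rng_init)
    what_mod.train_centered(model, train_bank, n_epochs=profile.centered_epochs,
                            samples_per_epoch=profile.centered_samples_per_epoch,
                            lr=profile.what_lr, rng=rng_centered)
    centered_acc = (what_mod.centered_validation_accuracy(model, val_bank)
                    if val_bank is not None and len(val_bank) else None)
    what_mod.train_curriculum(model, train_bank, schedule=profile.curriculum,
                              noise=profile.noise, lr=profile.what_lr,
                              rng=rng_curr)
    return model, centered_acc


def run_pipeline(profile: Profile | None = None,
                 train_bank: TargetBank | None = None,
                 val_bank: TargetBank | None = None,
                 seed: int = 0,
                 verbose: bool = False) -> TrainedSystem:
    """Train both pathways from scratch under one master seed."""
    profile = ci_profile() if profile is None else profile
    if train_bank is None:
        train_bank, val_bank = make_glyph_dataset(120, seed=seed).split(0.2)

    def log(msg):
        if verbose:
            print(f"[whatwhere] {msg}", flush=True)

    log(f"profile={profile.name} seed={seed}")
    what_model, centered_acc = train_what(profile, train_bank, seed, val_bank)
    log(f"What pathway trained (clean centered val acc: {centered_acc})")

    rng_map, rng_data, rng_init, rng_train = child_rngs(seed + 1, 4)
    eval_bank = val_bank if val_bank is not None and len(val_bank) else train_bank
    shift_map = what_mod.estimate_shift_accuracy_map(
        what_model, eval_bank, n_per_shift=profile.n_per_shift,
        noise=profile.noise, contrast_range=profile.contrast_range,
        shift_step=profile.shift_step, rng=rng_map)
    log(f"shift map measured (center={shift_map.at((0, 0)):.2f}, "
        f"border={shift_map.border_level:.2f})")

    encoder = RetinalEncoder(profile.grid)
    projection = build_projection(profile.grid)
    X, Y = where_mod.make_where_dataset(
        profile.where.samples_per_epoch, train_bank, shift_map, projection,
        encoder, noise=profile.noise, contrast_range=profile.contrast_range,
        eccentricity_policy=profile.where_eccentricity_policy, rng=rng_data)
    where_model = where_mod.build_where_net(profile.where, profile.grid, rng_init)
    losses = where_mod.train_where(where_model, X, Y, profile.where, rng=rng_train)
    log(f"Where pathway trained (BCE {losses[0]:.4f} -> {losses[-1]:.4f}, "
        f"floor {where_mod.bce_entropy_floor(Y):.4f})")
    return TrainedSystem(what_model=what_model, shift_map=shift_map,
                         where_model=where_model, encoder=encoder,
                         projection=projection, profile=profile, seed=seed,
                         where_losses=losses, centered_val_accuracy=centered_acc)


# -- persistence ----------------------------------------------------------

def save_system(system: TrainedSystem, out_dir: str | Path):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "weights.npz",
                        shift_map=system.shift_map.values,
                        **{f"what_{k}": v for k, v in system.what_model.state_dict().items()},
                        **{f"where_{k}": v for k, v in system.where_model.state_dict().items()})
    (out / "manifest.json").write_text(json.dumps({
        "profile": system.profile.name, "seed": system.seed,
        "shift_map_n_samples": system.shift_map.n_samples,
        "profile_yaml": system.profile.to_yaml(),
    }, indent=1))


def load_system(in_dir: str | Path) -> TrainedSystem:
    from .config import Profile

    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    profile = Profile.from_yaml(manifest["profile_yaml"])
    data = np.load(in_dir / "weights.npz")
    what_model = what_mod.build_classifier(np.random.default_rng(0))
    what_model.load_state_dict(
        {k[5:]: data[k] for k in data.files if k.startswith("what_")})
    where_model = where_mod.build_where_net(profile.where, profile.grid,
                                            np.random.default_rng(0))
    where_model.load_state_dict(
        {k[6:]: data[k] for k in data.files if k.startswith("where_")})
    shift_map = ShiftAccuracyMap(values=data["shift_map"],
                                 n_samples=manifest["shift_map_n_samples"])
    encoder = RetinalEncoder(profile.grid)
    return TrainedSystem(what_model=what_model, shift_map=shift_map,
                         where_model=where_model, encoder=encoder,
                         projection=build_projection(profile.grid),
                         profile=profile, seed=manifest["seed"])
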