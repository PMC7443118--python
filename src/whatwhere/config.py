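"""Run profiles: the full-scale reference protocol and a reduced profile.

The two profiles differ only in scale (epochs, samples, grid and
network sizes, trial counts) — never in an algorithmic switch — so the
reduced profile exercises exactly the code paths of the full one while
completing on one CPU core in minutes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .display import NoiseParams
from .retina import LogPolarGrid
from .what import CurriculumSchedule
from .where import WhereConfig


@dataclass(frozen=True)
class Profile:
    name: str
    noise: NoiseParams = NoiseParams()
    noise_gain: float = 1.0
    contrast_range: tuple[float, float] = (0.3, 0.7)
    grid: LogPolarGrid = LogPolarGrid()
    # What pathway
    centered_epochs: int = 20
    centered_samples_per_epoch: int = 60_000
    curriculum: CurriculumSchedule = CurriculumSchedule()
    what_lr: float = 1e-3
    # Shift-accuracy map
    shift_step: int = 1
    n_per_shift: int = 1000
    # Where pathway
    where: WhereConfig = WhereConfig()
    where_eccentricity_policy: object = "uniform"
    # Evaluation
    n_trials: int = 1000
    eccentricities: tuple[float, ...] = (4, 8, 12, 16, 20, 24, 28, 32, 36, 40)
    max_saccades: int = 3
    false_detection_radius: float = 13.0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "Profile":
        d = yaml.safe_load(text)
        d["noise"] = NoiseParams(**d["noise"])
        g = d["grid"]
        g["eccentricities"] = tuple(g["eccentricities"])
        d["grid"] = LogPolarGrid(**g)
        c = d["curriculum"]
        c["contrast_range"] = tuple(c["contrast_range"])
        d["curriculum"] = CurriculumSchedule(**c)
        w = d["where"]
        w["hidden_sizes"] = tuple(w["hidden_sizes"])
        d["where"] = WhereConfig(**w)
        d["contrast_range"] = tuple(d["contrast_range"])
        d["eccentricities"] = tuple(d["eccentricities"])
        return cls(**d)


def paper_profile() -> Profile:
    """The full-scale protocol: 75-epoch curriculum of 60,000 cluttered
    patches, 55x55 shift map at 1,000 samples/shift, 60 x 60,000 Where
    training, 1,000 evaluation trials per condition.  Hours of CPU."""
    return Profile(name="paper")


def ci_profile() -> Profile:
    """Reduced profile: the complete pipeline (generate -> train What ->
    shift map -> train Where -> evaluate) in a few minutes on one core."""
    return Profile(
        name="ci",
        centered_epochs=3,
        centered_samples_per_epoch=3000,
        curriculum=CurriculumSchedule(
            n_epochs=14, samples_per_epoch=6000,
            epochs_per_step=2, std_increment=1.0),
        shift_step=5,
        n_per_shift=100,
        where=WhereConfig(n_epochs=45, samples_per_epoch=8000,
                          lr=1e-3, batch_size=128),
        n_trials=200,
    )
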