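"""Closed-loop saccade/answer policy.

At each fixation the agent compares the foveal accuracy predicted by
the What classifier with the best peripheral accuracy predicted by the
Where map: if the fovea wins (ties included), it answers with the
classifier's label; otherwise it saccades to the argmax cell and the
process repeats, up to ``max_saccades`` (then a forced answer).  Each
saccade's benefit is summarized by the information gain
log p(y|x') - log p(y|x) at the true label, which can be negative when
a saccade worsens the view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colliculus import CollicularMap, SaccadeCommand, decode_saccade
from .display import Display
from .retina import RetinalEncoder, crop_fovea
from .what import ClassPosterior, predict
from .where import predict_map

LIKELIHOOD_FLOOR = 1e-6


@dataclass
class GazeState:
    position: tuple[int, int]  # (row, col) fixation in display coordinates
    step: int = 0


@dataclass
class Decision:
    kind: str  # "ANSWER" | "SACCADE"
    what_acc: float
    where_max: float
    answer_label: int | None = None
    saccade: SaccadeCommand | None = None


@dataclass
class TrialRecord:
    display: Display
    trajectory: list[tuple[int, int]]
    decisions: list[Decision]
    answer: int
    success: bool
    info_gains: list[float] = field(default_factory=list)

    @property
    def n_saccades(self) -> int:
        return len(self.trajectory) - 1

    def to_json(self) -> dict:
        return {
            "label": self.display.target.label,
            "position": list(self.display.target.position),
            "contrast": self.display.target.contrast,
            "trajectory": [list(p) for p in self.trajectory],
            "decisions": [d.kind for d in self.decisions],
            "answer": self.answer,
            "success": self.success,
            "info_gains": self.info_gains,
        }


def decide(posterior: ClassPosterior, coll_map: CollicularMap) -> Decision:
    """Answer iff the foveal accuracy >= the peripheral maximum (the tie
    goes to answering, which rules out saccade loops at equilibrium)."""
    what_acc = posterior.foveal_accuracy
    where_max = float(coll_map.values.max())
    if what_acc >= where_max:
        return Decision(kind="ANSWER", what_acc=what_acc, where_max=where_max,
                        answer_label=posterior.label)
    cmd = decode_saccade(coll_map.argmax_cell(), coll_map.grid)
    return Decision(kind="SACCADE", what_acc=what_acc, where_max=where_max,
                    saccade=cmd)


def apply_saccade(gaze: GazeState, cmd: SaccadeCommand,
                  display_size: int) -> GazeState:
    """Additive gaze update, clipped to the display bounds."""
    r = int(np.clip(gaze.position[0] + cmd.displacement[0], 0, display_size - 1))
    c = int(np.clip(gaze.position[1] + cmd.displacement[1], 0, display_size - 1))
    return GazeState(position=(r, c), step=gaze.step + 1)


def information_gain(posterior_before: ClassPosterior,
                     posterior_after: ClassPosterior,
                     true_label: int) -> float:
    """log p(y|x') - log p(y|x) at the true label, in nats, with a 1e-6
    floor on likelihoods before taking the log."""
    p0 = max(float(posterior_before.likelihoods[true_label]), LIKELIHOOD_FLOOR)
    p1 = max(float(posterior_after.likelihoods[true_label]), LIKELIHOOD_FLOOR)
    return float(np.log(p1) - np.log(p0))


class SaccadeAgent:
    """Bundles the trained pathways with the retinal encoder."""

    def __init__(self, what_model, where_model, encoder: RetinalEncoder):
        self.what_model = what_model
        self.where_model = where_model
        self.encoder = encoder

    def look(self, display: Display, gaze: GazeState):
        posterior = predict(self.what_model, crop_fovea(display, gaze.position))
        features = self.encoder.encode(display, gaze.position)
        coll_map = predict_map(self.where_model, features)
        return posterior, coll_map

    def step(self, gaze: GazeState, display: Display):
        """One decision: (Decision, next GazeState)."""
        posterior, coll_map = self.look(display, gaze)
        decision = decide(posterior, coll_map)
        if decision.kind == "SACCADE":
            return decision, apply_saccade(gaze, decision.saccade, display.size)
        return decision, gaze

    def run_trial(self, display: Display, max_saccades: int = 3,
                  min_saccades: int = 0,
                  forced_saccades: int | None = None) -> TrialRecord:
        """Run the encode -> predict -> decide loop until an answer.

        The adaptive rule (answer iff fovea >= periphery) operates
        between ``min_saccades`` and ``max_saccades``: below the minimum
        a saccade is forced, at the maximum a foveal answer is forced.
        ``forced_saccades=k`` is shorthand for min = max = k (the fixed
        0/1/2/3-saccade evaluation protocols).
        """
        if forced_saccades is not None:
            min_saccades = max_saccades = forced_saccades
        gaze = GazeState(position=display.center)
        trajectory = [gaze.position]
        decisions: list[Decision] = []
        info_gains: list[float] = []
        prev_posterior = None
        while True:
            posterior, coll_map = self.look(display, gaze)
            if prev_posterior is not None:
                info_gains.append(information_gain(
                    prev_posterior, posterior, display.target.label))
            decision = decide(posterior, coll_map)
            if gaze.step < min_saccades and decision.kind == "ANSWER":
                cmd = decode_saccade(coll_map.argmax_cell(), coll_map.grid)
                decision = Decision(kind="SACCADE", what_acc=decision.what_acc,
                                    where_max=decision.where_max, saccade=cmd)
            elif gaze.step >= max_saccades and decision.kind == "SACCADE":
                decision = Decision(kind="ANSWER", what_acc=decision.what_acc,
                                    where_max=decision.where_max,
                                    answer_label=posterior.label)
            decisions.append(decision)
            if decision.kind == "ANSWER":
                return TrialRecord(
                    display=display, trajectory=trajectory, decisions=decisions,
                    answer=decision.answer_label,
                    success=decision.answer_label == display.target.label,
                    info_gains=info_gains)
            prev_posterior = posterior
            gaze = apply_saccade(gaze, decision.saccade, display.size)
            trajectory.append(gaze.position)
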