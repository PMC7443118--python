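"""Decision policy: answer/saccade comparison, gaze updates, trials."""

import numpy as np
import pytest

from whatwhere.agent import (Decision, GazeState, SaccadeAgent, apply_saccade,
                             decide, information_gain)
from whatwhere.colliculus import CollicularMap, SaccadeCommand
from whatwhere.display import NoiseParams, make_trial
from whatwhere.what import ClassPosterior


def _posterior(peak, label=0):
    lik = np.full(10, 0.05)
    lik[label] = peak
    return ClassPosterior(likelihoods=lik)


def _map(grid, peak, cell=(5, 0)):
    vals = np.full(grid.map_dim, min(peak, 0.05))
    vals[cell[0] * grid.n_azimuth + cell[1]] = peak
    return CollicularMap(values=vals, grid=grid)


class TestDecide:
    def test_answer_when_fovea_wins(self, grid):
        d = decide(_posterior(0.9, label=3), _map(grid, 0.5))
        assert d.kind == "ANSWER" and d.answer_label == 3
        assert d.what_acc == pytest.approx(0.9)
        assert d.where_max == pytest.approx(0.5)

    def test_saccade_to_argmax_cell_when_periphery_wins(self, grid):
        d = decide(_posterior(0.1), _map(grid, 0.8, cell=(5, 0)))
        assert d.kind == "SACCADE"
        assert d.saccade.cell == (5, 0)
        assert d.saccade.displacement == (0, 13)

    def test_exact_tie_answers(self, grid):
        d = decide(_posterior(0.5), _map(grid, 0.5))
        assert d.kind == "ANSWER"


class TestGazeUpdate:
    def test_additive_update(self):
        cmd = SaccadeCommand(cell=(5, 6), displacement=(13, 0))
        g = apply_saccade(GazeState(position=(64, 64)), cmd, 128)
        assert g.position == (77, 64) and g.step == 1

    def test_clipped_at_border(self):
        cmd = SaccadeCommand(cell=(9, 0), displacement=(0, 51))
        g = apply_saccade(GazeState(position=(64, 120)), cmd, 128)
        assert g.position == (64, 127)


class TestInformationGain:
    def test_identical_posteriors_give_zero(self):
        p = _posterior(0.4, label=2)
        assert information_gain(p, p, 2) == 0.0

    def test_tenth_to_eighty_percent_is_ln8(self):
        assert information_gain(_posterior(0.1, 1), _posterior(0.8, 1), 1) \
            == pytest.approx(np.log(8), abs=1e-12)

    def test_worsening_view_gives_negative_gain(self):
        assert information_gain(_posterior(0.6, 0), _posterior(0.2, 0), 0) < 0

    def test_zero_likelihood_floored(self):
        p0 = ClassPosterior(likelihoods=np.zeros(10))
        p1 = _posterior(1.0, 0)
        ig = information_gain(p0, p1, 0)
        assert np.isfinite(ig) and ig == pytest.approx(np.log(1.0 / 1e-6))


class TestRunTrial:
    @pytest.fixture(scope="class")
    def untrained_agent(self, encoder):
        from whatwhere.what import build_classifier
        from whatwhere.where import WhereConfig, build_where_net

        rng = np.random.default_rng(0)
        return SaccadeAgent(build_classifier(rng),
                            build_where_net(WhereConfig(hidden_sizes=(32, 32)),
                                            encoder.grid, rng),
                            encoder)

    @pytest.fixture(scope="class")
    def display(self, banks):
        return make_trial(np.random.default_rng(3), banks[0], (0.7, 0.7), 20.0,
                          NoiseParams())

    @pytest.mark.parametrize("max_saccades", [0, 1, 3])
    def test_terminates_within_budget(self, untrained_agent, display, max_saccades):
        rec = untrained_agent.run_trial(display, max_saccades=max_saccades)
        assert rec.n_saccades <= max_saccades
        assert len(rec.decisions) == rec.n_saccades + 1
        assert rec.decisions[-1].kind == "ANSWER"

    def test_zero_budget_answers_from_center(self, untrained_agent, display):
        rec = untrained_agent.run_trial(display, max_saccades=0)
        assert rec.trajectory == [(64, 64)]

    def test_forced_saccade_count(self, untrained_agent, display):
        rec = untrained_agent.run_trial(display, forced_saccades=2)
        assert rec.n_saccades == 2

    def test_decision_consistency_recorded(self, untrained_agent, display):
        rec = untrained_agent.run_trial(display, max_saccades=3)
        for d in rec.decisions[:-1]:
            assert d.kind == "SACCADE" and d.what_acc < d.where_max
        assert 0 <= rec.decisions[-1].what_acc <= 1

    def test_success_flag_matches_answer(self, untrained_agent, display):
        rec = untrained_agent.run_trial(display)
        assert rec.success == (rec.answer == display.target.label)

    def test_record_serializes_to_json(self, untrained_agent, display):
        import json

        rec = untrained_agent.run_trial(display)
        blob = json.dumps(rec.to_json())
        assert json.loads(blob)["label"] == display.target.label


class TestTrainedPolicy:
    def test_centered_high_contrast_target_answered_without_saccade(
            self, trained_system, banks):
        # near zero offset the foveal accuracy beats the peripheral map
        # by construction, so the agent should mostly answer immediately
        agent = trained_system.agent()
        rng = np.random.default_rng(11)
        n_zero = 0
        for _ in range(40):
            disp = make_trial(rng, banks[1], (0.7, 0.7), 0,
                              trained_system.profile.noise)
            rec = agent.run_trial(disp, max_saccades=3)
            n_zero += rec.n_saccades == 0
        assert n_zero > 20

    def test_mean_info_gain_smaller_for_central_targets(self, trained_system,
                                                        banks):
        agent = trained_system.agent()
        rng = np.random.default_rng(12)

        def mean_ig(ecc, n=30):
            igs = []
            for _ in range(n):
                disp = make_trial(rng, banks[1], (0.7, 0.7), ecc,
                                  trained_system.profile.noise)
                rec = agent.run_trial(disp, forced_saccades=1)
                igs.extend(rec.info_gains)
            return np.mean(igs)

        assert mean_ig(2.0) < mean_ig(20.0)
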