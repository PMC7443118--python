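"""Quantitative evaluation protocols.

Reproduces the reference study designs: pre- vs. postsaccadic accuracy
across contrast x eccentricity, the multi-saccade budget comparison,
first-saccade false-detection rates, and single-parameter robustness
scans.  All rates carry binomial (Wilson) confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .agent import SaccadeAgent, TrialRecord
from .config import Profile
from .display import make_trial
from .glyphs import TargetBank


def binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a proportion."""
    if n == 0:
        return (np.nan, np.nan)
    z = stats.norm.ppf(1 - alpha / 2)
    p = k / n
    denom = 1 + z ** 2 / n
    center = (p + z ** 2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z ** 2 / (4 * n ** 2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class EvalResult:
    contrast: float
    eccentricity: float
    n_saccades: int
    n_trials: int
    accuracy: float
    ci_low: float
    ci_high: float
    false_detection_rate: float | None = None


def _records_for_condition(agent: SaccadeAgent, bank: TargetBank,
                           contrast: float, eccentricity: float,
                           n_saccades: int, n_trials: int, profile: Profile,
                           seed: int, adaptive: bool = False) -> list[TrialRecord]:
    """One evaluation cell.  The display stream depends only on
    (contrast, eccentricity, seed), so different saccade budgets see
    identical trials (shared-seed protocol)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, int(contrast * 1000), int(eccentricity)]))
    records = []
    for _ in range(n_trials):
        disp = make_trial(rng, bank, (contrast, contrast), eccentricity,
                          profile.noise, noise_gain=profile.noise_gain)
        if adaptive:
            rec = agent.run_trial(disp, max_saccades=n_saccades,
                                  min_saccades=min(1, n_saccades))
        else:
            rec = agent.run_trial(disp, forced_saccades=n_saccades)
        records.append(rec)
    return records


def first_saccade_error(record: TrialRecord) -> float:
    """Pixel distance between the first landing point and the target."""
    if record.n_saccades < 1:
        return np.nan
    center = record.display.center
    tr, tc = record.display.target.position
    land = record.trajectory[1]
    return float(np.hypot(land[0] - (center[0] + tr), land[1] - (center[1] + tc)))


def false_detection_rate(records: list[TrialRecord],
                         criterion_radius: float = 13.0) -> float:
    """Fraction of trials whose first saccade lands farther than the
    criterion radius from the true target (a localization failure,
    distinct from a misclassification at a correct landing)."""
    if not records:
        raise ValueError("empty record list")
    errors = np.array([first_saccade_error(r) for r in records])
    errors = errors[~np.isnan(errors)]
    if len(errors) == 0:
        raise ValueError("no record contains a saccade")
    if np.isinf(criterion_radius):
        return 0.0
    return float((errors > criterion_radius).mean())


def eval_eccentricity_contrast(agent: SaccadeAgent, bank: TargetBank,
                               profile: Profile,
                               contrasts=(0.3, 0.5, 0.7),
                               eccentricities=None,
                               n_trials: int | None = None,
                               n_saccades=(0, 1),
                               seed: int = 0) -> pd.DataFrame:
    """Pre- (0-saccade) and postsaccadic (1-saccade) accuracy for every
    contrast x eccentricity condition; 1-saccade rows also report the
    false-detection rate."""
    n_trials = profile.n_trials if n_trials is None else n_trials
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    eccentricities = profile.eccentricities if eccentricities is None else eccentricities
    rows = []
    for contrast in contrasts:
        for ecc in eccentricities:
            for k in n_saccades:
                recs = _records_for_condition(agent, bank, contrast, ecc, k,
                                              n_trials, profile, seed)
                n_ok = sum(r.success for r in recs)
                lo, hi = binomial_ci(n_ok, n_trials)
                fdr = (false_detection_rate(recs, profile.false_detection_radius)
                       if k >= 1 else None)
                rows.append(EvalResult(contrast, ecc, k, n_trials,
                                       n_ok / n_trials, lo, hi, fdr))
    return pd.DataFrame([vars(r) for r in rows])


def eval_multisaccade(agent: SaccadeAgent, bank: TargetBank, profile: Profile,
                      n_saccades_list=(1, 2, 3), contrast: float = 0.7,
                      eccentricities=None, n_trials: int | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Final accuracy vs. saccade budget.  The first saccade is always
    executed; further ones only while the peripheral prediction beats
    the foveal one (the stopping criterion), up to the budget."""
    n_trials = profile.n_trials if n_trials is None else n_trials
    eccentricities = profile.eccentricities if eccentricities is None else eccentricities
    rows = []
    for ecc in eccentricities:
        for k in n_saccades_list:
            adaptive = k > 1
            recs = _records_for_condition(agent, bank, contrast, ecc, k,
                                          n_trials, profile, seed,
                                          adaptive=adaptive)
            n_ok = sum(r.success for r in recs)
            lo, hi = binomial_ci(n_ok, n_trials)
            rows.append(EvalResult(contrast, ecc, k, n_trials,
                                   n_ok / n_trials, lo, hi))
    return pd.DataFrame([vars(r) for r in rows])


SCANNABLE = ("noise", "offset_std", "sf_0", "b_sf", "epochs",
             "dim1", "dim2", "n_azimuth")


def _profile_with(profile: Profile, name: str, value) -> Profile:
    if name == "noise":
        return replace(profile, noise_gain=float(value))
    if name == "offset_std":
        return replace(profile, where_eccentricity_policy=("gaussian", float(value)))
    if name == "sf_0":
        return replace(profile, noise=replace(profile.noise, sf0=float(value)))
    if name == "b_sf":
        return replace(profile, noise=replace(profile.noise, b_sf=float(value)))
    if name == "epochs":
        return replace(profile, where=replace(profile.where, n_epochs=int(value)))
    if name == "dim1":
        h = profile.where.hidden_sizes
        return replace(profile, where=replace(profile.where,
                                              hidden_sizes=(int(value), h[1])))
    if name == "dim2":
        h = profile.where.hidden_sizes
        return replace(profile, where=replace(profile.where,
                                              hidden_sizes=(h[0], int(value))))
    if name == "n_azimuth":
        return replace(profile, grid=replace(profile.grid, n_azimuth=int(value)))
    raise ValueError(f"unknown parameter {name!r}; choose from {SCANNABLE}")


def scan_parameter(name: str, values, profile: Profile, bank: TargetBank,
                   val_bank: TargetBank | None = None, n_repeats: int = 8,
                   n_eval: int = 200, seed: int = 0,
                   alpha: float = 0.01) -> pd.DataFrame:
    """Robustness scan: retrain the system for each parameter value and
    report mean single-saccade accuracy with a t-based confidence
    interval over the repetitions (CI undefined for a single repeat)."""
    from .pipeline import run_pipeline

    rows = []
    for value in values:
        p = _profile_with(profile, name, value)
        accs = []
        for rep in range(n_repeats):
            system = run_pipeline(p, bank, val_bank, seed=seed + 1000 * rep)
            agent = system.agent()
            rng = np.random.default_rng([seed, rep, 17])
            ok = 0
            for _ in range(n_eval):
                disp = make_trial(rng, val_bank or bank, p.contrast_range,
                                  "uniform", p.noise, noise_gain=p.noise_gain)
                ok += agent.run_trial(disp, forced_saccades=1).success
            accs.append(ok / n_eval)
        accs = np.asarray(accs)
        if n_repeats > 1:
            half = (stats.t.ppf(1 - alpha / 2, n_repeats - 1)
                    * accs.std(ddof=1) / np.sqrt(n_repeats))
            lo, hi = accs.mean() - half, accs.mean() + half
        else:
            lo = hi = np.nan
        rows.append({"parameter": name, "value": value,
                     "accuracy": accs.mean(), "ci_low": lo, "ci_high": hi,
                     "n_repeats": n_repeats, "ci_defined": n_repeats > 1})
    return pd.DataFrame(rows)
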