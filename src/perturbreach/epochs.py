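"""Trial epoch windows, epoch firing rates, and unit classification.

Epochs follow the task timeline: CHT (pad hit to cue light, the baseline),
RTc (cue to pad release), MT (release to target hit, split into PD and PR on
perturbed trials at perturbation onset), and THT (hit to target release).
Units are screened for baseline stability across sets, flagged task-related
by the 2-SD rule, and tested for perturbation-response and anticipatory
modulation with two-sample t-tests; orientation/direction structure in
unperturbed trials is assessed with a two-way ANOVA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.design import TrialRecord

logger = logging.getLogger(__name__)

EPOCH_NAMES = ("cht", "rtc", "mt", "pd", "pr", "tht")

#: variance floor used when a baseline has zero spread across trials (Hz)
SD_FLOOR = 1e-9


class DataError(ValueError):
    """Inconsistent trial events or missing required data."""


@dataclass(frozen=True)
class EpochWindows:
    """Per-trial epoch boundaries in seconds; PD/PR are None when unperturbed."""

    cht: tuple[float, float]
    rtc: tuple[float, float]
    mt: tuple[float, float]
    tht: tuple[float, float]
    pd: Optional[tuple[float, float]] = None
    pr: Optional[tuple[float, float]] = None

    def as_dict(self) -> dict[str, Optional[tuple[float, float]]]:
        return {"cht": self.cht, "rtc": self.rtc, "mt": self.mt,
                "pd": self.pd, "pr": self.pr, "tht": self.tht}


def compute_epochs(trial: TrialRecord) -> EpochWindows:
    """Build the epoch windows of one trial from its event timestamps."""
    pairs = {
        "cht": (trial.t_pad_hit, trial.t_light_on),
        "rtc": (trial.t_light_on, trial.t_center_release),
        "mt": (trial.t_center_release, trial.t_target_hit),
        "tht": (trial.t_target_hit, trial.t_target_release),
    }
    for name, (a, b) in pairs.items():
        if not b > a:
            raise DataError(f"trial {trial.trial_id}: non-positive {name} window")
    pd_win = pr_win = None
    label_perturbed = trial.condition not in ("unperturbed", "random_none")
    if label_perturbed and trial.t_perturbation is None:
        raise DataError(f"trial {trial.trial_id}: perturbed but no t_perturbation")
    if trial.perturbed:
        pd_win = (trial.t_center_release, trial.t_perturbation)
        pr_win = (trial.t_perturbation, trial.t_target_hit)
        for name, (a, b) in (("pd", pd_win), ("pr", pr_win)):
            if not b > a:
                raise DataError(f"trial {trial.trial_id}: non-positive {name} window")
    return EpochWindows(pd=pd_win, pr=pr_win, **pairs)


def count_spikes(spikes: np.ndarray, start: float, end: float) -> int:
    """Spike count in the half-open window [start, end)."""
    spikes = np.asarray(spikes)
    return int(np.searchsorted(spikes, end, side="left")
               - np.searchsorted(spikes, start, side="left"))


def window_rate(spikes: np.ndarray, start: float, end: float) -> float:
    if not end > start:
        raise DataError("window must have positive length")
    return count_spikes(spikes, start, end) / (end - start)


def epoch_firing_rates(spikes: np.ndarray, windows: EpochWindows) -> dict[str, float]:
    """Firing rate (Hz) per epoch; NaN for epochs undefined on this trial."""
    out = {}
    for name, win in windows.as_dict().items():
        out[name] = np.nan if win is None else window_rate(spikes, *win)
    return out


def epoch_rate_table(trials: Iterable[TrialRecord],
                     spikes_by_trial: dict[int, np.ndarray],
                     neuron_id: int | None = None) -> pd.DataFrame:
    """Long table of per-trial epoch rates with the trial's condition labels."""
    rows = []
    for trial in trials:
        rates = epoch_firing_rates(
            spikes_by_trial.get(trial.trial_id, np.empty(0)),
            compute_epochs(trial))
        rows.append(dict(
            neuron_id=neuron_id, trial_id=trial.trial_id,
            set_index=trial.set_index, condition=trial.condition,
            target_side=trial.target_side,
            initial_orientation=trial.initial_orientation,
            final_orientation=trial.final_orientation, **rates))
    return pd.DataFrame(rows)


# --- statistical primitives ------------------------------------------------

def two_sample_t(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided",
                 equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test returning (t, p); degenerate inputs handled exactly.

    With zero variance in both groups the test is decided by the means alone:
    equal means give p = 1, unequal means p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        return np.nan, np.nan
    if np.var(x) == 0.0 and np.var(y) == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        t = np.inf if np.mean(x) > np.mean(y) else -np.inf
        if alternative == "two-sided":
            return t, 0.0
        return t, 0.0 if (t > 0) == (alternative == "greater") else 1.0
    res = stats.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


# --- unit-level screens and tests ------------------------------------------

@dataclass
class TaskRelatedResult:
    task_related: bool
    z_scores: dict[str, float]
    baseline_mean: float
    baseline_sd: float
    degenerate_baseline: bool = False


def detect_task_related(rates: pd.DataFrame) -> TaskRelatedResult:
    """2-SD rule: any of RTc/MT/THT mean rate above baseline mean + 2 SD.

    The SD is taken across trials of the baseline (CHT) rate.  A zero baseline
    SD is floored and flagged degenerate.
    """
    cht = rates["cht"].dropna().to_numpy()
    if cht.size < 10:
        raise DataError("need >= 10 trials with valid baseline rates")
    mu, sd = float(np.mean(cht)), float(np.std(cht, ddof=1))
    degenerate = sd == 0.0
    sd_eff = max(sd, SD_FLOOR)
    z = {}
    for epoch in ("rtc", "mt", "tht"):
        z[epoch] = (float(np.mean(rates[epoch].dropna())) - mu) / sd_eff
    return TaskRelatedResult(task_related=any(v > 2.0 for v in z.values()),
                             z_scores=z, baseline_mean=mu, baseline_sd=sd,
                             degenerate_baseline=degenerate)


@dataclass
class StabilityResult:
    excluded: bool
    testable: bool
    p_values: dict[tuple[int, int], float]


def baseline_stability_filter(rates: pd.DataFrame, alpha: float = 0.05,
                              min_trials: int = 5,
                              equal_var: bool = True) -> StabilityResult:
    """Exclude units whose CHT baseline differs between sets.

    All pairwise two-sided t-tests between sets' CHT rates, uncorrected; any
    p < alpha excludes the unit.  Units with fewer than two testable sets are
    retained and flagged untestable.
    """
    groups = {int(s): g["cht"].dropna().to_numpy()
              for s, g in rates.groupby("set_index")}
    groups = {s: v for s, v in groups.items() if v.size >= min_trials}
    if len(groups) < 2:
        return StabilityResult(excluded=False, testable=False, p_values={})
    p_values = {}
    for a, b in combinations(sorted(groups), 2):
        _, p = two_sample_t(groups[a], groups[b], equal_var=equal_var)
        p_values[(a, b)] = p
    excluded = any(p < alpha for p in p_values.values() if np.isfinite(p))
    return StabilityResult(excluded=excluded, testable=True, p_values=p_values)


@dataclass
class TestResult:
    p_value: float
    statistic: float
    flag: bool
    n_test: int
    n_control: int


def _matched_control_window(trial: TrialRecord, latency: float,
                            duration: float) -> tuple[float, float]:
    start = trial.t_center_release + latency
    end = min(start + duration, trial.t_target_release)
    return start, end


def perturbation_response_rates(
    trials: Iterable[TrialRecord],
    spikes_by_trial: dict[int, np.ndarray],
    schedule: str,
) -> tuple[np.ndarray, np.ndarray]:
    """PR-epoch rates of perturbed trials and matched-window unperturbed rates.

    The control group is the 90-degree unperturbed trials, scored over the
    same release-locked window as the average perturbed PR epoch so window
    placement and length cannot masquerade as a perturbation response.
    """
    trials = list(trials)
    prefix = {"random": "random_", "repeat": "repeat_"}[schedule]
    perturbed = [t for t in trials
                 if t.condition.startswith(prefix) and t.perturbed]
    controls = [t for t in trials
                if not t.perturbed and t.final_orientation == t.initial_orientation
                and t.initial_orientation == 90.0]
    if not perturbed or not controls:
        return np.empty(0), np.empty(0)
    latency = float(np.median([t.t_perturbation - t.t_center_release
                               for t in perturbed]))
    duration = float(np.mean([t.t_target_hit - t.t_perturbation
                              for t in perturbed]))
    x = np.array([window_rate(spikes_by_trial.get(t.trial_id, np.empty(0)),
                              t.t_perturbation, t.t_target_hit)
                  for t in perturbed])
    y = np.array([window_rate(spikes_by_trial.get(t.trial_id, np.empty(0)),
                              *_matched_control_window(t, latency, duration))
                  for t in controls])
    return x, y


def perturbation_response_test(perturbed_rates: np.ndarray,
                               control_rates: np.ndarray,
                               alpha: float = 0.05,
                               equal_var: bool = True) -> TestResult:
    """Two-sided t-test for altered discharge in the PR epoch."""
    t, p = two_sample_t(perturbed_rates, control_rates, "two-sided", equal_var)
    flag = bool(np.isfinite(p) and p < alpha)
    return TestResult(p_value=p, statistic=t, flag=flag,
                      n_test=len(perturbed_rates), n_control=len(control_rates))


def anticipatory_rates(
    trials: Iterable[TrialRecord],
    spikes_by_trial: dict[int, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-perturbation (PD-window) rates: repeat trials vs matched unperturbed."""
    trials = list(trials)
    repeat = [t for t in trials if t.condition.startswith("repeat_")]
    controls = [t for t in trials
                if not t.perturbed and t.final_orientation == t.initial_orientation
                and t.initial_orientation == 90.0]
    if not repeat or not controls:
        return np.empty(0), np.empty(0)
    latency = float(np.median([t.t_perturbation - t.t_center_release
                               for t in repeat]))
    x = np.array([window_rate(spikes_by_trial.get(t.trial_id, np.empty(0)),
                              t.t_center_release, t.t_perturbation)
                  for t in repeat])
    y = np.array([window_rate(spikes_by_trial.get(t.trial_id, np.empty(0)),
                              t.t_center_release, t.t_center_release + latency)
                  for t in controls])
    return x, y


def anticipatory_test(repeat_rates: np.ndarray, control_rates: np.ndarray,
                      alpha: float = 0.05, equal_var: bool = True) -> TestResult:
    """One-sided t-test for elevated pre-perturbation activity on repeat trials."""
    t, p = two_sample_t(repeat_rates, control_rates, "greater", equal_var)
    flag = bool(np.isfinite(p) and p < alpha)
    return TestResult(p_value=p, statistic=t, flag=flag,
                      n_test=len(repeat_rates), n_control=len(control_rates))


def two_way_anova(rates: pd.DataFrame, value: str = "mt") -> dict[str, float]:
    """Fixed-effects 2 (direction) x 3 (orientation) ANOVA with interaction.

    Runs on unperturbed-trial epoch rates.  Uses type-II sums of squares,
    which coincide with the classical balanced decomposition on the balanced
    design; unbalanced input is accepted under the same convention.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = rates[rates["condition"] == "unperturbed"][
        ["target_side", "initial_orientation", value]].dropna()
    df = df.rename(columns={value: "rate"})
    cells = df.groupby(["target_side", "initial_orientation"]).size()
    if len(cells) < 6 or (cells < 2).any():
        raise DataError("two-way ANOVA needs >= 2 trials in all 6 cells")
    if np.ptp(df["rate"].to_numpy()) == 0.0:
        # no variation at all: every effect is exactly null
        return {f"F_{k}": 0.0 for k in ("direction", "orientation", "interaction")} | {
            f"p_{k}": 1.0 for k in ("direction", "orientation", "interaction")}
    model = smf.ols(
        "rate ~ C(target_side) * C(initial_orientation)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    def row(key):
        return table.loc[key]
    return {
        "F_direction": float(row("C(target_side)")["F"]),
        "p_direction": float(row("C(target_side)")["PR(>F)"]),
        "F_orientation": float(row("C(initial_orientation)")["F"]),
        "p_orientation": float(row("C(initial_orientation)")["PR(>F)"]),
        "F_interaction": float(row("C(target_side):C(initial_orientation)")["F"]),
        "p_interaction": float(row("C(target_side):C(initial_orientation)")["PR(>F)"]),
    }


# --- population pipeline ---------------------------------------------------

def classify_neuron(trials: list[TrialRecord],
                    spikes_by_trial: dict[int, np.ndarray],
                    neuron_id: int | None = None,
                    alpha: float = 0.05,
                    equal_var: bool = True,
                    run_anova: bool = True) -> dict:
    """Run the full screen/test battery on one unit; returns one flat record."""
    rates = epoch_rate_table(trials, spikes_by_trial, neuron_id)
    task = detect_task_related(rates)
    stability = baseline_stability_filter(rates, alpha, equal_var=equal_var)
    out = dict(
        neuron_id=neuron_id,
        task_related=task.task_related,
        excluded_unstable_baseline=stability.excluded,
        baseline_mean=task.baseline_mean,
        baseline_sd=task.baseline_sd,
        z_rtc=task.z_scores["rtc"], z_mt=task.z_scores["mt"],
        z_tht=task.z_scores["tht"],
    )
    for schedule in ("random", "repeat"):
        x, y = perturbation_response_rates(trials, spikes_by_trial, schedule)
        res = perturbation_response_test(x, y, alpha, equal_var)
        out[f"corrective_{schedule}"] = res.flag
        out[f"p_corrective_{schedule}"] = res.p_value
    x, y = anticipatory_rates(trials, spikes_by_trial)
    res = anticipatory_test(x, y, alpha, equal_var)
    out["anticipatory"] = res.flag
    out["p_anticipatory"] = res.p_value
    if run_anova:
        try:
            out.update({k: v for k, v in two_way_anova(rates).items()})
            for eff in ("direction", "orientation", "interaction"):
                out[f"{eff}_effect"] = bool(out[f"p_{eff}"] < alpha)
        except DataError as exc:
            logger.info("neuron %s: ANOVA skipped (%s)", neuron_id, exc)
    out["category"] = _category(out)
    return out


def _category(rec: dict) -> str | None:
    if not rec["task_related"]:
        return None
    rnd, rep = rec["corrective_random"], rec["corrective_repeat"]
    if rnd and rep:
        return "both"
    if rnd:
        return "random_only"
    if rep:
        return "repeat_only"
    return "unperturbed_only"


def classify_population(trials: list[TrialRecord],
                        spikes: dict[int, dict[int, np.ndarray]],
                        alpha: float = 0.05,
                        equal_var: bool = True,
                        run_anova: bool = True) -> pd.DataFrame:
    """Classify every unit of a session; one row per neuron."""
    rows = [classify_neuron(trials, per_trial, nid, alpha, equal_var, run_anova)
            for nid, per_trial in spikes.items()]
    df = pd.DataFrame(rows)
    n_excluded = int(df["excluded_unstable_baseline"].sum())
    logger.info("classified %d units (%d excluded for unstable baseline)",
                len(df), n_excluded)
    return df


def categorize_population(classifications: pd.DataFrame,
                          drop_unstable: bool = True) -> dict[str, float]:
    """Category fractions over retained task-related units (sums to 1)."""
    df = classifications
    if drop_unstable:
        df = df[~df["excluded_unstable_baseline"]]
    df = df[df["task_related"]]
    if df.empty:
        return {}
    counts = df["category"].value_counts()
    return {cat: float(counts.get(cat, 0)) / float(len(df))
            for cat in ("random_only", "repeat_only", "both", "unperturbed_only")}
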