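"""Perturbation reaction time from hand-orientation trajectories.

RTp is estimated by comparing each perturbed trial's orientation trace,
aligned to central-pad release, against a band built from matched unperturbed
trials: the first run of ``k`` consecutive samples outside the band on the
side of the new target orientation marks the detectable deviation, and RTp is
that time minus perturbation onset (negative values mean the correction began
before the perturbation, i.e. anticipation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .simulate.design import TrialRecord
from .simulate.trajectory import SAMPLE_STEP

#: floor on the band half-width, degrees
BAND_EPS = 1e-6


@dataclass
class TrajectoryBand:
    """Release-aligned mean trajectory of unperturbed trials with a spread band."""

    time: np.ndarray            # seconds relative to center release
    mean: np.ndarray            # degrees
    half_width: np.ndarray      # degrees, > 0 everywhere
    n_trials: int
    kind: str = "normal"        # "normal" (mean +/- 1.96 sd) or "sem"

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.half_width

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.half_width


@dataclass
class RtpEstimate:
    trial_id: int
    detected: bool
    deviation_time: float = np.nan  # absolute trial clock, seconds
    rtp: float = np.nan             # deviation_time - t_perturbation


def _align(trial: TrialRecord, t: np.ndarray, angle: np.ndarray,
           grid: np.ndarray) -> np.ndarray:
    """Interpolate a trial's trace onto a release-relative time grid."""
    return np.interp(grid, t - trial.t_center_release, angle)


def build_band(
    trials: Iterable[TrialRecord],
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]],
    kind: str = "normal",
    t_start: float = -0.100,
    t_stop: float = 0.600,
    side: str | None = None,
    orientation: float = 90.0,
) -> TrajectoryBand:
    """Build the unperturbed reference band on a common release-aligned grid.

    Only unperturbed trials to the (default 90-degree) start-posture target
    enter the band — those are the trials a perturbed movement tracks until
    its correction begins.  ``kind='normal'`` gives a 95% normal-range band
    (mean +/- 1.96 sd), the default for single-trial deviation detection;
    ``kind='sem'`` gives the t-based 95% confidence band of the mean.
    """
    trials = [t for t in trials if not t.perturbed
              and t.final_orientation == orientation
              and (side is None or t.target_side == side)]
    if len(trials) < 10:
        raise ValueError("need at least 10 unperturbed trials to build a band")
    grid = np.arange(round(t_start / SAMPLE_STEP),
                     round(t_stop / SAMPLE_STEP) + 1) * SAMPLE_STEP
    traces = np.vstack([_align(t, *trajectories[t.trial_id], grid) for t in trials])
    mean = traces.mean(axis=0)
    sd = traces.std(axis=0, ddof=1)
    if kind == "normal":
        half = 1.96 * sd
    elif kind == "sem":
        tcrit = stats.t.ppf(0.975, len(trials) - 1)
        half = tcrit * sd / np.sqrt(len(trials))
    else:
        raise ValueError(f"unknown band kind {kind!r}")
    return TrajectoryBand(time=grid, mean=mean,
                          half_width=np.maximum(half, BAND_EPS),
                          n_trials=len(trials), kind=kind)


def estimate_rtp(
    trial: TrialRecord,
    trajectory: tuple[np.ndarray, np.ndarray],
    band: TrajectoryBand,
    k: int = 3,
) -> RtpEstimate:
    """Detect the corrective deviation of one perturbed trial.

    The search starts at center release (so negative RTp is measurable) and
    requires ``k`` consecutive samples beyond the band on the side of the new
    target orientation.  The reported deviation time is the first sample of
    the qualifying run.
    """
    if not trial.perturbed:
        raise ValueError("RTp is defined for perturbed trials only")
    direction = trial.perturbation_direction
    trace = _align(trial, *trajectory, band.time)
    if direction > 0:
        outside = trace > band.upper
    else:
        outside = trace < band.lower
    searchable = (band.time >= 0.0) & (
        band.time <= trial.t_target_hit - trial.t_center_release)
    outside &= searchable
    run = np.convolve(outside.astype(int), np.ones(k, dtype=int), mode="valid")
    hits = np.flatnonzero(run == k)
    if hits.size == 0:
        return RtpEstimate(trial_id=trial.trial_id, detected=False)
    t_dev = band.time[hits[0]] + trial.t_center_release
    return RtpEstimate(trial_id=trial.trial_id, detected=True,
                       deviation_time=t_dev,
                       rtp=t_dev - trial.t_perturbation)


def estimate_rtp_block(
    trials: Iterable[TrialRecord],
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]],
    band: TrajectoryBand | None = None,
    k: int = 3,
    band_kind: str = "normal",
) -> pd.DataFrame:
    """RTp estimates for all perturbed trials of a block (one row per trial)."""
    trials = list(trials)
    bands: dict[str, TrajectoryBand] = {}
    rows = []
    for trial in trials:
        if not trial.perturbed:
            continue
        if band is not None:
            trial_band = band
        else:
            if trial.target_side not in bands:
                bands[trial.target_side] = build_band(
                    trials, trajectories, kind=band_kind,
                    side=trial.target_side,
                    orientation=trial.initial_orientation)
            trial_band = bands[trial.target_side]
        est = estimate_rtp(trial, trajectories[trial.trial_id], trial_band, k)
        rows.append(dict(trial_id=trial.trial_id, condition=trial.condition,
                         target_side=trial.target_side,
                         repeat_trial_index=trial.repeat_trial_index,
                         detected=est.detected, deviation_time=est.deviation_time,
                         rtp=est.rtp))
    return pd.DataFrame(rows)


@dataclass
class RtpSeries:
    """Per-condition RTp adaptation curves with the random-trial reference CI."""

    repeat_series: pd.DataFrame     # condition, trial_index, mean_rtp, n, predicted
    random_mean: float
    random_ci: tuple[float, float]
    n_random: int


def rtp_adaptation_series(
    estimates: pd.DataFrame,
    n_indices: int = 15,
    ci_level: float = 0.95,
) -> RtpSeries:
    """Average repeat-condition RTp by within-set trial index across blocks.

    The random-perturbation trials provide the reference: their pooled mean
    and a Student-t confidence interval of the mean.  A repeat index whose
    mean RTp falls below the lower CI bound is flagged as predictive.
    """
    det = estimates[estimates["detected"]]
    rand = det[det["condition"].str.startswith("random_")
               & (det["condition"] != "random_none")]["rtp"].to_numpy()
    if rand.size < 2:
        raise ValueError("need at least 2 detected random-perturbation trials")
    mean = float(np.mean(rand))
    sem = stats.sem(rand)
    tcrit = stats.t.ppf(0.5 + ci_level / 2, rand.size - 1)
    ci = (mean - tcrit * sem, mean + tcrit * sem)

    rep = det[det["condition"].str.startswith("repeat_")]
    rows = []
    for (cond, side), grp in rep.groupby(["condition", "target_side"]):
        for idx in range(1, n_indices + 1):
            vals = grp[grp["repeat_trial_index"] == idx]["rtp"].to_numpy()
            if vals.size == 0:
                continue
            m = float(np.mean(vals))
            rows.append(dict(condition=cond, target_side=side, trial_index=idx,
                             mean_rtp=m, n=vals.size, predicted=m < ci[0]))
    return RtpSeries(repeat_series=pd.DataFrame(rows), random_mean=mean,
                     random_ci=ci, n_random=int(rand.size))
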