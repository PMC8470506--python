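"""Block design and trial-event generation.

A block is four sets of reach-to-grasp trials (240 total):

* set 1 — 90 unperturbed trials, targets at 45/90/135 degrees on the left or
  right target, balanced so every consecutive window of 6 trials holds 3
  trials per target side and each (side, orientation) cell appears 15 times;
* set 2 — 90 trials from the 90-degree posture, perturbed 45 degrees CW or
  CCW (or left unperturbed) with probability 1/3 each, exactly balanced;
* sets 3 and 4 — 30 repeat-perturbation trials each, all CW45 in one set and
  all CCW45 in the other, set order randomised.

Trial clock is zero at central-pad hit.  The perturbation fires a fixed
latency (default 70 ms) after central-pad release.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

ORIENTATIONS = (45.0, 90.0, 135.0)
SIDES = ("left", "right")

#: perturbation latency after central-pad release, seconds
DEFAULT_PERTURBATION_LATENCY = 0.070


class ConfigurationError(ValueError):
    """Invalid design or generator configuration."""


@dataclass(frozen=True)
class BlockDesign:
    """Parameters of the four-set block layout."""

    n_set1: int = 90
    n_set2: int = 90
    n_set3: int = 30
    n_set4: int = 30
    set2_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # CW, CCW, none
    perturbation_latency: float = DEFAULT_PERTURBATION_LATENCY
    perturbation_size: float = 45.0  # degrees
    start_orientation: float = 90.0  # holding-pad posture, degrees

    def __post_init__(self) -> None:
        if self.n_set1 % 6 != 0:
            raise ConfigurationError("set 1 size must be a multiple of 6")
        if abs(sum(self.set2_probs) - 1.0) > 1e-9:
            raise ConfigurationError("set 2 probabilities must sum to 1")
        if self.n_set2 % 3 != 0:
            raise ConfigurationError("set 2 size must be a multiple of 3")
        for n in (self.n_set1, self.n_set2, self.n_set3, self.n_set4):
            if n <= 0:
                raise ConfigurationError("set sizes must be positive")
        if self.perturbation_latency <= 0:
            raise ConfigurationError("perturbation latency must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_set1 + self.n_set2 + self.n_set3 + self.n_set4


@dataclass
class TrialRecord:
    """One trial's condition labels and event timestamps (seconds from pad hit)."""

    trial_id: int
    set_index: int
    target_side: str
    initial_orientation: float
    final_orientation: float
    condition: str  # unperturbed | random_CW | random_CCW | random_none | repeat_CW | repeat_CCW
    t_pad_hit: float
    t_light_on: float
    t_center_release: float
    t_perturbation: Optional[float]  # None on unperturbed trials
    t_target_hit: float
    t_target_release: float
    success: bool = True
    repeat_trial_index: int = 0  # 1-based ordinal within a repeat set, else 0

    @property
    def perturbed(self) -> bool:
        return self.t_perturbation is not None

    @property
    def perturbation_direction(self) -> int:
        """+1 for CCW (angle increases), -1 for CW, 0 for none."""
        d = self.final_orientation - self.initial_orientation
        return int(np.sign(d))

    def validate(self) -> None:
        ts = (self.t_pad_hit, self.t_light_on, self.t_center_release,
              self.t_target_hit, self.t_target_release)
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trial {self.trial_id}: event times out of order")
        if self.t_light_on - self.t_pad_hit < 0.300 - 1e-12:
            raise ValueError(f"trial {self.trial_id}: holding phase under 300 ms")
        if self.perturbed and not (self.t_center_release < self.t_perturbation < self.t_target_hit):
            raise ValueError(f"trial {self.trial_id}: perturbation time out of range")


def _set1_conditions(n: int, rng: np.random.Generator) -> list[tuple[str, float]]:
    """(side, orientation) sequence: windows of 6 each holding all 6 cells once."""
    cells = [(s, o) for s in SIDES for o in ORIENTATIONS]
    out: list[tuple[str, float]] = []
    for _ in range(n // 6):
        perm = rng.permutation(len(cells))
        out.extend(cells[i] for i in perm)
    return out


def _set2_perturbations(design: BlockDesign, rng: np.random.Generator) -> list[str]:
    """Balanced pseudo-random CW/CCW/none sequence for the random set."""
    counts = np.round(np.asarray(design.set2_probs) * design.n_set2).astype(int)
    counts[2] = design.n_set2 - counts[0] - counts[1]
    labels = ["CW"] * counts[0] + ["CCW"] * counts[1] + ["none"] * counts[2]
    return [labels[i] for i in rng.permutation(len(labels))]


def generate_block(
    seed: int | np.random.Generator,
    design: BlockDesign | None = None,
    *,
    timing_rng: np.random.Generator | None = None,
    behavior=None,
) -> tuple[BlockDesign, list[TrialRecord]]:
    """Generate the condition sequence and event timeline of one block.

    Parameters
    ----------
    seed
        Integer seed or a ``numpy`` generator; the same seed reproduces the
        block exactly.
    design
        Block layout; defaults to the standard 90/90/30/30 design.
    behavior
        Optional :class:`~perturbreach.simulate.trajectory.BehaviorParams`
        controlling the event-time distributions.

    Returns
    -------
    (design, trials)
        ``trials`` is a list of 240 validated :class:`TrialRecord`.
    """
    from .trajectory import BehaviorParams

    design = design or BlockDesign()
    behavior = behavior or BehaviorParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timing_rng = timing_rng or rng

    plan: list[dict] = []
    for side, orient in _set1_conditions(design.n_set1, rng):
        plan.append(dict(set_index=1, target_side=side, initial_orientation=orient,
                         final_orientation=orient, condition="unperturbed",
                         repeat_trial_index=0))
    sides2 = ["left"] * (design.n_set2 // 2) + ["right"] * (design.n_set2 - design.n_set2 // 2)
    sides2 = [sides2[i] for i in rng.permutation(len(sides2))]
    for side, pert in zip(sides2, _set2_perturbations(design, rng)):
        init = design.start_orientation
        if pert == "none":
            final, cond = init, "random_none"
        elif pert == "CW":
            final, cond = init - design.perturbation_size, "random_CW"
        else:
            final, cond = init + design.perturbation_size, "random_CCW"
        plan.append(dict(set_index=2, target_side=side, initial_orientation=init,
                         final_orientation=final, condition=cond, repeat_trial_index=0))

    # sets 3 and 4 occur in random order; one is all-CW, the other all-CCW
    cw_first = bool(rng.integers(2))
    repeat_sets = [(3, "CW", design.n_set3), (4, "CCW", design.n_set4)]
    if not cw_first:
        repeat_sets = [(3, "CCW", design.n_set4), (4, "CW", design.n_set3)]
    for set_index, pert, n in repeat_sets:
        sides = ["left"] * (n // 2) + ["right"] * (n - n // 2)
        sides = [sides[i] for i in rng.permutation(n)]
        sign = -1.0 if pert == "CW" else 1.0
        for k, side in enumerate(sides, start=1):
            plan.append(dict(
                set_index=set_index, target_side=side,
                initial_orientation=design.start_orientation,
                final_orientation=design.start_orientation + sign * design.perturbation_size,
                condition=f"repeat_{pert}", repeat_trial_index=k))

    trials: list[TrialRecord] = []
    for trial_id, p in enumerate(plan):
        perturbed = p["condition"] not in ("unperturbed", "random_none")
        t = _draw_event_times(behavior, design, perturbed, timing_rng,
                              p["repeat_trial_index"])
        rec = TrialRecord(trial_id=trial_id, success=True, **p, **t)
        rec.validate()
        trials.append(rec)
    return design, trials


def _draw_event_times(behavior, design: BlockDesign, perturbed: bool,
                      rng: np.random.Generator,
                      repeat_trial_index: int = 0) -> dict:
    t_pad_hit = 0.0
    t_light_on = 0.300 + rng.uniform(0.0, behavior.hold_jitter)
    rtc = behavior.draw_rtc(rng)
    t_center_release = t_light_on + rtc
    if perturbed:
        t_pert = t_center_release + design.perturbation_latency
        mt_mean = behavior.mt_perturbed_mean
        if repeat_trial_index >= 1:
            # movement duration relaxes toward the unperturbed value as the
            # correction is anticipated over repeat trials
            mt_mean = behavior.mt_unperturbed_mean + (
                behavior.mt_perturbed_mean - behavior.mt_unperturbed_mean
            ) * float(np.exp(-repeat_trial_index / behavior.mt_adaptation_decay))
        mt = max(mt_mean + rng.normal(0.0, behavior.mt_sd),
                 design.perturbation_latency + 0.100)
    else:
        t_pert = None
        mt = max(behavior.mt_unperturbed_mean + rng.normal(0.0, behavior.mt_sd), 0.100)
    t_hit = t_center_release + mt
    t_release = t_hit + max(behavior.tht_mean + rng.normal(0.0, behavior.tht_sd), 0.050)
    return dict(t_pad_hit=t_pad_hit, t_light_on=t_light_on,
                t_center_release=t_center_release, t_perturbation=t_pert,
                t_target_hit=t_hit, t_target_release=t_release)


def trials_to_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in trials])
    return df


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    recs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        if pd.isna(d["t_perturbation"]):
            d["t_perturbation"] = None
        recs.append(TrialRecord(**d))
    return recs
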