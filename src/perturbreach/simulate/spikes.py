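"""Ground-truth neuron models and inhomogeneous-Poisson spike generation.

The intensity of a neuron on a trial is a sum of interpretable components:
a constant baseline, a movement-locked Gaussian bump, a corrective Gaussian
bump after the perturbation (its gain adapting over repeat trials), an
anticipatory ramp from cue light to perturbation onset that grows over repeat
trials, cosine orientation tuning during the movement, and a target-side
offset.  Spikes are drawn by Lewis-Shedler thinning, which is exact for any
bounded intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .design import ConfigurationError, TrialRecord

NEURON_CLASSES = (
    "non_responsive",
    "corrective_only",
    "corrective_anticipatory",
    "orientation_tuned",
    "mixed",
)


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Generative parameters of one synthetic neuron; all gains in Hz."""

    neuron_id: int = 0
    neuron_class: str = "mixed"
    baseline_rate: float = 8.0
    movement_gain: float = 25.0
    movement_latency: float = 0.135     # bump centre after center release, s
    movement_width: float = 0.080       # bump sd, s
    corrective_gain_random: float = 0.0
    corrective_gain_repeat: float = 0.0
    corrective_peak_latency: float = 0.250  # after center release, s
    corrective_width: float = 0.040         # bump sd, s
    corrective_adaptation_tau: float = 30.0  # repeat trials
    anticipatory_gain: float = 0.0
    anticipatory_learning_rate: float = 0.3  # per repeat trial
    # depth in [0, 1] by which the ramp is scaled toward the orientation-tuning
    # weight of the predicted (final) orientation: 0 = direction-blind
    # anticipation, 1 = the unit anticipates one specific target orientation
    anticipatory_tuning_depth: float = 0.0
    preferred_orientation: float = 45.0      # degrees
    orientation_gain: float = 0.0
    # if True, tuning re-references to the perturbed (final) target orientation;
    # if False the unit keeps encoding the originally planned orientation
    tuning_follows_perturbation: bool = True
    direction_gain: float = 0.0
    preferred_side: str = "right"

    def __post_init__(self) -> None:
        gains = (self.baseline_rate, self.movement_gain, self.corrective_gain_random,
                 self.corrective_gain_repeat, self.anticipatory_gain,
                 self.orientation_gain, self.direction_gain)
        if any(g < 0 for g in gains):
            raise ConfigurationError("rate parameters must be non-negative")
        if self.neuron_class not in NEURON_CLASSES:
            raise ConfigurationError(f"unknown neuron class {self.neuron_class!r}")

    @property
    def max_rate(self) -> float:
        """Upper bound on the intensity, used by the thinning sampler."""
        return (self.baseline_rate + self.movement_gain
                + max(self.corrective_gain_random, self.corrective_gain_repeat)
                + self.anticipatory_gain + self.orientation_gain + self.direction_gain)


def _gauss(t: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sd) ** 2)


def intensity(neuron: NeuronGroundTruth, trial: TrialRecord,
              t: np.ndarray, repeat_trial_index: int | None = None) -> np.ndarray:
    """Evaluate the firing intensity lambda(t) in Hz at times ``t`` (trial clock)."""
    if repeat_trial_index is None:
        repeat_trial_index = trial.repeat_trial_index
    t = np.asarray(t, dtype=float)
    lam = np.full_like(t, neuron.baseline_rate)

    rel = trial.t_center_release
    lam += neuron.movement_gain * _gauss(t, rel + neuron.movement_latency,
                                         neuron.movement_width)

    is_repeat = trial.condition.startswith("repeat")
    if trial.perturbed:
        if is_repeat:
            k = max(repeat_trial_index, 1)
            gain = neuron.corrective_gain_repeat * float(
                np.exp(-(k - 1) / neuron.corrective_adaptation_tau))
        else:
            gain = neuron.corrective_gain_random
        lam += gain * _gauss(t, rel + neuron.corrective_peak_latency,
                             neuron.corrective_width)

    if is_repeat and neuron.anticipatory_gain > 0:
        k = max(repeat_trial_index, 1)
        level = neuron.anticipatory_gain * (
            1.0 - np.exp(-k * neuron.anticipatory_learning_rate))
        if neuron.anticipatory_tuning_depth > 0:
            dtheta = np.deg2rad(trial.final_orientation
                                - neuron.preferred_orientation)
            w = 0.5 * (1.0 + np.cos(2.0 * dtheta))
            d = neuron.anticipatory_tuning_depth
            level *= (1.0 - d) + d * w
        t0, t1 = trial.t_light_on, trial.t_perturbation
        ramp = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
        ramp[t > t1] = 0.0
        lam += level * ramp

    # tuned drives persist through the grasp hold so epoch comparisons across
    # conditions with different movement durations see the same tonic level
    in_movement = (t >= rel) & (t < trial.t_target_release)
    if neuron.orientation_gain > 0:
        ref = (trial.final_orientation if neuron.tuning_follows_perturbation
               else trial.initial_orientation)
        dtheta = np.deg2rad(ref - neuron.preferred_orientation)
        tuning = 0.5 * (1.0 + np.cos(2.0 * dtheta))
        lam += neuron.orientation_gain * tuning * in_movement
    if neuron.direction_gain > 0 and trial.target_side == neuron.preferred_side:
        lam += neuron.direction_gain * in_movement

    return np.clip(lam, 0.0, None)


def sample_inhomogeneous_poisson(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    rate_max: float,
    t_stop: float,
    rng: np.random.Generator,
    t_start: float = 0.0,
) -> np.ndarray:
    """Thinning sampler: exact draw from a Poisson process with bounded rate."""
    duration = t_stop - t_start
    if duration <= 0 or rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    if n == 0:
        return np.empty(0)
    cand = np.sort(rng.uniform(t_start, t_stop, n))
    keep = rng.uniform(0.0, rate_max, n) < rate_fn(cand)
    return cand[keep]


def simulate_spikes(neuron: NeuronGroundTruth, trial: TrialRecord,
                    repeat_trial_index: int | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Spike timestamps (trial clock, seconds) for one neuron on one trial."""
    rng = rng or np.random.default_rng()
    return sample_inhomogeneous_poisson(
        lambda t: intensity(neuron, trial, t, repeat_trial_index),
        neuron.max_rate, trial.t_target_release, rng)


# --- population presets ----------------------------------------------------

#: Class mixture mirroring the reported task-related population split:
#: 293/885 responsive to random perturbation only, 315/885 to both schedules,
#: 235/885 repeat-only units carrying anticipatory activity, 42/885 with
#: movement activity only.
PAPER_MIXTURE: dict[str, float] = {
    "corrective_only": 293 / 885,
    "mixed": 315 / 885,
    "corrective_anticipatory": 235 / 885,
    "orientation_tuned": 42 / 885,
}

_CLASS_TEMPLATES: dict[str, dict] = {
    "non_responsive": dict(movement_gain=0.0),
    # responds to random perturbation only
    "corrective_only": dict(corrective_gain_random=60.0),
    # responds under both schedules, smaller repeat gain
    "mixed": dict(corrective_gain_random=60.0, corrective_gain_repeat=35.0,
                  orientation_gain=20.0, tuning_follows_perturbation=False),
    # repeat-only: corrective under repeat plus a strong anticipatory build-up
    "corrective_anticipatory": dict(corrective_gain_repeat=60.0,
                                    anticipatory_gain=120.0,
                                    anticipatory_learning_rate=0.5),
    # task-related through movement/orientation activity only
    "orientation_tuned": dict(orientation_gain=25.0, direction_gain=10.0,
                              tuning_follows_perturbation=False),
}


def make_neuron(neuron_class: str, neuron_id: int,
                rng: np.random.Generator | None = None, **overrides) -> NeuronGroundTruth:
    """Instantiate a neuron of a named class with mild parameter jitter."""
    if neuron_class not in _CLASS_TEMPLATES:
        raise ConfigurationError(f"unknown neuron class {neuron_class!r}")
    params = dict(_CLASS_TEMPLATES[neuron_class])
    base = dict(neuron_id=neuron_id, neuron_class=neuron_class)
    if neuron_class == "non_responsive":
        base["movement_gain"] = 0.0
    if rng is not None:
        base["baseline_rate"] = float(rng.uniform(5.0, 12.0))
        base["preferred_orientation"] = float(rng.choice([45.0, 90.0, 135.0]))
        base["corrective_peak_latency"] = float(rng.uniform(0.23, 0.28))
    params.update(base)
    params.update(overrides)
    return NeuronGroundTruth(**params)


def strong_neuron(neuron_id: int = 0) -> NeuronGroundTruth:
    """A single unit with strong corrective, anticipatory, and tuning signals.

    Used for the single-unit decoding demonstrations: random perturbations
    evoke a large corrective burst, repeat perturbations a smaller one plus a
    pre-perturbation ramp, and orientation tuning separates CW from CCW.
    """
    return NeuronGroundTruth(
        neuron_id=neuron_id, neuron_class="mixed",
        baseline_rate=8.0, movement_gain=25.0,
        corrective_gain_random=350.0, corrective_gain_repeat=100.0,
        corrective_width=0.080,
        anticipatory_gain=500.0, anticipatory_learning_rate=1.5,
        anticipatory_tuning_depth=0.5,
        orientation_gain=250.0, preferred_orientation=45.0,
    )


def anticipatory_only_neuron(neuron_id: int = 0) -> NeuronGroundTruth:
    """A unit whose only condition information is the repeat-trial ramp.

    The ramp is partially orientation-tuned, so a direction-task network can
    learn it, but random-perturbation trials carry no pre-perturbation signal
    at all.
    """
    return NeuronGroundTruth(
        neuron_id=neuron_id, neuron_class="corrective_anticipatory",
        baseline_rate=8.0, movement_gain=20.0,
        corrective_gain_random=0.0, corrective_gain_repeat=0.0,
        anticipatory_gain=400.0, anticipatory_learning_rate=1.5,
        anticipatory_tuning_depth=0.5, preferred_orientation=45.0,
    )


def allocate_classes(n_neurons: int, mixture: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of class counts."""
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-6:
        raise ConfigurationError("class mixture proportions must sum to 1")
    names = sorted(mixture)
    exact = np.array([mixture[c] * n_neurons for c in names])
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder)[: n_neurons - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for name, c in zip(names, counts):
        out.extend([name] * int(c))
    return out


def generate_population(
    n_neurons: int,
    class_mixture: dict[str, float] | str = "paper_mixture",
    seed: int | np.random.Generator = 0,
    trials: list[TrialRecord] | None = None,
) -> tuple[list[NeuronGroundTruth], dict[int, dict[int, np.ndarray]] | None]:
    """Generate a ground-truth population and (optionally) its spike trains.

    Returns ``(neurons, spikes)`` where ``spikes[neuron_id][trial_id]`` is an
    array of spike times; ``spikes`` is None when no trials are given.
    """
    if isinstance(class_mixture, str):
        if class_mixture != "paper_mixture":
            raise ConfigurationError(f"unknown mixture preset {class_mixture!r}")
        class_mixture = PAPER_MIXTURE
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = allocate_classes(n_neurons, class_mixture)
    neurons = [make_neuron(c, i, rng) for i, c in enumerate(classes)]
    if trials is None:
        return neurons, None
    spikes: dict[int, dict[int, np.ndarray]] = {}
    for neuron in neurons:
        per_trial = {}
        for trial in trials:
            per_trial[trial.trial_id] = simulate_spikes(neuron, trial, rng=rng)
        spikes[neuron.neuron_id] = per_trial
    return neurons, spikes


def ground_truth_frame(neurons: list[NeuronGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(n) for n in neurons])
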