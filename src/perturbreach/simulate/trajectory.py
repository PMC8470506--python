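"""Hand-orientation trajectory synthesis.

Trajectories are built from minimum-jerk position segments sampled at 100 Hz.
On perturbed trials a corrective segment toward the new target orientation
begins ``true_rtp`` seconds after perturbation onset, with a transient
over-rotation past the final orientation whose amplitude decays over repeat
trials.  Additive noise is smooth (Gaussian-filtered white noise) so the
band-deviation reaction-time detector sees realistically correlated jitter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ConfigurationError, TrialRecord

SAMPLE_STEP = 0.010  # 100 Hz


@dataclass(frozen=True)
class BehaviorParams:
    """Kinematic and timing parameters of the synthetic subject."""

    rtc_mean: float = 0.250
    rtc_sd: float = 0.050
    hold_jitter: float = 0.200          # uniform jitter added to the 300 ms hold
    mt_unperturbed_mean: float = 0.270
    mt_perturbed_mean: float = 0.400
    mt_adaptation_decay: float = 8.0     # repeat-trial MT relaxes toward unperturbed
    mt_sd: float = 0.020
    tht_mean: float = 0.300
    tht_sd: float = 0.030
    true_rtp_initial: float = 0.100      # corrective delay after perturbation onset
    rtp_decay_constant: float = 5.0      # trials
    rtp_floor: float = -0.020            # late repeat trials may anticipate
    overrotation_initial: float = 10.0   # degrees
    overrotation_decay: float = 8.0      # trials
    overshoot_fraction: float = 0.35     # share of corrective time spent overshooting
    trajectory_noise_sd: float = 0.75    # degrees
    noise_smoothing_sd: float = 0.030    # seconds

    def __post_init__(self) -> None:
        if self.mt_perturbed_mean <= self.mt_unperturbed_mean:
            raise ConfigurationError("perturbed MT mean must exceed unperturbed")
        if self.rtp_decay_constant <= 0 or self.overrotation_decay <= 0:
            raise ConfigurationError("decay constants must be positive")
        if not 0.0 < self.overshoot_fraction < 1.0:
            raise ConfigurationError("overshoot_fraction must lie in (0, 1)")

    def draw_rtc(self, rng: np.random.Generator) -> float:
        """Cue reaction time, lognormal with the configured mean and sd."""
        var = self.rtc_sd ** 2
        mu = np.log(self.rtc_mean ** 2 / np.sqrt(var + self.rtc_mean ** 2))
        sigma = np.sqrt(np.log(1.0 + var / self.rtc_mean ** 2))
        return float(rng.lognormal(mu, sigma))


def true_rtp(behavior: BehaviorParams, repeat_trial_index: int, schedule: str) -> float:
    """Ground-truth corrective delay after perturbation onset.

    Repeat trials adapt exponentially from ``true_rtp_initial`` toward
    ``rtp_floor``; random trials keep the initial delay.
    """
    if schedule != "repeat":
        return behavior.true_rtp_initial
    k = max(int(repeat_trial_index), 1)
    return behavior.rtp_floor + (behavior.true_rtp_initial - behavior.rtp_floor) * float(
        np.exp(-k / behavior.rtp_decay_constant)
    )


def minimum_jerk(t: np.ndarray, t0: float, t1: float, a0: float, a1: float) -> np.ndarray:
    """Minimum-jerk position profile from a0 at t0 to a1 at t1 (clamped outside)."""
    s = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return a0 + (a1 - a0) * (10 * s**3 - 15 * s**4 + 6 * s**5)


def _smooth_noise(n: int, sd: float, smoothing_samples: float,
                  rng: np.random.Generator) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n + 1)
    half = int(np.ceil(4 * smoothing_samples))
    x = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (x / max(smoothing_samples, 1e-9)) ** 2)
    w /= np.sqrt(np.sum(w**2))  # unit output variance for unit white input
    return sd * np.convolve(white, w, mode="same")[:n]


def simulate_trajectory(
    trial: TrialRecord,
    behavior: BehaviorParams | None = None,
    repeat_trial_index: int | None = None,
    rng: np.random.Generator | None = None,
    *,
    start_orientation: float = 90.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one trial's orientation-angle series.

    Returns ``(sample_times, angle_deg)`` on a uniform 10 ms grid from pad hit
    to target release.  Noiseless output hits ``final_orientation`` exactly at
    ``t_target_hit`` and over-rotates by exactly the configured amplitude.
    """
    behavior = behavior or BehaviorParams()
    rng = rng or np.random.default_rng()
    if repeat_trial_index is None:
        repeat_trial_index = trial.repeat_trial_index

    n = int(np.floor(trial.t_target_release / SAMPLE_STEP)) + 1
    t = np.arange(n) * SAMPLE_STEP

    rel, hit = trial.t_center_release, trial.t_target_hit
    if not trial.perturbed:
        angle = minimum_jerk(t, rel, hit, start_orientation, trial.initial_orientation)
    else:
        schedule = "repeat" if trial.condition.startswith("repeat") else "random"
        if schedule == "repeat" and repeat_trial_index < 1:
            raise ValueError("repeat trials need repeat_trial_index >= 1")
        # primary movement heads for the pre-perturbation target
        angle = minimum_jerk(t, rel, rel + behavior.mt_unperturbed_mean,
                             start_orientation, trial.initial_orientation)
        t_corr = trial.t_perturbation + true_rtp(behavior, repeat_trial_index, schedule)
        t_corr = min(max(t_corr, rel), hit - 2 * SAMPLE_STEP)
        a_corr = float(minimum_jerk(np.array([t_corr]), rel,
                                    rel + behavior.mt_unperturbed_mean,
                                    start_orientation, trial.initial_orientation)[0])
        if schedule == "repeat":
            amp = behavior.overrotation_initial * float(
                np.exp(-repeat_trial_index / behavior.overrotation_decay))
        else:
            amp = behavior.overrotation_initial
        sign = np.sign(trial.final_orientation - trial.initial_orientation)
        peak = trial.final_orientation + sign * amp
        t_peak = t_corr + behavior.overshoot_fraction * (hit - t_corr)
        corr = np.where(
            t < t_peak,
            minimum_jerk(t, t_corr, t_peak, a_corr, peak),
            minimum_jerk(t, t_peak, hit, peak, trial.final_orientation),
        )
        angle = np.where(t >= t_corr, corr, angle)

    angle = angle + _smooth_noise(
        n, behavior.trajectory_noise_sd,
        behavior.noise_smoothing_sd / SAMPLE_STEP, rng)
    return t, angle
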