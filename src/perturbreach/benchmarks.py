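"""Desk-scale benchmark quantities recomputed from scratch.

Each function simulates its own inputs from a seed, runs the relevant part of
the pipeline, and returns the measured quantity on the scale the headline
numbers are quoted in (counts, milliseconds, percent).  They back both the
acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import decode, epochs, kinematics
from .report import PRE_PERTURBATION_WINDOW
from .simulate import (
    BehaviorParams,
    anticipatory_only_neuron,
    generate_block,
    generate_session,
    simulate_trajectory,
    strong_neuron,
)


def _seeds(seed: int, label: int, n: int = 1) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence([int(seed), label]).spawn(n)


def block_trial_count(seed: int) -> tuple[int, dict[int, int]]:
    """Total trials and per-set sizes of one generated block."""
    _, trials = generate_block(int(seed))
    sizes: dict[int, int] = {}
    for t in trials:
        sizes[t.set_index] = sizes.get(t.set_index, 0) + 1
    return len(trials), sizes


def perturbation_latency_ms(seed: int) -> tuple[float, int]:
    """Common release-to-perturbation interval over all perturbed trials (ms)."""
    _, trials = generate_block(int(seed))
    lat = {round((t.t_perturbation - t.t_center_release) * 1e3, 6)
           for t in trials if t.perturbed}
    if len(lat) != 1:
        raise AssertionError(f"perturbation latency not constant: {lat}")
    return lat.pop(), sum(1 for t in trials if t.perturbed)


def _decode_rep(session_seed, train_seed, task: str) -> float:
    session = generate_session(session_seed, neurons=[strong_neuron()],
                               with_trajectories=False)
    fm = decode.extract_features(session.spikes[0], session.trials, task=task)
    rng = np.random.default_rng(train_seed)
    decoder = decode.train_bp(fm, seed=rng)
    res = decode.classify_test_set(decoder, n_per_class=6, rng=rng)
    return res.rate


def single_unit_decode_median(seed: int, task: str, n_seeds: int = 20
                              ) -> tuple[float, int]:
    """Median correct prediction rate (%) over replicate sessions/networks.

    18 stratified held-out trials (6 per class), +/-0.6 threshold rule.
    """
    label = {"condition": 3, "direction": 4}[task]
    rates = []
    for rep_ss in _seeds(seed, label, n_seeds):
        sess_ss, train_ss = rep_ss.spawn(2)
        rates.append(_decode_rep(sess_ss, train_ss, task))
    return float(np.median(rates) * 100.0), n_seeds * 18


def cross_test_rate(seed: int, n_seeds: int = 20) -> tuple[float, int]:
    """Median rate of the direction-task net scored on random trials.

    Pre-perturbation feature window; the neuron's anticipatory modulation
    exists only on repeat trials, so random trials look unperturbed and the
    outputs never commit to +/-1.
    """
    rates, n_trials = [], 0
    for rep_ss in _seeds(seed, 5, n_seeds):
        sess_ss, train_ss = rep_ss.spawn(2)
        session = generate_session(sess_ss, neurons=[anticipatory_only_neuron()],
                                   with_trajectories=False)
        fm = decode.extract_features(session.spikes[0], session.trials,
                                     task="direction",
                                     window=PRE_PERTURBATION_WINDOW)
        decoder = decode.train_bp(fm, seed=np.random.default_rng(train_ss))
        res = decode.cross_test_random(decoder, session.spikes[0], session.trials)
        rates.append(res.rate)
        n_trials += res.labels.size
    return float(np.median(rates)), n_trials


def rtp_mean_ms(seed: int, n_trials: int = 200) -> tuple[float, int]:
    """Mean estimated RTp (ms) over random-perturbation trials."""
    behavior = BehaviorParams()
    rtps: list[float] = []
    for i, block_ss in enumerate(_seeds(seed, 6, 16)):
        design_ss, traj_ss = block_ss.spawn(2)
        _, trials = generate_block(np.random.default_rng(design_ss),
                                   behavior=behavior)
        rng = np.random.default_rng(traj_ss)
        trajs = {t.trial_id: simulate_trajectory(t, behavior, rng=rng)
                 for t in trials}
        df = kinematics.estimate_rtp_block(trials, trajs)
        rand = df[df["condition"].isin(["random_CW", "random_CCW"])
                  & df["detected"]]
        rtps.extend(rand["rtp"].tolist())
        if len(rtps) >= n_trials:
            break
    rtps = rtps[:n_trials]
    return float(np.mean(rtps) * 1e3), len(rtps)


def mixture_flag_fractions(seed: int, n_neurons: int = 885,
                           run_anova: bool = False) -> dict[str, float]:
    """Flagged anticipatory / corrective-under-random percentages.

    Generates a "paper_mixture" population, runs the epoch pipeline, and
    reports each flag's prevalence among task-related units (percent).
    """
    session = generate_session(int(seed), n_neurons=n_neurons,
                               with_trajectories=False)
    df = epochs.classify_population(session.trials, session.spikes,
                                    run_anova=run_anova)
    related = df[df["task_related"]]
    return {
        "anticipatory_pct": float(related["anticipatory"].mean() * 100.0),
        "corrective_random_pct": float(
            related["corrective_random"].mean() * 100.0),
        "n_task_related": int(len(related)),
    }
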