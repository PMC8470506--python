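import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbreach import epochs
from perturbreach.epochs import (
    DataError,
    anticipatory_rates,
    anticipatory_test,
    baseline_stability_filter,
    categorize_population,
    classify_neuron,
    compute_epochs,
    detect_task_related,
    epoch_firing_rates,
    epoch_rate_table,
    perturbation_response_rates,
    perturbation_response_test,
    two_sample_t,
    two_way_anova,
    window_rate,
)
from perturbreach.simulate import generate_block, simulate_spikes
from perturbreach.simulate.design import TrialRecord
from perturbreach.simulate.spikes import NeuronGroundTruth, make_neuron


def _trial(**kw):
    base = dict(trial_id=0, set_index=2, target_side="right",
                initial_orientation=90.0, final_orientation=135.0,
                condition="random_CCW", t_pad_hit=0.0, t_light_on=0.35,
                t_center_release=0.550, t_perturbation=0.620,
                t_target_hit=0.950, t_target_release=1.3)
    base.update(kw)
    return TrialRecord(**base)


# --- windows ---------------------------------------------------------------

def test_epoch_example_pd_pr():
    w = compute_epochs(_trial())
    assert w.pd[1] - w.pd[0] == pytest.approx(0.070)
    assert w.pr[1] - w.pr[0] == pytest.approx(0.330)
    assert w.cht == (0.0, 0.35)
    assert w.rtc == (0.35, 0.550)


def test_unperturbed_has_no_pd_pr():
    w = compute_epochs(_trial(condition="unperturbed", t_perturbation=None,
                              final_orientation=90.0))
    assert w.pd is None and w.pr is None
    assert w.mt == (0.550, 0.950)


def test_degenerate_window_raises():
    with pytest.raises(DataError):
        compute_epochs(_trial(t_target_hit=0.550))


def test_missing_perturbation_time_raises():
    trial = _trial()
    trial.t_perturbation = None  # perturbed condition label, no timestamp
    with pytest.raises(DataError):
        compute_epochs(trial)


def test_pd_plus_pr_equals_mt(trials):
    for t in trials:
        if not t.perturbed:
            continue
        w = compute_epochs(t)
        assert (w.pd[1] - w.pd[0]) + (w.pr[1] - w.pr[0]) == pytest.approx(
            w.mt[1] - w.mt[0], abs=1e-12)


# --- rates -----------------------------------------------------------------

def test_five_spikes_quarter_second_is_20hz():
    spikes = np.array([0.60, 0.65, 0.70, 0.75, 0.79])
    w = compute_epochs(_trial(t_target_hit=0.800))
    rates = epoch_firing_rates(spikes, w)
    assert rates["mt"] == pytest.approx(5 / 0.25)


def test_empty_train_all_zero(trials):
    w = compute_epochs(trials[0])
    rates = epoch_firing_rates(np.empty(0), w)
    for name, val in rates.items():
        if not np.isnan(val):
            assert val == 0.0


def test_half_open_window_excludes_end():
    # spike exactly at the window end is not counted
    assert window_rate(np.array([1.0]), 0.0, 1.0) == 0.0
    assert window_rate(np.array([0.0]), 0.0, 1.0) == 1.0


# --- t-test primitive ------------------------------------------------------

def test_t_test_matches_textbook_formula(rng):
    # oracle: pooled-variance two-sample t computed from first principles
    for _ in range(100):
        nx, ny = rng.integers(3, 20, size=2)
        x = rng.normal(0, 1, nx)
        y = rng.normal(0.3, 1.4, ny)
        t, p = two_sample_t(x, y)
        sp2 = (((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
               / (nx + ny - 2))
        t_ref = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        p_ref = 2 * stats.t.sf(abs(t_ref), nx + ny - 2)
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)


def test_t_test_identical_constant_samples():
    t, p = two_sample_t(np.ones(5), np.ones(6))
    assert p == 1.0


def test_t_test_constant_but_unequal():
    _, p = two_sample_t(np.full(5, 2.0), np.full(5, 1.0), "greater")
    assert p == 0.0


# --- task-related rule -----------------------------------------------------

def _rates_frame(cht, rtc, mt, tht, set_index=None, condition="unperturbed"):
    n = len(cht)
    return pd.DataFrame({
        "neuron_id": 0, "trial_id": np.arange(n),
        "set_index": set_index if set_index is not None else np.ones(n, int),
        "condition": condition, "target_side": "right",
        "initial_orientation": 90.0, "final_orientation": 90.0,
        "cht": cht, "rtc": rtc, "mt": mt, "pd": np.nan, "pr": np.nan,
        "tht": tht})


def test_task_related_rule_arithmetic(rng):
    cht = rng.normal(10, 2, 200)
    mu, sd = cht.mean(), cht.std(ddof=1)
    mt_hot = np.full(200, mu + 2.5 * sd)
    flat = np.full(200, mu)
    res = detect_task_related(_rates_frame(cht, flat, mt_hot, flat))
    assert res.task_related
    assert res.z_scores["mt"] > 2.0 > res.z_scores["rtc"]


def test_all_epochs_at_baseline_not_task_related(rng):
    cht = rng.normal(10, 2, 200)
    flat = np.full(200, cht.mean())
    res = detect_task_related(_rates_frame(cht, flat, flat, flat))
    assert not res.task_related


def test_task_related_needs_10_trials(rng):
    df = _rates_frame(*(rng.normal(10, 1, 5) for _ in range(4)))
    with pytest.raises(DataError):
        detect_task_related(df)


def test_degenerate_zero_sd_baseline_flagged():
    cht = np.full(20, 10.0)
    hot = np.full(20, 10.5)
    res = detect_task_related(_rates_frame(cht, hot, cht, cht))
    assert res.degenerate_baseline
    assert res.task_related  # any elevation beats a floored sd


# --- baseline stability ----------------------------------------------------

def test_identical_baselines_retained(rng):
    sets = np.repeat([1, 2, 3, 4], 30)
    cht = rng.normal(10, 2, sets.size)
    df = _rates_frame(cht, cht, cht, cht, set_index=sets)
    res = baseline_stability_filter(df)
    assert res.testable and not res.excluded
    assert len(res.p_values) == 6


def test_shifted_set_excluded(rng):
    sets = np.repeat([1, 2, 3, 4], 30)
    cht = rng.normal(10, 1, sets.size)
    cht[sets == 3] += 5.0
    res = baseline_stability_filter(_rates_frame(cht, cht, cht, cht, set_index=sets))
    assert res.excluded


def test_too_few_sets_untestable(rng):
    sets = np.ones(30, int)
    cht = rng.normal(10, 1, 30)
    res = baseline_stability_filter(_rates_frame(cht, cht, cht, cht, set_index=sets))
    assert not res.testable and not res.excluded


def test_null_exclusion_matches_familywise_oracle(rng):
    # oracle: direct simulation of 6 uncorrected pairwise t-tests on the
    # same four groups, sharing samples exactly as the filter does
    sizes = {1: 90, 2: 90, 3: 30, 4: 30}
    n_units = 400

    def familywise(reject_fn):
        hits = 0
        for _ in range(n_units):
            groups = {s: rng.normal(10, 3, n) for s, n in sizes.items()}
            hits += reject_fn(groups)
        return hits / n_units

    def oracle(groups):
        from itertools import combinations
        for a, b in combinations(sorted(groups), 2):
            if stats.ttest_ind(groups[a], groups[b]).pvalue < 0.05:
                return True
        return False

    def filt(groups):
        sets = np.concatenate([np.full(v.size, s) for s, v in groups.items()])
        cht = np.concatenate(list(groups.values()))
        df = _rates_frame(cht, cht, cht, cht, set_index=sets)
        return baseline_stability_filter(df).excluded

    r_oracle = familywise(oracle)
    r_filter = familywise(filt)
    assert r_filter == pytest.approx(r_oracle, abs=0.06)
    assert 0.10 < r_filter < 0.35


# --- perturbation response and anticipatory tests --------------------------

def _spikes_for(neuron, trials, rng):
    return {t.trial_id: simulate_spikes(neuron, t, rng=rng) for t in trials}


def test_corrective_power_and_null(trials, rng):
    n_units, flagged_hot, flagged_null = 40, 0, 0
    for i in range(n_units):
        hot = NeuronGroundTruth(baseline_rate=8, movement_gain=20,
                                corrective_gain_random=30.0)
        null = NeuronGroundTruth(baseline_rate=8, movement_gain=20)
        for neuron, bucket in ((hot, "hot"), (null, "null")):
            spk = _spikes_for(neuron, trials, rng)
            x, y = perturbation_response_rates(trials, spk, "random")
            res = perturbation_response_test(x, y)
            if bucket == "hot":
                flagged_hot += res.flag
            else:
                flagged_null += res.flag
    assert flagged_hot / n_units >= 0.95
    assert flagged_null / n_units <= 0.20


def test_anticipatory_power_and_null(trials, rng):
    n_units, flagged_hot, flagged_null = 40, 0, 0
    for i in range(n_units):
        hot = NeuronGroundTruth(baseline_rate=8, movement_gain=20,
                                anticipatory_gain=25.0,
                                anticipatory_learning_rate=0.5)
        null = NeuronGroundTruth(baseline_rate=8, movement_gain=20,
                                 corrective_gain_random=30.0)
        for neuron, bucket in ((hot, "hot"), (null, "null")):
            spk = _spikes_for(neuron, trials, rng)
            x, y = anticipatory_rates(trials, spk)
            res = anticipatory_test(x, y)
            if bucket == "hot":
                flagged_hot += res.flag
            else:
                flagged_null += res.flag
    assert flagged_hot / n_units >= 0.95
    assert flagged_null / n_units <= 0.20


def test_identical_samples_not_flagged():
    res = perturbation_response_test(np.ones(8), np.ones(9))
    assert res.p_value == 1.0 and not res.flag


# --- two-way ANOVA ---------------------------------------------------------

def _anova_frame(rates, sides, orients):
    n = len(rates)
    return pd.DataFrame({
        "condition": "unperturbed", "target_side": sides,
        "initial_orientation": orients, "mt": rates})


def test_anova_identical_rates_null():
    sides = np.repeat(["left", "right"], 45)
    orients = np.tile(np.repeat([45.0, 90.0, 135.0], 15), 2)
    out = two_way_anova(_anova_frame(np.full(90, 7.0), sides, orients))
    for eff in ("direction", "orientation", "interaction"):
        assert out[f"F_{eff}"] == pytest.approx(0.0, abs=1e-9)
        assert out[f"p_{eff}"] == pytest.approx(1.0)


def test_anova_matches_balanced_ss_oracle(rng):
    # oracle: classical balanced two-way sum-of-squares decomposition
    for _ in range(100):
        r = rng.integers(3, 8)  # replicates per cell
        y = rng.normal(0, 1, (2, 3, r))
        y += rng.normal(0, 1, (2, 1, 1))   # direction effect
        y += rng.normal(0, 1, (1, 3, 1))   # orientation effect
        grand = y.mean()
        a_means = y.mean(axis=(1, 2))
        b_means = y.mean(axis=(0, 2))
        cell_means = y.mean(axis=2)
        ss_a = 3 * r * np.sum((a_means - grand) ** 2)
        ss_b = 2 * r * np.sum((b_means - grand) ** 2)
        ss_cells = r * np.sum((cell_means - grand) ** 2)
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = np.sum((y - cell_means[:, :, None]) ** 2)
        df_err = 2 * 3 * (r - 1)
        f_a = (ss_a / 1) / (ss_err / df_err)
        f_b = (ss_b / 2) / (ss_err / df_err)
        f_ab = (ss_ab / 2) / (ss_err / df_err)

        sides = np.repeat(["left", "right"], 3 * r)
        orients = np.tile(np.repeat([45.0, 90.0, 135.0], r), 2)
        out = two_way_anova(_anova_frame(y.reshape(-1), sides, orients))
        assert out["F_direction"] == pytest.approx(f_a, rel=1e-10)
        assert out["F_orientation"] == pytest.approx(f_b, rel=1e-10)
        assert out["F_interaction"] == pytest.approx(f_ab, rel=1e-10)
        assert out["p_orientation"] == pytest.approx(
            stats.f.sf(f_b, 2, df_err), rel=1e-10)


def test_orientation_tuned_neuron_flagged(trials, rng):
    hits_orient, hits_dir = 0, 0
    n_units = 20
    for i in range(n_units):
        neuron = NeuronGroundTruth(baseline_rate=8, movement_gain=10,
                                   orientation_gain=20.0,
                                   preferred_orientation=45.0)
        spk = _spikes_for(neuron, trials, rng)
        rec = classify_neuron(trials, spk, neuron_id=i, run_anova=True)
        hits_orient += rec["orientation_effect"]
        hits_dir += rec["direction_effect"]
    assert hits_orient / n_units >= 0.90
    assert hits_dir / n_units <= 0.25


def test_anova_empty_cell_raises():
    sides = np.repeat(["left", "right"], 6)
    orients = np.tile([45.0, 90.0, 90.0, 135.0, 135.0, 135.0], 2)
    with pytest.raises(DataError):
        two_way_anova(_anova_frame(np.ones(12), sides, orients))


# --- categories and invariance ---------------------------------------------

def test_category_assignment():
    base = dict(task_related=True, corrective_random=False, corrective_repeat=False)
    assert epochs._category(base) == "unperturbed_only"
    assert epochs._category({**base, "corrective_random": True}) == "random_only"
    assert epochs._category({**base, "corrective_repeat": True}) == "repeat_only"
    assert epochs._category({**base, "corrective_random": True,
                             "corrective_repeat": True}) == "both"
    assert epochs._category({**base, "task_related": False}) is None


def test_category_fractions_partition(small_session):
    df = epochs.classify_population(small_session.trials, small_session.spikes,
                                    run_anova=False)
    fr = categorize_population(df)
    if fr:
        assert sum(fr.values()) == pytest.approx(1.0)


def test_classification_invariant_to_time_translation(trials, rng):
    neuron = make_neuron("mixed", 0)
    spk = _spikes_for(neuron, trials[:120], rng)
    rec = classify_neuron(trials[:120], spk, run_anova=False)

    delta = 3.7
    shifted_trials = []
    for t in trials[:120]:
        d = dataclasses.asdict(t)
        for key in ("t_pad_hit", "t_light_on", "t_center_release",
                    "t_target_hit", "t_target_release"):
            d[key] += delta
        if d["t_perturbation"] is not None:
            d["t_perturbation"] += delta
        shifted_trials.append(TrialRecord(**d))
    shifted_spk = {tid: s + delta for tid, s in spk.items()}
    rec2 = classify_neuron(shifted_trials, shifted_spk, run_anova=False)
    for key in ("task_related", "corrective_random", "corrective_repeat",
                "anticipatory"):
        assert rec[key] == rec2[key]
    for key in ("p_corrective_random", "p_corrective_repeat", "p_anticipatory"):
        assert rec[key] == pytest.approx(rec2[key], rel=1e-6, nan_ok=True)
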