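"""End-to-end pipeline: simulate a session, run every analysis stage, and
emit a report bundle (TSV tables + summary JSON + recovery comparison).

A run is fully determined by its :class:`RunConfig` and seed; the config
round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode, epochs, kinematics, psth
from .simulate import (
    generate_session,
    write_session,
)

logger = logging.getLogger(__name__)

#: release-aligned feature window ending at perturbation onset (decoder
#: anticipatory analyses); bounds are multiples of the 20 ms bin
PRE_PERTURBATION_WINDOW = (-0.300, 0.060)


@dataclass
class RunConfig:
    seed: int = 0
    n_neurons: int = 40
    class_mixture: str = "paper_mixture"
    alpha: float = 0.05
    band_kind: str = "normal"
    deviation_k: int = 3
    decoder_hidden: int = 10
    decoder_learning_rate: float = 0.05
    decoder_epochs: int = 500
    decoder_window: tuple[float, float] = (-0.300, 0.500)
    decoder_bin: float = 0.020
    n_decode_neurons: int = 10
    run_anova: bool = True
    make_plots: bool = True
    out_dir: str = "perturbreach_run"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["decoder_window"] = list(d["decoder_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "decoder_window" in d:
            d["decoder_window"] = tuple(d["decoder_window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return inner
    return wrap


def _recovery_table(session, classifications: pd.DataFrame) -> pd.DataFrame:
    """Ground truth vs recovered flags, per generator class."""
    truth = pd.DataFrame(
        [{"neuron_id": n.neuron_id, "neuron_class": n.neuron_class,
          "true_corrective_random": n.corrective_gain_random > 0,
          "true_corrective_repeat": n.corrective_gain_repeat > 0,
          "true_anticipatory": n.anticipatory_gain > 0}
         for n in session.neurons])
    merged = truth.merge(classifications, on="neuron_id")
    rows = []
    for cls, grp in merged.groupby("neuron_class"):
        rows.append(dict(
            neuron_class=cls, n=len(grp),
            true_anticipatory=float(grp["true_anticipatory"].mean()),
            flagged_anticipatory=float(grp["anticipatory"].mean()),
            true_corrective_random=float(grp["true_corrective_random"].mean()),
            flagged_corrective_random=float(grp["corrective_random"].mean()),
            task_related=float(grp["task_related"].mean()),
        ))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Run simulate -> epochs -> kinematics -> psth -> decode and summarise."""
    out = Path(config.out_dir)
    session = _stage("simulate")(generate_session)(
        config.seed, n_neurons=config.n_neurons,
        class_mixture=config.class_mixture)
    logger.info("simulated %d trials, %d neurons", len(session.trials),
                len(session.neurons))

    classifications = _stage("epochs")(epochs.classify_population)(
        session.trials, session.spikes, alpha=config.alpha,
        run_anova=config.run_anova)
    fractions = epochs.categorize_population(classifications)

    rtp_df = _stage("kinematics")(kinematics.estimate_rtp_block)(
        session.trials, session.trajectories, k=config.deviation_k,
        band_kind=config.band_kind)
    series = kinematics.rtp_adaptation_series(rtp_df)

    psth_df = _stage("psth")(psth.psth_table)(
        session.spikes, session.trials, event="center_release")

    decode_rows = []
    retained = classifications[classifications["task_related"]
                               & ~classifications["excluded_unstable_baseline"]]
    decode_ids = retained["neuron_id"].head(config.n_decode_neurons)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xDEC0DE]))
    for nid in decode_ids:
        for task in decode.TASKS:
            fm = decode.extract_features(
                session.spikes[nid], session.trials, task=task,
                window=config.decoder_window, bin_width=config.decoder_bin)
            decoder = _stage("decode")(decode.train_bp)(
                fm, hidden=config.decoder_hidden,
                learning_rate=config.decoder_learning_rate,
                epochs=config.decoder_epochs, seed=rng)
            res = decode.classify_test_set(decoder)
            decode_rows.append(dict(neuron_id=nid, task=task, rate=res.rate,
                                    cluster=res.cluster))
    decode_df = pd.DataFrame(decode_rows)
    clusters = {
        task: decode.cluster_rates(decode_df[decode_df["task"] == task]["rate"])
        for task in decode.TASKS
    } if not decode_df.empty else {}

    recovery = _recovery_table(session, classifications)

    summary = {
        "seed": config.seed,
        "n_trials": len(session.trials),
        "n_neurons": len(session.neurons),
        "n_task_related": int(classifications["task_related"].sum()),
        "n_excluded_unstable": int(
            classifications["excluded_unstable_baseline"].sum()),
        "category_fractions": fractions,
        "anticipatory_fraction": float(
            retained["anticipatory"].mean()) if len(retained) else None,
        "corrective_random_fraction": float(
            retained["corrective_random"].mean()) if len(retained) else None,
        "rtp_random_mean": series.random_mean,
        "rtp_random_ci": list(series.random_ci),
        "decode_clusters": clusters,
    }

    bundle = dict(session=session, classifications=classifications,
                  fractions=fractions, rtp=rtp_df, rtp_series=series,
                  psth=psth_df, decode=decode_df, recovery=recovery,
                  summary=summary)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        write_session(session, out / "session")
        classifications.to_csv(out / "classification.tsv", sep="\t", index=False)
        rtp_df.to_csv(out / "rtp.tsv", sep="\t", index=False)
        series.repeat_series.to_csv(out / "rtp_series.tsv", sep="\t", index=False)
        psth_df.to_csv(out / "psth.tsv", sep="\t", index=False)
        if not decode_df.empty:
            decode_df.to_csv(out / "decode_results.tsv", sep="\t", index=False)
        recovery.to_csv(out / "recovery.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if config.make_plots:
            from . import plots
            from .psth import align_spikes, build_psth
            plots.plot_rtp_series(series, out / "rtp_series.png")
            if len(decode_ids):
                nid = int(decode_ids.iloc[0])
                sel = [t for t in session.trials
                       if t.condition in ("random_CW", "random_CCW")]
                aligned = align_spikes(session.spikes[nid], sel, "center_release")
                h = build_psth(aligned, window=(-0.5, 0.7),
                               event="center_release")
                plots.plot_raster_histogram(
                    aligned, h, out / f"raster_neuron{nid}.png",
                    title=f"neuron {nid}: random perturbation trials")
        logger.info("report written to %s", out)
    return bundle
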