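"""Assemble and persist complete synthetic sessions.

A session bundles one block's trial table, per-trial orientation
trajectories, per-neuron spike trains, and the generating ground truth.
Everything is written as tab-separated text so a session round-trips through
plain files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import BlockDesign, TrialRecord, generate_block, trials_to_frame, frame_to_trials
from .trajectory import BehaviorParams, simulate_trajectory
from .spikes import (
    NeuronGroundTruth,
    generate_population,
    ground_truth_frame,
    simulate_spikes,
)


@dataclass
class Session:
    """One synthetic recording session with ground truth attached."""

    design: BlockDesign
    behavior: BehaviorParams
    trials: list[TrialRecord]
    trajectories: dict[int, tuple[np.ndarray, np.ndarray]]  # trial_id -> (t, angle)
    neurons: list[NeuronGroundTruth]
    spikes: dict[int, dict[int, np.ndarray]]  # neuron_id -> trial_id -> times
    seed: int | None = None

    @property
    def trials_frame(self) -> pd.DataFrame:
        return trials_to_frame(self.trials)

    @property
    def spikes_frame(self) -> pd.DataFrame:
        rows = []
        for nid, per_trial in self.spikes.items():
            for tid, times in per_trial.items():
                for ts in times:
                    rows.append((nid, tid, ts))
        return pd.DataFrame(rows, columns=["neuron_id", "trial_id", "t_spike"])

    @property
    def trajectories_frame(self) -> pd.DataFrame:
        parts = []
        for tid, (t, angle) in self.trajectories.items():
            parts.append(pd.DataFrame(
                {"trial_id": tid, "t": t, "angle_deg": angle}))
        return pd.concat(parts, ignore_index=True)


def generate_session(
    seed: int,
    n_neurons: int = 0,
    class_mixture: dict[str, float] | str = "paper_mixture",
    design: BlockDesign | None = None,
    behavior: BehaviorParams | None = None,
    neurons: list[NeuronGroundTruth] | None = None,
    with_trajectories: bool = True,
) -> Session:
    """Generate a full session deterministically from one integer seed.

    Either ``n_neurons`` (with a class mixture) or an explicit ``neurons``
    list selects the population.  Independent random substreams are spawned
    for the design, kinematics, and each neuron, so e.g. adding neurons does
    not change the behaviour of the block.
    """
    design = design or BlockDesign()
    behavior = behavior or BehaviorParams()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    design_ss, traj_ss, pop_ss, spike_ss = ss.spawn(4)

    _, trials = generate_block(np.random.default_rng(design_ss), design,
                               behavior=behavior)

    trajectories: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    if with_trajectories:
        traj_rng = np.random.default_rng(traj_ss)
        for trial in trials:
            trajectories[trial.trial_id] = simulate_trajectory(
                trial, behavior, rng=traj_rng,
                start_orientation=design.start_orientation)

    if neurons is None:
        neurons, _ = generate_population(n_neurons, class_mixture,
                                         np.random.default_rng(pop_ss))
    spikes: dict[int, dict[int, np.ndarray]] = {}
    spike_streams = spike_ss.spawn(len(neurons))
    for neuron, sub in zip(neurons, spike_streams):
        rng = np.random.default_rng(sub)
        spikes[neuron.neuron_id] = {
            trial.trial_id: simulate_spikes(neuron, trial, rng=rng)
            for trial in trials
        }
    return Session(design=design, behavior=behavior, trials=trials,
                   trajectories=trajectories, neurons=neurons, spikes=spikes,
                   seed=seed)


def write_session(session: Session, out_dir: str | Path) -> dict[str, Path]:
    """Write trials.tsv, spikes.tsv, traj.tsv, and ground_truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["trials"] = out / "trials.tsv"
    session.trials_frame.to_csv(paths["trials"], sep="\t", index=False)
    paths["spikes"] = out / "spikes.tsv"
    session.spikes_frame.to_csv(paths["spikes"], sep="\t", index=False)
    if session.trajectories:
        paths["traj"] = out / "traj.tsv"
        session.trajectories_frame.to_csv(paths["traj"], sep="\t", index=False)
    paths["ground_truth"] = out / "ground_truth.tsv"
    ground_truth_frame(session.neurons).to_csv(paths["ground_truth"], sep="\t",
                                               index=False)
    return paths


def read_trials(path: str | Path) -> list[TrialRecord]:
    return frame_to_trials(pd.read_csv(path, sep="\t"))


def read_spikes(path: str | Path) -> dict[int, dict[int, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, dict[int, np.ndarray]] = {}
    for (nid, tid), grp in df.groupby(["neuron_id", "trial_id"]):
        out.setdefault(int(nid), {})[int(tid)] = np.sort(grp["t_spike"].to_numpy())
    return out


def read_trajectories(path: str | Path) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    df = pd.read_csv(path, sep="\t")
    return {int(tid): (grp["t"].to_numpy(), grp["angle_deg"].to_numpy())
            for tid, grp in df.groupby("trial_id")}


def read_session(in_dir: str | Path) -> Session:
    """Load a previously written session directory (ground truth optional)."""
    in_dir = Path(in_dir)
    trials = read_trials(in_dir / "trials.tsv")
    spikes = read_spikes(in_dir / "spikes.tsv") if (in_dir / "spikes.tsv").exists() else {}
    trajs = (read_trajectories(in_dir / "traj.tsv")
             if (in_dir / "traj.tsv").exists() else {})
    neurons: list[NeuronGroundTruth] = []
    gt = in_dir / "ground_truth.tsv"
    if gt.exists():
        for row in pd.read_csv(gt, sep="\t").itertuples(index=False):
            neurons.append(NeuronGroundTruth(**row._asdict()))
    return Session(design=BlockDesign(), behavior=BehaviorParams(), trials=trials,
                   trajectories=trajs, neurons=neurons, spikes=spikes)
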