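"""Perievent rasters and histograms.

Spike times are re-referenced to a named trial event; histograms use uniform
bins (20 ms by default) with an edge pinned at time zero so peak latencies
read off reproducibly.  Rates are in Hz (count / bin / trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .simulate.design import TrialRecord

logger = logging.getLogger(__name__)

ALIGNMENT_EVENTS = {
    "center_release": "t_center_release",
    "light_on": "t_light_on",
    "perturbation": "t_perturbation",
    "target_hit": "t_target_hit",
}

DEFAULT_BIN = 0.020


@dataclass
class PerieventHistogram:
    event: str
    bin_edges: np.ndarray       # seconds relative to the event
    rate: np.ndarray            # Hz per bin, trial-averaged
    n_trials: int
    counts: np.ndarray          # raw per-bin spike counts summed over trials

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def peak_time(self) -> float:
        """Centre of the highest-rate bin."""
        return float(self.bin_centers[int(np.argmax(self.rate))])


def align_spikes(
    spikes_by_trial: dict[int, np.ndarray],
    trials: Iterable[TrialRecord],
    event: str,
) -> dict[int, np.ndarray]:
    """Event-relative spike times per trial; trials lacking the event are dropped."""
    if event not in ALIGNMENT_EVENTS:
        raise ValueError(f"unknown alignment event {event!r}; "
                         f"choose from {sorted(ALIGNMENT_EVENTS)}")
    attr = ALIGNMENT_EVENTS[event]
    out: dict[int, np.ndarray] = {}
    skipped = 0
    for trial in trials:
        t_event = getattr(trial, attr)
        if t_event is None:
            skipped += 1
            continue
        out[trial.trial_id] = np.asarray(
            spikes_by_trial.get(trial.trial_id, np.empty(0))) - t_event
    if skipped:
        logger.info("align_spikes(%s): %d trials lacked the event and were "
                    "excluded", event, skipped)
    return out


def build_psth(
    aligned: dict[int, np.ndarray],
    window: tuple[float, float] = (-0.500, 0.700),
    bin_width: float = DEFAULT_BIN,
    event: str = "",
) -> PerieventHistogram:
    """Trial-averaged perievent histogram over ``window``.

    Bin edges sit at integer multiples of the bin width so one edge falls at
    t = 0; the window bounds must be multiples of the bin width.
    """
    lo, hi = window
    for bound in window:
        if abs(round(bound / bin_width) * bin_width - bound) > 1e-9:
            raise ValueError("window bounds must be multiples of the bin width")
    edges = np.arange(round(lo / bin_width), round(hi / bin_width) + 1) * bin_width
    n_trials = len(aligned)
    counts = np.zeros(len(edges) - 1)
    for rel in aligned.values():
        idx = np.floor(np.asarray(rel) / bin_width).astype(int) - round(lo / bin_width)
        idx = idx[(idx >= 0) & (idx < len(counts))]
        np.add.at(counts, idx, 1)
    rate = (counts / (bin_width * n_trials)) if n_trials else np.zeros_like(counts)
    return PerieventHistogram(event=event, bin_edges=edges, rate=rate,
                              n_trials=n_trials, counts=counts)


def psth_table(
    spikes: dict[int, dict[int, np.ndarray]],
    trials: list[TrialRecord],
    event: str = "center_release",
    window: tuple[float, float] = (-0.500, 0.700),
    bin_width: float = DEFAULT_BIN,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Long PSTH table (neuron, condition, bin_center, rate) across units."""
    rows = []
    groups = ({c: [t for t in trials if t.condition == c]
               for c in sorted({t.condition for t in trials})}
              if by_condition else {"all": trials})
    for nid, per_trial in spikes.items():
        for cond, cond_trials in groups.items():
            if not cond_trials:
                continue
            aligned = align_spikes(per_trial, cond_trials, event)
            if not aligned:
                continue
            h = build_psth(aligned, window, bin_width, event)
            for c, r in zip(h.bin_centers, h.rate):
                rows.append(dict(neuron_id=nid, condition=cond,
                                 bin_center=c, rate=r))
    return pd.DataFrame(rows)
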