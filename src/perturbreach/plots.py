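"""Figure-style plots: RTp adaptation panels, perievent rasters/histograms."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .kinematics import RtpSeries
from .psth import PerieventHistogram


def plot_rtp_series(series: RtpSeries, path: str | Path) -> Path:
    """Per-condition RTp adaptation curves with the random-trial CI band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (cond, side), grp in series.repeat_series.groupby(
            ["condition", "target_side"]):
        grp = grp.sort_values("trial_index")
        ax.plot(grp["trial_index"], grp["mean_rtp"] * 1e3, marker="o",
                label=f"{cond} / {side}")
    ax.axhline(series.random_mean * 1e3, color="k", lw=1, label="random mean")
    for bound in series.random_ci:
        ax.axhline(bound * 1e3, color="k", lw=0.8, ls="--")
    ax.set_xlabel("repeat trial index")
    ax.set_ylabel("RTp (ms)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_raster_histogram(aligned: dict[int, np.ndarray],
                          histogram: PerieventHistogram,
                          path: str | Path, title: str = "") -> Path:
    """Raster (top) over the perievent histogram (bottom), aligned at 0."""
    fig, (ax_r, ax_h) = plt.subplots(
        2, 1, sharex=True, figsize=(6, 5),
        gridspec_kw={"height_ratios": [2, 1]})
    for row, (tid, rel) in enumerate(sorted(aligned.items())):
        ax_r.vlines(rel, row + 0.6, row + 1.4, lw=0.5, color="k")
    ax_r.axvline(0.0, color="r", lw=0.8)
    ax_r.set_ylabel("trial")
    if title:
        ax_r.set_title(title)
    ax_h.bar(histogram.bin_centers, histogram.rate,
             width=histogram.bin_width, align="center", color="0.3")
    ax_h.axvline(0.0, color="r", lw=0.8)
    ax_h.set_xlabel(f"time from {histogram.event or 'event'} (s)")
    ax_h.set_ylabel("rate (Hz)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
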