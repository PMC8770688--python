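"""Trajectory figures: cohort mean +/- SE and SD-over-trials panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_trajectories(summary: pd.DataFrame, out_path, value: str = "mean") -> None:
    """One row of panels per season: per-trial cohort mean with SE bars
    (``value='mean'``) or the SD trajectory (``value='sd'``)."""
    seasons = sorted(summary["season"].unique())
    conditions = sorted(summary["condition"].unique())
    fig, axes = plt.subplots(len(seasons), 1, figsize=(7, 3 * len(seasons)), sharex=True)
    if len(seasons) == 1:
        axes = [axes]
    for ax, season in zip(axes, seasons):
        for condition in conditions:
            sub = summary.query("season == @season and condition == @condition")
            if value == "mean":
                ax.errorbar(sub["trial"], sub["mean"], yerr=sub["se"], label=condition,
                            capsize=2, markersize=3, marker="o")
            else:
                ax.plot(sub["trial"], sub[value], label=condition, marker="o", markersize=3)
        ax.set_ylabel(f"Season {season}\n{'fitness' if value == 'mean' else value} (cal)")
    axes[-1].set_xlabel("trial")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
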