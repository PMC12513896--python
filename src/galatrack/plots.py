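"""Figures: decision-time bars with Morey error bars, mean time courses."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import GridSpec
from .stats import TimecourseDifference

__all__ = ["plot_decision_times", "plot_timecourse", "plot_difference"]


def plot_decision_times(summary: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Bar plot of condition cell means with within-participant error bars.

    ``summary`` is the output of :func:`galatrack.stats.condition_summary`
    (columns: condition, mean, ci_half_width, optionally group).
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    groups = summary["group"].unique() if "group" in summary else ["all"]
    width = 0.8 / len(groups)
    conditions = summary["condition"].unique()
    xs = np.arange(len(conditions))
    for gi, grp in enumerate(groups):
        sub = summary[summary["group"] == grp] if "group" in summary else summary
        sub = sub.set_index("condition").reindex(conditions)
        ax.bar(
            xs + gi * width,
            sub["mean"],
            width=width,
            yerr=sub["ci_half_width"],
            capsize=3,
            label=str(grp),
        )
    ax.set_xticks(xs + (len(groups) - 1) * width / 2)
    ax.set_xticklabels(conditions, rotation=20, ha="right")
    ax.set_ylabel("decision time (ms)")
    if title:
        ax.set_title(title)
    if len(groups) > 1:
        ax.legend(title="group")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_timecourse(
    curves_by_level: Mapping[str, Mapping[str, np.ndarray]],
    path: str | Path,
    grid: GridSpec | None = None,
    title: str = "",
) -> None:
    """Grand-mean oriented cursor position over time, one line per level."""
    grid = grid or GridSpec()
    t = grid.times() * 1000.0
    fig, ax = plt.subplots(figsize=(6, 4))
    for level, per_participant in sorted(curves_by_level.items()):
        mean = np.mean(list(per_participant.values()), axis=0)
        ax.plot(t, mean, label=str(level))
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("time from target onset (ms)")
    ax.set_ylabel("oriented cursor x (screen widths)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_difference(result: TimecourseDifference, path: str | Path, title: str = "") -> None:
    """Bootstrap difference curve with its percentile band and zero line."""
    t = result.times * 1000.0
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(t, result.lower, result.upper, alpha=0.3, label="bootstrap band")
    ax.plot(t, result.difference, label="mean difference")
    ax.axhline(0.0, color="grey", lw=0.8)
    for lo, hi in result.intervals:
        ax.axvspan(lo * 1000.0, hi * 1000.0, color="red", alpha=0.1)
    ax.set_xlabel("time from target onset (ms)")
    ax.set_ylabel("difference (screen widths)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
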