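"""Plot helpers for study results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .robustness import QTable

__all__ = ["plot_nearest_histogram", "plot_q", "write_report"]


def plot_nearest_histogram(counts: pd.Series, path: str | Path) -> None:
    """Bar chart: how often each condition is the nearest match to the reference."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    counts.plot.bar(ax=ax, color="steelblue")
    ax.set_ylabel("# features nearest to reference")
    ax.set_xlabel("condition")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_q(qtable: QTable, path: str | Path) -> None:
    """Strip plot of Q per condition, with the Q = 1 robustness line."""
    fig, ax = plt.subplots(figsize=(9, 4))
    conds = sorted(qtable.data["condition"].unique())
    for i, cond in enumerate(conds):
        q = qtable.data.loc[qtable.data["condition"] == cond, "q"]
        ax.plot([i] * len(q), q, "o", ms=3, alpha=0.5, color="steelblue")
    ax.axhline(1.0, color="firebrick", ls="--", lw=1)
    ax.set_xticks(range(len(conds)), conds, rotation=45, ha="right")
    ax.set_ylabel("Q (reproducibility / repeatability)")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(result, out_dir: str | Path) -> None:
    """Write the plot files for a study result."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plot_nearest_histogram(result.nearest_histogram, out / "nearest_condition.png")
    if result.q_table is not None:
        plot_q(result.q_table, out / "q_plot.png")
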