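"""Growth-curve figure export."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_growth_curves(summary: pd.DataFrame, path: str) -> None:
    """Plot mean +/- SEM confluence per condition over time and save to ``path``.

    Expects the summary layout produced by :func:`cellquant.stats.summarize`
    (columns condition, timepoint_days, n, mean_area_percent, sem).
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for condition, sub in summary.groupby("condition"):
        sub = sub.sort_values("timepoint_days")
        ax.errorbar(
            sub["timepoint_days"],
            sub["mean_area_percent"],
            yerr=sub["sem"],
            marker="o",
            capsize=3,
            label=str(condition),
        )
    ax.set_xlabel("time (days)")
    ax.set_ylabel("area covered by cells (%)")
    ax.set_ylim(bottom=0)
    ax.legend(title="condition", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
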