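"""Summary figures from an evaluation results table."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_auc_by_configuration(table: pd.DataFrame, out_path: str | Path) -> None:
    """Per-dish AUCs (markers) by input configuration, one column each."""
    fig, ax = plt.subplots(figsize=(1.2 * table.configuration.nunique() + 2, 4))
    configs = list(table.configuration.unique())
    markers = {1: "^", 2: "o", 3: "s"}
    for i, name in enumerate(configs):
        g = table[table.configuration == name]
        for dish, gd in g.groupby("test_dish"):
            ax.scatter([i] * len(gd), gd.auc,
                       marker=markers.get(dish, "x"), color="tab:blue",
                       label=f"validation {dish}" if i == 0 else None)
    ax.set_xticks(range(len(configs)), configs, rotation=45, ha="right")
    ax.set_ylabel("AUC")
    ax.set_ylim(0.4, 1.02)
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def plot_auc_vs_train_size(sweep: pd.DataFrame, out_path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    means = sweep.groupby("train_size").auc.mean()
    for seed, g in sweep.groupby("seed"):
        ax.plot(g.train_size, g.auc, "o-", alpha=0.3, color="tab:blue")
    ax.plot(means.index, means.values, "k-o", lw=2, label="mean over seeds")
    ax.set_xscale("log")
    ax.set_xlabel("training cells")
    ax.set_ylabel("AUC (fixed test set)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
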