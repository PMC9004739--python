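"""Optional matplotlib renderings of the plottable outputs.

These are conveniences; every figure-ready table is already written as TSV.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from seedtox.seeds import RNA_ALPHABET

_NUC_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "U": "#e31a1c"}


def seed_tox_graph(table_c: pd.DataFrame, path: str | Path) -> Path:
    """Line graph of binned counts vs. seed viability (one line per column)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for col in table_c.columns:
        if col == "bin":
            continue
        ax.plot(table_c["bin"], table_c[col], label=col, linewidth=1)
    ax.set_xlabel("% seed viability (1% bins)")
    ax.set_ylabel("read count")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)
    return Path(path)


def toxicity_boxplot(table_d: pd.DataFrame, path: str | Path) -> Path:
    """Boxplot of per-instance viability values per unit."""
    units = list(dict.fromkeys(table_d["unit"]))
    data = [table_d.loc[table_d["unit"] == u, "viability"] for u in units]
    fig, ax = plt.subplots(figsize=(1.2 * len(units) + 2, 4))
    ax.boxplot(data, tick_labels=units)
    ax.set_ylabel("% seed viability")
    fig.tight_layout()
    fig.savefig(path, dpi=200)
    plt.close(fig)
    return Path(path)


def seed_logo(pfm: pd.DataFrame, path: str | Path) -> Path:
    """Stacked-bar rendering of the 4x6 position frequency matrix."""
    fig, ax = plt.subplots(figsize=(5, 3))
    bottom = [0.0] * pfm.shape[1]
    for base in RNA_ALPHABET:
        vals = pfm.loc[base].to_numpy()
        ax.bar(pfm.columns, vals, bottom=bottom, label=base, color=_NUC_COLORS[base])
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_xlabel("seed position")
    ax.set_ylabel("frequency")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=300)
    plt.close(fig)
    return Path(path)
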