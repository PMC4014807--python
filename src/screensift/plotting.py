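"""Static figures for QC and hit inspection (matplotlib, optional extra)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data_model import SAMPLE, ScreenTable


def _mpl():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def qc_figure(table: ScreenTable, column: str, path: str | Path) -> Path:
    """Scatter of a column in well order with controls highlighted, plus a
    per-well-type box plot, the first-look view of screen quality."""
    plt = _mpl()
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4), width_ratios=[2, 1])
    rec = table.records
    y = rec[column].to_numpy(dtype=float)
    x = np.arange(len(y))
    is_sample = (rec["well_type"] == SAMPLE).to_numpy()
    ax1.scatter(x[is_sample], y[is_sample], s=4, c="0.7", label=SAMPLE)
    for ctrl in table.control_types:
        m = (rec["well_type"] == ctrl).to_numpy()
        if m.any():
            ax1.scatter(x[m], y[m], s=10, label=ctrl)
    ax1.set_xlabel("well (screen order)")
    ax1.set_ylabel(column)
    ax1.legend(fontsize=7, ncol=2)

    groups, labels = [], []
    for wt in [SAMPLE, *table.control_types]:
        v = table.values_of_type(wt, column)
        if len(v):
            groups.append(v)
            labels.append(wt)
    ax2.boxplot(groups, tick_labels=labels)
    ax2.tick_params(axis="x", rotation=45)
    ax2.set_ylabel(column)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def ranked_plot(table: ScreenTable, column: str, path: str | Path, threshold: float | None = None) -> Path:
    """Ordered plot of a score column, the view used to pick a cut-off."""
    plt = _mpl()
    v = np.sort(table.records[column].dropna().to_numpy(dtype=float))[::-1]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.arange(1, len(v) + 1), v, ".", ms=3)
    if threshold is not None:
        ax.axhline(threshold, color="r", lw=1, label=f"threshold {threshold:g}")
        ax.legend(fontsize=8)
    ax.set_xlabel("rank")
    ax.set_ylabel(column)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
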