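"""Optional figure helpers (volcano, clustered heatmap).

Figures are conveniences; the delimited tables are the contract.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .select import hierarchical_order  # noqa: E402


def volcano_plot(volcano: pd.DataFrame, path: str | Path,
                 title: str = "") -> None:
    """Scatter of log2FC vs -log10 p with the threshold guide lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    sel = volcano["selected_p02"] & volcano["selected_fc15"]
    ax.scatter(volcano.loc[~sel, "log2_fc"], volcano.loc[~sel, "neg_log10_p"],
               s=12, c="grey", alpha=0.6)
    ax.scatter(volcano.loc[sel, "log2_fc"], volcano.loc[sel, "neg_log10_p"],
               s=16, c="crimson")
    fc = volcano.attrs.get("fc_cut_log2", 0.585)
    p = volcano.attrs.get("p_cut", 0.2)
    for x in (-fc, fc):
        ax.axvline(x, ls=":", c="k", lw=0.8)
    ax.axhline(-np.log10(p), ls=":", c="k", lw=0.8)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap_plot(zmatrix: pd.DataFrame, path: str | Path,
                 linkage_method: str = "average") -> None:
    """Row/column-clustered heatmap of z-transformed fold changes."""
    order = hierarchical_order(zmatrix, method=linkage_method)
    rows = order["row_order"]
    cols = order.get("col_order", list(zmatrix.columns))
    z = zmatrix.loc[rows, cols]
    fig, ax = plt.subplots(figsize=(max(3, 0.5 * len(cols)),
                                    max(3, 0.2 * len(rows))))
    im = ax.imshow(z.to_numpy(float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(cols)), cols, rotation=90, fontsize=7)
    ax.set_yticks(range(len(rows)), rows, fontsize=6)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
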