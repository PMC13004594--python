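"""Ranking, discovery thresholds, and heatmap/volcano-ready matrices.

Discovery is deliberately liberal: assays are ranked by effect magnitude and
flagged by an unadjusted p < 0.2 screen, with a separate |log2FC| >= 0.585
(1.5-fold) effect-size flag for downstream enrichment work, and a p < 0.05
flag for the conventionally significant subset.  p thresholds are strict.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

LOG2_FC_CUTOFF = 0.585          # |ddCq| for a 1.5-fold change
P_DISCOVERY = 0.2
P_SIGNIFICANT = 0.05


def rank_and_select(effects: pd.DataFrame, p_cut: float = P_DISCOVERY,
                    fc_cut_log2: float = LOG2_FC_CUTOFF,
                    p_sig: float = P_SIGNIFICANT,
                    p_column: str = "p_skillings_mack") -> pd.DataFrame:
    """Sort by |log2FC| (descending; ties by ascending p then assay id) and
    attach selection flags.

    Assays with a missing primary p are kept in the table, flagged
    ``p_missing`` and excluded from the p-based selections.  An empty input
    yields an empty result.
    """
    cols = ["assay_id", "log2_fc", p_column]
    out = effects[[c for c in effects.columns if c in
                   set(cols) | {"sd_log2_fc", "n_pairs"}]].copy()
    if out.empty:
        for c in ("rank_by_effect", "selected_p02", "selected_fc15",
                  "significant_p05", "p_missing"):
            out[c] = pd.Series(dtype=float)
        return out
    lfc = out["log2_fc"].to_numpy(float)
    p = out[p_column].to_numpy(float)
    estimable = np.isfinite(lfc)
    out["p_missing"] = ~np.isfinite(p)
    order = out.assign(_abs=np.abs(lfc)).sort_values(
        ["_abs", p_column, "assay_id"], ascending=[False, True, True],
        na_position="last").index
    out = out.loc[order].reset_index(drop=True)
    ranks = np.full(len(out), np.nan)
    ranks[np.isfinite(out["log2_fc"].to_numpy(float))] = \
        np.arange(1, int(estimable.sum()) + 1)
    out["rank_by_effect"] = ranks
    p = out[p_column].to_numpy(float)
    lfc = out["log2_fc"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        out["selected_p02"] = np.isfinite(p) & (p < p_cut)
        out["significant_p05"] = np.isfinite(p) & (p < p_sig)
        out["selected_fc15"] = np.isfinite(lfc) & \
            (np.abs(lfc) >= fc_cut_log2 - 1e-12)
    return out


def signature_assays(selection: pd.DataFrame) -> list[str]:
    """Assays passing both the p < 0.2 screen and the 1.5-fold cutoff."""
    keep = selection["selected_p02"] & selection["selected_fc15"]
    return sorted(selection.loc[keep, "assay_id"])


def zscore_matrix(fc_matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-transform: (x - row mean) / row SD (population SD).

    Rows with zero SD map to all zeros.  Requires >= 2 columns.
    """
    if fc_matrix.shape[1] < 2:
        raise ValueError("z-transform needs at least 2 columns")
    x = fc_matrix.to_numpy(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    return pd.DataFrame(z, index=fc_matrix.index, columns=fc_matrix.columns)


def hierarchical_order(zmatrix: pd.DataFrame, method: str = "average"
                       ) -> dict:
    """Agglomerative clustering on Euclidean distances for rows and columns.

    Returns leaf orderings (deterministic; scipy breaks ties by input
    order) and the linkage matrices, whose third column holds the merge
    heights.  Raises on non-finite entries.
    """
    x = zmatrix.to_numpy(float)
    if not np.isfinite(x).all():
        bad = [(zmatrix.index[i], zmatrix.columns[j])
               for i, j in zip(*np.where(~np.isfinite(x)))]
        raise ValueError(f"non-finite entries at {bad[:10]}")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    row_link = linkage(pdist(x, metric="euclidean"), method=method)
    result = {
        "row_order": [zmatrix.index[i] for i in leaves_list(row_link)],
        "row_linkage": row_link,
    }
    if x.shape[1] >= 2:
        col_link = linkage(pdist(x.T, metric="euclidean"), method=method)
        result["col_order"] = [zmatrix.columns[i]
                               for i in leaves_list(col_link)]
        result["col_linkage"] = col_link
    return result


def volcano_table(effects: pd.DataFrame, p_cut: float = P_DISCOVERY,
                  fc_cut_log2: float = LOG2_FC_CUTOFF,
                  p_column: str = "p_skillings_mack") -> pd.DataFrame:
    """Plotting table: assay, log2FC, -log10 p and the selection flags.

    The threshold guide values are attached as DataFrame ``attrs``.
    A p of exactly 0 is clamped to the smallest positive float with a
    warning before taking the logarithm.
    """
    if effects.empty:
        out = pd.DataFrame(columns=["assay_id", "log2_fc", "neg_log10_p",
                                    "selected_p02", "selected_fc15"])
    else:
        p = effects[p_column].to_numpy(float).copy()
        if (p == 0).any():
            warnings.warn("p-value of 0 clamped before log10",
                          RuntimeWarning, stacklevel=2)
            p[p == 0] = np.finfo(float).tiny
        lfc = effects["log2_fc"].to_numpy(float)
        with np.errstate(invalid="ignore"):
            out = pd.DataFrame({
                "assay_id": effects["assay_id"],
                "log2_fc": lfc,
                "neg_log10_p": -np.log10(p),
                "selected_p02": np.isfinite(p) & (p < p_cut),
                "selected_fc15": np.isfinite(lfc)
                & (np.abs(lfc) >= fc_cut_log2 - 1e-12),
            })
    out.attrs["fc_cut_log2"] = fc_cut_log2
    out.attrs["p_cut"] = p_cut
    return out
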