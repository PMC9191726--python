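"""Single-cell expression pipeline: QC, normalization, activation
classification, differential expression, and dose fold-changes.

The container is an AnnData of raw counts (cells x genes) whose ``obs``
carries per-cell dose, total_count, n_detected_genes and mito_ratio and
whose ``var`` flags marker genes.  Normalized values are stored in
``layers['normalized']`` (per-cell depth scaling to the median depth,
then log1p); raw counts stay in ``X``.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

__all__ = ["qc_filter", "normalize", "classify_cells", "find_degs",
           "dose_fold_changes"]


class QCError(ValueError):
    pass


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def qc_filter(
    adata: ad.AnnData,
    min_total: float = 1.5e6,
    min_genes: int = 8500,
    max_mito: float = 0.04,
) -> ad.AnnData:
    """Retain cells with total_count >= min_total, n_detected_genes >=
    min_genes and mito_ratio < max_mito (boundary semantics as published).

    Idempotent; raises :class:`QCError` when no cell survives.
    """
    for col in ("total_count", "n_detected_genes", "mito_ratio"):
        if col not in adata.obs:
            raise QCError(f"obs lacks QC column {col!r}")
    keep = (
        (adata.obs["total_count"] >= min_total)
        & (adata.obs["n_detected_genes"] >= min_genes)
        & (adata.obs["mito_ratio"] < max_mito)
    ).to_numpy()
    if not keep.any():
        raise QCError("QC removed every cell; check thresholds vs data scale")
    return adata[keep].copy()


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """Depth-scale each cell to the median depth, then log1p.

    Writes two layers and returns the same object:

    * ``layers['scaled']`` — depth-scaled counts on the linear scale,
      used for Fano factors and fold-changes (the Poisson reference
      variance/mean = 1 only exists on the count scale);
    * ``layers['normalized']`` — log1p of the scaled counts, used for
      classification and rank-based differential testing.
    """
    X = _dense(adata.X).astype(float)
    depth = X.sum(axis=1)
    if np.any(depth == 0):
        raise ValueError("zero-depth cell encountered during normalization")
    target = float(np.median(depth))
    scaled = X * (target / depth)[:, None]
    adata.layers["scaled"] = scaled
    adata.layers["normalized"] = np.log1p(scaled)
    adata.uns["normalization"] = {
        "method": "median-depth scaling + log1p", "target_depth": target}
    return adata


def _normalized(adata: ad.AnnData) -> np.ndarray:
    if "normalized" not in adata.layers:
        raise ValueError("run normalize() first")
    return np.asarray(adata.layers["normalized"])


def classify_cells(adata: ad.AnnData, marker_genes=None) -> pd.Series:
    """Two-state activation call from mean marker expression.

    A two-component Gaussian mixture is fit to the per-cell mean
    normalized expression of the marker genes; the component with the
    higher mean is the activated state.  Invariant to component
    relabeling by construction.
    """
    if marker_genes is None:
        if "is_marker" not in adata.var:
            raise ValueError("no marker genes given and var lacks is_marker")
        marker_genes = list(adata.var.index[adata.var["is_marker"]])
    missing = [g for g in marker_genes if g not in adata.var.index]
    if missing or not marker_genes:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    X = _normalized(adata)
    cols = [adata.var.index.get_loc(g) for g in marker_genes]
    score = X[:, cols].mean(axis=1)
    states = pd.Series("inactivated", index=adata.obs.index, name="state")
    if adata.n_obs < 2 or np.allclose(score, score[0]):
        warnings.warn("degenerate marker expression: all cells inactivated",
                      stacklevel=2)
        return states
    gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
    labels = gm.fit_predict(score.reshape(-1, 1))
    activated_comp = int(np.argmax(gm.means_.ravel()))
    states[labels == activated_comp] = "activated"
    return states


def find_degs(adata: ad.AnnData, states: pd.Series, alpha: float = 0.05,
              pseudocount: float = 1.0) -> pd.DataFrame:
    """Wilcoxon rank-sum DEGs between activated and inactivated cells.

    Benjamini-Hochberg adjusted p < alpha (a deliberately lenient rule so
    heterogeneous genes are retained); log2 fold-change of state means
    with a pseudocount.
    """
    states = states.reindex(adata.obs.index)
    act = (states == "activated").to_numpy()
    ina = (states == "inactivated").to_numpy()
    if act.sum() < 3 or ina.sum() < 3:
        raise ValueError("each state needs at least 3 cells for DEG testing")
    X = _normalized(adata)
    a, b = X[act], X[ina]
    pvals = np.ones(adata.n_vars)
    for j in range(adata.n_vars):
        if np.all(a[:, j] == a[0, j]) and np.all(b[:, j] == a[0, j]):
            continue  # identical constant in both states: not a DEG
        pvals[j] = mannwhitneyu(a[:, j], b[:, j],
                                alternative="two-sided").pvalue
    padj = multipletests(pvals, method="fdr_bh")[1]
    lfc = np.log2((a.mean(axis=0) + pseudocount)
                  / (b.mean(axis=0) + pseudocount))
    table = pd.DataFrame({
        "gene": adata.var.index,
        "log2_fc": lfc,
        "pval": pvals,
        "padj": padj,
        "direction": np.where(lfc >= 0, "up", "down"),
    }).set_index("gene")
    return table[table["padj"] < alpha].copy()


def dose_fold_changes(adata: ad.AnnData, pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene mean-expression fold-change of each dose vs dose 0.

    Mean normalized (depth-scaled, linear) expression per dose group
    divided by the mean at dose 0, with a pseudocount on both means.
    """
    if "dose" not in adata.obs:
        raise ValueError("obs lacks dose labels")
    doses = sorted(adata.obs["dose"].unique())
    if 0.0 not in [float(d) for d in doses]:
        raise ValueError("dose 0 group is required as the reference")
    if "scaled" not in adata.layers:
        raise ValueError("run normalize() first")
    X = np.asarray(adata.layers["scaled"])
    means = {}
    for d in doses:
        mask = (adata.obs["dose"] == d).to_numpy()
        if not mask.any():
            raise ValueError(f"missing dose group {d}")
        means[float(d)] = X[mask].mean(axis=0)
    ref = means[0.0] + pseudocount
    fc = pd.DataFrame(
        {d: (m + pseudocount) / ref for d, m in means.items()},
        index=adata.var.index,
    )
    fc.columns.name = "dose"
    return fc
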