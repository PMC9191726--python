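"""Transcriptional heterogeneity: Fano factors, dynamics clustering, and
undersampled group comparisons.

The Fano factor (variance/mean) measures deviation from Poisson noise
(where it equals 1) and serves as the per-gene, per-dose heterogeneity
index.  Gene-wise Fano trajectories across doses are z-scaled and
clustered with Ward linkage (the squared-distance 'ward.D2' variant) to
find heterogeneity-dynamics archetypes.  Group comparisons subsample all
groups to the smallest group size before testing, so unequal group sizes
do not drive significance.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = ["fano_factor", "fano", "fano_ratio", "cluster_fano_dynamics",
           "compare_groups_undersampled"]


def fano_factor(values: np.ndarray) -> float:
    """Variance/mean of a sample (ddof=1); NaN when the mean is 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("Fano factor needs at least 2 observations")
    mu = x.mean()
    if mu == 0:
        return np.nan
    return float(x.var(ddof=1) / mu)


def fano(adata: ad.AnnData, genes=None, per_dose: bool = True,
         layer: str = "scaled") -> pd.DataFrame:
    """Per-gene (per-dose) Fano factor and CV of normalized expression
    (the depth-scaled linear layer by default — the Poisson reference
    variance/mean = 1 is only meaningful on the count scale).

    Returns a tidy frame with columns gene, dose, fano, cv; zero-mean
    groups yield NaN (flagged as undefined, never coerced to 0).  With
    ``per_dose=False`` a single pooled row per gene (dose = NaN).
    """
    X = np.asarray(adata.layers[layer]) if layer else np.asarray(adata.X)
    if genes is None:
        genes = list(adata.var.index)
    cols = [adata.var.index.get_loc(g) for g in genes]
    groups = (
        [(d, (adata.obs["dose"] == d).to_numpy())
         for d in sorted(adata.obs["dose"].unique())]
        if per_dose else [(np.nan, np.ones(adata.n_obs, dtype=bool))]
    )
    rows = []
    for d, mask in groups:
        if mask.sum() < 2:
            raise ValueError(f"dose group {d} has fewer than 2 cells")
        sub = X[mask][:, cols]
        mu = sub.mean(axis=0)
        var = sub.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(mu > 0, var / mu, np.nan)
            cv = np.where(mu > 0, np.sqrt(var) / mu, np.nan)
        for g, fi, ci in zip(genes, f, cv):
            rows.append({"gene": g, "dose": d, "fano": fi, "cv": ci})
    return pd.DataFrame(rows)


def fano_ratio(profiles: pd.DataFrame, top_dose: float, ref_dose: float = 0.0,
               column: str = "fano") -> pd.Series:
    """Per-gene ratio of the statistic at top_dose vs ref_dose.

    Undefined (NaN) entries propagate rather than being imputed.
    """
    wide = profiles.pivot(index="gene", columns="dose", values=column)
    for d in (top_dose, ref_dose):
        if d not in wide.columns:
            raise ValueError(f"dose {d} absent from profiles")
    return (wide[top_dose] / wide[ref_dose]).rename(f"{column}_ratio")


def cluster_fano_dynamics(profiles: pd.DataFrame, k: int = 4) -> pd.Series:
    """Ward-cluster z-scaled per-gene Fano trajectories across doses.

    Each gene's Fano vector is centered and scaled by its sd across dose
    points — floored at the panel-median sd, so near-flat profiles are
    not amplified into pure noise — then agglomerated with Ward linkage
    on Euclidean distances (hclust ward.D2 equivalent) and the tree cut
    at k clusters.  Genes with undefined (NaN) entries are excluded with
    a warning.  The partition is invariant to gene order; the numeric
    ids 1..k are not meaningful beyond identity.
    """
    wide = profiles.pivot(index="gene", columns="dose", values="fano")
    defined = wide.dropna()
    if len(defined) < len(wide):
        warnings.warn(
            f"excluded {len(wide) - len(defined)} gene(s) with undefined "
            "Fano entries from clustering", stacklevel=2)
    if len(defined) < k:
        raise ValueError(f"need at least k={k} fully defined profiles")
    X = defined.to_numpy()
    sd = X.std(axis=1, ddof=0)
    floor = float(np.median(sd))
    if floor == 0:
        floor = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / np.maximum(sd, floor)[:, None]
    if k == 1:
        labels = np.ones(len(defined), dtype=int)
    else:
        Zl = linkage(Z, method="ward")
        labels = fcluster(Zl, t=k, criterion="maxclust")
    return pd.Series(labels, index=defined.index, name="cluster_id")


def compare_groups_undersampled(
    groups, test: str = "anova", seed: int = 0,
) -> tuple[float, int]:
    """Test for a group effect after undersampling to the smallest group.

    Every group is subsampled without replacement to the smallest group
    size (a no-op for equal sizes), then a one-way ANOVA or Welch t-test
    (two groups) is run.  Returns (p-value, undersample size).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    n = min(a.size for a in arrays)
    if n < 2:
        raise ValueError("smallest group has fewer than 2 values")
    rng = np.random.default_rng(seed)
    sub = [
        a if a.size == n else rng.choice(a, size=n, replace=False)
        for a in arrays
    ]
    if test == "anova":
        p = stats.f_oneway(*sub).pvalue
    elif test == "welch":
        if len(sub) != 2:
            raise ValueError("welch test requires exactly 2 groups")
        p = stats.ttest_ind(sub[0], sub[1], equal_var=False).pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(p), int(n)
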