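"""Single-cell ATAC co-accessibility via a distance-penalized graphical
lasso over sliding genomic windows.

Sparse per-cell fragment counts are first densified into meta-cells
(TF-IDF embedding, truncated SVD, k-nearest-neighbour grouping with
Jaccard deduplication).  Within each overlapping genomic window the
standardized meta-cell x peak matrix yields a correlation matrix that is
inverted under an L1 penalty growing with inter-peak distance
(penalty = alpha * (d/s)^0.75); the negated, rescaled off-diagonal
entries of the precision matrix are partial correlations in [-1, 1],
and pairs scored in several windows take the mean.  Stimulated-vs-
unstimulated score pairs are filtered with the published rule
(stimulated score >= 0.1 and difference >= 0.05) to call gained pairs,
which are then counted per gene around annotated TSSs and correlated
with expression statistics (Spearman).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import spearmanr
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

__all__ = ["aggregate_cells", "coaccess_scores", "differential_pairs",
           "gene_pair_counts", "correlate", "penalized_glasso"]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)


def aggregate_cells(adata: ad.AnnData, k: int = 30,
                    n_components: int = 15,
                    jaccard_cap: float = 0.9,
                    random_state: int = 0) -> ad.AnnData:
    """Sum k-nearest-neighbour cell groups into meta-cells.

    Cells are embedded by TF-IDF + truncated SVD; each cell seeds a
    candidate meta-cell from its k nearest neighbours (itself included),
    and candidates overlapping an accepted group by more than
    ``jaccard_cap`` (Jaccard index) are dropped.  With k=1 the result is
    the identity.
    """
    n_cells = adata.n_obs
    if k < 1 or k > n_cells:
        raise ValueError(f"k must be in [1, {n_cells}]")
    X = _dense(adata.X).astype(float)
    if k == 1:
        groups = [[i] for i in range(n_cells)]
    else:
        tf = X / np.maximum(X.sum(axis=1, keepdims=True), 1)
        idf = n_cells / np.maximum((X > 0).sum(axis=0), 1)
        emb = tf * idf[None, :]
        n_comp = min(n_components, min(emb.shape) - 1)
        svd = TruncatedSVD(n_components=n_comp, random_state=random_state)
        Z = svd.fit_transform(emb)
        norms = np.linalg.norm(Z, axis=1, keepdims=True)
        Z = Z / np.maximum(norms, 1e-12)
        nn = NearestNeighbors(n_neighbors=k).fit(Z)
        _, idx = nn.kneighbors(Z)
        accepted: list[set] = []
        groups = []
        for i in range(n_cells):
            cand = set(idx[i])
            if any(len(cand & g) / len(cand | g) > jaccard_cap
                   for g in accepted):
                continue
            accepted.append(cand)
            groups.append(sorted(cand))
    M = np.vstack([X[g].sum(axis=0) for g in groups])
    obs = pd.DataFrame(index=pd.Index(
        [f"meta{j:04d}" for j in range(len(groups))], name="meta_cell"))
    obs["n_members"] = [len(g) for g in groups]
    out = ad.AnnData(X=M, obs=obs, var=adata.var.copy())
    out.uns["member_lists"] = [list(map(int, g)) for g in groups]
    return out


def penalized_glasso(S: np.ndarray, rho: np.ndarray,
                     tol: float = 1e-4, max_sweeps: int = 200) -> np.ndarray:
    """Graphical lasso with an element-wise penalty matrix.

    Maximizes log det(Theta) - tr(S Theta) - sum rho_ij |Theta_ij| by
    block coordinate descent on the covariance estimate W (Friedman's
    algorithm); each column subproblem is an L1-penalized regression
    solved by cyclic coordinate descent.  With rho identically zero the
    result is the plain inverse of S (computed directly).

    Returns the precision matrix estimate Theta.
    """
    p = S.shape[0]
    if np.all(rho == 0):
        return np.linalg.inv(S)
    W = S + np.diag(np.diag(rho))
    B = np.zeros((p, p))  # regression coefficients per column
    off = ~np.eye(p, dtype=bool)
    for _ in range(max_sweeps):
        W_old = W.copy()
        for j in range(p):
            idx = np.arange(p) != j
            W11 = W[np.ix_(idx, idx)]
            s12 = S[idx, j]
            r12 = rho[idx, j]
            beta = B[idx, j].copy()
            # lasso: min 1/2 b' W11 b - s12' b + r12'|b|
            for _ in range(100):
                delta = 0.0
                for m in range(p - 1):
                    grad = W11[m] @ beta - W11[m, m] * beta[m] - s12[m]
                    new = -np.sign(grad) * max(abs(grad) - r12[m], 0.0) / W11[m, m]
                    delta = max(delta, abs(new - beta[m]))
                    beta[m] = new
                if delta < tol * max(np.abs(s12).max(), 1e-12):
                    break
            B[idx, j] = beta
            W[idx, j] = W11 @ beta
            W[j, idx] = W[idx, j]
        if np.mean(np.abs(W - W_old)[off]) < tol * np.mean(np.abs(S)[off] + 1e-12):
            break
    # recover Theta from W and the regression coefficients
    Theta = np.zeros_like(W)
    for j in range(p):
        idx = np.arange(p) != j
        theta_jj = 1.0 / (W[j, j] - W[idx, j] @ B[idx, j])
        Theta[j, j] = theta_jj
        Theta[idx, j] = -B[idx, j] * theta_jj
    return (Theta + Theta.T) / 2.0


def _partial_corr(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.abs(np.diag(Theta)))
    P = -Theta / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return np.clip(P, -1.0, 1.0)


def coaccess_scores(adata: ad.AnnData, window: int = 500_000,
                    stride: int = 250_000,
                    base_penalty: float = 0.5,
                    penalty_exponent: float = 0.75,
                    distance_scale: float | None = None,
                    min_cells: int = 3) -> pd.DataFrame:
    """Co-accessibility scores for same-window peak pairs.

    Per window, the meta-cell x peak submatrix is standardized, its
    correlation matrix penalized-inverted with
    rho_ij = base_penalty * (d_ij / s)^penalty_exponent (s defaults to
    half the window), and the resulting partial correlations reported.
    Pairs appearing in several windows are averaged.  Windows with fewer
    than ``min_cells`` meta-cells are skipped with a warning.
    """
    var = adata.var
    X = _dense(adata.X).astype(float)
    if X.shape[0] < min_cells:
        warnings.warn("too few meta-cells for any window; empty result",
                      stacklevel=2)
        return pd.DataFrame(columns=["peak_i", "peak_j", "distance", "score"])
    s = distance_scale if distance_scale else window / 2.0
    acc: dict[tuple, list] = {}
    for chrom in sorted(var["chrom"].unique()):
        mask = (var["chrom"] == chrom).to_numpy()
        pos = ((var.loc[mask, "start"] + var.loc[mask, "end"]) // 2).to_numpy()
        names = var.index[mask].to_numpy()
        order = np.argsort(pos)
        pos, names = pos[order], names[order]
        cols = np.nonzero(mask)[0][order]
        start = (int(pos.min()) // stride) * stride
        stop = int(pos.max())
        for w0 in range(start, stop + 1, stride):
            sel = (pos >= w0) & (pos < w0 + window)
            if sel.sum() < 2:
                continue
            sub = X[:, cols[sel]]
            sd = sub.std(axis=0, ddof=1)
            keep = sd > 0
            if keep.sum() < 2:
                continue
            sub = sub[:, keep]
            psel = pos[sel][keep]
            nsel = names[sel][keep]
            Z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
            C = (Z.T @ Z) / (Z.shape[0] - 1)
            C += np.eye(C.shape[0]) * 1e-6
            dist = np.abs(psel[:, None] - psel[None, :]).astype(float)
            rho = base_penalty * (dist / s) ** penalty_exponent
            np.fill_diagonal(rho, 0.0)
            P = _partial_corr(penalized_glasso(C, rho))
            for a in range(len(nsel)):
                for b in range(a + 1, len(nsel)):
                    key = (nsel[a], nsel[b]) if nsel[a] < nsel[b] else (nsel[b], nsel[a])
                    acc.setdefault((chrom, *key), []).append(
                        (P[a, b], dist[a, b]))
    rows = [
        {"chrom": chrom, "peak_i": i, "peak_j": j,
         "distance": vals[0][1],
         "score": float(np.mean([v[0] for v in vals]))}
        for (chrom, i, j), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def differential_pairs(scores_stim: pd.DataFrame,
                       scores_unstim: pd.DataFrame,
                       score_min: float = 0.1,
                       delta_min: float = 0.05) -> pd.DataFrame:
    """Gained-pair calls: stim score >= score_min and delta >= delta_min.

    Pairs absent from one condition score 0 there.  Thresholds are
    boundary-inclusive, matching the published rule.
    """
    key = ["chrom", "peak_i", "peak_j"]
    a = scores_stim.set_index(key)["score"]
    b = scores_unstim.set_index(key)["score"]
    dist_parts = [df.set_index(key)["distance"]
                  for df in (scores_stim, scores_unstim) if len(df)]
    dist = (pd.concat(dist_parts).groupby(level=key).first()
            if dist_parts else pd.Series(dtype=float))
    idx = a.index.union(b.index)
    stim = a.reindex(idx, fill_value=0.0)
    unstim = b.reindex(idx, fill_value=0.0)
    out = pd.DataFrame({
        "score_stim": stim, "score_unstim": unstim,
        "delta": stim - unstim,
        "distance": dist.reindex(idx),
    }).reset_index()
    out["gained"] = (out["score_stim"] >= score_min) & (out["delta"] >= delta_min)
    return out


def gene_pair_counts(pairs: pd.DataFrame, tss_table: pd.DataFrame,
                     peaks: pd.DataFrame, flank: int = 1000,
                     gained_only: bool = True) -> pd.Series:
    """Per-gene count of distinct partner regions of gained pairs whose
    other end overlaps [TSS - flank, TSS + flank].
    """
    coords = peaks.set_index("name")[["chrom", "start", "end"]]
    sub = pairs[pairs["gained"]] if gained_only else pairs
    counts = {}
    for row in tss_table.itertuples():
        lo, hi = row.position - flank, row.position + flank
        partners = set()
        for pr in sub.itertuples():
            if pr.chrom != row.chrom:
                continue
            for end_a, end_b in ((pr.peak_i, pr.peak_j),
                                 (pr.peak_j, pr.peak_i)):
                ca = coords.loc[end_a]
                if ca["start"] <= hi and ca["end"] > lo:  # overlaps TSS window
                    partners.add(end_b)
        counts[row.gene] = len(partners)
    return pd.Series(counts, name="gained_pair_count")


def correlate(counts: pd.Series, statistic: pd.Series) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) of per-gene
    gained-pair counts against an expression statistic.

    Returns (rho, p-value) over the genes present in both series.
    """
    joined = pd.concat([counts, statistic], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    rho, p = spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)
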