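"""Ground-truth-planted synthetic data for the whole pipeline.

Three generators emulate the study's three data modalities:

* :func:`simulate_expression` — dose-resolved single-cell RNA counts.
  Each cell flips into the activated state with Hill probability
  p(d) = d^N/(Km^N + d^N); counts are negative-binomial with gene-class-
  and state-dependent mean and dispersion, so SE-like genes carry a
  larger planted Fano-factor increase (top dose vs 0) than TE-like ones.
* :func:`simulate_atac` — per-condition cell x peak fragment counts
  driven by latent accessibility factors.  Planted co-accessible peak
  pairs share a private factor whose loading is amplified by
  ``stim_gain`` in the stimulated condition only, so differential
  co-accessibility has a known answer key.  Peaks are laid out on
  synthetic chromosomes in clusters whose internal gaps are below and
  whose inter-cluster gaps are above the 5-kb stitching distance, so
  enhancer stitching reconstructs the planted architectures.
* :func:`simulate_foci` — per-cell nuclear foci counts drawn Poisson
  around the Hill dose-response a + k*d^N/(Km^N + d^N), optionally
  zero-inflated as in the imaging data.

A single run seed expands into independent child streams (see
:mod:`sehet.config`), so outputs are bit-identical under a fixed seed
and adding one generator never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .config import BurstParams, ConfigError, SimConfig

__all__ = ["SimTruth", "simulate_expression", "simulate_atac", "simulate_foci"]


@dataclass
class SimTruth:
    """Planted ground truth for one simulation run."""

    activation: pd.DataFrame | None = None      # cell_id, dose, activated
    gene_class: pd.Series | None = None         # gene -> SE/TE/background
    hill_params: dict = field(default_factory=dict)
    fano_by_dose: pd.DataFrame | None = None    # expected count Fano per class
    planted_pairs: pd.DataFrame | None = None   # peak_i, peak_j, chrom
    enhancer_membership: pd.DataFrame | None = None  # peak -> enhancer id
    tss: pd.DataFrame | None = None             # gene, chrom, position, strand
    activation_prob: dict = field(default_factory=dict)  # dose -> p

    def to_json(self, path) -> None:
        payload = {
            "hill_params": self.hill_params,
            "activation_prob": {str(k): v for k, v in self.activation_prob.items()},
        }
        for name in ("activation", "fano_by_dose", "planted_pairs",
                     "enhancer_membership", "tss"):
            df = getattr(self, name)
            if df is not None:
                payload[name] = df.to_dict(orient="list")
        if self.gene_class is not None:
            payload["gene_class"] = self.gene_class.to_dict()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _activation_prob(dose: float, N: float, Km: float) -> float:
    if dose <= 0:
        return 0.0
    r = (dose / Km) ** N
    return r / (1.0 + r)


def _nb_draw(rng, mean, theta, size):
    """Negative binomial with mean/dispersion parameterization.

    var = mean + mean^2/theta; theta -> inf recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if np.all(mean == 0):
        return np.zeros(size, dtype=np.int64)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=size)


def _gene_classes(cfg: SimConfig) -> pd.Series:
    n_se = int(round(cfg.frac_se_genes * cfg.n_genes))
    n_null = int(round(cfg.frac_null_genes * cfg.n_genes))
    n_te = cfg.n_genes - n_se - n_null
    classes = ["SE"] * n_se + ["TE"] * n_te + ["background"] * n_null
    genes = [f"gene{i:04d}" for i in range(cfg.n_genes)]
    return pd.Series(classes, index=genes, name="gene_class")


def _planted_fano(bp: BurstParams, p: float) -> float:
    """Count-scale Fano factor of the two-state NB mixture at activation p."""
    m_off, m_on, th = bp.mean_off, bp.mean_on, bp.dispersion
    mean = (1 - p) * m_off + p * m_on
    var = ((1 - p) * (m_off + m_off**2 / th)
           + p * (m_on + m_on**2 / th)
           + p * (1 - p) * (m_on - m_off) ** 2)
    return var / mean if mean > 0 else np.nan


def simulate_expression(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Dose-resolved cell x gene count matrix with planted activation truth.

    Returns an AnnData whose ``obs`` carries dose, total_count,
    n_detected_genes and mito_ratio (all derived from the emitted counts),
    and the :class:`SimTruth` answer key.
    """
    config.validate()
    rng = config.rng("expression")
    hill = config.activation_hill
    doses = list(config.doses)
    gene_class = _gene_classes(config)
    genes = list(gene_class.index) + [f"mito{i}" for i in range(config.n_mito_genes)]

    n_cells = config.n_cells_per_dose * len(doses)
    p_by_dose = {d: _activation_prob(d, hill["N"], hill["Km"]) for d in doses}

    depth = rng.lognormal(mean=0.0, sigma=config.depth_sigma, size=n_cells)
    low_q = rng.random(n_cells) < config.frac_low_quality
    mito_scale = np.where(low_q, 6.0, 1.0)
    depth = np.where(low_q, depth * 0.15, depth)

    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    cell_dose = np.repeat(doses, config.n_cells_per_dose).tolist()
    state = np.concatenate([
        rng.random(config.n_cells_per_dose) < p_by_dose[d] for d in doses
    ])
    activated = state.tolist()

    # per-gene burst parameters: class means with lognormal gene-to-gene
    # variability (real genes differ in burst size and noise within a class)
    m_off = np.empty(config.n_genes)
    m_on = np.empty(config.n_genes)
    theta_off = np.empty(config.n_genes)
    theta_on = np.empty(config.n_genes)
    for gi, g in enumerate(gene_class.index):
        bp = config.burst_params[gene_class[g]]
        jitter_m = rng.lognormal(0.0, 0.4)
        m_off[gi] = bp.mean_off * jitter_m
        m_on[gi] = (bp.mean_on * jitter_m
                    if gene_class[g] == "background" else
                    bp.mean_on * rng.lognormal(0.0, 0.4))
        # noise change upon activation varies per gene, independently of
        # the mean change
        theta_off[gi] = bp.dispersion * rng.lognormal(0.0, 0.3)
        theta_on[gi] = bp.dispersion * rng.lognormal(0.0, 0.8)

    mean_matrix = np.where(state[:, None], m_on[None, :], m_off[None, :])
    mean_matrix = mean_matrix * depth[:, None]
    mean_matrix = np.maximum(mean_matrix, 1e-9)
    theta = np.where(state[:, None], theta_on[None, :], theta_off[None, :])
    p_nb = theta / (theta + mean_matrix)
    X_genes = rng.negative_binomial(theta, p_nb)
    # mitochondrial panel: ~3% of a typical library, inflated in low-
    # quality cells
    mito_mean = 50.0 * depth[:, None] * mito_scale[:, None]
    X_mito = rng.poisson(mito_mean * np.ones((1, config.n_mito_genes)))
    X = np.hstack([X_genes, X_mito]).astype(np.int64)
    obs = pd.DataFrame(index=pd.Index(cell_ids, name="cell_id"))
    obs["dose"] = cell_dose
    obs["total_count"] = X.sum(axis=1)
    obs["n_detected_genes"] = (X > 0).sum(axis=1)
    is_mito = np.array([g.startswith("mito") for g in genes])
    obs["mito_ratio"] = X[:, is_mito].sum(axis=1) / np.maximum(
        obs["total_count"].to_numpy(), 1)
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_mito"] = is_mito
    var["gene_class"] = [gene_class.get(g, "mito") for g in genes]
    # SE-like high-induction genes double as activation markers
    var["is_marker"] = [
        gene_class.get(g, "") == "SE" and i < 3 for i, g in enumerate(genes)
    ]
    adata = ad.AnnData(X=X, obs=obs, var=var)

    fano_rows = []
    for cls in ("SE", "TE", "background"):
        bp = config.burst_params[cls]
        for d in doses:
            fano_rows.append({
                "gene_class": cls, "dose": d,
                "fano": _planted_fano(bp, p_by_dose[d]),
            })
    truth = SimTruth(
        activation=pd.DataFrame({
            "cell_id": cell_ids, "dose": cell_dose, "activated": activated}),
        gene_class=gene_class,
        hill_params=dict(hill),
        fano_by_dose=pd.DataFrame(fano_rows),
        activation_prob=p_by_dose,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# scATAC


def _peak_layout(cfg: SimConfig, rng) -> pd.DataFrame:
    """Place peaks in clusters so 5-kb stitching recovers the clusters.

    Intra-cluster gaps are drawn in [200, 3000] bp (< 5 kb), inter-cluster
    gaps in [8, 40] kb (> 5 kb).
    """
    peaks = []
    per_chrom = np.array_split(np.arange(cfg.n_peaks), cfg.n_chromosomes)
    enh_id = 0
    for k, idx in enumerate(per_chrom):
        pos = 10_000
        i = 0
        while i < len(idx):
            size = int(rng.integers(2, 6))
            size = min(size, len(idx) - i)
            for j in range(size):
                width = int(rng.integers(300, 900))
                peaks.append({
                    "chrom": f"chr{k + 1}", "start": pos, "end": pos + width,
                    "name": f"peak{idx[i + j]:04d}", "enhancer_id": f"enh{enh_id:03d}",
                })
                pos += width + int(rng.integers(200, 3000))
            pos += int(rng.integers(8_000, 40_000))
            enh_id += 1
            i += size
    return pd.DataFrame(peaks)


def simulate_atac(config: SimConfig):
    """Per-condition cell x peak fragment counts with planted gained pairs.

    Returns ``(matrices, peaks, truth)`` where ``matrices`` maps condition
    ('unstim', 'stim') to an AnnData of fragment counts, ``peaks`` is a
    BED-like DataFrame, and ``truth`` lists the planted co-accessible
    pairs and the enhancer membership of each peak.
    """
    config.validate()
    rng = config.rng("atac")
    cf = config.coaccess_factors
    n_factors = cf["n_factors"]
    if n_factors >= config.n_peaks:
        raise ConfigError("n_factors must be smaller than n_peaks")

    peaks = _peak_layout(config, rng)
    n_peaks = len(peaks)
    n_cells = config.n_cells_atac

    # gene anchoring: enhancer clusters ranked by total peak length;
    # SE-like genes take the longest clusters, TE-like the rest, so the
    # planted SE architectures are the long ones.  Each gene's TSS sits
    # inside the first peak of its cluster.
    gene_class = _gene_classes(config)
    lengths = (peaks["end"] - peaks["start"]).groupby(peaks["enhancer_id"]).sum()
    ranked_clusters = lengths.sort_values(ascending=False).index.to_list()
    se_genes = [g for g, c in gene_class.items() if c == "SE"]
    te_genes = [g for g, c in gene_class.items() if c == "TE"]
    # anchor a cluster-proportional subset of genes: ~20% of enhancer
    # architectures are SE-like (long + dense), the rest TE-like; genes
    # beyond the cluster budget carry no ATAC annotation
    n_se_anchored = max(1, round(0.2 * len(ranked_clusters)))
    anchored = (se_genes[:n_se_anchored]
                + te_genes[:max(0, len(ranked_clusters) - n_se_anchored)])
    tss_rows = []
    cluster_gene = {}
    for cluster, gene in zip(ranked_clusters, anchored):
        first = peaks[peaks["enhancer_id"] == cluster].iloc[0]
        tss_rows.append({"gene": gene, "chrom": first["chrom"],
                         "position": int(first["start"]) + 100,
                         "strand": "+"})
        cluster_gene[cluster] = gene
    tss_table = pd.DataFrame(tss_rows)

    # background factors: each loads a random subset of peaks, equally in
    # both conditions (shared biological covariance, not condition-specific)
    bg_loadings = np.zeros((n_peaks, n_factors))
    for f in range(n_factors):
        members = rng.choice(n_peaks, size=max(4, n_peaks // n_factors), replace=False)
        bg_loadings[members, f] = cf["loading_scale"] * 0.5

    # planted pairs: one end is the TSS peak of a gene-anchored cluster
    # (SE clusters preferred), the other a nearby same-chromosome peak;
    # each pair shares a private factor.
    n_pairs = cf["n_planted_pairs"]
    by_pos = peaks.sort_values(["chrom", "start"])
    pair_rows = []
    used = set()
    anchors = []
    for cluster in ranked_clusters:
        if cluster in cluster_gene:
            anchors.append(peaks.index[peaks["enhancer_id"] == cluster][0])
    pair_loading_cols = []
    for anchor in anchors:
        if len(pair_rows) >= n_pairs:
            break
        chrom = peaks.loc[anchor, "chrom"]
        pos = peaks.loc[anchor, "start"]
        nearby = by_pos[
            (by_pos["chrom"] == chrom)
            & (by_pos.index != anchor)
            & ((by_pos["start"] - pos).abs() < 200_000)
        ].index.to_numpy()
        nearby = [j for j in nearby if (anchor, j) not in used]
        if not nearby:
            continue
        j = int(nearby[int(rng.integers(len(nearby)))])
        used.add((anchor, j))
        used.add((j, anchor))
        col = np.zeros(n_peaks)
        col[anchor] = cf["loading_scale"]
        col[j] = cf["loading_scale"]
        pair_loading_cols.append(col)
        a, b = sorted([anchor, j])
        pair_rows.append({
            "peak_i": peaks.loc[a, "name"],
            "peak_j": peaks.loc[b, "name"],
            "chrom": chrom,
            "anchor_gene": cluster_gene[peaks.loc[anchor, "enhancer_id"]],
        })
    pair_loadings = (np.column_stack(pair_loading_cols)
                     if pair_loading_cols else np.zeros((n_peaks, 0)))

    # SE-like architectures carry disproportionately dense accessibility,
    # so the rank-ordered signal curve has the ROSE hockey-stick shape
    se_clusters = {c for c, g in cluster_gene.items()
                   if gene_class.get(g) == "SE"}
    rate_mult = np.where(
        peaks["enhancer_id"].isin(se_clusters).to_numpy(),
        rng.lognormal(np.log(3.0), 0.3, n_peaks), 1.0)
    # lognormal per-peak strength: rank-ordered region totals then form
    # the convex hockey-stick curve the slope-1 rule expects
    rate_mult = rate_mult * rng.lognormal(0.0, 0.4, n_peaks)

    matrices = {}
    base = np.log(config.atac_base_rate)
    for cond in ("unstim", "stim"):
        gain = cf["stim_gain"] if cond == "stim" else 1.0
        L = np.hstack([bg_loadings, pair_loadings * gain])
        z = rng.standard_normal((n_cells, L.shape[1]))
        log_rate = (base + np.log(rate_mult)
                    + z @ L.T - 0.5 * (L**2).sum(axis=1))
        counts = rng.poisson(np.exp(log_rate))
        obs = pd.DataFrame(index=pd.Index(
            [f"{cond}_cell{i:04d}" for i in range(n_cells)], name="cell_id"))
        obs["condition"] = cond
        var = peaks.set_index("name")[["chrom", "start", "end"]].copy()
        adata = ad.AnnData(X=sparse.csr_matrix(counts), obs=obs, var=var)
        matrices[cond] = adata

    truth = SimTruth(
        planted_pairs=pd.DataFrame(pair_rows),
        enhancer_membership=peaks[["name", "enhancer_id"]].rename(
            columns={"name": "peak"}),
        tss=tss_table,
        gene_class=gene_class,
    )
    return matrices, peaks, truth


# ---------------------------------------------------------------------------
# foci imaging


def simulate_foci(config: SimConfig) -> pd.DataFrame:
    """Per-cell foci counts across the imaging dose ladder at t = 20 min.

    Counts are Poisson with mean a + k * d^N/(Km^N + d^N), i.e. the
    generator inverts the Hill model that the analysis fits to per-dose
    medians.  An optional zero-inflation fraction silences cells
    entirely, mimicking the bimodal per-dose distributions seen in
    imaging data.
    """
    config.validate()
    rng = config.rng("foci")
    fh = config.foci_hill
    if fh["a"] < 0 or fh["k"] < 0:
        raise ConfigError("foci_hill a and k must be non-negative")
    rows = []
    n = config.n_cells_per_dose_foci
    ci = 0
    for d in config.foci_doses:
        p = _activation_prob(d, fh["N"], fh["Km"])
        mean = fh["a"] + fh["k"] * p
        counts = rng.poisson(mean, size=n)
        if config.foci_zero_inflation > 0:
            counts[rng.random(n) < config.foci_zero_inflation] = 0
        for c in counts:
            rows.append({"cell_id": f"foci{ci:05d}", "dose": d,
                         "time_min": 20, "foci": int(c)})
            ci += 1
    return pd.DataFrame(rows)
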