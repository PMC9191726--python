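"""End-to-end orchestration of the synthetic-data analysis.

`run_pipeline` simulates all modalities under one seed, runs every
analysis stage, and writes the report tables as CSV into an output
directory.  Outputs are byte-identical across runs with the same config
and seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import coaccess, enhancers, expression, foci, gene_hill, heterogeneity
from .config import RunConfig, SimConfig
from .io import write_bed, write_foci_csv, write_provenance
from .synthetic import simulate_atac, simulate_expression, simulate_foci


def peak_bed(peaks: pd.DataFrame, adata) -> pd.DataFrame:
    """BED6 view of the peak table.

    Score carries the depth-normalized signal (fragments per 10k
    library, i.e. library fraction x 10^3 x 10) clamped to the BED
    maximum of 1000.
    """
    sig = _peak_signal(adata).set_index("name")["signal"]
    out = peaks.copy()
    out["score"] = np.clip(
        np.round(sig.reindex(out["name"]).to_numpy()), 0, 1000
    ).astype(int)
    out["strand"] = "."
    return out[["chrom", "start", "end", "name", "score", "strand"]]


def _peak_signal(adata) -> pd.DataFrame:
    """Depth-normalized per-peak signal (mean fragments per 10k total)."""
    X = np.asarray(adata.X.todense()) if hasattr(adata.X, "todense") \
        else np.asarray(adata.X)
    total = X.sum()
    sig = X.sum(axis=0) * 1e4 / total
    out = adata.var[["chrom", "start", "end"]].copy()
    out["name"] = adata.var.index
    out["signal"] = sig
    return out.reset_index(drop=True)


def run_pipeline(sim: SimConfig, run: RunConfig, outdir) -> dict:
    """Simulate, analyse, and write all report tables; returns key results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- foci dose-response
    foci_table = simulate_foci(sim)
    write_foci_csv(foci_table, outdir / "foci.csv")
    med = foci.median_response(foci_table, time=20)
    fit = foci.fit_hill(med, with_basal=True)
    pd.DataFrame([fit.to_dict()]).to_csv(outdir / "foci_hill_fit.csv",
                                         index=False)
    activation = foci.activation_from_foci(foci_table, time=20)
    activation.rename_axis("dose").to_csv(outdir / "foci_activation.csv")
    results["foci_hill"] = fit

    # --- expression
    adata, truth = simulate_expression(sim)
    adata = expression.qc_filter(
        adata, min_total=sim.qc_min_total, min_genes=sim.qc_min_genes,
        max_mito=sim.qc_max_mito)
    adata = expression.normalize(adata)
    states = expression.classify_cells(adata)
    degs = expression.find_degs(adata, states, alpha=run.deg_alpha,
                                pseudocount=run.fc_pseudocount)
    degs.to_csv(outdir / "degs.csv")
    fc = expression.dose_fold_changes(adata, pseudocount=run.fc_pseudocount)
    fc.to_csv(outdir / "dose_fold_changes.csv")
    results["n_degs"] = len(degs)
    results["states"] = states

    # --- heterogeneity
    up_degs = [g for g in degs.index[degs["direction"] == "up"]
               if not g.startswith("mito")]
    profiles = heterogeneity.fano(adata, genes=up_degs or None)
    profiles.to_csv(outdir / "fano_profiles.csv", index=False)
    top = max(float(d) for d in adata.obs["dose"].unique())
    ratios = heterogeneity.fano_ratio(profiles, top_dose=top)
    cv_ratios = heterogeneity.fano_ratio(profiles, top_dose=top, column="cv")
    clusters = heterogeneity.cluster_fano_dynamics(profiles, k=4)
    summary = pd.DataFrame({"fano_ratio": ratios, "cv_ratio": cv_ratios})
    summary["cluster_id"] = clusters
    summary.to_csv(outdir / "fano_summary.csv")
    results["fano_summary"] = summary

    # --- gene-level Hill
    panel = gene_hill.fit_gene_panel(fc, min_response=run.gene_fc_min_response)
    panel.to_csv(outdir / "gene_hill.csv")
    results["gene_hill"] = panel

    # --- enhancer calling
    matrices, peaks, atac_truth = simulate_atac(sim)
    write_bed(peak_bed(peaks, matrices["unstim"]), outdir / "peaks.bed")
    signal = {c: _peak_signal(m) for c, m in matrices.items()}
    by_cond = {}
    for cond, sig in signal.items():
        stitched = enhancers.stitch(sig, max_gap=run.stitch_gap)
        by_cond[cond] = enhancers.classify_se_te(stitched)
    merged = enhancers.merge_conditions(by_cond)

    def region_signal(sig_df, regions):
        out = np.zeros(len(regions))
        for i, row in enumerate(regions.itertuples()):
            m = ((sig_df["chrom"] == row.chrom)
                 & (sig_df["start"] < row.end) & (sig_df["end"] > row.start))
            out[i] = sig_df.loc[m, "signal"].sum()
        return out

    merged = enhancers.fold_change_and_categorize(
        merged,
        region_signal(signal["stim"], merged),
        region_signal(signal["unstim"], merged),
        pseudocount=run.signal_pseudocount,
        quantiles=run.fc_quantiles)
    merged["total_signal"] = region_signal(signal["stim"], merged)
    merged = enhancers.assign_genes(merged, atac_truth.tss)
    merged.assign(
        provenance=merged["provenance"].map(",".join)
    ).to_csv(outdir / "enhancers.csv")
    results["enhancers"] = merged

    # --- co-accessibility
    scores = {}
    for cond, m in matrices.items():
        meta = coaccess.aggregate_cells(m, k=run.knn_k)
        scores[cond] = coaccess.coaccess_scores(
            meta, window=run.coaccess_window, stride=run.coaccess_stride,
            base_penalty=run.coaccess_base_penalty,
            penalty_exponent=run.coaccess_penalty_exponent)
    pairs = coaccess.differential_pairs(
        scores["stim"], scores["unstim"],
        score_min=run.coaccess_score_min, delta_min=run.coaccess_delta_min)
    pairs.to_csv(outdir / "coaccess_pairs.csv", index=False)
    counts = coaccess.gene_pair_counts(pairs, atac_truth.tss, peaks,
                                       flank=run.tss_flank)
    corr_rows = []
    for stat_name, stat in (
        ("fano_ratio", summary["fano_ratio"]),
        ("rna_fold_change", fc[top]),
    ):
        try:
            rho, p = coaccess.correlate(counts, stat)
        except ValueError:
            rho, p = np.nan, np.nan
        corr_rows.append({"statistic": stat_name, "spearman_r": rho, "p": p})
    pd.DataFrame(corr_rows).to_csv(outdir / "coaccess_correlations.csv",
                                   index=False)
    counts.rename_axis("gene").to_csv(outdir / "gene_pair_counts.csv")
    results["pairs"] = pairs
    results["atac_truth"] = atac_truth

    write_provenance(outdir, {"sim": sim.to_dict(), "run": vars(run)},
                     seed=sim.seed)
    return results
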