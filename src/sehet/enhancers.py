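"""ROSE-style enhancer calling from peak signal tables.

Peaks within ``max_gap`` (default 5 kb) are stitched into enhancer
regions; regions are rank-ordered by total normalized signal and split
into super-enhancers (SE) and typical enhancers (TE) at the point of the
rescaled rank/signal curve where the tangent slope reaches 1 (the
classic ROSE geometry, implemented as the maximizer of
scaled_signal - scaled_rank).  Cross-condition region sets are merged
per class, assigned to their nearest TSS (a gene with both SE and TE
keeps the SE), and categorized gained / lost / unchanged by the
quartiles of the stimulated-vs-unstimulated log2 signal fold-change,
computed separately per class.

Regions are plain DataFrames with 0-based half-open coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["stitch", "classify_se_te", "merge_conditions", "assign_genes",
           "fold_change_and_categorize"]

REGION_COLUMNS = ["chrom", "start", "end", "members", "total_signal"]


def _check_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    bad = peaks.index[(peaks["start"] >= peaks["end"])
                      | (peaks["start"] < 0)]
    if len(bad):
        raise ValueError(f"malformed interval at line(s) {list(bad[:5])}")
    return peaks


def stitch(peaks: pd.DataFrame, max_gap: int = 5000) -> pd.DataFrame:
    """Stitch peaks whose inter-peak gap (next.start - prev.end) is at
    most ``max_gap``, per chromosome.

    Region signal is the sum of member signals; member peak names are
    retained.  Output covers exactly the union of input bases.
    """
    _check_peaks(peaks)
    if "name" not in peaks.columns:
        peaks = peaks.assign(name=[f"p{i}" for i in range(len(peaks))])
    regions = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start - cur["end"] <= max_gap:
                cur["end"] = max(cur["end"], row.end)
                cur["members"].append(row.name)
                cur["total_signal"] += float(row.signal)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": chrom, "start": int(row.start),
                       "end": int(row.end), "members": [row.name],
                       "total_signal": float(row.signal)}
        if cur is not None:
            regions.append(cur)
    out = pd.DataFrame(regions, columns=REGION_COLUMNS)
    out.index.name = "region_id"
    return out


def classify_se_te(regions: pd.DataFrame) -> pd.DataFrame:
    """Slope-1 SE/TE split on the rank-ordered signal curve.

    Regions are sorted by total signal ascending; rank and signal are
    rescaled to [0, 1] and the cutoff is the point maximizing
    (scaled_signal - scaled_rank) — for a convex hockey-stick curve this
    is where the tangent slope passes 1.  Ties take the last (highest-
    signal) maximizer, so a degenerate linear ramp yields boundary-only
    SEs.  Regions at or above the cutoff rank are SE.  Adds 'rank'
    (ascending signal order) and 'enh_class' columns.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions to classify SE vs TE")
    out = regions.sort_values(
        ["total_signal", "chrom", "start"]).reset_index(drop=True)
    out["rank"] = np.arange(len(out))
    sig = out["total_signal"].to_numpy(dtype=float)
    if sig.max() == sig.min():
        warnings.warn("all region signals equal: classifying everything TE",
                      stacklevel=2)
        out["enh_class"] = "TE"
        return out
    x = out["rank"].to_numpy() / (len(out) - 1)
    y = (sig - sig.min()) / (sig.max() - sig.min())
    diff = y - x
    # last maximizer, with an epsilon so degenerate (linear) geometries
    # where diff is constant up to rounding resolve to the boundary
    ties = np.flatnonzero(diff >= diff.max() - 1e-9)
    cut = int(ties[-1])
    out["enh_class"] = np.where(out["rank"] >= cut, "SE", "TE")
    return out


def merge_conditions(regions_by_condition: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Coordinate union-merge of stitched regions across conditions,
    separately for SE and TE sets.

    Overlapping or bookended intervals merge; member provenance
    (condition of origin) is retained.
    """
    frames = []
    for cond, df in regions_by_condition.items():
        d = df.copy()
        d["condition"] = cond
        frames.append(d)
    allr = pd.concat(frames, ignore_index=True)
    merged = []
    for enh_class, by_class in allr.groupby("enh_class", sort=True):
        for chrom, grp in by_class.groupby("chrom", sort=True):
            grp = grp.sort_values(["start", "end"])
            cur = None
            for row in grp.itertuples():
                if cur is not None and row.start <= cur["end"]:  # bookended merges
                    cur["end"] = max(cur["end"], row.end)
                    cur["provenance"].append(row.condition)
                else:
                    if cur is not None:
                        merged.append(cur)
                    cur = {"chrom": chrom, "start": int(row.start),
                           "end": int(row.end), "enh_class": enh_class,
                           "provenance": [row.condition]}
            if cur is not None:
                merged.append(cur)
    out = pd.DataFrame(merged)
    out.index.name = "region_id"
    return out


def assign_genes(regions: pd.DataFrame, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Assign each region to its nearest TSS and keep one enhancer per gene.

    Distance is from the region midpoint to the TSS position.  A gene
    with both SE and TE keeps the SE; within a class, the highest total
    signal wins.  Equidistant TSSs resolve to the lower coordinate.
    Regions on chromosomes absent from the TSS table stay unassigned
    with a warning.
    """
    out = regions.copy()
    out["assigned_gene"] = pd.NA
    tss_by_chrom = {
        c: g.sort_values(["position", "gene"]) for c, g in tss_table.groupby("chrom")
    }
    missing_chroms = set()
    for idx, row in out.iterrows():
        cands = tss_by_chrom.get(row["chrom"])
        if cands is None:
            missing_chroms.add(row["chrom"])
            continue
        mid = (row["start"] + row["end"]) / 2
        dist = (cands["position"] - mid).abs().to_numpy()
        best = int(np.argmin(dist))  # first minimum = lower coordinate
        out.at[idx, "assigned_gene"] = cands.iloc[best]["gene"]
    if missing_chroms:
        warnings.warn(
            f"no TSS entries for chromosome(s) {sorted(missing_chroms)}; "
            "regions left unassigned", stacklevel=2)

    # one enhancer per gene: SE beats TE, then highest signal
    class_prio = out["enh_class"].map({"SE": 0, "TE": 1}).fillna(2)
    sig = out.get("total_signal", pd.Series(0.0, index=out.index))
    ranked = out.assign(_prio=class_prio, _sig=-sig.astype(float))
    keep_idx = (
        ranked.dropna(subset=["assigned_gene"])
        .sort_values(["_prio", "_sig"])
        .drop_duplicates(subset="assigned_gene", keep="first")
        .index
    )
    dropped = out["assigned_gene"].notna() & ~out.index.isin(keep_idx)
    out.loc[dropped, "assigned_gene"] = pd.NA
    return out


def fold_change_and_categorize(
    regions: pd.DataFrame,
    signal_stim: np.ndarray,
    signal_unstim: np.ndarray,
    pseudocount: float = 1.0,
    quantiles: tuple[float, float] = (0.25, 0.75),
) -> pd.DataFrame:
    """Quartile-based gained / lost / unchanged categories per class.

    log2 FC = log2((stim + c) / (unstim + c)); per enh_class, regions
    with FC strictly above the upper quantile are gained, strictly below
    the lower quantile lost, otherwise unchanged.
    """
    out = regions.copy()
    stim = np.asarray(signal_stim, dtype=float)
    unstim = np.asarray(signal_unstim, dtype=float)
    out["log2_fc"] = np.log2((stim + pseudocount) / (unstim + pseudocount))
    out["category"] = "unchanged"
    lo_q, hi_q = quantiles
    for enh_class, grp in out.groupby("enh_class", sort=True):
        if grp.empty:
            warnings.warn(f"empty class {enh_class}: skipped", stacklevel=2)
            continue
        lo = grp["log2_fc"].quantile(lo_q)
        hi = grp["log2_fc"].quantile(hi_q)
        out.loc[grp.index[grp["log2_fc"] > hi], "category"] = "gained"
        out.loc[grp.index[grp["log2_fc"] < lo], "category"] = "lost"
    return out
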