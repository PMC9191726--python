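"""Motif-density stratification across enhancer categories.

Builds synthetic enhancer sequences whose planted NF-κB site content
rises from lost to unchanged to gained regions (PU.1 content flat),
scans them with the built-in PWMs, and compares densities per group with
the undersampled ANOVA.  Writes results under results/motifs/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sehet.io import write_provenance
from sehet.motifs import builtin_motifs, density_compare, scan_motifs

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "motifs"
SEED = 13

NFKB_SITE = "GGGAATTTCC"
PU1_SITE = "AGAGGAAGTG"
SITES_PER_10KB = {"gained": 5.0, "unchanged": 3.3, "lost": 2.5}  # NF-κB
PU1_PER_10KB = 10.0


def synth_region(rng, length, n_nfkb, n_pu1):
    parts = list(rng.choice(list("ACGT"), length))
    seq = "".join(parts)
    for site, n in ((NFKB_SITE, n_nfkb), (PU1_SITE, n_pu1)):
        for _ in range(n):
            pos = int(rng.integers(0, length - len(site)))
            seq = seq[:pos] + site + seq[pos + len(site):]
    return seq


def main() -> None:
    rng = np.random.default_rng(SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    seqs, labels = {}, {}
    for cat, rate in SITES_PER_10KB.items():
        for i in range(30):
            length = int(rng.integers(4000, 12_000))
            rid = f"{cat}_{i:02d}"
            seqs[rid] = synth_region(
                rng, length,
                n_nfkb=rng.poisson(rate * length / 1e4),
                n_pu1=rng.poisson(PU1_PER_10KB * length / 1e4))
            labels[rid] = cat
    models = builtin_motifs()
    hits = scan_motifs(seqs, models)
    hits.to_csv(OUT / "motif_hits.csv", index=False)

    grouping = pd.Series(labels)
    rows = []
    for family in ("NFkB", "PU.1"):
        res = density_compare(hits, grouping, family=family, seed=SEED)
        rows.append({"family": family, **res["medians"],
                     "pvalue": res["pvalue"], "n": res["n_undersampled"]})
        meds = ", ".join(f"{k} {v:.1f}" for k, v in res["medians"].items())
        verdict = "differs" if res["pvalue"] < 0.05 else "flat"
        print(f"{family} density per 10 kb: {meds} "
              f"(undersampled ANOVA p = {res['pvalue']:.2g} -> {verdict})")
    pd.DataFrame(rows).to_csv(OUT / "density_by_category.csv", index=False)
    print("NF-κB density tracks the gained > unchanged > lost ordering; "
          "PU.1 does not separate the categories.")
    write_provenance(OUT, {"seed": SEED}, SEED)


if __name__ == "__main__":
    main()
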