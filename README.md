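# sehet — super-enhancer-mediated transcriptional heterogeneity

`sehet` re-implements, as a tested and reusable pipeline, the analysis of
how NF-κB-driven super-enhancers (SEs) shape dose-dependent,
heterogeneous gene expression in activated B cells. It is aimed at
computational biologists who want each step of that analysis —
enhancer calling from ATAC signal, single-cell noise statistics,
dose-response cooperativity, motif content, and single-cell ATAC
co-accessibility — as an importable, seed-reproducible library, exercised
end to end on synthetic data with planted ground truth.

## What it computes

* **ROSE-style enhancer calling.** Peaks within 5 kb are stitched into
  regions; regions are rank-ordered by total normalized signal and split
  into SEs and typical enhancers (TEs) at the point of the rescaled
  rank/signal curve where the tangent slope passes 1 (the maximizer of
  *y* − *x*). Merged cross-condition regions are categorized
  gained / lost / unchanged by the quartiles of their log2 signal
  fold-change, per class.
* **Fano-factor heterogeneity.** For each gene *g* and dose *d*, the Fano
  factor Ω²/μ of normalized expression (1 under Poisson noise) measures
  transcriptional noise; 10-vs-0 µg/mL ratios and Ward-clustered (ward.D2)
  dynamics profiles summarize how noise evolves with stimulation.
* **Hill cooperativity.** Dose responses (median nuclear RelA foci per
  cell, or per-gene expression fold-changes) are fitted to
  *f*(*d*) = *a* + *k·d^N* / (*Km^N* + *d^N*) by multi-start least
  squares; the Hill coefficient *N* classifies switch-likeness
  (high 5 ≤ *N* < 9, med 1 < *N* < 5, low *N* ≤ 1; *N* > 9 or *N* < 0.3
  excluded as non-fitting).
* **Motif density.** A FIMO-like PWM scan (exact DP threshold at
  p ≤ 1e-4, both strands) yields motif occurrences per 10⁴ bp, compared
  across enhancer groups with undersampled ANOVA / Welch tests.
* **Co-accessibility.** Cell × peak fragment counts are scored per
  500-kb window with a distance-penalized graphical lasso
  (penalty ∝ (distance/s)^0.75); partial correlations are the
  co-accessibility scores, and pairs with stimulated score ≥ 0.1 and
  stimulated-minus-unstimulated difference ≥ 0.05 are "gained".
  Gained partners within ±1 kb of a TSS are counted per gene and
  correlated (Spearman) with expression statistics.
* **Synthetic data.** `sehet.synthetic` generates every input modality
  with planted truth: Hill-gated bimodal cell activation,
  negative-binomial counts whose noise structure differs for SE-like vs
  TE-like genes, clustered ATAC peak architectures, latent-factor
  co-accessibility that strengthens upon stimulation, and Hill-shaped
  foci dose-responses.

## Worked example

```python
from sehet.config import SimConfig
from sehet.synthetic import simulate_foci
from sehet.foci import median_response, fit_hill

table = simulate_foci(SimConfig(seed=1))        # 11,500 cells, 23 doses
fit = fit_hill(median_response(table, time=20), with_basal=True)
print(f"N = {fit.N:.2f}, Km = {fit.Km:.3f} ug/mL, k = {fit.k:.1f}, a = {fit.a:.2f}")
```

prints

```
N = 4.18, Km = 0.103 ug/mL, k = 12.0, a = 0.90
```

— the fitted Hill coefficient *N* ≈ 4 says foci formation is strongly
cooperative (switch-like): the median foci count rises from its basal
level *a* ≈ 1 to saturation *a* + *k* ≈ 13 over roughly a two-fold dose
range around the half-maximal dose *Km* ≈ 0.1 µg/mL, recovering the
parameters the generator planted (a=1, k=12, N=4, Km=0.1).

The numbered scripts under `analysis/` run the whole study on synthetic
data and narrate their findings, writing tables under `results/`:

```sh
python analysis/01_simulate_inputs.py
python analysis/02_foci_cooperativity.py
...
python analysis/06_coaccessibility.py
```

A `sehet` command-line tool exposes the same stages
(`sehet simulate | foci-fit | expr | fano | rose | hill | motif |
coaccess | report`); every run drops a provenance JSON with the config
hash, seed and package versions.

## Layout

```
src/sehet/        library: config, synthetic, foci, hill, expression,
                  heterogeneity, enhancers, gene_hill, motifs, coaccess,
                  io, pipeline, cli
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property, and pipeline-level tests)
scripts/          acceptance.py
docs/methods.md   models, parameters, numerical choices, limitations
```
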