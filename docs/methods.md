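# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Study design emulated

The pipeline targets a dose-resolved B-cell activation experiment:
cells stimulated with anti-IgM at 0, 0.01, 0.1, 1 and 10 µg/mL, read
out by (i) imaging of nuclear RelA foci per cell, (ii) deep single-cell
RNA profiling (~90 cells per dose), and (iii) single-cell ATAC in an
unstimulated and a 10 µg/mL-stimulated condition. All three modalities
are generated synthetically with planted ground truth so every
downstream claim is checkable.

## Synthetic-data generator

**Cell activation.** Each cell activates with Hill probability
p(d) = d^N/(Km^N + d^N), default N = 4, Km = 0.1 µg/mL. At dose 0 the
probability is exactly 0; it is non-decreasing in dose.

**Expression counts.** Counts are negative binomial, parameterized by
(mean, dispersion θ) with variance m + m²/θ, i.e. a two-state mixture
(off/on per cell) rather than explicit telegraph kinetics — sufficient
to plant Fano-factor structure, which is the measured quantity. Gene
classes and class defaults:

| class       | mean off | mean on | θ    | share |
|-------------|----------|---------|------|-------|
| SE-like     | 1        | 25      | 1.5  | 25%   |
| TE-like     | 3        | 10      | 8    | 55%   |
| background  | 150      | 150     | 20   | 20%   |

Background genes model the housekeeping bulk of a library: without this
high-expressed, dose-independent mass, per-cell depth normalization
would absorb the global induction and invert the sign of TE-gene
changes (a composition artifact, not a bug — the generator must supply
a realistic library composition for depth scaling to be meaningful).
Per-gene lognormal jitter (σ = 0.4 on means; σ = 0.3 / 0.8 on the off-
and on-state dispersions, drawn independently) gives genes individual
burst sizes and noise changes; the independent on-state dispersion is
what lets Fano-ratio and CV-ratio ranks agree positively across genes,
as observed in real data (with a single shared dispersion the two
ratios differ only through the mean change and their correlation
degenerates). Per-cell depth is lognormal (σ = 0.3); 5% of cells are
planted low-quality (0.15× depth, 6× mitochondrial load) so QC has
something to remove. Five mitochondrial genes carry ~3% of a typical
library.

**ATAC counts.** Peaks are laid out in clusters (2–5 peaks, internal
gaps 0.2–3 kb, inter-cluster gaps 8–40 kb) so stitching at 5 kb
reconstructs the planted architectures exactly. About 20% of clusters
— the longest — are SE-like: they anchor SE-class genes and carry
~3× denser per-peak signal, which gives the rank-ordered region totals
the convex hockey-stick shape the slope-1 rule expects; each peak also
has a lognormal strength (σ = 0.4). Accessibility is emitted Poisson
around latent log-normal factors: background factors load random peak
subsets equally in both conditions; each planted co-accessible pair
shares a private factor (loading 0.3) whose loading is multiplied by
stim_gain = 3 in the stimulated condition only. Planted pairs anchor at
the TSS peaks of gene-assigned clusters (SE clusters first), which
plants the coupling between gained cis-pairs and expression response
that the correlation stage measures.

**Foci counts.** Per-cell foci are Poisson with mean
a + k·d^N/(Km^N + d^N) (defaults a = 1, k = 12, N = 4, Km = 0.1), i.e.
the generator inverts the model the analysis fits to per-dose medians;
optional zero-inflation reproduces bimodal per-dose histograms. The
default imaging ladder is 0, a 21-point 1.25-fold titration from
0.01 µg/mL, and a saturating 10 µg/mL. This fine ladder is a design
requirement, not a convenience: with decade-spaced doses only one dose
falls inside the Hill transition and the exponent N is structurally
unidentifiable from medians (the residual surface has a ridge running
to the optimizer bound), and because per-dose medians of counts are
quantized to half-integers, several doses per quantization step are
needed before the fitted N is stable.

**Seeding.** One run seed expands to per-modality child streams via
counter-based spawn keys (expression 0, atac 1, foci 2), so outputs are
bit-identical under a fixed seed and adding one generator never
perturbs another.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequencing reads (counts are drawn
directly), sequence-level motif placement inside the ATAC peaks,
ambient contamination and doublets, cell-cycle structure, batch
effects, and transcript-length or GC biases. Library depth is
panel-scaled, not transcriptome-scaled, so the published QC cutoffs
(total ≥ 1.5 × 10⁶, detected genes ≥ 8500, mitochondrial ratio < 0.04)
remain the defaults of `qc_filter` but the synthetic pipeline uses
panel-scaled equivalents (total ≥ 2000, genes ≥ 120, mito < 0.1) from
`SimConfig`; a 205-gene panel can never satisfy a "≥ 8500 detected
genes" rule.

## Analysis stages

**QC / normalization.** Threshold semantics are ≥, ≥, < as published.
Normalization is per-cell depth scaling to the median depth; the
linear scaled layer feeds Fano factors and fold-changes (the Poisson
reference Ω²/μ = 1 exists only on the count scale), the log1p layer
feeds classification and rank tests. Empirical-Bayes count recovery
(Baynorm-style imputation) is out of scope; the downstream statistics
need only a monotone per-cell scaling, and the choice is recorded in
each run's provenance.

**Activation states.** A two-component Gaussian mixture on the mean
normalized expression of marker genes (defaults: the flagged SE-like
markers); the higher-mean component is "activated". This targets the
same definition the original cluster-based analysis validated by marker
means. Cell-cycle regression is omitted.

**DEGs.** Per-gene Wilcoxon rank-sum between states on log1p values,
Benjamini–Hochberg adjustment, adjusted p < 0.05 (deliberately lenient
to retain heterogeneous genes); log2 fold-change of state means with
pseudocount 1. The depth-composition effect makes background genes
weakly "down" in activated cells; this is a real property of
composition-confounded differential expression, and specificity is
therefore tested with label permutations rather than against the
background class.

**Fano dynamics clustering.** Per-gene trajectories are centered and
divided by their sd across doses **floored at the panel-median sd**,
then Ward-linked (scipy's `ward` on observations ≡ hclust ward.D2 on
Euclidean distances) and cut at k = 4. A plain z-score would blow
near-flat profiles up into unit-variance noise and make the flat
archetype unrecoverable; the floor leaves genuinely dynamic profiles
effectively z-scored while keeping flat profiles small.

**Undersampled tests.** All groups are subsampled without replacement
to the smallest group size (seeded), then one-way ANOVA (or Welch's
t-test for two groups) runs on the subsample. Equal group sizes make
undersampling a no-op, so the result then equals the plain test.

**Hill fitting.** An 8×8 log-spaced grid over (N, Km) — N ∈ [0.25, 16],
Km ∈ [min positive dose/10, max dose×10] — with the conditionally
linear (a, k) solved analytically per node, then Nelder–Mead and
L-BFGS-B polish from the three best nodes; the basket's best rss wins,
emulating a best-of-many-optimizers strategy with reproducible parts.
N is bounded to [0.05, 20] (recorded in the fit) to avoid overflow.
Among rss ties within 1e-6 relative, the smallest N wins: steepness is
reported only when the data demand it. Non-negativity of a and k is
enforced by clip-and-resolve. Dose 0 is included as-is (model value a).
Gene-level fits are basal-free (a = 0) and applied to FC − 1, the
response above the fold-change floor of 1 at dose 0 — fitting the raw
ratio would force a structural misfit at low doses since the basal-free
model passes through 0. Genes enter the fit only if their top-dose
response FC − 1 exceeds 0.2 (the published "fold change above 0.2"
filter, resolved to this reading and configurable). Category bounds
follow the plotted groups: excluded outside (0.3, 9], high [5, 9],
med (1, 5), low ≤ 1.

**Foci-based activation fractions.** Binary labels from a
two-component Poisson mixture (EM) over pooled foci counts, a logistic
regression of label on count, and per-dose mean predicted
probabilities. If the mixture means separate by < 0.5 counts, a median
threshold is used with a warning. Limitation: with the unimodal
per-dose emission of the default generator the procedure estimates
P(foci above the separatrix | dose), which coincides with the planted
activation probability only where that probability is near 0 or 1; at
transition doses it is systematically steeper. The tests assert
recovery in the near-binary regime plus monotonicity.

**Enhancer calling.** Stitching merges peaks whose gap ≤ 5 kb (region
signal = sum of member signals; output covers exactly the union of
input bases). SE/TE: sort by total signal, rescale rank and signal to
[0, 1], cut at the *last* maximizer of (scaled signal − scaled rank)
with a 1e-9 tie epsilon — so a degenerate linear ramp yields boundary-
only SEs and an all-equal panel is all-TE with a warning. Merging is a
coordinate union (bookended intervals merge), SE and TE separately.
Gene assignment: nearest TSS to the region midpoint, one enhancer per
gene, SE beats TE, then highest signal; equidistant TSSs resolve to the
lower coordinate. Gained/lost: log2((stim+1)/(unstim+1)) against the
class-wise quartiles, strict inequalities (upper/lower "quantile" read
as Q3/Q1, computed per class; both choices configurable). The ROSE
promoter-exclusion window is not used.

**Motif scanning.** PWMs score log2((p + 0.01 pseudocount, renormalized)
/ background); the hit threshold is the smallest score whose exact tail
probability under the background model is ≤ 1e-4, computed by dynamic
programming over per-position score distributions discretized at 1/1000
bit. Both strands are scanned and opposite-strand hits at one position
both count; N-containing windows are skipped; family counts (three
NF-κB-type, two PU.1-type matrices in the built-in set) are summed.
Densities are hits × 10⁴ / region length. The built-in PWMs are
synthetic consensus-derived stand-ins (so named in code), adequate for
planted-motif simulations, not for scanning real genomes. A TATA-box
note: an 8-bp motif cannot reach p ≤ 1e-4 under a uniform background
(its best-score class alone is ~1.2e-4), so the built-in TATA model is
10 bp; short motifs generally need a looser per-motif threshold, which
is exposed.

**Co-accessibility.** Optional meta-cell densification (TF-IDF →
truncated SVD → k-NN group sums, Jaccard-deduplicated above 0.9)
exists for sparse fragment data; the default pipeline uses k = 1
because the simulator's deep counts need no densification and
overlapping meta-cells pseudo-replicate observations, which destroys
the precision of differential calls. Scores: per 500-kb window
(stride 250 kb), the correlation matrix of standardized peak counts is
inverted under an element-wise L1 penalty
ρ_ij = α·(d_ij/s)^0.75 with s = window/2, by Friedman-style block
coordinate descent (inner lasso, tolerance 1e-4, ≤ 200 sweeps; ρ ≡ 0
short-circuits to the exact inverse). Partial correlations
−Θ_ij/√(Θ_ii Θ_jj), clipped to [−1, 1], are the scores; multi-window
pairs average. The base penalty α = 0.5 was calibrated once so that
planted-null pairs score ~0 (median magnitude ≪ 0.02) while planted
pairs survive; the off-diagonal estimates agree with scikit-learn's
scalar-penalty graphical lasso to < 5e-3 where comparable. Gained
pairs: stimulated score ≥ 0.1 and difference ≥ 0.05, both boundary-
inclusive. Gene counts: distinct gained partners of any peak
overlapping TSS ± 1 kb. Correlations are Spearman with average ranks.

## Problem sizes

Default study conditions: 450 expression cells × 205 genes over five
doses; 500 ATAC cells × 200 peaks × two conditions; 11,500 imaged
cells over 23 doses. Replicate studies use 100 seeds for Hill recovery,
2000 replicates for the ANOVA type-I calibration, and 500 regions /
1000 peaks for the oracle-equivalence checks. These sizes keep a full
pipeline run under a minute while leaving every statistical conclusion
comfortably powered.

## Known limitations

* SE calling on a ~55-region miniature panel yields 1–3 SEs (a
  proportionally faithful ~2–5%), so SE-stratified group comparisons in
  the analysis scripts are thin; the motif-density stratification
  therefore runs on purpose-built synthetic region sets.
* Gene-level Hill exponents from five decade-spaced doses are weakly
  identified above N ≈ 2 (one dose in the transition); the
  high/excluded categories absorb the resulting ridge artifacts — this
  is exactly why exponents above 9 are discarded as over-fitted.
* The Fano factor is mean-dependent; the pipeline reports CV ratios
  alongside, and the generator's independent on-state dispersion is
  what makes their ranks agree — real data need not behave this way
  gene-by-gene.
* Bimodal dose-responses (mixture-of-states expression) are fitted
  "roughly" by a single Hill curve by design; mixture dose-response
  models are out of scope.
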