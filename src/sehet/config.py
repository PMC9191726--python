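"""Run and simulation configuration.

All tunable thresholds of the pipeline live here with their published
defaults (QC cutoffs, stitch gap, co-accessibility thresholds, Hill
category bounds, ...), so every stage can be driven from one validated
config object.  A single user seed is expanded into independent
per-submodule child seeds through a counter-based spawn scheme: adding a
new generator consumes a new counter slot and never perturbs the streams
of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

# fixed counter slots for child seed streams; append only, never reorder
_STREAMS = {
    "expression": 0,
    "atac": 1,
    "foci": 2,
    "qc": 3,
}

#: anti-IgM doses (µg/mL) used for the single-cell RNA experiment
RNA_DOSES = (0.0, 0.01, 0.1, 1.0, 10.0)

#: imaging dose ladder (µg/mL) for foci counting: zero, a 21-point
#: 1.25-fold automated titration spanning the response transition, and a
#: saturating top dose.  Decade spacing leaves the Hill exponent
#: unidentifiable from per-dose medians (a single dose falls inside the
#: transition zone), and per-dose medians of counts are quantized to
#: half-integers, so several doses per quantization step are needed.
FOCI_DOSES = (0.0,) + tuple(
    round(0.01 * 1.25**j, 6) for j in range(21)
) + (10.0,)


def child_rng(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named submodule stream derived from the run seed."""
    if stream not in _STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],))
    )


class ConfigError(ValueError):
    """Invalid simulation or run configuration."""


@dataclass
class BurstParams:
    """Negative-binomial emission parameters for one gene class.

    ``mean_off``/``mean_on`` are the expected counts in inactivated and
    activated cells; ``dispersion`` is the NB size parameter theta, so the
    count Fano factor in a pure state is 1 + mean/theta.
    """

    mean_off: float
    mean_on: float
    dispersion: float

    def validate(self, name: str) -> None:
        if self.mean_off < 0 or self.mean_on < 0:
            raise ConfigError(f"{name}: negative burst mean")
        if self.dispersion <= 0:
            raise ConfigError(f"{name}: dispersion must be positive")


@dataclass
class SimConfig:
    """Ground-truth-planted simulation settings.

    Defaults emulate the study design: five anti-IgM doses at ~90 cells
    per dose for expression, two scATAC conditions (unstimulated /
    10 µg/mL stimulated), and a dose-resolved foci-count table whose
    medians follow a Hill curve.
    """

    n_cells_per_dose: int = 90
    doses: Sequence[float] = RNA_DOSES
    n_genes: int = 200
    frac_se_genes: float = 0.25
    frac_null_genes: float = 0.2
    n_mito_genes: int = 5
    # cell activation vs dose: p(d) = d^N / (Km^N + d^N)
    activation_hill: dict = field(default_factory=lambda: {"N": 4.0, "Km": 0.1})
    burst_params: dict = field(
        default_factory=lambda: {
            # SE-like genes: near-silent basal state, large noisy bursts on
            "SE": BurstParams(mean_off=1.0, mean_on=25.0, dispersion=1.5),
            # TE-like genes: modest induction, tighter dispersion
            "TE": BurstParams(mean_off=3.0, mean_on=10.0, dispersion=8.0),
            # background genes: dose-independent housekeeping expression;
            # high means so library size is not dominated by induced genes
            "background": BurstParams(mean_off=150.0, mean_on=150.0,
                                      dispersion=20.0),
        }
    )
    depth_sigma: float = 0.3  # lognormal sd of per-cell depth factor
    frac_low_quality: float = 0.05
    # panel-scaled QC thresholds applied by the synthetic pipeline
    qc_min_total: float = 2000.0
    qc_min_genes: int = 120
    qc_max_mito: float = 0.1

    # scATAC
    n_cells_atac: int = 500
    n_peaks: int = 200
    n_chromosomes: int = 2
    coaccess_factors: dict = field(
        default_factory=lambda: {
            "n_factors": 8,
            "loading_scale": 0.3,
            "stim_gain": 3.0,
            "n_planted_pairs": 20,
        }
    )
    atac_base_rate: float = 3.0

    # foci imaging
    foci_doses: Sequence[float] = FOCI_DOSES
    n_cells_per_dose_foci: int = 500
    foci_hill: dict = field(
        default_factory=lambda: {"a": 1.0, "k": 12.0, "N": 4.0, "Km": 0.1}
    )
    foci_zero_inflation: float = 0.0

    seed: int = 0

    def validate(self) -> None:
        for name, doses in (("doses", self.doses), ("foci_doses", self.foci_doses)):
            d = np.asarray(doses, dtype=float)
            if d.size < 2 or d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ConfigError(
                    f"{name} must be strictly increasing and start at 0"
                )
        for n, label in (
            (self.n_cells_per_dose, "n_cells_per_dose"),
            (self.n_genes, "n_genes"),
            (self.n_peaks, "n_peaks"),
            (self.n_chromosomes, "n_chromosomes"),
            (self.n_cells_atac, "n_cells_atac"),
            (self.n_cells_per_dose_foci, "n_cells_per_dose_foci"),
        ):
            if n <= 0:
                raise ConfigError(f"{label} must be positive")
        if not 0 <= self.frac_se_genes <= 1:
            raise ConfigError("frac_se_genes must lie in [0, 1]")
        if not 0 <= self.frac_null_genes <= 1 - self.frac_se_genes:
            raise ConfigError("frac_null_genes incompatible with frac_se_genes")
        if self.activation_hill["N"] <= 0 or self.activation_hill["Km"] <= 0:
            raise ConfigError("activation_hill N and Km must be positive")
        for key, bp in self.burst_params.items():
            bp.validate(key)
        if self.foci_hill["a"] < 0 or self.foci_hill["k"] < 0:
            raise ConfigError("foci_hill a and k must be non-negative")
        if self.coaccess_factors["n_factors"] >= self.n_peaks:
            raise ConfigError("n_factors must be smaller than n_peaks")

    def rng(self, stream: str) -> np.random.Generator:
        return child_rng(self.seed, stream)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["doses"] = list(self.doses)
        d["foci_doses"] = list(self.foci_doses)
        return d


@dataclass
class RunConfig:
    """Analysis-stage thresholds, all defaulting to the published values."""

    # expression QC (published defaults; panel-scaled values come from SimConfig)
    qc_min_total: float = 1.5e6
    qc_min_genes: int = 8500
    qc_max_mito: float = 0.04
    deg_alpha: float = 0.05
    fc_pseudocount: float = 1.0

    # enhancer calling
    stitch_gap: int = 5000
    fc_quantiles: tuple = (0.25, 0.75)
    signal_pseudocount: float = 1.0

    # gene Hill categorization (Fig-style bins)
    hill_exclude_low: float = 0.3
    hill_exclude_high: float = 9.0
    hill_high: float = 5.0
    hill_low: float = 1.0
    gene_fc_min_response: float = 0.2

    # co-accessibility
    coaccess_window: int = 500_000
    coaccess_stride: int = 250_000
    coaccess_penalty_exponent: float = 0.75
    # calibrated so planted-null pairs score ~0 (median well under 0.02)
    coaccess_base_penalty: float = 0.5
    coaccess_score_min: float = 0.1
    coaccess_delta_min: float = 0.05
    # meta-cell aggregation densifies sparse fragment data; the deep-count
    # regime of the simulator needs none (k=1 is the identity)
    knn_k: int = 1
    tss_flank: int = 1000

    # motif scanning
    motif_pvalue: float = 1e-4

    seed: int = 0
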