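"""Generator contracts: determinism, planted structure, error handling."""

import numpy as np
import pandas as pd
import pytest

from sehet.config import ConfigError, SimConfig
from sehet.enhancers import stitch
from sehet.synthetic import simulate_atac, simulate_expression, simulate_foci


def small_config(**kw):
    defaults = dict(n_cells_per_dose=40, n_genes=60, n_peaks=80,
                    n_cells_atac=150, n_cells_per_dose_foci=100, seed=0)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(doses=(0.0, 0.1, 0.1)),
        dict(doses=(0.01, 0.1)),          # must start at 0
        dict(doses=(0.0, 1.0, 0.1)),
        dict(n_genes=0),
        dict(n_cells_per_dose=-3),
        dict(frac_se_genes=1.5),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ConfigError):
            small_config(**kw).validate()

    def test_too_many_factors_rejected(self):
        cfg = small_config()
        cfg.coaccess_factors["n_factors"] = cfg.n_peaks
        with pytest.raises(ConfigError):
            simulate_atac(cfg)

    def test_negative_foci_params_rejected(self):
        cfg = small_config()
        cfg.foci_hill["k"] = -1.0
        with pytest.raises(ConfigError):
            simulate_foci(cfg)


class TestDeterminism:
    def test_expression_bit_identical(self):
        a1, _ = simulate_expression(small_config(seed=11))
        a2, _ = simulate_expression(small_config(seed=11))
        assert np.array_equal(np.asarray(a1.X), np.asarray(a2.X))
        assert a1.obs.equals(a2.obs)

    def test_atac_bit_identical(self):
        m1, p1, _ = simulate_atac(small_config(seed=11))
        m2, p2, _ = simulate_atac(small_config(seed=11))
        for cond in m1:
            assert (m1[cond].X != m2[cond].X).nnz == 0
        assert p1.equals(p2)

    def test_foci_bit_identical(self):
        assert simulate_foci(small_config(seed=11)).equals(
            simulate_foci(small_config(seed=11)))

    def test_streams_independent(self):
        """Regenerating one modality never perturbs another."""
        _, _, _ = simulate_atac(small_config(seed=11))
        f1 = simulate_foci(small_config(seed=11))
        f2 = simulate_foci(small_config(seed=11))
        assert f1.equals(f2)


class TestExpressionTruth:
    def test_counts_non_negative_integers(self):
        adata, _ = simulate_expression(small_config())
        X = np.asarray(adata.X)
        assert X.min() >= 0 and np.issubdtype(X.dtype, np.integer)

    def test_zero_dose_never_activated(self):
        adata, truth = simulate_expression(small_config(seed=2))
        act = truth.activation
        assert not act.loc[act["dose"] == 0.0, "activated"].any()

    def test_half_maximal_dose_activates_half(self):
        cfg = small_config(n_cells_per_dose=400, seed=3)
        _, truth = simulate_expression(cfg)
        act = truth.activation
        frac = act.loc[act["dose"] == 0.1, "activated"].mean()
        # Km = 0.1 -> p = 0.5; allow 4 binomial standard errors
        assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / 400)

    def test_activation_fraction_monotone_in_dose(self):
        _, truth = simulate_expression(SimConfig(seed=1))
        frac = truth.activation.groupby("dose")["activated"].mean()
        assert (np.diff(frac[sorted(frac.index)]) >= -0.05).all()

    def test_metadata_matches_counts(self):
        adata, _ = simulate_expression(small_config(seed=4))
        X = np.asarray(adata.X)
        assert np.array_equal(adata.obs["total_count"], X.sum(axis=1))
        assert np.array_equal(adata.obs["n_detected_genes"], (X > 0).sum(axis=1))

    def test_se_fano_ratio_exceeds_te_median(self):
        """Brute-force count-scale Fano ratio: SE-like above TE-like median."""
        cfg = SimConfig(n_genes=200, frac_se_genes=0.25, seed=1)
        adata, truth = simulate_expression(cfg)
        X = np.asarray(adata.X, dtype=float)
        dose = adata.obs["dose"].to_numpy()

        def fano_ratio(j):
            hi, lo = X[dose == 10.0, j], X[dose == 0.0, j]
            return ((hi.var(ddof=1) / hi.mean())
                    / (lo.var(ddof=1) / lo.mean()))

        gc = truth.gene_class
        cols = {g: i for i, g in enumerate(adata.var.index)}
        se = np.median([fano_ratio(cols[g]) for g in gc.index[gc == "SE"]])
        te = np.median([fano_ratio(cols[g]) for g in gc.index[gc == "TE"]])
        assert se > te

    def test_se_fold_change_exceeds_te(self):
        adata, truth = simulate_expression(SimConfig(seed=2))
        X = np.asarray(adata.X, dtype=float)
        dose = adata.obs["dose"].to_numpy()
        fc = ((X[dose == 10.0].mean(axis=0) + 1)
              / (X[dose == 0.0].mean(axis=0) + 1))
        gc = truth.gene_class
        cols = {g: i for i, g in enumerate(adata.var.index)}
        se = np.median([fc[cols[g]] for g in gc.index[gc == "SE"]])
        te = np.median([fc[cols[g]] for g in gc.index[gc == "TE"]])
        assert se > te


class TestAtacTruth:
    def test_planted_pairs_reference_valid_same_chromosome_peaks(
            self, sim_atac_seed7):
        _, peaks, truth = sim_atac_seed7
        byname = peaks.set_index("name")
        for row in truth.planted_pairs.itertuples():
            assert row.peak_i in byname.index and row.peak_j in byname.index
            assert byname.loc[row.peak_i, "chrom"] == \
                byname.loc[row.peak_j, "chrom"] == row.chrom

    def test_stitching_reconstructs_planted_architectures(self, sim_atac_seed7):
        _, peaks, truth = sim_atac_seed7
        sig = peaks.assign(signal=1.0)
        regions = stitch(sig, max_gap=5000)
        planted = {
            tuple(sorted(g["name"]))
            for _, g in peaks.groupby("enhancer_id")
        }
        stitched = {tuple(sorted(m)) for m in regions["members"]}
        assert planted == stitched

    def test_se_architectures_longer_than_te_median(self, sim_atac_seed7):
        _, peaks, truth = sim_atac_seed7
        lengths = (peaks["end"] - peaks["start"]).groupby(
            peaks["enhancer_id"]).sum()
        gc = truth.gene_class
        cluster_class = {}
        for row in truth.tss.itertuples():
            cluster = peaks.loc[
                (peaks["chrom"] == row.chrom)
                & (peaks["start"] <= row.position)
                & (peaks["end"] > row.position), "enhancer_id"]
            if len(cluster):
                cluster_class[cluster.iloc[0]] = gc[row.gene]
        se_len = [lengths[c] for c, k in cluster_class.items() if k == "SE"]
        te_len = [lengths[c] for c, k in cluster_class.items() if k == "TE"]
        assert min(se_len) > np.median(te_len)

    def test_no_gain_when_stim_gain_is_one(self):
        cfg = small_config(seed=5, n_cells_atac=400)
        cfg.coaccess_factors["stim_gain"] = 1.0
        mats, peaks, truth = simulate_atac(cfg)
        idx = {n: i for i, n in enumerate(peaks["name"])}
        diffs = []
        for row in truth.planted_pairs.itertuples():
            cors = {}
            for cond, m in mats.items():
                X = np.asarray(m.X.todense(), dtype=float)
                cors[cond] = np.corrcoef(X[:, idx[row.peak_i]],
                                         X[:, idx[row.peak_j]])[0, 1]
            diffs.append(cors["stim"] - cors["unstim"])
        assert abs(np.mean(diffs)) < 0.1

    def test_correlation_grows_toward_one_with_loading(self):
        def pair_corr(loading):
            cfg = small_config(seed=6, n_cells_atac=500)
            cfg.coaccess_factors["loading_scale"] = loading
            mats, peaks, truth = simulate_atac(cfg)
            X = np.asarray(mats["unstim"].X.todense(), dtype=float)
            idx = {n: i for i, n in enumerate(peaks["name"])}
            row = truth.planted_pairs.iloc[0]
            return np.corrcoef(np.log1p(X[:, idx[row.peak_i]]),
                               np.log1p(X[:, idx[row.peak_j]]))[0, 1]

        weak, strong = pair_corr(0.3), pair_corr(1.2)
        assert strong > weak and strong > 0.6

    def test_planted_gain_visible_to_brute_force_correlation(
            self, sim_atac_seed7):
        """Every planted pair's stim-vs-unstim correlation difference is
        positive, so the truth listing matches the brute-force count."""
        mats, peaks, truth = sim_atac_seed7
        idx = {n: i for i, n in enumerate(peaks["name"])}
        # variance-stabilized counts for the brute-force correlation
        X = {c: np.log1p(np.asarray(m.X.todense(), dtype=float))
             for c, m in mats.items()}
        n_pos = 0
        for row in truth.planted_pairs.itertuples():
            i, j = idx[row.peak_i], idx[row.peak_j]
            d = (np.corrcoef(X["stim"][:, i], X["stim"][:, j])[0, 1]
                 - np.corrcoef(X["unstim"][:, i], X["unstim"][:, j])[0, 1])
            n_pos += d > 0
        assert n_pos == len(truth.planted_pairs)


class TestFociGenerator:
    def test_flat_when_k_zero(self):
        cfg = small_config(seed=8, n_cells_per_dose_foci=2000)
        cfg.foci_hill.update({"k": 0.0, "a": 2.0})
        table = simulate_foci(cfg)
        med = table.groupby("dose")["foci"].median()
        assert med.nunique() == 1

    def test_saturation_mean_approaches_a_plus_k(self):
        cfg = small_config(seed=9, n_cells_per_dose_foci=2000)
        table = simulate_foci(cfg)
        top = table[table["dose"] == max(cfg.foci_doses)]["foci"].mean()
        a, k = cfg.foci_hill["a"], cfg.foci_hill["k"]
        assert abs(top - (a + k)) < 3 * np.sqrt((a + k) / 2000)

    def test_refitting_recovers_generating_cooperativity(self, foci_seed3):
        from sehet.foci import fit_hill, median_response
        med = median_response(foci_seed3, time=20)
        brute = {
            d: float(np.sort(g["foci"].to_numpy())[
                [len(g) // 2 - 1, len(g) // 2]].mean()) if len(g) % 2 == 0
            else float(np.sort(g["foci"].to_numpy())[len(g) // 2])
            for d, g in foci_seed3.groupby("dose")
        }
        assert med == brute  # sort-and-pick median oracle
        fit = fit_hill(med, with_basal=True)
        assert abs(fit.N - 4.0) / 4.0 <= 0.15
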