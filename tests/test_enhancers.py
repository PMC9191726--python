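"""Stitching, SE/TE classification, merging, gene assignment, categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sehet.enhancers import (assign_genes, classify_se_te,
                             fold_change_and_categorize, merge_conditions,
                             stitch)


def peak_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "signal",
                                       "name"])


def random_peaks(seed, n=1000, span=2_000_000):
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, span, n))
    return pd.DataFrame({
        "chrom": rng.choice(["chr1", "chr2"], n),
        "start": starts,
        "end": starts + rng.integers(100, 900, n),
        "signal": rng.lognormal(0, 1, n),
        "name": [f"p{i}" for i in range(n)],
    })


class TestStitch:
    def test_gap_rule_arithmetic(self):
        peaks = peak_frame([
            ("chr1", 0, 500, 1.0, "a"),
            ("chr1", 3000, 3500, 2.0, "b"),     # gap 2500 -> merges
            ("chr1", 9000, 9500, 4.0, "c"),     # gap 5500 -> separate
        ])
        out = stitch(peaks, max_gap=5000)
        assert len(out) == 2
        assert out.iloc[0]["members"] == ["a", "b"]
        assert out.iloc[0]["total_signal"] == 3.0
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (0, 3500)

    def test_single_peak_is_itself(self):
        peaks = peak_frame([("chr1", 10, 400, 2.5, "only")])
        out = stitch(peaks)
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (10, 400)

    def test_malformed_interval_reports_line(self):
        peaks = peak_frame([("chr1", 500, 100, 1.0, "bad")])
        with pytest.raises(ValueError, match="line"):
            stitch(peaks)

    def test_matches_interval_graph_oracle(self):
        peaks = random_peaks(seed=6)
        out = stitch(peaks, max_gap=5000)
        # brute force: connected components of the <=5kb gap graph
        comps = []
        for chrom in ("chr1", "chr2"):
            sub = peaks[peaks["chrom"] == chrom].reset_index(drop=True)
            n = len(sub)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            arr = sub[["start", "end"]].to_numpy()
            for i in range(n):
                for j in range(i + 1, n):
                    gap = max(arr[i, 0], arr[j, 0]) - min(arr[i, 1], arr[j, 1])
                    if gap <= 5000:
                        parent[find(i)] = find(j)
            groups = {}
            for i in range(n):
                groups.setdefault(find(i), []).append(sub.loc[i, "name"])
            comps.extend(tuple(sorted(g)) for g in groups.values())
        got = {tuple(sorted(m)) for m in out["members"]}
        assert got == set(comps)

    def test_covers_exactly_union_of_input_bases(self):
        peaks = random_peaks(seed=13, n=300)
        out = stitch(peaks, max_gap=5000)
        for chrom in ("chr1", "chr2"):
            covered = set()
            for r in out[out["chrom"] == chrom].itertuples():
                covered.update(range(r.start, r.end))
            expected = set()
            for r in peaks[peaks["chrom"] == chrom].itertuples():
                expected.update(range(r.start, r.end))
            assert expected <= covered
            # no base outside the stitched envelope of the inputs
            assert min(covered) == min(expected)
            assert max(covered) == max(expected)


class TestClassifySETE:
    def region_frame(self, signals):
        return pd.DataFrame({
            "chrom": "chr1",
            "start": np.arange(len(signals)) * 10_000,
            "end": np.arange(len(signals)) * 10_000 + 500,
            "members": [[f"p{i}"] for i in range(len(signals))],
            "total_signal": signals,
        })

    def test_single_dominant_region_is_the_only_se(self):
        out = classify_se_te(self.region_frame([1.0, 1.0, 1.0, 100.0]))
        assert set(out.loc[out["enh_class"] == "SE", "total_signal"]) == {100.0}

    def test_linear_ramp_boundary_only(self):
        out = classify_se_te(self.region_frame(np.linspace(1, 10, 50)))
        assert (out["enh_class"] == "SE").sum() <= 1

    def test_all_equal_signals_all_te_with_warning(self):
        with pytest.warns(UserWarning, match="all region signals equal"):
            out = classify_se_te(self.region_frame([2.0] * 5))
        assert (out["enh_class"] == "TE").all()

    def test_needs_three_regions(self):
        with pytest.raises(ValueError):
            classify_se_te(self.region_frame([1.0, 2.0]))

    def test_invariant_to_uniform_signal_scaling(self):
        rng = np.random.default_rng(3)
        sig = rng.lognormal(0, 1, 200)
        a = classify_se_te(self.region_frame(sig))
        b = classify_se_te(self.region_frame(sig * 37.5))
        assert (a["enh_class"] == b["enh_class"]).all()

    def test_matches_brute_force_cutoff_scan(self):
        rng = np.random.default_rng(8)
        sig = rng.lognormal(0, 1, 500)
        out = classify_se_te(self.region_frame(sig))
        s = np.sort(sig)
        x = np.arange(500) / 499
        y = (s - s.min()) / (s.max() - s.min())
        d = y - x
        cut = max(j for j in range(500) if d[j] == d.max())
        expected_se = set(np.round(s[cut:], 12))
        got_se = set(np.round(
            out.loc[out["enh_class"] == "SE", "total_signal"], 12))
        assert got_se == expected_se


class TestMergeConditions:
    def classified(self, rows, cond):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "enh_class"])
        return df

    def test_identical_sets_unchanged(self):
        rows = [("chr1", 0, 100, "SE"), ("chr1", 500, 800, "TE")]
        merged = merge_conditions({
            "stim": self.classified(rows, "stim"),
            "unstim": self.classified(rows, "unstim")})
        assert len(merged) == 2
        assert sorted(merged["start"]) == [0, 500]

    def test_disjoint_sets_concatenate(self):
        merged = merge_conditions({
            "stim": self.classified([("chr1", 0, 100, "TE")], "stim"),
            "unstim": self.classified([("chr1", 5000, 5100, "TE")], "unstim")})
        assert len(merged) == 2

    def test_se_and_te_merged_separately(self):
        merged = merge_conditions({
            "stim": self.classified([("chr1", 0, 100, "SE")], "stim"),
            "unstim": self.classified([("chr1", 50, 150, "TE")], "unstim")})
        assert len(merged) == 2  # overlap but different classes

    def test_matches_interval_union_oracle(self):
        rng = np.random.default_rng(17)
        def rand_set():
            starts = np.sort(rng.integers(0, 100_000, 60))
            return pd.DataFrame({
                "chrom": "chr1", "start": starts,
                "end": starts + rng.integers(50, 3000, 60),
                "enh_class": "TE"})
        sets = {"stim": rand_set(), "unstim": rand_set()}
        merged = merge_conditions(sets)
        # oracle: base-level union -> maximal runs (bookended intervals merge)
        allr = pd.concat(sets.values())
        covered = np.zeros(200_000, dtype=bool)
        for r in allr.itertuples():
            covered[r.start:r.end] = True
        edges = np.flatnonzero(np.diff(covered.astype(int)))
        runs = [(int(edges[i]) + 1, int(edges[i + 1]) + 1)
                for i in range(0, len(edges), 2)]
        got = sorted(zip(merged["start"], merged["end"]))
        assert got == sorted(runs)


class TestAssignGenes:
    def tss(self, rows):
        return pd.DataFrame(rows, columns=["gene", "chrom", "position",
                                           "strand"])

    def regions(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "enh_class", "total_signal"])
        return df

    def test_se_beats_te_for_shared_gene(self):
        regions = self.regions([
            ("chr1", 0, 1000, "SE", 5.0),
            ("chr1", 2000, 3000, "TE", 50.0),
        ])
        tss = self.tss([("geneA", "chr1", 1500, "+")])
        out = assign_genes(regions, tss)
        assert out.loc[out["enh_class"] == "SE", "assigned_gene"].iloc[0] == \
            "geneA"
        assert out.loc[out["enh_class"] == "TE", "assigned_gene"].isna().all()

    def test_equidistant_tss_lower_coordinate_wins(self):
        regions = self.regions([("chr1", 900, 1100, "TE", 1.0)])
        tss = self.tss([("hi", "chr1", 1500, "+"), ("lo", "chr1", 500, "+")])
        out = assign_genes(regions, tss)
        assert out["assigned_gene"].iloc[0] == "lo"

    def test_unknown_chromosome_left_unassigned_with_warning(self):
        regions = self.regions([("chrZ", 0, 100, "TE", 1.0)])
        tss = self.tss([("geneA", "chr1", 50, "+")])
        with pytest.warns(UserWarning, match="chrZ"):
            out = assign_genes(regions, tss)
        assert out["assigned_gene"].isna().all()

    def test_matches_nearest_tss_oracle(self):
        rng = np.random.default_rng(21)
        starts = np.sort(rng.integers(0, 500_000, 40))
        regions = self.regions([
            ("chr1", int(s), int(s) + 200, "TE", float(sig))
            for s, sig in zip(starts, rng.random(40))])
        tss = self.tss([(f"g{i}", "chr1", int(p), "+")
                        for i, p in enumerate(
                            np.sort(rng.integers(0, 500_000, 15)))])
        out = assign_genes(regions, tss)
        # oracle: nearest TSS per region, then per-gene best region by signal
        nearest = {}
        for r in regions.itertuples():
            mid = (r.start + r.end) / 2
            dists = (tss["position"] - mid).abs()
            nearest[r.Index] = tss.loc[dists.idxmin(), "gene"]
        best = {}
        for idx, gene in nearest.items():
            sig = regions.loc[idx, "total_signal"]
            if gene not in best or sig > regions.loc[best[gene],
                                                     "total_signal"]:
                best[gene] = idx
        for idx in regions.index:
            want = nearest[idx] if best.get(nearest[idx]) == idx else None
            got = out.loc[idx, "assigned_gene"]
            assert (got if pd.notna(got) else None) == want


class TestFoldChangeCategories:
    def regions(self, n, enh_class="SE"):
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500, "enh_class": enh_class})

    def test_exact_quartile_counts_without_ties(self):
        n = 1000
        rng = np.random.default_rng(9)
        stim = 2.0 ** rng.permutation(n).astype(float)
        out = fold_change_and_categorize(self.regions(n), stim, np.ones(n))
        counts = out["category"].value_counts()
        assert counts["gained"] == 250
        assert counts["lost"] == 250
        assert counts["unchanged"] == 500

    def test_all_equal_fold_changes_all_unchanged(self):
        n = 40
        out = fold_change_and_categorize(
            self.regions(n), np.full(n, 3.0), np.full(n, 1.5))
        assert (out["category"] == "unchanged").all()

    def test_classes_categorized_separately(self):
        n = 40
        regions = pd.concat([self.regions(20, "SE"), self.regions(20, "TE")],
                            ignore_index=True)
        rng = np.random.default_rng(10)
        stim = rng.lognormal(0, 1, n)
        out = fold_change_and_categorize(regions, stim, np.ones(n))
        for cls in ("SE", "TE"):
            sub = out[out["enh_class"] == cls]
            lo = sub["log2_fc"].quantile(0.25)
            hi = sub["log2_fc"].quantile(0.75)
            assert (sub.loc[sub["log2_fc"] > hi, "category"] == "gained").all()
            assert (sub.loc[sub["log2_fc"] < lo, "category"] == "lost").all()

    @given(st.integers(min_value=5, max_value=60), st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_categories_partition_every_region(self, n, seed):
        rng = np.random.default_rng(seed)
        out = fold_change_and_categorize(
            self.regions(n), rng.lognormal(0, 1, n), rng.lognormal(0, 1, n))
        assert out["category"].isin(["gained", "lost", "unchanged"]).all()
        assert len(out) == n
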