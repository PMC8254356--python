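"""DEG classification, binding-expression association and target calls."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from hifmap import annotate
from hifmap.core import GeneAnnotation, GeneExpressionRecord, GenomicInterval, Peak
from hifmap.expression import (
    DEGCall,
    GeneBindingSummary,
    UNBOUND,
    association_2x2,
    classify_deg,
    classify_targets,
    deg_counts,
    distance_stratified_association,
    magnitude_test,
    overlap_counts,
    summarize_gene_binding,
    target_counts,
)
from tests.conftest import random_genes, random_peaks


def make_summary(gene_id, min_dist=math.inf, dists=()):
    dists = list(dists) or ([min_dist] if not math.isinf(min_dist) else [])
    if not dists:
        return GeneBindingSummary(gene_id, **UNBOUND)
    return GeneBindingSummary(
        gene_id=gene_id,
        is_nearest_neighbor_of_peak=True,
        min_abs_distance=min(dists),
        bound_within_3kb=any(d <= 3000 for d in dists),
        bound_3_10kb=any(3000 < d <= 10000 for d in dists),
        bound_10_100kb=any(10000 < d <= 100000 for d in dists),
        bound_within_100kb=min(dists) <= 100000,
        n_peaks=len(dists),
    )


class TestGeneBindingSummary:
    def test_multi_stratum_gene(self, toy_genome):
        gene = GeneAnnotation("g1", "chr1", "+", 100_000, 150_000)
        other = GeneAnnotation("g2", "chr1", "+", 900_000, 950_000)
        peaks = [
            Peak(GenomicInterval("chr1", 101_900, 102_100)),  # 2 kb
            Peak(GenomicInterval("chr1", 149_900, 150_100)),  # 50 kb
        ]
        anns = annotate.assign_nearest_tss(peaks, [gene, other])
        (s1, s2) = summarize_gene_binding(anns, [gene, other])
        assert s1.bound_within_3kb and s1.bound_10_100kb and not s1.bound_3_10kb
        assert s1.min_abs_distance == 2000
        assert not s2.is_nearest_neighbor_of_peak
        assert math.isinf(s2.min_abs_distance)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_gene_brute_force(self, seed, toy_genome):
        rng = np.random.default_rng(seed)
        genes = random_genes(rng, toy_genome, 100)
        peaks = random_peaks(rng, toy_genome, 300)
        anns = annotate.assign_nearest_tss(peaks, genes)
        summaries = {s.gene_id: s for s in summarize_gene_binding(anns, genes)}
        for g in genes:
            dists = [
                a.abs_distance for a in anns if a.nearest_gene == g.gene_id
            ]
            s = summaries[g.gene_id]
            if not dists:
                assert not s.is_nearest_neighbor_of_peak
                continue
            assert s.min_abs_distance == min(dists)
            assert s.bound_within_3kb == any(d <= 3000 for d in dists)
            assert s.bound_3_10kb == any(3000 < d <= 10000 for d in dists)
            assert s.bound_10_100kb == any(10000 < d <= 100000 for d in dists)
            assert s.n_peaks == len(dists)


class TestClassifyDeg:
    @pytest.mark.parametrize(
        "lfc,p,status",
        [
            (0.7, 0.01, "up"),
            (-0.61, 0.049, "down"),
            (2.0, 0.2, "non"),
            (0.6, 0.01, "non"),   # threshold is strict
            (-0.6, 0.01, "non"),
            (0.61, 0.05, "non"),  # alpha is strict
        ],
    )
    def test_thresholds(self, lfc, p, status):
        (call,) = classify_deg([GeneExpressionRecord("g", lfc, p)])
        assert call.status == status

    def test_counts_partition_records(self):
        rng = np.random.default_rng(0)
        records = [
            GeneExpressionRecord(f"g{i}", float(rng.normal(0, 1)), float(rng.uniform()))
            for i in range(500)
        ]
        counts = deg_counts(classify_deg(records))
        assert counts["up"] + counts["down"] + counts["non"] == 500

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(1)
        records = [
            GeneExpressionRecord(f"g{i}", float(rng.normal(0, 1)), float(rng.uniform()))
            for i in range(500)
        ]
        n_deg = []
        for thr in (0.2, 0.6, 1.0, 1.5):
            c = deg_counts(classify_deg(records, lfc_threshold=thr))
            n_deg.append(c["up"] + c["down"])
        assert n_deg == sorted(n_deg, reverse=True)

    def test_nonpositive_threshold_errors(self):
        with pytest.raises(ValueError):
            classify_deg([], lfc_threshold=0)


class TestAssociation2x2:
    def test_reported_proportions(self):
        res = association_2x2((212, 528), (713, 16777))
        assert round(res.prop_a) == 40

    def test_equal_proportions_give_null(self):
        res = association_2x2((10, 100), (20, 200))
        assert res.chi2_stat == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_degenerate_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            association_2x2((0, 10), (0, 20))
        with pytest.raises(ValueError, match="margin"):
            association_2x2((10, 10), (20, 20))
        with pytest.raises(ValueError):
            association_2x2((5, 0), (1, 10))

    def test_statistic_matches_hand_summation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a, b = int(rng.integers(5, 50)), int(rng.integers(5, 50))
            ta, tb = a + int(rng.integers(5, 80)), b + int(rng.integers(5, 80))
            res = association_2x2((a, ta), (b, tb))
            table = np.array([[a, ta - a], [b, tb - b]], dtype=float)
            n = table.sum()
            rows, cols = table.sum(1), table.sum(0)
            exp = np.outer(rows, cols) / n
            want = ((table - exp) ** 2 / exp).sum()
            assert res.chi2_stat == pytest.approx(want, rel=1e-9)

    def test_pvalue_close_to_exact_test(self):
        """Chi-square p stays within the usual discrepancy envelope of
        Fisher's conditional exact p on moderately filled tables."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b = int(rng.integers(10, 40)), int(rng.integers(10, 40))
            ta, tb = a + int(rng.integers(20, 80)), b + int(rng.integers(20, 80))
            res = association_2x2((a, ta), (b, tb))
            _, p_exact = stats.fisher_exact(
                [[a, ta - a], [b, tb - b]], alternative="two-sided"
            )
            # agreement matters most where decisions are made; near p=1
            # the discrete exact p can sit well above the chi-square p
            if p_exact < 0.2:
                assert abs(res.pvalue - p_exact) < 0.05
            else:
                assert abs(res.pvalue - p_exact) < 0.25


class TestDistanceStratifiedAssociation:
    def test_reported_within_3kb_proportions(self):
        """61/526 DEGs vs 940/16777 non-DEGs bound within 3 kb."""
        degs, summaries = [], []
        for i in range(526):
            degs.append(DEGCall(f"d{i}", "up" if i % 2 else "down", 1.0, 0.01))
            summaries.append(make_summary(f"d{i}", 2000 if i < 61 else math.inf))
        for i in range(16777):
            degs.append(DEGCall(f"n{i}", "non", 0.0, 0.5))
            summaries.append(make_summary(f"n{i}", 2000 if i < 940 else math.inf))
        rows = distance_stratified_association(degs, summaries)
        row = next(
            r for r in rows if r.comparison == "deg_vs_non" and r.stratum == "0-3kb"
        )
        assert (row.a_bound, row.a_total) == (61, 526)
        assert (row.b_bound, row.b_total) == (940, 16777)
        assert round(row.prop_a, 1) == 11.6
        assert round(row.prop_b, 1) == 5.6
        assert row.direction == "enriched"
        assert row.pvalue < 0.001

    def test_strata_are_cumulative_exclusive_on_min_distance(self):
        degs = [DEGCall("a", "up", 1, 0.01), DEGCall("b", "non", 0, 0.9)]
        summaries = [make_summary("a", dists=[2500, 8000]), make_summary("b", 50_000)]
        rows = distance_stratified_association(degs, summaries)
        by = {(r.comparison, r.stratum): r for r in rows}
        # gene a has min distance 2.5 kb -> only the 0-3kb stratum
        assert by[("up_vs_non", "0-3kb")].a_bound == 1
        assert by[("up_vs_non", "3-10kb")].a_bound == 0

    def test_all_non_deg_yields_empty_result(self):
        degs = [DEGCall("a", "non", 0, 0.9), DEGCall("b", "non", 0, 0.8)]
        summaries = [make_summary("a", 2000), make_summary("b")]
        assert distance_stratified_association(degs, summaries) == []

    def test_gene_id_mismatch_rate_guard(self):
        degs = [DEGCall(f"x{i}", "up", 1, 0.01) for i in range(10)]
        summaries = [make_summary("y0", 2000)]
        with pytest.raises(ValueError, match="identifiers"):
            distance_stratified_association(degs, summaries)


class TestMagnitudeTest:
    def test_identical_lists_are_null(self):
        _, p = magnitude_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.99

    def test_hand_enumerated_extreme(self):
        u, p = magnitude_test([3, 4, 5], [0, 1, 2])
        assert u == 9
        assert p == pytest.approx(0.1)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            magnitude_test([], [1.0])

    def test_uses_absolute_values(self):
        u1, p1 = magnitude_test([-3, -4, -5], [0, 1, 2])
        u2, p2 = magnitude_test([3, 4, 5], [0, 1, 2])
        assert (u1, p1) == (u2, p2)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_p_matches_permutation_enumeration(self, seed):
        """Small-sample exact p equals full enumeration over all
        assignments of the pooled values to the two groups."""
        rng = np.random.default_rng(seed)
        for _ in range(6):
            n, m = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            pool = rng.permutation(np.arange(n + m, dtype=float) + rng.uniform(0, 0.4))
            x, y = pool[:n], pool[n:]
            u_obs, p_obs = magnitude_test(x, y)
            # enumerate U over all choices of which pooled values form x
            values = np.abs(np.concatenate([x, y]))
            us = []
            for idx in itertools.combinations(range(n + m), n):
                xs = values[list(idx)]
                ys = np.delete(values, list(idx))
                us.append(sum(1 for a in xs for b in ys if a > b))
            us = np.array(us)
            lo, hi = min(u_obs, n * m - u_obs), max(u_obs, n * m - u_obs)
            p_enum = min(1.0, (np.sum(us <= lo) + np.sum(us >= hi)) / len(us))
            assert p_obs == pytest.approx(p_enum, rel=1e-9)


class TestTargets:
    def test_target_window_rule(self):
        degs = [
            DEGCall("up40k", "up", 1.2, 0.01),
            DEGCall("down150k", "down", -1.2, 0.01),
            DEGCall("non5k", "non", 0.1, 0.8),
        ]
        summaries = [
            make_summary("up40k", 40_000),
            make_summary("down150k", 150_000),
            make_summary("non5k", 5_000),
        ]
        calls = {c.gene_id: c for c in classify_targets(degs, summaries)}
        assert calls["up40k"].hif1a_dependent and calls["up40k"].direction == "activated"
        assert not calls["down150k"].hif1a_dependent
        assert not calls["non5k"].hif1a_dependent

    def test_known_hypoxia_split_case_insensitive(self):
        degs = [DEGCall("BNIP3L", "up", 2.0, 0.001), DEGCall("novelg", "down", -1.0, 0.01)]
        summaries = [make_summary("BNIP3L", 500), make_summary("novelg", 500)]
        calls = classify_targets(degs, summaries, known_hypoxia=["bnip3l"])
        counts = target_counts(calls)
        assert counts == {
            "activated": 1, "repressed": 1, "total": 2, "known_hypoxia": 1, "novel": 1,
        }

    def test_printed_split_sums_to_202(self):
        """96 activated + 106 repressed targets -> 202 dependent genes."""
        degs, summaries = [], []
        for i in range(96):
            degs.append(DEGCall(f"u{i}", "up", 1.0, 0.01))
            summaries.append(make_summary(f"u{i}", 50_000))
        for i in range(106):
            degs.append(DEGCall(f"d{i}", "down", -1.0, 0.01))
            summaries.append(make_summary(f"d{i}", 50_000))
        counts = target_counts(classify_targets(degs, summaries))
        assert counts["activated"] == 96
        assert counts["repressed"] == 106
        assert counts["total"] == 202


class TestOverlapCounts:
    def test_no_peaks_means_no_bound_genes(self):
        degs = [DEGCall("a", "up", 1, 0.01), DEGCall("b", "down", -1, 0.01)]
        summaries = [make_summary("a"), make_summary("b")]
        counts = overlap_counts(degs, summaries)
        assert counts["up_bound"] == 0 and counts["down_bound"] == 0
        assert counts["deg_unbound"] == 2

    def test_consistent_with_target_counts(self):
        rng = np.random.default_rng(8)
        degs, summaries = [], []
        for i in range(300):
            status = ("up", "down", "non")[int(rng.integers(0, 3))]
            lfc = {"up": 1.0, "down": -1.0, "non": 0.0}[status]
            degs.append(DEGCall(f"g{i}", status, lfc, 0.01 if status != "non" else 0.9))
            d = float(rng.choice([2000, 50_000, 150_000, math.inf]))
            summaries.append(make_summary(f"g{i}", d))
        counts = overlap_counts(degs, summaries)
        tc = target_counts(classify_targets(degs, summaries))
        assert counts["up_bound"] + counts["down_bound"] == tc["total"]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_intersection_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        degs, summaries = [], []
        for i in range(120):
            status = ("up", "down", "non")[int(rng.integers(0, 3))]
            degs.append(DEGCall(f"g{i}", status, 0.0, 0.5))
            d = float(rng.choice([500, 90_000, 140_000, math.inf]))
            summaries.append(make_summary(f"g{i}", d))
        counts = overlap_counts(degs, summaries)
        bound = {s.gene_id for s in summaries if s.min_abs_distance <= 100_000}
        up = {d.gene_id for d in degs if d.status == "up"}
        down = {d.gene_id for d in degs if d.status == "down"}
        non = {d.gene_id for d in degs if d.status == "non"}
        assert counts["up_bound"] == len(up & bound)
        assert counts["down_bound"] == len(down & bound)
        assert counts["bound_non_deg"] == len(non & bound)
        assert counts["deg_unbound"] == len((up | down) - bound)
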