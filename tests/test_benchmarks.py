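"""Evaluation statistics: Dice overlap, greedy matching, resampling and
Fisher/Westfall-Young significance, checked against independent oracles
(hand arithmetic, step-by-step simulation, exhaustive enumeration)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bicbench as bb
from bicbench.benchmarks import OverlapMatrix


# ---------------------------------------------------------------------------
# Dice / Sørensen
# ---------------------------------------------------------------------------


class TestDiceOverlap:
    def test_identity_disjoint_and_worked_value(self):
        a = {f"x{i}" for i in range(7)}
        assert bb.dice_overlap(a, a) == 1.0
        assert bb.dice_overlap(a, {"y1", "y2"}) == 0.0
        # a 13-sample type fully contained in a 20-sample bicluster
        t = {f"s{i}" for i in range(13)}
        b = {f"s{i}" for i in range(20)}
        assert bb.dice_overlap(t, b) == pytest.approx(26 / 33, abs=0)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            bb.dice_overlap(set(), set())

    @settings(deadline=None, max_examples=200)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetry_range_and_equality(self, a, b):
        if not a and not b:
            return
        s = bb.dice_overlap(a, b)
        assert s == bb.dice_overlap(b, a)
        assert 0.0 <= s <= 1.0
        assert (s == 1.0) == (a == b)


# ---------------------------------------------------------------------------
# Overlap matrix + greedy matching
# ---------------------------------------------------------------------------


def greedy_match_oracle(scores: np.ndarray):
    """Independent step-by-step simulation of the stated extraction rule."""
    d = scores.astype(float).copy()
    v = []
    while d.shape[0] and d.shape[1]:
        best = (-1.0, None)
        for i in range(d.shape[0]):
            for j in range(d.shape[1]):
                if d[i, j] > best[0]:
                    best = (d[i, j], (i, j))
        (i, j) = best[1]
        v.append(best[0])
        d = np.delete(np.delete(d, i, axis=0), j, axis=1)
    return v


class TestGreedyMatch:
    def test_identity_like(self):
        d = OverlapMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]), ["A", "B"])
        r = bb.greedy_match(d)
        np.testing.assert_array_equal(r.v, [1.0, 1.0])

    def test_hand_simulated_trace(self):
        d = OverlapMatrix(np.array([[0.9, 0.2], [0.8, 0.7]]), ["A", "B"])
        r = bb.greedy_match(d)
        np.testing.assert_array_equal(r.v, [0.9, 0.7])
        assert r.pairing == [(0, "A"), (1, "B")]

    def test_ties_break_lowest_row_then_column(self):
        d = OverlapMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]), ["A", "B"])
        r = bb.greedy_match(d)
        assert r.pairing == [(0, "A"), (1, "B")]

    def test_matches_simulation_oracle_on_random_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            scores = rng.random((6, 4))
            d = OverlapMatrix(scores, list("ABCD"))
            got = bb.greedy_match(d).v
            np.testing.assert_array_equal(got, greedy_match_oracle(scores))

    def test_v_is_non_increasing(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            shape = (int(rng.integers(1, 8)), int(rng.integers(1, 6)))
            d = OverlapMatrix(rng.random(shape),
                              [f"T{j}" for j in range(shape[1])])
            v = bb.greedy_match(d).v
            assert all(v[i] >= v[i + 1] for i in range(len(v) - 1))


class TestSampleDif:
    def test_oracle_on_planted_data_is_one(self, desk_dataset):
        _, _, labels, truth = desk_dataset
        bs = bb.oracle_bicluster_set(truth, labels)
        assert bb.sample_dif(bs, labels) == 1.0

    def test_single_all_sample_bicluster_arithmetic(self):
        n = 4
        assignment = {f"s{t}{i}": f"T{t}" for t in range(5) for i in range(n)}
        labels = bb.SampleTypeLabels(assignment)
        bs = bb.BiclusterSet("one", biclusters=[
            bb.Bicluster({"g1"}, set(assignment))])
        # v = [2n / (5n + n)] = [1/3]
        assert bb.sample_dif(bs, labels) == pytest.approx(1 / 3)

    def test_two_equal_types_in_one_bicluster(self):
        assignment = {f"a{i}": "A" for i in range(6)}
        assignment.update({f"b{i}": "B" for i in range(6)})
        labels = bb.SampleTypeLabels(assignment)
        bs = bb.BiclusterSet("x", biclusters=[
            bb.Bicluster({"g"}, set(assignment))])
        d = bb.overlap_matrix(bs, labels)
        np.testing.assert_allclose(d.scores, [[2 / 3, 2 / 3]])

    def test_empty_set_scores_zero(self):
        labels = bb.SampleTypeLabels({"s1": "A"})
        assert bb.sample_dif(bb.BiclusterSet("none"), labels) == 0.0

    def test_unknown_sample_id_is_named(self):
        labels = bb.SampleTypeLabels({"s1": "A"})
        bs = bb.BiclusterSet("x", biclusters=[bb.Bicluster({"g"}, {"zz"})])
        with pytest.raises(ValueError, match="zz"):
            bb.overlap_matrix(bs, labels)

    def test_random_assignment_scores_well_below_one(self):
        rng = np.random.default_rng(99)
        samples = [f"s{i}" for i in range(100)]
        labels = bb.SampleTypeLabels(
            {s: f"T{i % 5}" for i, s in enumerate(samples)})
        bics = [
            bb.Bicluster({"g"}, set(rng.choice(samples, 20, replace=False)))
            for _ in range(10)
        ]
        sd = bb.sample_dif(bb.BiclusterSet("rand", biclusters=bics), labels)
        assert sd < 0.6  # random 20-sample picks cannot mirror the types


# ---------------------------------------------------------------------------
# Resampling overlap p-value
# ---------------------------------------------------------------------------


class TestResamplingPvalue:
    def test_converges_to_exhaustive_enumeration(self):
        universe = ["g1", "g2", "g3", "g4"]
        bic = {"g1", "g2"}
        spec = {"g1", "g2"}
        obs = bb.dice_overlap(bic, spec)
        hits = sum(
            bb.dice_overlap(set(c), spec) >= obs
            for c in itertools.combinations(universe, 2)
        )
        exact = hits / math.comb(4, 2)  # 1/6
        p = bb.resampling_overlap_pvalue(bic, spec, universe,
                                         n_resamples=20000, seed=3)
        assert p == pytest.approx(exact, abs=0.01)

    def test_special_equals_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        p = bb.resampling_overlap_pvalue({"g0", "g1"}, set(uni), uni,
                                         n_resamples=500, seed=0)
        assert p == 1.0

    def test_p_in_valid_range_and_monotone_in_overlap(self):
        uni = [f"g{i}" for i in range(40)]
        spec = set(uni[:10])
        outside = sorted(set(uni) - spec)
        b = 400
        ps = []
        for n_hit in (0, 2, 4, 6, 8, 10):
            bic = set(sorted(spec)[:n_hit]) | set(outside[: 10 - n_hit])
            assert len(bic) == 10
            ps.append(bb.resampling_overlap_pvalue(bic, spec, uni,
                                                   n_resamples=b, seed=7))
        assert all(1 / (b + 1) <= p <= 1.0 for p in ps)
        assert all(ps[i] >= ps[i + 1] for i in range(len(ps) - 1))

    def test_strict_variant_is_less_conservative(self):
        uni = [f"g{i}" for i in range(30)]
        spec = set(uni[:10])
        bic = set(uni[5:15])
        loose = bb.resampling_overlap_pvalue(bic, spec, uni, 500, seed=1)
        strict = bb.resampling_overlap_pvalue(bic, spec, uni, 500, seed=1,
                                              strict=True)
        assert strict <= loose

    def test_bicluster_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            bb.resampling_overlap_pvalue({"zz"}, {"g1"}, ["g1", "g2"], 10, 0)


class TestTigerSig:
    def test_oracle_fraction_is_one(self, desk_dataset, desk_annotations):
        _, matrix, labels, truth = desk_dataset
        tiger, _ = desk_annotations
        bs = bb.oracle_bicluster_set(truth, labels)
        cfg = bb.BenchmarkConfig(alpha=0.05, n_resamples=1000, seed=5)
        res = bb.tiger_sig(bs, tiger, matrix.gene_ids, cfg)
        assert res.significant_fraction == 1.0
        assert (res.per_bicluster_p < 0.05).all()

    def test_empty_set_scores_zero(self, desk_dataset, desk_annotations):
        _, matrix, _, _ = desk_dataset
        tiger, _ = desk_annotations
        cfg = bb.BenchmarkConfig(seed=1, n_resamples=50)
        res = bb.tiger_sig(bb.BiclusterSet("none"), tiger, matrix.gene_ids, cfg)
        assert res.significant_fraction == 0.0

    def test_empty_union_is_error(self, desk_dataset):
        _, matrix, labels, truth = desk_dataset
        bs = bb.oracle_bicluster_set(truth, labels)
        cfg = bb.BenchmarkConfig(seed=1, n_resamples=50)
        with pytest.raises(ValueError):
            bb.tiger_sig(bs, bb.GeneSetCollection([]), matrix.gene_ids, cfg)


# ---------------------------------------------------------------------------
# Fisher's exact enrichment
# ---------------------------------------------------------------------------


def fisher_oracle(n_universe, n_cat, n_draw, x_obs):
    """Exhaustive enumeration of P(|draw ∩ category| >= x_obs)."""
    uni = list(range(n_universe))
    cat = set(uni[:n_cat])
    hits = total = 0
    for comb in itertools.combinations(uni, n_draw):
        total += 1
        if len(cat & set(comb)) >= x_obs:
            hits += 1
    return hits / total


class TestFisherEnrichment:
    def test_worked_closed_form(self):
        uni = [f"g{i}" for i in range(10)]
        cat = set(uni[:5])
        p = bb.fisher_enrichment_pvalue(cat, cat, uni)
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_zero_intersection_gives_one(self):
        uni = [f"g{i}" for i in range(8)]
        p = bb.fisher_enrichment_pvalue(set(uni[:3]), set(uni[5:]), uni)
        assert p == 1.0

    @pytest.mark.parametrize("n,k,m", [(8, 3, 4), (10, 5, 5), (12, 6, 3)])
    def test_matches_exhaustive_enumeration(self, n, k, m):
        uni = [f"g{i}" for i in range(n)]
        cat = set(uni[:k])
        for x in range(0, min(k, m) + 1):
            bic = set(uni[:x]) | set(uni[k:k + m - x])
            assert len(bic) == m and len(bic & cat) == x
            got = bb.fisher_enrichment_pvalue(bic, cat, uni)
            assert got == pytest.approx(fisher_oracle(n, k, m, x), rel=1e-9)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            bb.fisher_enrichment_pvalue({"g"}, {"g"}, [])


# ---------------------------------------------------------------------------
# Westfall-Young + GO-Sig
# ---------------------------------------------------------------------------


class TestWestfallYoung:
    def test_single_category_matches_raw_resampling_estimate(self):
        rng = np.random.default_rng(2)
        uni = [f"g{i}" for i in range(60)]
        cat = bb.GeneSetCollection([bb.GeneSet("c", "", frozenset(uni[:15]))])
        bic = set(uni[5:20])
        adj = bb.westfall_young_adjust(bic, cat, uni, n_resamples=4000, seed=9)
        raw = bb.fisher_enrichment_pvalue(bic, cat["c"].genes, uni)
        # with one category min-p == that category's p; the resampling
        # estimate of P(p* <= raw) is the permutation version of raw itself
        m = len(bic)
        draws = [set(rng.choice(uni, m, replace=False)) for _ in range(2000)]
        est = np.mean([
            bb.fisher_enrichment_pvalue(d, cat["c"].genes, uni) <= raw
            for d in draws
        ])
        assert adj["c"] == pytest.approx(est, abs=0.04)

    def test_adjusted_values_monotone_in_raw_order(self):
        rng = np.random.default_rng(11)
        uni = [f"g{i}" for i in range(80)]
        cats = bb.GeneSetCollection([
            bb.GeneSet(f"c{i}", "",
                       frozenset(rng.choice(uni, 12, replace=False)))
            for i in range(8)
        ])
        bic = set(rng.choice(uni, 15, replace=False))
        adj = bb.westfall_young_adjust(bic, cats, uni, n_resamples=300, seed=4)
        raw = {c: bb.fisher_enrichment_pvalue(bic, cats[c].genes, uni)
               for c in cats.names}
        order = sorted(cats.names, key=lambda c: raw[c])
        vals = [adj[c] for c in order]
        assert all(vals[i] <= vals[i + 1] + 1e-12 for i in range(len(vals) - 1))
        assert all(1 / 301 <= v <= 1.0 for v in vals)


class TestGoSig:
    def test_oracle_modules_as_categories_score_one(self, desk_dataset,
                                                    desk_annotations):
        _, matrix, labels, truth = desk_dataset
        _, go = desk_annotations
        bs = bb.oracle_bicluster_set(truth, labels)
        cfg = bb.BenchmarkConfig(alpha=0.05, n_resamples=500, seed=8)
        res = bb.go_sig(bs, go, matrix.gene_ids, cfg)
        assert res.significant_fraction == 1.0

    def test_empty_set_scores_zero(self, desk_dataset, desk_annotations):
        _, matrix, _, _ = desk_dataset
        _, go = desk_annotations
        cfg = bb.BenchmarkConfig(seed=1, n_resamples=50)
        assert bb.go_sig(bb.BiclusterSet("none"), go, matrix.gene_ids,
                         cfg).significant_fraction == 0.0


class TestGeneOverlapDiagnostic:
    def test_shared_and_disjoint_extremes(self):
        g = frozenset({"a", "b", "c"})
        same = bb.BiclusterSet("x", biclusters=[
            bb.Bicluster(g, {"s1"}), bb.Bicluster(g, {"s2"}),
            bb.Bicluster(g, {"s3"})])
        assert bb.mean_pairwise_gene_overlap(same) == 1.0
        disjoint = bb.BiclusterSet("y", biclusters=[
            bb.Bicluster({"a"}, {"s"}), bb.Bicluster({"b"}, {"s"})])
        assert bb.mean_pairwise_gene_overlap(disjoint) == 0.0

    def test_half_shared_worked_value(self):
        a = {f"g{i}" for i in range(10)}
        b = {f"g{i}" for i in range(5, 15)}
        bs = bb.BiclusterSet("z", biclusters=[
            bb.Bicluster(a, {"s"}), bb.Bicluster(b, {"s"})])
        assert bb.mean_pairwise_gene_overlap(bs) == 0.5

    def test_fewer_than_two_is_error(self):
        bs = bb.BiclusterSet("x", biclusters=[bb.Bicluster({"g"}, {"s"})])
        with pytest.raises(ValueError):
            bb.mean_pairwise_gene_overlap(bs)
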