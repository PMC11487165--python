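"""Enrichment statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esckit.enrichment import (
    _enrichment_score,
    bh_adjust,
    gsea_preranked,
    hypergeom_ora,
    single_sample_pathway_score,
)
from esckit.io import ExpressionMatrix, GeneSetCollection


def ora_enumeration_oracle(N, K, n, k):
    """P[overlap >= k] by exhaustive enumeration of n-subsets of a universe
    of N genes containing a K-set."""
    universe = list(range(N))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g < K) >= k:
            hits += 1
    return hits / total


def es_bruteforce_oracle(scores, in_set, weight):
    """O(N^2) literal running-sum maximal deviation."""
    n = len(scores)
    nh = sum(in_set)
    denom = sum(abs(s) ** weight for s, h in zip(scores, in_set) if h)
    best, rs = 0.0, 0.0
    for s, h in zip(scores, in_set):
        rs += (abs(s) ** weight / denom) if h else (-1.0 / (n - nh))
        if abs(rs) > abs(best):
            best = rs
    return best


def bh_stepup_oracle(ps):
    """Literal BH: sort, multiply by m/i, enforce monotonicity from the tail."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, ps[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestORA:
    def test_full_overlap_equals_one_over_binomial(self):
        sets = GeneSetCollection.from_dict({"S": {f"g{i}" for i in range(5)}})
        universe = {f"g{i}" for i in range(10)}
        query = {f"g{i}" for i in range(5)}
        res = hypergeom_ora(query, sets, universe)
        assert res.loc["S", "p"] == pytest.approx(1 / math.comb(10, 5), rel=1e-12)
        assert res.loc["S", "neg_log10_p"] == pytest.approx(
            -math.log10(1 / 252), rel=1e-9
        )

    def test_zero_overlap_p_is_one(self):
        sets = GeneSetCollection.from_dict({"S": {"g0", "g1"}})
        res = hypergeom_ora({"g8", "g9"}, sets, {f"g{i}" for i in range(10)})
        assert res.loc["S", "p"] == 1.0

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 4), (7, 2, 3)])
    def test_matches_enumeration_for_small_universes(self, N, K, n):
        universe = {f"g{i}" for i in range(N)}
        sets = GeneSetCollection.from_dict({"S": {f"g{i}" for i in range(K)}})
        rng = np.random.default_rng(N * 100 + K)
        query = set(rng.choice(sorted(universe), size=n, replace=False))
        k = len(query & sets["S"].genes)
        res = hypergeom_ora(query, sets, universe)
        assert res.loc["S", "p"] == pytest.approx(
            ora_enumeration_oracle(N, K, n, k), rel=1e-10
        )

    def test_disjoint_set_dropped_with_warning_not_nan(self):
        sets = GeneSetCollection.from_dict({"S": {"zz"}, "T": {"g0"}})
        with pytest.warns(UserWarning, match="disjoint"):
            res = hypergeom_ora({"g0"}, sets, {"g0", "g1"})
        assert list(res.index) == ["T"]
        assert res["p"].notna().all()

    def test_empty_inputs_rejected(self, tiny_sets):
        with pytest.raises(ValueError):
            hypergeom_ora(set(), tiny_sets, {"gA"})
        with pytest.raises(ValueError):
            hypergeom_ora({"gA"}, tiny_sets, set())


class TestBH:
    def test_hand_stepup_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=30)
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_literal_stepup_and_properties(self, ps):
        out = bh_adjust(ps)
        np.testing.assert_allclose(out, bh_stepup_oracle(ps), atol=1e-12)
        assert (out >= np.asarray(ps) - 1e-15).all()
        assert (out <= 1.0 + 1e-15).all()
        # re-adjusting adjusted values can only push them further up
        assert (bh_adjust(out) >= out - 1e-15).all()


class TestGSEA:
    def test_top_gene_singleton_set_has_es_one(self):
        ranked = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        sets = GeneSetCollection.from_dict({"top": {"a"}})
        res = gsea_preranked(ranked, sets, weight=0.0, n_perm=50, seed=0)
        assert res.table.loc["top", "ES"] == pytest.approx(1.0)

    def test_bottom_gene_singleton_set_has_es_minus_one(self):
        ranked = pd.Series({"a": 4.0, "b": 3.0, "c": 2.0, "d": 1.0})
        sets = GeneSetCollection.from_dict({"bot": {"d"}})
        res = gsea_preranked(ranked, sets, weight=0.0, n_perm=50, seed=0)
        # running sum: -1/3, -2/3, -1, then +1 -> max deviation is -1
        assert res.table.loc["bot", "ES"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    @pytest.mark.parametrize("trial", range(5))
    def test_es_matches_bruteforce_on_short_lists(self, weight, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 21))
        scores = np.sort(rng.normal(size=n))[::-1]
        size = int(rng.integers(1, n - 1))
        members = rng.choice(n, size=size, replace=False)
        in_set = np.zeros(n, dtype=bool)
        in_set[members] = True
        got = _enrichment_score(scores, in_set, weight)
        want = es_bruteforce_oracle(list(scores), list(in_set), weight)
        assert got == pytest.approx(want, abs=1e-12)

    def test_negation_symmetry(self):
        ranked = pd.Series({"a": 3.0, "b": 1.5, "c": -0.5, "d": -2.0})
        sets = GeneSetCollection.from_dict({"S": {"a", "c"}})
        fwd = gsea_preranked(ranked, sets, n_perm=20, seed=1)
        rev = gsea_preranked(-ranked, sets, n_perm=20, seed=1)
        assert fwd.table.loc["S", "ES"] == pytest.approx(
            -rev.table.loc["S", "ES"], abs=1e-12
        )

    def test_set_covering_whole_list_rejected(self):
        ranked = pd.Series({"a": 1.0, "b": 0.5})
        sets = GeneSetCollection.from_dict({"all": {"a", "b"}})
        with pytest.raises(ValueError, match="strict"):
            gsea_preranked(ranked, sets, n_perm=10, seed=0)

    def test_nes_sign_matches_es_sign(self):
        rng = np.random.default_rng(5)
        ranked = pd.Series(rng.normal(size=40),
                           index=[f"g{i}" for i in range(40)])
        sets = GeneSetCollection.from_dict(
            {"A": {f"g{i}" for i in range(5)}, "B": {f"g{i}" for i in range(30, 38)}}
        )
        res = gsea_preranked(ranked, sets, n_perm=200, seed=2)
        t = res.table.dropna(subset=["NES"])
        assert (np.sign(t["NES"]) == np.sign(t["ES"])).all()
        assert ((t["fdr_q"] >= 0) & (t["fdr_q"] <= 1)).all()


class TestSingleSampleScore:
    def test_single_gene_set_equals_gene_z(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(3, 6)),
            index=["g1", "g2", "g3"],
            columns=[f"s{i}" for i in range(6)],
        )
        expr = ExpressionMatrix(frame)
        sets = GeneSetCollection.from_dict({"one": {"g2"}})
        score = single_sample_pathway_score(expr, sets)
        z = (frame.loc["g2"] - frame.loc["g2"].mean()) / frame.loc["g2"].std(ddof=0)
        np.testing.assert_allclose(score.loc["one"], z, atol=1e-12)

    def test_planted_two_sd_shift_scores_near_two(self, rng):
        n = 40
        frame = pd.DataFrame(
            rng.normal(size=(10, n)),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(n)],
        )
        # push the set genes up by 2 sample-sds in sample s0
        member = ["g0", "g1", "g2", "g3"]
        for g in member:
            sd = frame.loc[g].std(ddof=0)
            frame.loc[g, "s0"] = frame.loc[g].mean() + 2 * sd
        expr = ExpressionMatrix(frame)
        score = single_sample_pathway_score(
            expr, GeneSetCollection.from_dict({"S": set(member)})
        )
        assert score.loc["S", "s0"] == pytest.approx(2.0, abs=0.35)

    def test_all_genes_one_set_columns_center_at_zero(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(6, 5)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(5)],
        )
        expr = ExpressionMatrix(frame)
        sets = GeneSetCollection.from_dict({"all": set(frame.index)})
        score = single_sample_pathway_score(expr, sets)
        # mean-z over all genes need not be 0 per column, but its mean over
        # columns is exactly 0 (z-scores center across samples)
        assert score.loc["all"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_gene_scores_zero_with_warning(self):
        frame = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [2.0, 5.0], "s3": [3.0, 5.0]},
            index=["var", "flat"],
        )
        expr = ExpressionMatrix(frame)
        with pytest.warns(UserWarning, match="zero-variance"):
            score = single_sample_pathway_score(
                expr, GeneSetCollection.from_dict({"F": {"flat"}})
            )
        np.testing.assert_allclose(score.loc["F"], 0.0)
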