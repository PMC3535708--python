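"""Rescoring, normalization, ranking and the score/rank combinations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakfusion import (
    PeakSet,
    Region,
    ScoredFusion,
    build_union,
    combine_ranks,
    combine_scores,
    normalize_scores,
    order_regions,
    rank_scores,
)
from peakfusion.scoring import assign_system_scores

from conftest import random_peakset

scores_arrays = st.lists(
    st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=30
).map(np.asarray)


class TestAssignSystemScores:
    def test_worked_example_sides(self, two_system_pair):
        u = build_union(*two_system_pair)
        assert assign_system_scores(u, "x").tolist() == [10, 5, 0]
        assert assign_system_scores(u, "y").tolist() == [8, 0, 4]

    def test_merged_sums_same_side_members(self):
        x = PeakSet("x", [Region("chr1", 0, 50, 10, "x", "x_1"),
                          Region("chr1", 80, 120, 7, "x", "x_2")])
        y = PeakSet("y", [Region("chr1", 40, 90, 3, "y", "y_1")])
        u = build_union(x, y)
        assert assign_system_scores(u, "x").tolist() == [17]
        assert assign_system_scores(u, "y").tolist() == [3]


class TestNormalizeScores:
    def test_minmax(self):
        assert normalize_scores(np.array([10, 5, 0])).tolist() == [1.0, 0.5, 0.0]

    @pytest.mark.parametrize("raw", [[8, 8, 8], [3.0]])
    def test_degenerate_constant_column_is_neutral(self, raw):
        assert normalize_scores(np.array(raw)).tolist() == [0.5] * len(raw)

    @given(scores_arrays)
    @settings(derandomize=True, database=None, max_examples=60)
    def test_bounds_and_extremes(self, raw):
        star = normalize_scores(raw)
        assert np.all((star >= 0) & (star <= 1))
        if raw.max() > raw.min():
            assert star[np.argmax(raw)] == 1.0
            assert star[np.argmin(raw)] == 0.0


class TestRankScores:
    def test_strict_descending(self):
        assert rank_scores(np.array([10, 5, 0])).tolist() == [1, 2, 3]

    def test_midranks(self):
        assert rank_scores(np.array([10, 0, 0])).tolist() == [1, 2.5, 2.5]
        assert rank_scores(np.array([7.0])).tolist() == [1]

    @given(scores_arrays)
    @settings(derandomize=True, database=None, max_examples=60)
    def test_rank_sum_preserved_and_monotone_on_normalized(self, raw):
        r = rank_scores(raw)
        p = raw.size
        assert r.sum() == pytest.approx(p * (p + 1) / 2)
        assert np.array_equal(r, rank_scores(normalize_scores(raw)))


class TestCombinations:
    @pytest.mark.parametrize("sx,sy,expected", [
        ([1.0], [1.0], [1.0]),
        ([0.5], [0.0], [0.25]),
        ([0.0, 0.0], [0.0, 0.0], [0.0, 0.0]),
    ])
    def test_score_combination_mean(self, sx, sy, expected):
        assert combine_scores(np.array(sx), np.array(sy)).tolist() == expected

    def test_rank_combination_mean(self):
        got = combine_ranks(np.array([1, 2, 3]), np.array([1, 3, 2]))
        assert got.tolist() == [1.0, 2.5, 2.5]


class TestOrdering:
    def test_coordinate_tie_break(self, two_system_pair):
        scored = ScoredFusion.from_fusion(build_union(*two_system_pair))
        by_score = [(r.start, r.end) for r in order_regions(scored, "score_comb")]
        assert by_score == [(100, 250), (500, 600), (800, 900)]
        by_rank = [(r.start, r.end) for r in order_regions(scored, "rank_comb")]
        assert by_rank == by_score

    def test_system_side_ordering(self, two_system_pair):
        scored = ScoredFusion.from_fusion(build_union(*two_system_pair))
        by_y = [(r.start, r.end) for r in order_regions(scored, "system_y")]
        assert by_y == [(100, 250), (800, 900), (500, 600)]

    def test_unknown_column_errors(self, two_system_pair):
        scored = ScoredFusion.from_fusion(build_union(*two_system_pair))
        with pytest.raises(ValueError, match="unknown ordering"):
            order_regions(scored, "banana")


class TestEndToEndProperties:
    def test_micro_fixture_full_chain(self, two_system_pair):
        scored = ScoredFusion.from_fusion(build_union(*two_system_pair))
        assert scored.s_x_star.tolist() == [1.0, 0.5, 0.0]
        assert scored.s_y_star.tolist() == [1.0, 0.0, 0.5]
        assert scored.s_comb.tolist() == [1.0, 0.25, 0.25]
        assert scored.r_comb.tolist() == [1.0, 2.5, 2.5]

    def test_swap_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x, y = random_peakset(rng, "x"), random_peakset(rng, "y")
            if not x.n or not y.n:
                continue
            a = ScoredFusion.from_fusion(build_union(x, y))
            b = ScoredFusion.from_fusion(build_union(y, x))
            np.testing.assert_allclose(a.s_comb, b.s_comb)
            np.testing.assert_allclose(a.r_comb, b.r_comb)

    def test_scale_invariance_of_one_system(self, two_system_pair):
        x, y = two_system_pair
        x_scaled = PeakSet("x", [Region(r.chrom, r.start, r.end, r.score * 37,
                                        "x", r.region_id) for r in x])
        a = ScoredFusion.from_fusion(build_union(x, y))
        b = ScoredFusion.from_fusion(build_union(x_scaled, y))
        np.testing.assert_allclose(a.s_x_star, b.s_x_star)
        np.testing.assert_allclose(a.r_x_prime, b.r_x_prime)
        np.testing.assert_allclose(a.s_comb, b.s_comb)
        np.testing.assert_allclose(a.r_comb, b.r_comb)

    def test_monotone_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x, y = random_peakset(rng, "x"), random_peakset(rng, "y")
            if not x.n or not y.n:
                continue
            s = ScoredFusion.from_fusion(build_union(x, y))
            n = len(s.fusion.regions)
            for i in range(n):
                for j in range(n):
                    if (s.s_x_prime[i] >= s.s_x_prime[j]
                            and s.s_y_prime[i] >= s.s_y_prime[j]):
                        assert s.s_comb[i] >= s.s_comb[j] - 1e-12
                        assert s.r_comb[i] <= s.r_comb[j] + 1e-12

    def test_identical_systems_reduce_to_single(self):
        regs = [("chr1", 0, 10, 9.0), ("chr1", 50, 80, 2.0), ("chr2", 5, 25, 4.0)]
        x = PeakSet("x", [Region(c, s, e, sc, "x", f"x_{k}")
                          for k, (c, s, e, sc) in enumerate(regs)])
        y = PeakSet("y", [Region(c, s, e, sc, "y", f"y_{k}")
                          for k, (c, s, e, sc) in enumerate(regs)])
        scored = ScoredFusion.from_fusion(build_union(x, y))
        np.testing.assert_allclose(scored.s_comb, scored.s_x_star)
        np.testing.assert_allclose(scored.r_comb, scored.r_x_prime)
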