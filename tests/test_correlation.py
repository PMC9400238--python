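import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cenweaver as cw
from cenweaver.correlation import MutualRankMatrix, RankMatrix

from conftest import make_matrix


def brute_force_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Direct evaluation of the Pearson formula."""
    xb, yb = x.mean(), y.mean()
    num = ((x - xb) * (y - yb)).sum()
    den = np.sqrt(((x - xb) ** 2).sum() * ((y - yb) ** 2).sum())
    return num / den


class TestComputePcc:
    def test_toy_values(self, toy_corr):
        ids = list(toy_corr.gene_ids)
        v = toy_corr.values
        assert v[ids.index("g1"), ids.index("g2")] == pytest.approx(1.0)
        assert v[ids.index("g1"), ids.index("g3")] == pytest.approx(-1.0)
        assert v[ids.index("g1"), ids.index("g4")] == pytest.approx(0.8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_formula(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.uniform(0, 50, size=(10, 6)))
        c = cw.compute_pcc(m)
        X = m.values
        for i in range(10):
            for j in range(i + 1, 10):
                assert c.values[i, j] == pytest.approx(
                    brute_force_pcc(X[i], X[j]), abs=1e-10)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(1)
        c = cw.compute_pcc(make_matrix(rng.uniform(0, 9, size=(15, 7))))
        assert np.abs(c.values - c.values.T).max() <= 1e-12
        np.testing.assert_allclose(np.diag(c.values), 1.0)

    def test_blockwise_identical_to_dense(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.uniform(0, 9, size=(23, 8)))
        dense = cw.compute_pcc(m)
        blocked = cw.compute_pcc(m, block_size=5)
        # summation order differs between the chunked and one-shot matrix
        # products, so agreement is to round-off, not bit-for-bit
        np.testing.assert_allclose(dense.values, blocked.values, atol=1e-14)

    def test_zero_variance_gene_flagged_not_nan_propagated(self):
        m = make_matrix([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        c = cw.compute_pcc(m)
        assert c.undefined_mask.tolist() == [False, True, False]
        assert np.isnan(c.values[1]).all()
        assert c.values[0, 2] == pytest.approx(-1.0)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            cw.compute_pcc(make_matrix([[1.0, 2.0], [2, 1]]))


class TestQuantileThresholds:
    def test_quantile_of_known_list(self):
        # force the defined off-diagonal PCC multiset (6 values -> 4 genes),
        # then check against numpy's linear-interpolation quantile of the list
        vals = np.array([-0.9, -0.5, 0.0, 0.3, 0.5, 0.9])
        c = _corr_from_offdiag(vals)
        t = cw.pcc_quantile_thresholds(c, top_q=0.2, bottom_q=0.2)
        offdiag = np.sort(c.defined_offdiag_values())
        assert t.pos_cut == pytest.approx(np.quantile(offdiag, 0.8))
        assert t.neg_cut == pytest.approx(np.quantile(offdiag, 0.2))

    def test_offset_additivity(self, toy_corr):
        base = cw.pcc_quantile_thresholds(toy_corr, top_q=0.4, bottom_q=0.4)
        shifted = cw.pcc_quantile_thresholds(toy_corr, top_q=0.4, bottom_q=0.4,
                                             offset=0.1)
        assert shifted.pos_cut == pytest.approx(base.pos_cut + 0.1)
        assert shifted.neg_cut == pytest.approx(base.neg_cut - 0.1)

    def test_clamp_with_warning(self, toy_corr):
        with pytest.warns(UserWarning, match="clamped"):
            t = cw.pcc_quantile_thresholds(toy_corr, offset=5.0)
        assert t.pos_cut == 1.0 and t.neg_cut == -1.0

    def test_positive_only_offset(self, toy_corr):
        sym = cw.pcc_quantile_thresholds(toy_corr, top_q=0.4, bottom_q=0.4, offset=0.1)
        one = cw.pcc_quantile_thresholds(toy_corr, top_q=0.4, bottom_q=0.4,
                                         offset=0.1, symmetric_offset=False)
        assert one.pos_cut == pytest.approx(sym.pos_cut)
        assert one.neg_cut == pytest.approx(sym.neg_cut + 0.1)


def _corr_from_offdiag(vals):
    """Build a CorrelationMatrix whose off-diagonal upper triangle is `vals`."""
    n = int((1 + np.sqrt(1 + 8 * len(vals))) / 2)
    m = np.eye(n)
    iu = np.triu_indices(n, 1)
    m[iu] = vals
    m[(iu[1], iu[0])] = vals
    ids = tuple(f"g{i}" for i in range(n))
    return cw.CorrelationMatrix(ids, m, np.zeros(n, dtype=bool))


class TestRanksAndMutualRank:
    def test_toy_ranks_brute_force(self, toy_corr):
        r = cw.compute_ranks(toy_corr)
        ids = list(toy_corr.gene_ids)
        g1 = ids.index("g1")
        # partners of g1 sorted by PCC desc: g2 (1.0), g4 (0.8), g3 (-1.0)
        assert r.ranks[g1, ids.index("g2")] == 1
        assert r.ranks[g1, ids.index("g4")] == 2
        assert r.ranks[g1, ids.index("g3")] == 3
        assert r.ranks[g1, g1] == 0

    def test_rank_rows_are_permutations(self, toy_corr):
        r = cw.compute_ranks(toy_corr)
        for i in range(4):
            row = np.delete(r.ranks[i], i)
            assert sorted(row) == [1, 2, 3]

    def test_tie_goes_to_lexicographically_smaller_gene(self):
        # gb and gc both correlate identically with ga
        m = make_matrix([[1, 2, 3, 4], [2, 4, 6, 8], [3, 6, 9, 12], [4, 3, 4, 3]],
                        gene_ids=["ga", "gb", "gc", "gd"])
        r = cw.compute_ranks(cw.compute_pcc(m))
        assert r.ranks[0, 1] == 1  # gb before gc
        assert r.ranks[0, 2] == 2

    def test_abs_ranking_promotes_strong_negative_partners(self, toy_corr):
        r = cw.compute_ranks(toy_corr, rank_on="abs")
        ids = list(toy_corr.gene_ids)
        g1 = ids.index("g1")
        # |pcc|: g2 -> 1.0, g3 -> 1.0, g4 -> 0.8; tie g2/g3 lexicographic
        assert r.ranks[g1, ids.index("g2")] == 1
        assert r.ranks[g1, ids.index("g3")] == 2
        assert r.ranks[g1, ids.index("g4")] == 3

    def test_two_gene_matrix(self):
        m = make_matrix([[1, 2, 3], [2, 4, 7.0]])
        r = cw.compute_ranks(cw.compute_pcc(m))
        assert r.ranks[0, 1] == 1 and r.ranks[1, 0] == 1
        mr = cw.compute_mr(r)
        assert mr.mr[0, 1] == pytest.approx(1.0)

    def test_mr_geometric_mean(self):
        r = RankMatrix(("A", "B"), np.array([[0, 4], [9, 0]]))
        mr = cw.compute_mr(r)
        assert mr.mr[0, 1] == pytest.approx(6.0)  # sqrt(4 * 9)
        assert mr.mr[1, 0] == pytest.approx(6.0)

    def test_mr_symmetric_and_invariant_to_monotone_transform(self, toy_matrix):
        c = cw.compute_pcc(toy_matrix)
        mr1 = cw.compute_mr(cw.compute_ranks(c))
        assert np.array_equal(mr1.mr, mr1.mr.T)
        # cube preserves order on [-1, 1]; ranks, hence MR, must not change
        c3 = cw.CorrelationMatrix(c.gene_ids, np.sign(c.values) * np.abs(c.values) ** 3,
                                  c.undefined_mask)
        mr3 = cw.compute_mr(cw.compute_ranks(c3))
        np.testing.assert_array_equal(mr1.mr, mr3.mr)

    def test_mr_at_least_min_rank_sqrt_bound(self, fitted):
        r = cw.compute_ranks(fitted.correlation)
        mr = cw.compute_mr(r)
        R = r.ranks.astype(float)
        both = (R > 0) & (R.T > 0)
        assert (mr.mr[both] >= np.sqrt(np.minimum(R, R.T))[both] - 1e-9).all()


class TestMrEdgeFilter:
    def _pair(self, rank_ab, rank_ba):
        ranks = np.array([[0, rank_ab], [rank_ba, 0]])
        r = RankMatrix(("A", "B"), ranks)
        return cw.compute_mr(r), r

    def test_mr_below_cut_kept_even_with_poor_min_rank(self):
        mrm, r = self._pair(47, 19)  # MR = sqrt(893) = 29.88 < 30; min rank 19
        edges = cw.mr_edge_filter(mrm, r, combine="any")
        assert len(edges) == 1

    def test_or_vs_and_combination(self):
        mrm, r = self._pair(2, 1250)  # MR = 50, min rank 2
        assert len(cw.mr_edge_filter(mrm, r, combine="any")) == 1
        assert len(cw.mr_edge_filter(mrm, r, combine="all")) == 0

    def test_mr_boundary_strict(self):
        mrm, r = self._pair(30, 30)  # MR exactly 30
        assert len(cw.mr_edge_filter(mrm, r, combine="any")) == 0

    def test_uni_rank_boundary_strict(self):
        mrm, r = self._pair(3, 3000)  # min rank exactly 3, MR huge
        assert len(cw.mr_edge_filter(mrm, r, combine="any")) == 0

    def test_relaxing_cuts_never_removes_edges(self, fitted):
        c = fitted.correlation
        r = cw.compute_ranks(c)
        mrm = cw.compute_mr(r)
        tight = cw.mr_edge_filter(mrm, r, c, mr_cut=10, uni_cut=2)
        loose = cw.mr_edge_filter(mrm, r, c, mr_cut=30, uni_cut=3)
        tight_pairs = set(zip(tight["gene_a"], tight["gene_b"]))
        loose_pairs = set(zip(loose["gene_a"], loose["gene_b"]))
        assert tight_pairs <= loose_pairs

    def test_inconsistent_universe_rejected(self):
        mrm, r = self._pair(1, 1)
        other = MutualRankMatrix(("A", "C"), mrm.mr)
        with pytest.raises(ValueError, match="universe"):
            cw.mr_edge_filter(other, r)

    def test_edges_carry_scores_and_sign(self, toy_corr):
        r = cw.compute_ranks(toy_corr)
        edges = cw.mr_edge_filter(cw.compute_mr(r), r, toy_corr, mr_cut=2, uni_cut=1)
        row = edges.set_index(["gene_a", "gene_b"]).loc[("g1", "g2")]
        assert row["mr"] == pytest.approx(1.0)
        assert row["pcc"] == pytest.approx(1.0)
        assert row["sign"] == "+"


class TestPccEdgeFilter:
    def test_closed_interval_boundaries(self):
        c = _corr_from_offdiag(np.array([0.58, 0.0, -0.45]))
        t = cw.PccThresholds(pos_cut=0.58, neg_cut=-0.45)
        edges = cw.pcc_edge_filter(c, t)
        kept = set(map(tuple, edges[["gene_a", "gene_b"]].values))
        assert len(kept) == 2  # both boundary pairs kept, pcc=0 dropped
        assert set(edges["sign"]) == {"+", "-"}

    def test_extreme_cuts(self):
        rng = np.random.default_rng(8)
        c = cw.compute_pcc(make_matrix(rng.uniform(0, 5, size=(8, 6))))
        none = cw.pcc_edge_filter(c, cw.PccThresholds(pos_cut=1.0, neg_cut=-1.0))
        assert len(none) == 0  # no exact +/-1 pairs in noise
        lo = float(c.defined_offdiag_values().min())
        every = cw.pcc_edge_filter(c, cw.PccThresholds(pos_cut=lo, neg_cut=-1.0))
        assert len(every) == 8 * 7 // 2

    def test_invalid_threshold_order_rejected(self):
        with pytest.raises(ValueError):
            cw.PccThresholds(pos_cut=-0.5, neg_cut=0.5)
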