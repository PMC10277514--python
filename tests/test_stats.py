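"""Unit and property tests for the statistical primitives.

Expected values are either trivial identities, hand computations, or frozen
outputs of the independent brute-force oracles defined in this file.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from seromics.stats import (
    bky_two_stage,
    chi_square_2xk,
    cut_tree,
    fdr_reject,
    mann_whitney,
    mcnemar,
    spearman,
    spearman_test,
    ward_linkage,
)

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def enumerate_mw_p(x, y):
    """Two-sided exact Mann-Whitney p by counting pairwise wins per
    arrangement — independent of the implementation's rank-sum route."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u_stat(first_idx):
        first = pooled[list(first_idx)]
        rest = pooled[[i for i in range(n) if i not in set(first_idx)]]
        wins = sum((a > b) + 0.5 * (a == b) for a in first for b in rest)
        return wins

    u_obs = u_stat(range(n1))
    us = [u_stat(c) for c in itertools.combinations(range(n), n1)]
    us = np.array(us)
    eps = 1e-9
    p = 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean())
    return min(1.0, p)


def literal_bky(p, q):
    """Straight transcription of the two-stage definition."""
    p = np.asarray(p, float)
    m = len(p)
    qp = q / (1 + q)

    def step_up(alpha):
        order = np.argsort(p)
        ps = p[order]
        ks = [i for i in range(m) if ps[i] <= (i + 1) * alpha / m]
        rej = np.zeros(m, bool)
        if ks:
            rej[order[: max(ks) + 1]] = True
        return rej

    r1 = int(step_up(qp).sum())
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return step_up(qp * m / (m - r1))


def oracle_ward(X):
    """Greedy Ward by exhaustive evaluation of the SSE-increase objective."""
    n = len(X)
    clusters = {i: (X[i].copy(), 1) for i in range(n)}
    Z = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ca, na = clusters[a]
                cb, nb = clusters[b]
                dsse = na * nb / (na + nb) * float(np.sum((ca - cb) ** 2))
                if (
                    best is None
                    or dsse < best[0] - 1e-12
                    or (abs(dsse - best[0]) <= 1e-12 and (a, b) < best[1:3])
                ):
                    best = (dsse, a, b)
        dsse, a, b = best
        ca, na = clusters.pop(a)
        cb, nb = clusters.pop(b)
        clusters[next_id] = ((na * ca + nb * cb) / (na + nb), na + nb)
        Z.append([a, b, np.sqrt(2 * dsse), na + nb])
        next_id += 1
    return np.array(Z)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_identical_symmetric_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5
        assert res.p_value == 1.0

    def test_most_extreme_exact(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.exact
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 6))
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            res = mann_whitney(x, y, mode="exact")
            assert res.p_value == pytest.approx(enumerate_mw_p(x, y), abs=1e-12)

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            p_ex = mann_whitney(x, y, mode="exact").p_value
            p_as = mann_whitney(x, y, mode="asymptotic").p_value
            assert abs(p_ex - p_as) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_auto_uses_exact_only_without_ties(self):
        assert mann_whitney([1, 2], [3, 4]).exact
        assert not mann_whitney([1, 1, 2], [2, 3, 3]).exact


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

class TestChiSquare:
    def test_balanced_table_is_null(self):
        res = chi_square_2xk([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_diagonal(self):
        # all expected counts are 10; sum (o-e)^2/e = 4 * 100/10 = 40
        res = chi_square_2xk([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)

    def test_row_swap_invariance(self):
        a = chi_square_2xk([[5, 9], [12, 3]])
        b = chi_square_2xk([[12, 3], [5, 9]])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2xk([[0, 0], [5, 5]])


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_perfect_agreement(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_perfect_reversal(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # ranks (1,2,3,4) vs (2,1,4,3): 1 - 6*4/(4*15) = 0.6
        assert spearman([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_flagged(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 5, 12).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            assert spearman(x, y) == pytest.approx(sps.spearmanr(x, y).statistic)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(-100, 100), min_size=4, max_size=15, unique=True)
    )
    def test_monotone_transform_invariance(self, xs):
        # integer support guarantees the transform stays injective in floats
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**32)
        ys = rng.normal(size=len(xs))
        base = spearman(np.asarray(xs, float), ys)
        transformed = spearman(np.exp(np.asarray(xs) / 50.0), ys)
        assert base == pytest.approx(transformed, abs=1e-12)


# ---------------------------------------------------------------------------
# BKY two-stage FDR
# ---------------------------------------------------------------------------

class TestBKY:
    def test_all_large_p(self):
        dec = bky_two_stage([0.9] * 10, 0.05)
        assert dec.n_rejected == 0

    def test_literal_oracle_example(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.5]
        dec = bky_two_stage(p, 0.05)
        assert np.array_equal(dec.rejected, literal_bky(p, 0.05))

    def test_single_hypothesis_closed_form(self):
        assert bky_two_stage([0.01], 0.05).n_rejected == 1          # 0.01 <= 0.05/1.05
        assert bky_two_stage([0.049], 0.05).n_rejected == 0         # 0.049 > 0.05/1.05

    def test_matches_literal_oracle_randomized(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            if rng.random() < 0.4:
                p[: max(1, m // 3)] *= 0.02
            assert np.array_equal(
                bky_two_stage(p, 0.05).rejected, literal_bky(p, 0.05)
            )

    def test_step_up_shape(self):
        # rejection set must be a lower set of the sorted p-values
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(30)
            dec = bky_two_stage(p, 0.05)
            order = np.argsort(p)
            flags = dec.rejected[order]
            if flags.any():
                last = np.max(np.nonzero(flags)[0])
                assert flags[: last + 1].all()

    def test_superset_of_bh(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.random(40)
            p[:10] *= 0.01
            bky = bky_two_stage(p, 0.05)
            bh = fdr_reject(p, 0.05, method="bh")
            if 0 < bky.stage1_rejections < len(p):
                assert np.all(bh.rejected <= bky.rejected)

    def test_q_bounds(self):
        with pytest.raises(ValueError):
            bky_two_stage([0.5], 1.5)

    def test_by_flag(self):
        p = np.array([0.001, 0.01, 0.2])
        by = fdr_reject(p, 0.05, method="by")
        bh = fdr_reject(p, 0.05, method="bh")
        assert by.n_rejected <= bh.n_rejected  # BY is more conservative


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

class TestMcNemar:
    def test_symmetric_discordance(self):
        assert mcnemar(5, 5, "exact").p_value == 1.0

    def test_binomial_tail(self):
        assert mcnemar(9, 1, "exact").p_value == pytest.approx(0.021484375)

    def test_exact_matches_binomial_oracle(self):
        for b in range(0, 15):
            for c in range(0, 15):
                if b + c == 0:
                    continue
                n, k = b + c, max(b, c)
                expect = 1.0 if b == c else min(1.0, 2 * sum(
                    sps.binom.pmf(i, n, 0.5) for i in range(k, n + 1)
                ))
                assert mcnemar(b, c, "exact").p_value == pytest.approx(expect)

    def test_no_discordance_convention(self):
        res = mcnemar(0, 0)
        assert res.p_value == 1.0
        assert res.note is not None

    def test_asymptotic_close_to_exact_for_large_n(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(25, 80))
            b = int(rng.integers(0, n + 1))
            c = n - b
            p_ex = mcnemar(b, c, "exact").p_value
            p_as = mcnemar(b, c, "asymptotic").p_value
            assert abs(p_ex - p_as) < 0.03

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mcnemar(-1, 3)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

class TestWard:
    def test_identical_points_merge_at_zero(self):
        Z = ward_linkage(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_one_dimensional_example(self):
        Z = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        assert set(Z[0, :2]) == {0.0, 1.0}
        assert Z[1, 2] > Z[0, 2]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(3, 8))
            X = rng.standard_normal((n, int(rng.integers(1, 4))))
            Z = ward_linkage(X)
            Zo = oracle_ward(X)
            assert np.array_equal(Z[:, :2], Zo[:, :2])
            assert np.allclose(Z[:, 2], Zo[:, 2], atol=1e-8)

    def test_heights_monotone(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            X = rng.standard_normal((int(rng.integers(3, 25)), 3))
            Z = ward_linkage(X)
            assert np.all(np.diff(Z[:, 2]) >= -1e-9)

    def test_deterministic_under_ties(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])  # symmetric spacing: tied costs
        Z1 = ward_linkage(X)
        Z2 = ward_linkage(X)
        assert np.array_equal(Z1, Z2)
        assert tuple(Z1[0, :2]) == (0.0, 1.0)  # lexicographic tie-break

    def test_distance_matrix_input(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        assert np.allclose(ward_linkage(X), ward_linkage(D, is_distance=True))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(np.array([[0.0], [np.nan]]))


class TestCutTree:
    def test_singletons_and_single_cluster(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((6, 2))
        Z = ward_linkage(X)
        assert len(set(cut_tree(Z, k=6))) == 6
        assert len(set(cut_tree(Z, k=1))) == 1

    def test_two_clusters_on_line_example(self):
        Z = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        labels = cut_tree(Z, k=2)
        assert labels[0] == labels[1] != labels[2]

    def test_height_cut(self):
        Z = ward_linkage(np.array([[0.0], [1.0], [10.0]]))
        labels = cut_tree(Z, height=Z[0, 2])
        assert labels[0] == labels[1] != labels[2]

    def test_k_out_of_range(self):
        Z = ward_linkage(np.array([[0.0], [1.0]]))
        with pytest.raises(ValueError):
            cut_tree(Z, k=5)
        with pytest.raises(ValueError):
            cut_tree(Z)


def test_spearman_test_p_matches_scipy():
    rng = np.random.default_rng(12)
    x = rng.normal(size=30)
    y = x + rng.normal(size=30)
    mine = spearman_test(x, y)
    ref = sps.spearmanr(x, y)
    assert mine.statistic == pytest.approx(ref.statistic)
    assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)
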