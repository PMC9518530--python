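"""Spatial weights and Moran statistics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from emresilience.core import SpatialWeights, ZeroVarianceError
from emresilience.spatial import (
    CoincidentPointsError,
    build_weights,
    global_moran,
    local_moran,
    moran_bounds,
    moran_variance,
    moran_zscore,
    permutation_test,
    subset_moran,
)


def brute_force_global(x, W):
    """Plain double-sum evaluation of the global statistic."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    w = W.matrix
    num = sum(
        w[i, j] * (x[i] - xbar) * (x[j] - xbar)
        for i in range(n) for j in range(n)
    )
    den = sum((xi - xbar) ** 2 for xi in x)
    s0 = sum(w[i, j] for i in range(n) for j in range(n))
    return n / s0 * num / den


def brute_force_local(x, W):
    x = np.asarray(x, dtype=float)
    n = x.size
    xbar = x.mean()
    den = sum((xi - xbar) ** 2 for xi in x)
    out = []
    for i in range(n):
        lag = sum(W.matrix[i, j] * (x[j] - xbar) for j in range(n))
        out.append(n * (x[i] - xbar) * lag / den)
    return np.array(out)


def random_weights(n, rng, standardize=False):
    w = rng.uniform(0, 1, (n, n))
    np.fill_diagonal(w, 0.0)
    W = SpatialWeights([f"R{i}" for i in range(n)], w)
    return W.row_standardized() if standardize else W


class TestBuildWeights:
    def test_collinear_inverse_distance(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_weights(coords, cutoff=np.inf)
        assert W.matrix[0, 1] == pytest.approx(1.0)
        assert W.matrix[0, 2] == pytest.approx(0.5)
        assert W.matrix[1, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(W.matrix, W.matrix.T)
        assert np.all(np.diag(W.matrix) == 0)

    def test_row_standardized_collinear(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = build_weights(coords, cutoff=np.inf, row_standardize=True)
        np.testing.assert_allclose(W.matrix[0], [0.0, 2 / 3, 1 / 3])

    def test_s0_equals_brute_force_double_sum(self, rng):
        coords = rng.uniform(0, 10, (10, 2))
        W = build_weights(coords, cutoff=np.inf)
        brute = sum(
            W.matrix[i, j] for i in range(10) for j in range(10)
        )
        assert W.s0 == pytest.approx(brute)

    def test_minimum_coverage_cutoff_leaves_no_island(self, rng):
        coords = rng.uniform(0, 100, (12, 2))
        W = build_weights(coords)  # default cutoff
        assert np.all(W.matrix.sum(axis=1) > 0)

    def test_coincident_points_named(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(CoincidentPointsError, match="R1.*R2"):
            build_weights(coords)

    def test_knn_rows_have_k_neighbors(self, rng):
        coords = rng.uniform(0, 10, (8, 2))
        W = build_weights(coords, method="knn", k=3)
        np.testing.assert_allclose(W.matrix.sum(axis=1), 3.0)


class TestGlobalMoran:
    def test_expected_value_for_17_regions(self, rng):
        coords = rng.uniform(0, 10, (17, 2))
        W = build_weights(coords)
        g = global_moran(rng.normal(size=17), W)
        assert g.expected == pytest.approx(-1.0 / 16)
        assert abs(g.expected) == pytest.approx(0.0625)

    def test_checkerboard_on_rook_lattice(self):
        # 2x2 lattice with rook neighbors, alternating values
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        W = build_weights(coords, method="distance_band", cutoff=1.0,
                          row_standardize=True)
        x = np.array([1.0, -1.0, -1.0, 1.0])
        g = global_moran(x, W)
        assert g.I == pytest.approx(brute_force_global(x, W), abs=1e-12)
        assert g.I == pytest.approx(-1.0)

    def test_oracle_equivalence_small_instances(self, rng):
        for n in range(4, 9):
            for standardized in (False, True):
                W = random_weights(n, rng, standardize=standardized)
                x = rng.normal(size=n)
                g = global_moran(x, W)
                assert g.I == pytest.approx(brute_force_global(x, W), abs=1e-12)

    def test_affine_invariance(self, rng):
        W = random_weights(7, rng)
        x = rng.normal(size=7)
        g1 = global_moran(x, W)
        g2 = global_moran(5.0 * x - 11.0, W)
        assert g1.I == pytest.approx(g2.I, abs=1e-12)

    def test_z_consistent_with_fields(self, rng):
        W = random_weights(9, rng)
        g = global_moran(rng.normal(size=9), W)
        assert g.z == pytest.approx(
            moran_zscore(g.I, g.expected, g.variance), abs=1e-12
        )
        assert 0.0 <= g.p_two_sided <= 1.0

    def test_constant_attribute_rejected(self, rng):
        W = random_weights(5, rng)
        with pytest.raises(ZeroVarianceError):
            global_moran(np.full(5, 2.0), W)


class TestMoranVariance:
    def test_positive_for_any_weights(self, rng):
        for _ in range(5):
            W = random_weights(8, rng)
            x = rng.normal(size=8)
            assert moran_variance(x, W, "normality") > 0
            assert moran_variance(x, W, "randomization") > 0

    def test_normality_matches_independent_moment_formula(self, rng):
        W = random_weights(5, rng)
        x = rng.normal(size=5)
        # from-scratch moments with explicit loops
        n = 5
        w = W.matrix
        s0 = sum(w[i, j] for i in range(n) for j in range(n))
        s1 = 0.5 * sum(
            (w[i, j] + w[j, i]) ** 2 for i in range(n) for j in range(n)
        )
        s2 = sum(
            (sum(w[i, :]) + sum(w[:, i])) ** 2 for i in range(n)
        )
        var_hand = (n * n * s1 - n * s2 + 3 * s0 * s0) / (
            s0 * s0 * (n * n - 1)
        ) - (1.0 / (n - 1)) ** 2
        assert moran_variance(x, W, "normality") == pytest.approx(var_hand, abs=1e-12)

    def test_randomization_matches_exact_permutation_enumeration(self, rng):
        # the permutation null's variance, enumerated exhaustively
        n = 6
        W = random_weights(n, rng)
        x = rng.normal(size=n)
        z = x - x.mean()
        stats = []
        for perm in itertools.permutations(z):
            zp = np.array(perm)
            stats.append(n / W.s0 * (zp @ W.matrix @ zp) / (zp @ zp))
        exact = np.var(stats)
        assert moran_variance(x, W, "randomization") == pytest.approx(
            exact, rel=1e-10
        )


class TestPermutationTest:
    def test_seed_reproducibility(self, rng):
        W = random_weights(10, rng)
        x = rng.normal(size=10)
        assert permutation_test(x, W, 199, seed=5) == permutation_test(
            x, W, 199, seed=5
        )

    def test_strong_sar_signal_detected(self, grid49):
        W = build_weights(grid49, method="distance_band", cutoff=1.0)
        Wr = W.row_standardized()
        rng = np.random.default_rng(8)
        x = np.linalg.solve(np.eye(49) - 0.8 * Wr.matrix, rng.standard_normal(49))
        assert permutation_test(x, W, 999, seed=1) <= 0.01


class TestLocalMoran:
    def test_sum_identity_with_global(self, rng):
        for standardized in (False, True):
            W = random_weights(8, rng, standardize=standardized)
            x = rng.normal(size=8)
            g = global_moran(x, W)
            loc = local_moran(x, W, permutations=99)
            assert loc.local_i.sum() == pytest.approx(W.s0 * g.I, abs=1e-9)

    def test_matches_brute_force(self, rng):
        W = random_weights(6, rng)
        x = rng.normal(size=6)
        loc = local_moran(x, W, permutations=99)
        np.testing.assert_allclose(loc.local_i, brute_force_local(x, W), atol=1e-12)

    def test_high_region_among_low_neighbors_is_hl(self):
        # star topology: center high, satellites low
        w = np.zeros((4, 4))
        w[0, 1:] = 1.0
        w[1:, 0] = 1.0
        W = SpatialWeights(["center", "s1", "s2", "s3"], w)
        x = np.array([10.0, 1.0, 1.0, 1.0])
        loc = local_moran(x, W, permutations=99)
        assert loc.quadrant[0] == "HL"
        assert all(q == "LH" for q in loc.quadrant[1:])

    def test_quadrants_agree_with_signs(self, rng):
        W = random_weights(9, rng, standardize=True)
        x = rng.normal(size=9)
        loc = local_moran(x, W, permutations=99)
        for dev, lag, quad in zip(loc.deviation, loc.lag, loc.quadrant):
            expected = (
                "HH" if dev >= 0 and lag >= 0 else
                "LL" if dev < 0 and lag < 0 else
                "HL" if dev >= 0 else "LH"
            )
            assert quad == expected


class TestSubsetMoran:
    def test_full_subset_equals_global(self, rng):
        W = random_weights(8, rng, standardize=True)
        x = rng.normal(size=8)
        res = subset_moran(x, W, W.labels, permutations=99)
        assert res.global_result.I == pytest.approx(global_moran(x, W).I, abs=1e-12)

    def test_alternating_cluster_is_negatively_correlated(self):
        # east-like line of regions with checkerboard values
        coords = np.column_stack([np.arange(6, dtype=float), np.zeros(6)])
        W = build_weights(coords, method="distance_band", cutoff=1.0,
                          row_standardize=True)
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        res = subset_moran(x, W, W.labels[:4], permutations=99)
        assert res.global_result.I < 0
        assert res.mean_local_i < 0

    def test_too_small_subset_rejected(self, rng):
        W = random_weights(6, rng)
        with pytest.raises(ValueError):
            subset_moran(rng.normal(size=6), W, W.labels[:2])

    def test_unknown_label_rejected(self, rng):
        W = random_weights(6, rng)
        with pytest.raises(ValueError, match="Nowhere"):
            subset_moran(rng.normal(size=6), W, ["Nowhere", "R0", "R1"])


class TestMoranBounds:
    def test_observed_i_within_spectral_bounds(self, rng):
        W = random_weights(10, rng)
        lo, hi = moran_bounds(W)
        assert lo < 0 < hi
        for _ in range(20):
            x = rng.normal(size=10)
            I = global_moran(x, W).I
            assert lo - 1e-9 <= I <= hi + 1e-9
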