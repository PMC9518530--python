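"""Weighting, scoring, Jenks classification, and the entropy-TOPSIS comparator."""

import math

import numpy as np
import pytest

from emresilience.core import GAConfig, IndicatorPanel, StandardizedPanel
from emresilience.measure import (
    DegenerateSpreadError,
    assign_levels,
    dimension_scores,
    entropy_topsis,
    index_weights,
    jenks_breaks,
    jenks_breaks_bruteforce,
    resilience_scores,
    run_measure,
)
from emresilience.preprocess import standardize
from emresilience.synthetic import SyntheticSpec, make_panel
from conftest import make_scheme


def std_from_values(values, scheme=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return StandardizedPanel(
        [f"R{i}" for i in range(m)],
        scheme or make_scheme(n),
        values,
        np.zeros(n),
        np.ones(n),
    )


@pytest.fixture(scope="module")
def synth_std():
    panel, _ = make_panel(SyntheticSpec(missing_rate=0.0, seed=21))
    return standardize(panel)


CFG = GAConfig(seed=9, max_iterations=60)


class TestIndexWeights:
    def test_duplicate_indicators_get_equal_values(self, rng):
        base = rng.uniform(0, 1, (6, 3))
        values = np.column_stack([base, base[:, 0]])  # col 3 copies col 0
        proj, w = index_weights(std_from_values(values), CFG)
        assert proj[0] == pytest.approx(proj[3], abs=1e-6)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(w >= 0)

    def test_fixed_seed_reproducible(self, synth_std):
        p1, w1 = index_weights(synth_std, CFG)
        p2, w2 = index_weights(synth_std, CFG)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(w1, w2)

    def test_column_scale_invariance_through_standardization(self, rng):
        values = rng.uniform(10, 20, (8, 4))
        panel = IndicatorPanel([f"R{i}" for i in range(8)], make_scheme(4), values)
        scaled = panel.copy()
        scaled.values[:, 2] *= 37.0
        p1, _ = index_weights(standardize(panel), CFG)
        p2, _ = index_weights(standardize(scaled), CFG)
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestResilienceScores:
    def test_identical_regions_score_equally(self, rng):
        values = rng.uniform(0, 1, (5, 4))
        values[3] = values[1]
        s = resilience_scores(std_from_values(values), CFG)
        assert s[3] == pytest.approx(s[1], abs=1e-6)

    def test_dominant_region_scores_highest(self, rng):
        values = rng.uniform(0.1, 0.7, (6, 4))
        values[2] = 1.0  # dominates every indicator
        values[0] = 0.0
        s = resilience_scores(std_from_values(values), CFG)
        assert np.argmax(s) == 2

    def test_row_permutation_permutes_scores(self, synth_std):
        perm = np.random.default_rng(0).permutation(synth_std.n_regions)
        shuffled = StandardizedPanel(
            [synth_std.region_labels[i] for i in perm],
            list(synth_std.scheme),
            synth_std.values[perm],
            synth_std.col_min,
            synth_std.col_max,
        )
        s1 = resilience_scores(synth_std, CFG)
        s2 = resilience_scores(shuffled, CFG)
        np.testing.assert_allclose(s2, s1[perm], atol=1e-9)


class TestDimensionScores:
    def test_unknown_dimension_rejected(self, synth_std):
        with pytest.raises(ValueError, match="unknown dimension"):
            dimension_scores(synth_std, "velocity", CFG)

    def test_single_indicator_dimension_rejected(self):
        scheme = make_scheme(3, dimensions=["resistance", "resistance", "restore"])
        std = std_from_values(np.random.default_rng(0).uniform(0, 1, (5, 3)), scheme)
        with pytest.raises(ValueError, match="restore"):
            dimension_scores(std, "restore", CFG)

    def test_degenerate_dimension_flagged(self):
        scheme = make_scheme(4, dimensions=["resistance"] * 2 + ["restore"] * 2)
        values = np.random.default_rng(0).uniform(0, 1, (5, 4))
        values[:, 0] = 0.3  # resistance block identical across regions
        values[:, 1] = 0.6
        std = std_from_values(values, scheme)
        with pytest.raises(DegenerateSpreadError):
            dimension_scores(std, "resistance", CFG)

    def test_composite_differs_from_weighted_dimension_mean(self, synth_std):
        report = run_measure(synth_std, CFG, comparator=False)
        assert np.any(np.abs(report.non_additivity) > 1e-6)
        assert set(report.dimension_scores) == {
            "resistance", "restore", "adaptability", "collaborative"
        }


class TestJenks:
    def test_two_well_separated_groups(self):
        result = jenks_breaks(np.array([1.0, 1.1, 9.0, 9.1]), 2)
        np.testing.assert_allclose(result.breaks, [9.0])
        assert result.gvf > 0.99
        np.testing.assert_array_equal(result.labels, [2, 2, 1, 1])

    def test_singleton_classes_have_perfect_fit(self):
        result = jenks_breaks(np.array([1.0, 4.0, 9.0]), 3)
        assert result.gvf == pytest.approx(1.0)

    def test_k_exceeding_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks(np.array([1.0, 1.0, 2.0]), 3)

    @pytest.mark.parametrize("m,k", [(6, 2), (9, 3), (12, 5)])
    def test_dp_matches_exhaustive_partition_search(self, m, k, rng):
        for _ in range(20):
            values = rng.uniform(0, 100, m)
            result = jenks_breaks(values, k)
            bf_breaks, bf_sse = jenks_breaks_bruteforce(values, k)
            np.testing.assert_allclose(result.breaks, bf_breaks)
            sse_total = ((values - values.mean()) ** 2).sum()
            np.testing.assert_allclose(
                (1 - result.gvf) * sse_total, bf_sse, atol=1e-9
            )

    def test_levels_follow_published_threshold_pattern(self):
        breaks = np.array([0.034, 0.051, 0.081, 0.131])
        assert assign_levels(np.array([0.14]), breaks)[0] == 1
        assert assign_levels(np.array([0.05]), breaks)[0] == 4
        assert assign_levels(np.array([0.02]), breaks)[0] == 5
        # boundary values belong to the class they open
        assert assign_levels(np.array([0.131]), breaks)[0] == 1
        assert assign_levels(np.array([0.081]), breaks)[0] == 2


class TestEntropyTopsis:
    def test_uniform_column_has_zero_weight(self):
        values = np.array([[0.5, 0.1], [0.5, 0.9], [0.5, 0.3]])
        w, _ = entropy_topsis(std_from_values(values))
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[1] == pytest.approx(1.0)

    def test_concentrated_column_dominates(self):
        values = np.array([[1.0, 0.4], [0.0, 0.6], [0.0, 0.5]])
        w, _ = entropy_topsis(std_from_values(values))
        assert w[0] > w[1]

    def test_hand_computed_four_by_three_panel(self):
        X = np.array([
            [0.2, 0.0, 1.0],
            [0.4, 1.0, 0.0],
            [0.6, 0.5, 0.5],
            [0.8, 0.5, 0.5],
        ])
        # spreadsheet-style independent computation
        m, n = X.shape
        e = []
        for j in range(n):
            col = X[:, j]
            p = col / col.sum()
            e.append(-sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(m))
        d = [1 - ej for ej in e]
        w_hand = np.array([dj / sum(d) for dj in d])
        V = X * w_hand
        ideal, anti = V.max(axis=0), V.min(axis=0)
        dp = np.sqrt(((V - ideal) ** 2).sum(axis=1))
        dm = np.sqrt(((V - anti) ** 2).sum(axis=1))
        closeness_hand = dm / (dp + dm)

        w, closeness = entropy_topsis(std_from_values(X))
        np.testing.assert_allclose(w, w_hand, atol=1e-12)
        np.testing.assert_allclose(closeness, closeness_hand, atol=1e-12)
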