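import itertools
import math

import numpy as np
import pytest

from episeq.errors import EpiseqError
from episeq.evaluation import auc
from episeq.fusion import (
    DEFAULT_WEIGHTS,
    FUSION_ORDER,
    SIGMA_EPSILON,
    NormalizationParams,
    enumerate_weight_grid,
    fit_normalization,
    fuse_mean,
    fuse_median,
    fuse_weighted,
    grid_count,
    grid_search_weights,
    normalize_matrix,
    normalize_per_instance,
    normalize_score,
)


class TestNormalizationFit:
    def test_population_moments(self):
        norm = fit_normalization([np.array([0.0, 1.0])])
        assert norm.mu[0] == pytest.approx(0.5)
        assert norm.sigma[0] == pytest.approx(0.5)  # ddof=0

    def test_constant_scores_floored_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            norm = fit_normalization([np.array([0.3, 0.3])])
        assert norm.sigma[0] == SIGMA_EPSILON
        assert "floored" in caplog.text

    def test_shift_invariance(self, rng):
        scores = rng.random(50)
        a = fit_normalization([scores])
        b = fit_normalization([scores + 0.2])
        assert b.mu[0] == pytest.approx(a.mu[0] + 0.2)
        assert b.sigma[0] == pytest.approx(a.sigma[0])

    def test_too_few_scores_rejected(self):
        with pytest.raises(EpiseqError):
            fit_normalization([np.array([0.5])])


class TestNormalizeScore:
    def test_mu_maps_to_half(self):
        assert normalize_score(0.37, mu=0.37, sigma=0.1) == pytest.approx(0.5)

    def test_saturation_limits(self):
        assert normalize_score(1e9, 0.5, 0.1) == pytest.approx(1.0)
        assert normalize_score(-1e9, 0.5, 0.1) == pytest.approx(0.0)

    def test_symmetric_pair_sums_to_one(self):
        lo = normalize_score(0.5 - 0.2, 0.5, 0.1)
        hi = normalize_score(0.5 + 0.2, 0.5, 0.1)
        assert lo + hi == pytest.approx(1.0)

    def test_strictly_monotone(self, rng):
        s = np.sort(rng.random(100))
        out = normalize_score(s, mu=0.4, sigma=0.2)
        assert (np.diff(out) > 0).all()

    def test_per_instance_scope_is_monotone_within_instance(self, rng):
        raw = rng.random((5, 30))
        out = normalize_per_instance(raw)
        for j in range(raw.shape[1]):
            order_raw = np.argsort(raw[:, j])
            order_out = np.argsort(out[:, j])
            np.testing.assert_array_equal(order_raw, order_out)


class TestCombination:
    def test_degenerate_weight_reproduces_subclassifier(self, rng):
        s = rng.random(4)
        for i in range(4):
            w = np.zeros(4)
            w[i] = 1.0
            assert fuse_weighted(s, w) == pytest.approx(s[i])

    def test_convexity_on_equal_scores(self):
        s = np.full(3, 0.42)
        assert fuse_weighted(s, np.array([0.2, 0.3, 0.5])) == pytest.approx(0.42)

    def test_two_score_average(self):
        assert fuse_weighted(
            np.array([0.2, 0.8]), np.array([0.5, 0.5])
        ) == pytest.approx(0.5)

    def test_dimension_mismatch(self):
        with pytest.raises(EpiseqError):
            fuse_weighted(np.array([0.2, 0.8]), np.array([1.0]))

    def test_mean_and_median(self):
        s = np.array([0.2, 0.4, 0.9])
        assert fuse_mean(s) == pytest.approx(0.5)
        assert fuse_median(s) == pytest.approx(0.4)
        single = np.array([0.7])
        assert fuse_mean(single) == pytest.approx(0.7)
        assert fuse_median(single) == pytest.approx(0.7)

    def test_mean_equals_uniform_weights(self, rng):
        s = rng.random((6, 10))
        np.testing.assert_allclose(
            fuse_mean(s), fuse_weighted(s, np.full(6, 1 / 6))
        )

    def test_empty_input_rejected(self):
        with pytest.raises(EpiseqError):
            fuse_mean(np.empty((0, 3)))

    def test_weighted_bounded_by_componentwise_extremes(self, rng):
        s = rng.random((5, 20))
        w = rng.random(5)
        w /= w.sum()
        fused = fuse_weighted(s, w)
        assert (fused <= s.max(axis=0) + 1e-12).all()
        assert (fused >= s.min(axis=0) - 1e-12).all()


class TestWeightGrid:
    def test_k2_half_step(self):
        grid = enumerate_weight_grid(2, 0.5)
        assert grid.shape == (3, 2)
        assert {tuple(row) for row in grid} == {(0, 1), (0.5, 0.5), (1, 0)}

    def test_k3_brute_force_oracle(self):
        # oracle: enumerate all multiples of step directly
        step = 0.5
        oracle = {
            (a * step, b * step, c * step)
            for a, b, c in itertools.product(range(3), repeat=3)
            if a + b + c == 2
        }
        grid = enumerate_weight_grid(3, step)
        assert {tuple(np.round(r, 10)) for r in grid} == oracle
        assert len(grid) == 6

    def test_k3_fine_step_count(self):
        grid = enumerate_weight_grid(3, 0.05)
        assert len(grid) == 231  # C(22, 2)
        np.testing.assert_allclose(grid.sum(axis=1), 1.0, atol=1e-9)
        # each weight a multiple of the step
        np.testing.assert_allclose(
            np.round(grid / 0.05) * 0.05, grid, atol=1e-9
        )

    def test_closed_form_count(self):
        assert grid_count(7, 0.05) == math.comb(26, 6)
        assert grid_count(3, 0.05) == 231

    def test_bad_step_rejected(self):
        with pytest.raises(EpiseqError):
            enumerate_weight_grid(3, 0.3)

    def test_lexicographic_order(self):
        grid = enumerate_weight_grid(3, 0.5)
        as_tuples = [tuple(r) for r in grid]
        assert as_tuples == sorted(as_tuples)


class TestGridSearch:
    def test_perfect_subclassifier_gets_full_weight(self, rng):
        n = 200
        labels = rng.integers(0, 2, n)
        antigens = np.repeat(["a", "b"], n // 2)
        perfect = labels * 0.8 + 0.1
        # noise amplitude exceeds the signal gap, so any dilution of the
        # perfect sub-classifier strictly loses ranking quality
        noise1, noise2 = rng.random(n) * 4, rng.random(n) * 4
        w = grid_search_weights(
            np.vstack([noise1, perfect, noise2]), labels, antigens, step=0.25
        )
        np.testing.assert_allclose(w, [0.0, 1.0, 0.0])

    def test_identical_subclassifiers_tie_break_lexicographic(self, rng):
        n = 100
        labels = rng.integers(0, 2, n)
        antigens = np.repeat(["a"], n)
        s = labels * 0.6 + rng.random(n) * 0.3
        w = grid_search_weights(np.vstack([s, s]), labels, antigens, step=0.5)
        # objective constant along the exchange; smallest vector wins
        np.testing.assert_allclose(w, [0.0, 1.0])

    def test_published_default_weights(self):
        assert len(DEFAULT_WEIGHTS) == len(FUSION_ORDER) == 7
        assert DEFAULT_WEIGHTS == (0.1, 0.0, 0.5, 0.0, 0.1, 0.2, 0.1)
        assert sum(DEFAULT_WEIGHTS) == pytest.approx(1.0)
        assert dict(zip(FUSION_ORDER, DEFAULT_WEIGHTS))["evolutionary"] == 0.5


def test_auc_invariant_under_normalization(rng):
    """Monotone normalization cannot change a ranking metric."""
    scores = rng.random(120)
    labels = rng.integers(0, 2, 120)
    norm = NormalizationParams(np.array([0.4]), np.array([0.17]))
    transformed = normalize_matrix(scores[None, :], norm)[0]
    assert auc(transformed, labels) == pytest.approx(auc(scores, labels))
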