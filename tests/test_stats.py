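"""Per-pixel correlation statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from gelcorr import (
    ExternalVariable,
    TestConfig,
    correlation_map,
    p_permutation,
    p_ttest,
    permutation_p_map,
    product_map,
    run_analysis,
    sigma_norm_map,
    spearman_rho,
)
from gelcorr.errors import (
    InsufficientSamplesError,
    UndefinedCorrelationError,
    UnknownMapError,
)
from .conftest import make_stack


def oracle_spearman(x, y):
    """Independent route: scipy's own Spearman implementation."""
    return sps.spearmanr(x, y).statistic


def oracle_exhaustive_p(x, y):
    """Brute force: enumerate every ordering of y with scipy's spearman."""
    obs = abs(oracle_spearman(x, y))
    n = len(y)
    count = sum(
        abs(oracle_spearman(x, perm)) >= obs - 1e-12
        for perm in itertools.permutations(y)
    )
    return count / math.factorial(n)


class TestSpearmanRho:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]) == 1.0

    def test_rank_difference_formula(self):
        # sum d^2 = 4 -> 1 - 24/120 = 0.8
        assert np.isclose(spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]), 0.8)

    def test_midranks_for_ties(self):
        assert np.isclose(spearman_rho([1, 2, 2, 3], [1, 2, 3, 4]), math.sqrt(0.9))

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientSamplesError):
            spearman_rho([1, 2], [2, 1])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.integers(0, 6, n).astype(float)  # frequent ties
        y = rng.normal(size=n)
        if np.unique(x).size < 2:
            x[0] += 1
        assert np.isclose(spearman_rho(x, y), oracle_spearman(x, y), atol=1e-12)


class TestCorrelationMap:
    def test_linear_pixel_has_rho_one(self, noise_stack):
        var = ExternalVariable("v", np.arange(6.0))
        noise_stack.data[:, 5, 5] = 10 + 2 * var.values
        rho, validity = correlation_map(noise_stack, var)
        assert rho[5, 5] == 1.0
        assert validity[5, 5]

    def test_null_noise_mean_rho_near_zero(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(5, 25, 40))  # 1000 pixels
        stack = make_stack(data)
        rho, _ = correlation_map(stack, ExternalVariable("v", np.arange(5.0)))
        assert abs(np.nanmean(rho)) < 0.05

    def test_min_valid_masks_sparse_pixels(self, noise_stack):
        noise_stack.valid[:3, 2, 2] = False  # 3 of 6 samples valid
        var = ExternalVariable("v", np.arange(6.0))
        rho, validity = correlation_map(noise_stack, var, min_valid=4)
        assert not validity[2, 2] and np.isnan(rho[2, 2])
        rho2, validity2 = correlation_map(noise_stack, var, min_valid=3)
        assert validity2[2, 2] and np.isfinite(rho2[2, 2])

    def test_partial_validity_uses_valid_subset(self, noise_stack):
        var = ExternalVariable("v", np.arange(6.0))
        noise_stack.valid[0, 4, 4] = False
        rho, _ = correlation_map(noise_stack, var, min_valid=3)
        expected = oracle_spearman(noise_stack.data[1:, 4, 4], var.values[1:])
        assert np.isclose(rho[4, 4], expected, atol=1e-12)

    def test_constant_column_masked(self, noise_stack):
        noise_stack.data[:, 1, 1] = 7.0
        rho, validity = correlation_map(
            noise_stack, ExternalVariable("v", np.arange(6.0))
        )
        assert not validity[1, 1] and np.isnan(rho[1, 1])


class TestSigmaNorm:
    def test_examples(self):
        data = np.zeros((3, 1, 3))
        data[:, 0, 0] = [5, 5, 5]          # std 0
        data[:, 0, 1] = [0, 2, 4]          # std 2
        data[:, 0, 2] = [0, 4, 8]          # std 4 -> global max
        out = sigma_norm_map(make_stack(data))
        assert np.allclose(out[0], [0.0, 0.5, 1.0])

    def test_max_is_exactly_one(self, noise_stack):
        out = sigma_norm_map(noise_stack)
        assert np.nanmax(out) == 1.0


class TestPTtest:
    def test_rho_zero_gives_one(self):
        for n in (4, 5, 10):
            assert p_ttest(0.0, n) == 1.0

    def test_against_student_t_oracle(self):
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        expected = 2 * sps.t.sf(t, df=3)
        assert np.isclose(p_ttest(0.8, 5), expected, atol=1e-10)
        assert np.isclose(expected, 0.1041, atol=5e-4)

    def test_two_sided_symmetry(self):
        assert p_ttest(-0.8, 5) == p_ttest(0.8, 5)

    def test_perfect_correlation_clamps(self):
        assert p_ttest(1.0, 5) == np.finfo(float).tiny

    def test_small_n_raises(self):
        with pytest.raises(InsufficientSamplesError):
            p_ttest(0.5, 3)


class TestPermutation:
    def test_monotone_n4(self):
        assert p_permutation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(2 / 24)

    def test_monotone_n5(self):
        p = p_permutation([1, 2, 3, 4, 5], [0, 1, 4, 9, 16])
        assert p == pytest.approx(2 / 120)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_exhaustive_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        x = rng.integers(0, 4, n).astype(float)  # ties included
        y = rng.normal(size=n)
        if np.unique(x).size < 2:
            x[0] += 1
        assert p_permutation(x, y) == pytest.approx(oracle_exhaustive_p(x, y))

    def test_monte_carlo_reproducible_and_close_to_exact(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        cfg = TestConfig(n_permutations=999, exhaustive_limit=2, seed=7)
        p1 = p_permutation(x, y, cfg)
        p2 = p_permutation(x, y, cfg)
        assert p1 == p2  # seeded, reproducible
        exact = p_permutation(x, y, TestConfig())  # 720 <= 40320 -> exhaustive
        assert abs(p1 - exact) <= 3 * math.sqrt(exact * (1 - exact) / 999) + 1 / 999

    def test_map_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(5, 4, 4))
        stack = make_stack(data)
        var = ExternalVariable("v", np.array([0.0, 2.0, 4.0, 6.0, 8.0]))
        pmap = permutation_p_map(stack, var, TestConfig(seed=1))
        for y in range(4):
            for x in range(4):
                assert pmap[y, x] == pytest.approx(
                    p_permutation(data[:, y, x], var.values)
                )


class TestProductsAndPipeline:
    def test_direct_product(self):
        maps = {
            "rho": np.array([[1.0]]),
            "sigma_norm": np.array([[0.5]]),
            "p": np.array([[np.finfo(float).tiny]]),
        }
        out = product_map(maps, ["rho", "significance", "sigma_norm"])
        assert np.isclose(out[0, 0], 0.5)

    def test_zero_factor_absorbs(self):
        maps = {"rho": np.array([[0.0]]), "sigma_norm": np.array([[0.9]])}
        assert product_map(maps, ["rho", "sigma_norm"])[0, 0] == 0.0

    def test_unknown_factor_raises(self):
        with pytest.raises(UnknownMapError):
            product_map({"rho": np.zeros((2, 2))}, ["rho", "bogus"])

    def test_cv_suppresses_strong_but_flat_correlation(self):
        """A perfectly correlated but nearly constant pixel scores low in CV."""
        data = np.zeros((5, 1, 2))
        v = np.arange(5.0)
        data[:, 0, 0] = 100 + 1e-4 * v   # strong rho, negligible variation
        data[:, 0, 1] = 100 + 50 * v     # strong rho, big variation
        stack = make_stack(data)
        maps = run_analysis(stack, ExternalVariable("v", v), scheme="none")
        cv = maps.products["CV"]
        assert maps.rho[0, 0] == 1.0 and maps.rho[0, 1] == 1.0
        assert cv[0, 0] < 0.01 * cv[0, 1]

    def test_negating_variable_negates_rho_keeps_p(self, noise_stack):
        var = ExternalVariable("v", np.arange(6.0))
        neg = ExternalVariable("v", -np.arange(6.0))
        a = run_analysis(noise_stack, var, scheme="median")
        b = run_analysis(noise_stack, neg, scheme="median")
        assert np.array_equal(a.rho, -b.rho)
        assert np.array_equal(a.p, b.p, equal_nan=True)

    def test_monotone_transform_leaves_maps_bit_identical(self, noise_stack):
        hours = np.arange(6.0)
        a = run_analysis(noise_stack, ExternalVariable("v", hours))
        b = run_analysis(noise_stack, ExternalVariable("v", hours**2))
        assert np.array_equal(a.rho, b.rho, equal_nan=True)
        assert np.array_equal(a.p, b.p, equal_nan=True)

    def test_common_global_scaling_leaves_maps_unchanged(self, noise_stack):
        var = ExternalVariable("v", np.arange(6.0))
        scaled = make_stack(noise_stack.data * 3.7)
        for scheme in ("none", "mean", "median", "zscore"):
            a = run_analysis(noise_stack, var, scheme=scheme)
            b = run_analysis(scaled, var, scheme=scheme)
            assert np.allclose(a.rho, b.rho, equal_nan=True)

    def test_ttest_pipeline_p_from_rho(self, noise_stack):
        var = ExternalVariable("v", np.arange(6.0))
        maps = run_analysis(noise_stack, var, cfg=TestConfig(test="t_test"))
        ok = maps.validity
        assert np.allclose(maps.p[ok], p_ttest(maps.rho[ok], 6))

    def test_meta_records_provenance(self, noise_stack):
        cfg = TestConfig(seed=11, n_permutations=199)
        maps = run_analysis(noise_stack, ExternalVariable("hrs", np.arange(6.0)),
                            scheme="mean", cfg=cfg)
        assert maps.meta["variable"] == "hrs"
        assert maps.meta["normalization"] == "mean"
        assert maps.meta["seed"] == 11
        assert maps.meta["n_permutations"] == 199
        assert maps.meta["n"] == 6
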