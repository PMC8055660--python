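"""Evaluation-harness tests against closed forms and enumeration oracles."""

import numpy as np
import pytest
from scipy import stats

from falff_prognosis.evaluation import (
    bootstrap_ci,
    compare_to_zero_order,
    mad,
    r_squared_with_test,
    signed_rank_test,
    treatment_effect_test,
    zero_order_deviations,
)
from .oracles import signed_rank_p_enumeration


class TestMad:
    def test_worked_example(self):
        assert mad([0.5, 0.6, 0.7], [0.4, 0.8, 0.7]) == pytest.approx(0.1)

    def test_perfect_predictions(self):
        assert mad([0.1, 0.9], [0.1, 0.9]) == 0.0

    def test_even_n_midpoint(self):
        assert mad([0.1, 0.3], [0.0, 0.0]) == pytest.approx(0.2)

    def test_translation_invariance_and_scale_equivariance(self):
        rng = np.random.default_rng(0)
        p, a = rng.random(11), rng.random(11)
        base = mad(p, a)
        assert mad(p + 0.3, a + 0.3) == pytest.approx(base)
        assert mad(2.5 * p, 2.5 * a) == pytest.approx(2.5 * base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mad([0.1], [0.1, 0.2])


class TestZeroOrder:
    def test_worked_example(self):
        np.testing.assert_allclose(
            zero_order_deviations([0.2, 0.4, 0.6]), [0.2, 0.0, 0.2], atol=1e-12
        )

    def test_constant_vector(self):
        np.testing.assert_allclose(zero_order_deviations([0.5, 0.5, 0.5]), 0.0)

    def test_two_point_mad(self):
        assert mad(zero_order_deviations([0.0, 1.0]), [0.0, 0.0]) == pytest.approx(0.5)


class TestSignedRank:
    @pytest.mark.parametrize("n,expected", [(10, 2**-10), (20, 2**-20)])
    def test_uniformly_better_exact_p(self, n, expected):
        rng = np.random.default_rng(1)
        worse = rng.uniform(0.2, 0.4, n)
        better = worse - rng.uniform(0.01, 0.1, n)
        assert signed_rank_test(better, worse, "less") == pytest.approx(expected)

    def test_identical_gives_one(self):
        x = np.linspace(0.1, 0.5, 8)
        with pytest.warns(UserWarning):
            assert signed_rank_test(x, x.copy(), "less") == 1.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(n)  # continuous: no ties, no zeros
        for alt in ("less", "greater"):
            assert signed_rank_test(d, alternative=alt) == pytest.approx(
                signed_rank_p_enumeration(d, alt)
            )

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_enumeration_with_ties_and_zeros(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.choice([-0.2, -0.1, 0.0, 0.1, 0.2, 0.3], size=9)
        if np.all(d == 0):
            d[0] = 0.1
        for alt in ("less", "greater"):
            assert signed_rank_test(d, alternative=alt) == pytest.approx(
                signed_rank_p_enumeration(d, alt)
            )

    def test_p_decreases_with_improvement(self):
        rng = np.random.default_rng(2)
        chance = rng.uniform(0.2, 0.5, 15)
        ps = []
        for improvement in (0.01, 0.05, 0.15):
            model = np.clip(chance - improvement + 0.005 * rng.standard_normal(15), 0, None)
            ps.append(signed_rank_test(model, chance, "less"))
        assert ps[0] >= ps[1] >= ps[2]


class TestCompareToZeroOrder:
    def test_better_model_small_p(self):
        rng = np.random.default_rng(3)
        actual = rng.uniform(0, 1, 20)
        pred = actual + 0.01 * rng.standard_normal(20)
        assert compare_to_zero_order(pred, actual) < 0.001

    def test_chance_model_large_p(self):
        actual = np.linspace(0.1, 0.9, 12)
        pred = np.full(12, actual.mean())  # exactly the zero-order model
        with pytest.warns(UserWarning):
            assert compare_to_zero_order(pred, actual) == 1.0

    def test_literal_variant_available(self):
        rng = np.random.default_rng(4)
        actual = rng.uniform(0, 1, 15)
        pred = actual + 0.05 * rng.standard_normal(15)
        p = compare_to_zero_order(pred, actual, zero_order_of="predicted")
        assert 0 < p <= 1


class TestRSquared:
    def test_perfect_positive(self):
        x = np.array([0.1, 0.4, 0.5, 0.9])
        r2, p = r_squared_with_test(x, x)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative_sidedness(self):
        x = np.array([0.1, 0.4, 0.5, 0.9])
        r2, p = r_squared_with_test(-x, x)
        assert r2 == pytest.approx(1.0)
        assert p > 0.99

    def test_closed_form_small_n(self):
        rng = np.random.default_rng(5)
        pred, actual = rng.random(5), rng.random(5)
        r = np.corrcoef(pred, actual)[0, 1]
        t = r * np.sqrt(3 / (1 - r**2))
        expected_p = stats.t.sf(t, df=3)
        r2, p = r_squared_with_test(pred, actual)
        assert r2 == pytest.approx(r**2, abs=1e-6)
        assert p == pytest.approx(expected_p, abs=1e-6)

    def test_constant_vector_warns(self):
        with pytest.warns(UserWarning):
            r2, p = r_squared_with_test([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert (r2, p) == (0.0, 1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        pred, actual = rng.random(10), rng.random(10)
        base = r_squared_with_test(pred, actual)[0]
        assert r_squared_with_test(3 * pred + 1, actual)[0] == pytest.approx(base)


class TestBootstrap:
    def test_perfect_model_collapsed_interval(self):
        x = np.linspace(0.1, 0.9, 10)
        lo, hi = bootstrap_ci(mad, x, x.copy(), n_boot=200, seed=0)
        assert lo == hi == 0.0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(7)
        p, a = rng.random(15), rng.random(15)
        assert bootstrap_ci(mad, p, a, seed=5) == bootstrap_ci(mad, p, a, seed=5)

    def test_r_squared_coverage(self):
        # nominal 95% interval should cover the population R^2 about 95% of
        # the time; checked by simulation at n = 50
        rho = 0.8
        n, n_sims = 50, 300
        covered = 0
        for s in range(n_sims):
            rng = np.random.default_rng(1000 + s)
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            lo, hi = bootstrap_ci(
                lambda p, a: np.corrcoef(p, a)[0, 1] ** 2, x, y, n_boot=400, seed=s
            )
            covered += lo <= rho**2 <= hi
        assert covered / n_sims == pytest.approx(0.95, abs=0.04)


class TestTreatmentEffect:
    def test_uniform_improvement_exact_p(self):
        pre = np.linspace(0.2, 0.6, 10)
        assert treatment_effect_test(pre, pre + 0.1) == pytest.approx(2**-10)

    def test_no_change(self):
        pre = np.linspace(0.2, 0.6, 8)
        with pytest.warns(UserWarning):
            assert treatment_effect_test(pre, pre.copy()) == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_mixed_signs_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pre = rng.uniform(0.2, 0.8, 7)
        post = pre + rng.standard_normal(7) * 0.1
        assert treatment_effect_test(pre, post) == pytest.approx(
            signed_rank_p_enumeration(post - pre, "greater")
        )
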