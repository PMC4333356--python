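import math

import numpy as np
import pytest

import rdgrow as rg
from rdgrow import GrowthModel, InitialCondition, Problem

from _oracles import exact_solution_images


def step_problem(growth, D=1e-3, k=0.105, C0=1.0, beta=0.2):
    return Problem(growth=growth, D=D, k=k, ic=InitialCondition.step(C0=C0, beta=beta))


class TestStepCoefficients:
    def test_leading_coefficient_is_covered_fraction(self):
        ic = InitialCondition.step(C0=1.0, beta=0.2)
        coeffs = rg.step_fourier_coefficients(ic, L0=1.0, n_max=5)
        assert coeffs[0] == pytest.approx(0.2, rel=1e-14)

    def test_first_mode_closed_form(self):
        ic = InitialCondition.step(C0=1.0, beta=0.2)
        coeffs = rg.step_fourier_coefficients(ic, L0=1.0, n_max=5)
        assert coeffs[1] == pytest.approx((2 / math.pi) * math.sin(0.2 * math.pi),
                                          rel=1e-14)
        assert coeffs[1] == pytest.approx(0.37420, abs=1e-5)

    def test_fully_covered_domain_has_only_constant_mode(self):
        ic = InitialCondition.step(C0=1.0, beta=1.0)
        coeffs = rg.step_fourier_coefficients(ic, L0=1.0, n_max=10)
        assert coeffs[0] == pytest.approx(1.0, rel=1e-14)
        assert np.max(np.abs(coeffs.values[1:])) < 1e-14

    def test_beta_beyond_domain_rejected(self):
        ic = InitialCondition.step(C0=1.0, beta=1.5)
        with pytest.raises(rg.ParameterError):
            rg.step_fourier_coefficients(ic, L0=1.0, n_max=5)


class TestGeneralCoefficients:
    def test_constant_profile(self):
        ic = InitialCondition.general(lambda x: 2.0)
        coeffs = rg.general_fourier_coefficients(ic, L0=1.0, n_max=6)
        assert coeffs[0] == pytest.approx(2.0, rel=1e-10)
        assert np.max(np.abs(coeffs.values[1:])) < 1e-9

    def test_step_as_general_matches_closed_form(self):
        step = InitialCondition.step(C0=1.0, beta=0.2)
        general = InitialCondition.general(lambda x: 1.0 if x < 0.2 else 0.0)
        a = rg.step_fourier_coefficients(step, L0=1.0, n_max=20)
        b = rg.general_fourier_coefficients(general, L0=1.0, n_max=20)
        assert np.allclose(a.values, b.values, atol=1e-8)

    def test_single_cosine_mode_orthogonality(self):
        ic = InitialCondition.general(lambda x: math.cos(math.pi * x))
        coeffs = rg.general_fourier_coefficients(ic, L0=1.0, n_max=6)
        assert coeffs[1] == pytest.approx(1.0, rel=1e-9)
        others = np.delete(coeffs.values, 1)
        assert np.max(np.abs(others)) < 1e-9


class TestEvaluateExact:
    def test_uniform_static_no_reaction_stays_uniform(self):
        p = step_problem(GrowthModel.static(1.0), k=0.0, beta=1.0)
        grid = np.linspace(0, 1, 11)
        for t in (0.0, 3.0, 50.0):
            prof = rg.evaluate_exact(p, grid, t, n_max=50)
            assert np.allclose(prof.values, 1.0, atol=1e-12)

    @pytest.mark.parametrize("growth", [
        GrowthModel.static(1.0),
        GrowthModel.exponential(1.0, 0.1),
        GrowthModel.linear(1.0, 0.05),
    ])
    def test_matches_image_oracle(self, growth):
        # dual route: cosine series vs method-of-images erfc representation
        p = step_problem(growth)
        for t in (1.0, 10.0):
            xi = np.linspace(0.0, 1.0, 21)
            prof = rg.evaluate_exact(p, xi, t, coordinate="xi")
            oracle = [exact_solution_images(p, x, t) for x in xi]
            assert np.allclose(prof.values, oracle, rtol=1e-9, atol=1e-12)

    def test_mass_law_random_parameters(self):
        # zero-flux ends: total mass must evolve as beta*C0*exp(k t)
        rng = np.random.default_rng(7)
        growths = [
            lambda: GrowthModel.static(rng.uniform(0.5, 2.0)),
            lambda: GrowthModel.exponential(rng.uniform(0.5, 2.0), rng.uniform(0.02, 0.3)),
            lambda: GrowthModel.linear(rng.uniform(0.5, 2.0), rng.uniform(0.01, 0.2)),
        ]
        for i in range(20):
            growth = growths[i % 3]()
            beta = rng.uniform(0.1, 0.9) * growth.L0
            C0 = rng.uniform(0.5, 2.0)
            k = rng.uniform(-0.2, 0.4)
            p = Problem(growth=growth, D=rng.uniform(1e-4, 1e-2), k=k,
                        ic=InitialCondition.step(C0=C0, beta=beta))
            t = rng.uniform(0.5, 10.0)
            xi = np.linspace(0.0, 1.0, 4001)
            prof = rg.evaluate_exact(p, xi, t, n_max=1000, coordinate="xi")
            mass = rg.total_mass(prof, growth)
            assert mass == pytest.approx(beta * C0 * math.exp(k * t), rel=1e-3)

    def test_boundary_flux_vanishes(self):
        # every cosine mode has zero slope at both ends; a one-sided
        # difference with step h picks up only O(h * C'') truncation plus
        # round-off, so h = 1e-8 resolves the zero-flux condition sharply
        p = step_problem(GrowthModel.exponential(1.0, 0.1))
        h = 1e-8
        for t in (1.0, 10.0):
            prof = rg.evaluate_exact(p, np.array([0.0, h, 1.0 - h, 1.0]), t,
                                     n_max=1000, coordinate="xi")
            L = p.growth.length(t)
            slope_left = (prof.values[1] - prof.values[0]) / h
            slope_right = (prof.values[3] - prof.values[2]) / h
            tol = 1e-6 * 1.0 / L
            assert abs(slope_left) < tol and abs(slope_right) < tol

    def test_small_growth_rate_approaches_static(self):
        p_static = step_problem(GrowthModel.static(1.0), k=0.0)
        p_slow = step_problem(GrowthModel.exponential(1.0, 1e-8), k=0.0)
        x = np.linspace(0.0, 1.0, 101)
        a = rg.evaluate_exact(p_static, x, 10.0, n_max=500)
        b = rg.evaluate_exact(p_slow, x, 10.0, n_max=500)
        assert np.max(np.abs(a.values - b.values)) < 1e-5

    def test_static_density_uniformizes(self):
        p = step_problem(GrowthModel.static(1.0), k=0.0)
        x = np.linspace(0.0, 1.0, 101)
        prof = rg.evaluate_exact(p, x, 5000.0, n_max=500)
        assert np.allclose(prof.values, 0.2, atol=1e-9)

    def test_overflow_guard(self):
        p = step_problem(GrowthModel.static(1.0), k=1.0)
        with pytest.raises(rg.OverflowGuardError):
            rg.evaluate_exact(p, np.linspace(0, 1, 5), 1000.0, n_max=10)

    def test_grid_outside_domain_rejected(self):
        p = step_problem(GrowthModel.static(1.0))
        with pytest.raises(rg.InputError):
            rg.evaluate_exact(p, np.linspace(0.0, 2.0, 5), 1.0)


class TestCaseFormulaEquivalence:
    @pytest.mark.parametrize("case", ["static", "exponential", "linear"])
    def test_unified_equals_printed_formula(self, case):
        # the unified growth-factor identity exp(kt) L0/L(t) must reproduce
        # the per-case exponents, including the linear case's exp(-k L0 / b)
        # coefficient factor, to round-off
        rng = np.random.default_rng(11)
        for _ in range(50):
            L0 = rng.uniform(0.5, 2.0)
            if case == "static":
                growth = GrowthModel.static(L0)
            elif case == "exponential":
                growth = GrowthModel.exponential(L0, rng.uniform(0.02, 0.3))
            else:
                growth = GrowthModel.linear(L0, rng.uniform(0.01, 0.2))
            p = Problem(growth=growth, D=rng.uniform(1e-4, 1e-2),
                        k=rng.uniform(-0.3, 0.5),
                        ic=InitialCondition.step(C0=rng.uniform(0.5, 2.0),
                                                 beta=rng.uniform(0.1, 0.95) * L0))
            t = rng.uniform(0.0, 20.0)
            xi = np.linspace(0.0, 1.0, 101)
            a = rg.evaluate_exact(p, xi, t, n_max=200, coordinate="xi")
            b = rg.evaluate_case_formula(p, xi, t, n_max=200, coordinate="xi")
            scale = np.max(np.abs(a.values))
            assert np.max(np.abs(a.values - b.values)) <= 1e-10 * scale

    def test_custom_growth_unsupported(self):
        growth = GrowthModel.custom(1.0, lambda t: 1.0 + 0.1 * t)
        p = step_problem(growth)
        with pytest.raises(rg.UnsupportedCaseError):
            rg.evaluate_case_formula(p, np.linspace(0, 1, 5), 1.0, coordinate="xi")


class TestTwoTermApproximation:
    def test_fully_covered_reduces_to_pure_growth(self):
        p = step_problem(GrowthModel.static(1.0), k=0.05, beta=1.0)
        prof = rg.two_term_longtime_approx(p, np.linspace(0, 1, 7), 10.0)
        assert np.allclose(prof.values, math.exp(0.5), rtol=1e-12)

    def test_accurate_at_long_times_on_static_domain(self):
        p = step_problem(GrowthModel.static(1.0), D=1e-3, k=0.0)
        x = np.linspace(0.0, 1.0, 201)
        full = rg.evaluate_exact(p, x, 500.0, n_max=1000)
        two = rg.two_term_longtime_approx(p, x, 500.0)
        assert np.max(np.abs(full.values - two.values)) <= 1e-6

    def test_poor_at_time_zero(self):
        p = step_problem(GrowthModel.static(1.0), D=1e-3, k=0.0)
        x = np.linspace(0.0, 1.0, 201)
        full = rg.evaluate_exact(p, x, 0.0, n_max=1000)
        two = rg.two_term_longtime_approx(p, x, 0.0)
        assert np.max(np.abs(full.values - two.values)) > 0.1

    def test_refuses_growing_domain(self):
        p = step_problem(GrowthModel.exponential(1.0, 0.1))
        with pytest.raises(rg.UnsupportedCaseError):
            rg.two_term_longtime_approx(p, np.linspace(0, 1, 5), 100.0)
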