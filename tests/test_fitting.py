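"""Cubic fitting layer: recovery, evaluation, root finding, minimisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from lactacurve import fitting
from lactacurve.errors import InsufficientDataError, LevelNotReachedError
from lactacurve.fitting import (
    CubicFit,
    eval_fit,
    fit_cubic,
    minimize_on,
    solve_level,
)

XS7 = np.array([175.0 + 25.0 * i for i in range(7)])
QUAD = 0.00025 * (XS7 - 175.0) ** 2 + 1.0  # closed-form quadratic in raw units


class TestFitCubic:
    def test_noiseless_quadratic_recovered_exactly(self):
        fit = fit_cubic(XS7, QUAD)
        # 0.00025(x-175)^2 + 1 = 8.65625 - 0.0875 x + 0.00025 x^2
        assert fit.coef == pytest.approx([8.65625, -0.0875, 0.00025, 0.0], abs=1e-8)
        assert fit.r_squared == 1.0
        assert fit.n_points == 7
        assert (fit.domain_lo, fit.domain_hi) == (175.0, 325.0)

    def test_four_points_interpolated(self):
        rng = np.random.default_rng(1)
        xs = np.array([175.0, 200.0, 225.0, 250.0])
        ys = rng.normal(2.0, 1.0, 4)
        fit = fit_cubic(xs, ys)
        assert eval_fit(fit, xs, warn=False) == pytest.approx(ys, abs=1e-7)
        assert fit.r_squared == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ys = np.sort(rng.normal(3.0, 1.5, 7)) + rng.normal(0, 0.3, 7)
        fit = fit_cubic(XS7, ys)
        expected = oracles.normal_equations_cubic(XS7, ys)
        assert fit.coef == pytest.approx(expected, rel=1e-7, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_cubic(XS7[:3], QUAD[:3])

    def test_constant_ys_degenerate(self):
        fit = fit_cubic(XS7, np.full(7, 2.5))
        assert fit.r_squared == 1.0
        assert fit.degenerate

    def test_non_increasing_xs_rejected(self):
        xs = np.array([175.0, 200.0, 200.0, 225.0, 250.0])
        with pytest.raises(ValueError):
            fit_cubic(xs, np.arange(5.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        shift=st.floats(-5, 5, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
    )
    def test_affine_equivariance(self, shift, scale):
        """Shifting ys moves only c0; scaling ys scales every coefficient."""
        rng = np.random.default_rng(42)
        ys = np.cumsum(rng.uniform(0.1, 1.0, 7)) + 1.0
        base = fit_cubic(XS7, ys)
        shifted = fit_cubic(XS7, ys + shift)
        assert shifted.c0 == pytest.approx(base.c0 + shift, abs=1e-6)
        assert shifted.coef[1:] == pytest.approx(base.coef[1:], rel=1e-6, abs=1e-9)
        scaled = fit_cubic(XS7, ys * scale)
        assert scaled.coef == pytest.approx(base.coef * scale, rel=1e-6, abs=1e-9)

    def test_r_squared_decreases_with_noise_in_expectation(self):
        truth = 1.0 + 0.0004 * (XS7 - 175.0) ** 2
        r2 = {}
        for sd in (0.1, 0.4):
            vals = []
            for rep in range(100):
                rng = np.random.default_rng(1000 + rep)
                vals.append(fit_cubic(XS7, truth + rng.normal(0, sd, 7)).r_squared)
            r2[sd] = np.mean(vals)
        assert r2[0.4] < r2[0.1] <= 1.0


class TestEvalFit:
    @pytest.fixture
    def quad_fit(self):
        return fit_cubic(XS7, QUAD)

    def test_closed_form_values(self, quad_fit):
        assert eval_fit(quad_fit, 175.0) == pytest.approx(1.0, abs=1e-9)
        assert eval_fit(quad_fit, 325.0) == pytest.approx(6.625, abs=1e-9)

    def test_matches_horner_oracle_at_midpoint(self, quad_fit):
        x = 250.0
        c = quad_fit.coef
        horner = ((c[3] * x + c[2]) * x + c[1]) * x + c[0]
        assert eval_fit(quad_fit, x) == pytest.approx(horner, abs=1e-12)

    def test_extrapolation_warns(self, quad_fit):
        with pytest.warns(UserWarning, match="extrapolation"):
            eval_fit(quad_fit, 400.0)


class TestSolveLevel:
    def test_quadratic_level_four_closed_form(self):
        fit = fit_cubic(XS7, QUAD)
        x = solve_level(fit, 4.0)
        assert x == pytest.approx(175.0 + np.sqrt(12000.0), abs=1e-6)
        assert abs(eval_fit(fit, x) - 4.0) <= 1e-6

    def test_level_below_minimum_not_reached(self):
        fit = fit_cubic(XS7, QUAD)
        with pytest.raises(LevelNotReachedError):
            solve_level(fit, 0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_oracle_on_random_monotone_cubics(self, seed):
        rng = np.random.default_rng(seed)
        ys = np.cumsum(rng.uniform(0.2, 1.2, 7)) + 1.0
        fit = fit_cubic(XS7, ys)
        level = float(np.median(ys))
        expected = oracles.first_rising_crossing(
            fit.coef, level, fit.domain_lo, fit.domain_hi
        )
        assert expected is not None
        assert solve_level(fit, level) == pytest.approx(expected, abs=0.01)

    def test_multiple_crossings_take_smallest(self):
        # rising-falling-rising cubic: the level is crossed rising twice
        fit = CubicFit(c0=0.0, c1=0.9, c2=-0.09, c3=0.002, domain_lo=0.0,
                       domain_hi=40.0, r_squared=1.0, n_points=7)
        level = float(eval_fit(fit, 2.0))
        roots = [x.real for x in np.roots([fit.c3, fit.c2, fit.c1, fit.c0 - level])
                 if abs(x.imag) < 1e-9 and 0 <= x.real <= 40]
        rising = [x for x in roots if 0.9 - 0.18 * x + 0.006 * x * x > 0]
        assert len(rising) >= 2  # genuinely multi-crossing on rising limbs
        assert solve_level(fit, level) == pytest.approx(2.0, abs=1e-6)


class TestMinimizeOn:
    def test_parabola_interior_minimum(self):
        res = minimize_on(lambda x: (x - 250.0) ** 2, 175.0, 325.0)
        assert res.x == pytest.approx(250.0, abs=1e-6)
        assert res.value == pytest.approx(0.0, abs=1e-10)
        assert not res.boundary

    def test_lactate_equivalent_closed_form(self):
        fit = fit_cubic(XS7, QUAD)
        res = minimize_on(
            lambda x: eval_fit(fit, x, warn=False) / x,
            175.0, 325.0,
            critical_points=fitting.equivalent_critical_points(fit),
        )
        # argmin of p(x)/x for the quadratic: x* = sqrt(175² + 1/0.00025)
        assert res.x == pytest.approx(np.sqrt(175.0**2 + 4000.0), abs=1e-4)

    def test_grid_fallback_matches_critical_point_route(self):
        fit = fit_cubic(XS7, QUAD)
        f = lambda x: eval_fit(fit, x, warn=False) / x
        a = minimize_on(f, 175.0, 325.0)
        b = minimize_on(f, 175.0, 325.0,
                        critical_points=fitting.equivalent_critical_points(fit))
        assert a.x == pytest.approx(b.x, abs=1e-4)

    def test_increasing_function_boundary_flag(self):
        res = minimize_on(lambda x: 0.01 * x, 175.0, 325.0)
        assert res.x == 175.0
        assert res.boundary
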