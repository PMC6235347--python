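"""The eight threshold concepts: worked examples, closed forms, oracles."""

import numpy as np
import pytest

import oracles
from conftest import WORKED_LACTATES, make_curve, random_analysable_curves
from lactacurve.fitting import eval_fit, fit_cubic
from lactacurve.thresholds import (
    Status,
    compute_all,
    dmax,
    dmax_mod,
    lt1,
    lt2,
    lt3,
    lt4,
    lt5,
    lt_4mmol,
)


@pytest.fixture
def worked(worked_curve):
    return worked_curve


class TestLT1:
    def test_surrogate_on_worked_curve(self, worked):
        r = lt1(worked)
        assert r.status is Status.OK
        assert r.power == 250.0  # resting 1.2, first lactate >= 1.7 is 2.1
        assert r.details["resting"] == 1.2

    def test_annotation_overrides_surrogate(self, worked):
        r = lt1(worked, annotation=225.0)
        assert r.power == 225.0
        assert r.details["mode"] == "annotation"

    def test_flat_curve_undefined(self):
        r = lt1(make_curve([1.2] * 7))
        assert r.status is Status.UNDEFINED_RULE
        assert r.power is None


class TestLT2:
    def test_baseline_mean_on_worked_curve(self, worked):
        r = lt2(worked, lt1_power=250.0)
        assert r.status is Status.OK
        assert r.power == 275.0  # baseline 1.3333, first above 2.3333 is 3.0
        assert r.details["baseline"] == pytest.approx(4.0 / 3.0)

    def test_lt1_at_first_sample_undefined(self, worked):
        assert lt2(worked, lt1_power=175.0).status is Status.UNDEFINED_RULE

    def test_never_exceeding_baseline_not_reached(self):
        c = make_curve([1.2, 1.3, 1.5, 1.8, 2.0, 2.1, 2.2])
        assert lt2(c, lt1_power=250.0).status is Status.NOT_REACHED


class TestLT4:
    def test_worked_curve(self, worked):
        # rises 0.1,0.2,0.6,0.9,1.4,2.1: first >=1 with successor >=1 starts at 275 W
        r = lt4(worked)
        assert r.status is Status.OK and r.power == 275.0

    def test_last_interval_rise_has_no_successor(self):
        c = make_curve([1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 3.0])
        assert lt4(c).status is Status.NOT_REACHED

    def test_all_rises_qualifying_gives_first_sample(self):
        c = make_curve([1.0, 2.1, 3.3, 4.6, 6.0, 7.5, 9.1])
        assert lt4(c).power == 175.0


class TestCurveConcepts:
    def test_lt3_quadratic_closed_form(self, quadratic_curve):
        r = lt3(quadratic_curve)
        assert r.status is Status.OK
        assert r.details["equivalent_min_at"] == pytest.approx(
            np.sqrt(175.0**2 + 4000.0), abs=1e-3
        )
        fit = fit_cubic(quadratic_curve.powers, quadratic_curve.lactates)
        expected, _, _ = oracles.lt3_oracle(fit.coef, 175.0, 325.0, n=200_001)
        assert r.power == pytest.approx(expected, abs=0.01)

    def test_lt3_boundary_min_flagged(self):
        # strictly decreasing equivalent never happens when lactate rises from
        # the very first stage: e(x) minimises at the lower boundary
        c = make_curve([1.0, 2.0, 3.2, 4.6, 6.2, 8.0, 10.0])
        r = lt3(c)
        assert r.status is Status.BOUNDARY_MIN
        assert r.power is not None

    def test_lt3_target_unreachable(self):
        c = make_curve([1.00, 1.01, 1.02, 1.03, 1.05, 1.08, 1.10])
        assert lt3(c).status is Status.NOT_REACHED

    def test_lt5_parabolic_ratio_recovers_vertex(self):
        powers = [175.0 + 25.0 * i for i in range(7)]
        vo2 = [30.0 + 0.1 * (p - 175.0) for p in powers]
        # lactate chosen so ratio = 1e-4*(p-250)^2 + 0.03 exactly
        ratio = [1e-4 * (p - 250.0) ** 2 + 0.03 for p in powers]
        la = [r * v for r, v in zip(ratio, vo2)]
        r = lt5(make_curve(la, vo2s=vo2))
        assert r.status is Status.OK
        assert r.power == pytest.approx(250.0, abs=1e-4)

    def test_lt5_missing_vo2_skipped(self, worked):
        assert lt5(worked).status is Status.MISSING_VO2

    def test_lt_4mmol_quadratic_closed_form(self, quadratic_curve):
        r = lt_4mmol(quadratic_curve)
        assert r.power == pytest.approx(175.0 + np.sqrt(12000.0), abs=1e-6)
        assert r.lactate_at_threshold == 4.0

    def test_lt_4mmol_not_reached(self):
        c = make_curve([1.0, 1.2, 1.5, 1.9, 2.4, 2.9, 3.4])
        assert lt_4mmol(c).status is Status.NOT_REACHED

    def test_dmax_quadratic_midpoint(self, quadratic_curve):
        r = dmax(quadratic_curve)
        assert r.status is Status.OK
        assert r.power == pytest.approx(250.0, abs=1e-6)
        assert r.details["chord"] == ((175.0, 1.0), (325.0, 6.625))

    def test_dmax_linear_data_degenerate(self):
        c = make_curve([1.0 + 0.02 * (p - 175.0) for p in
                        [175, 200, 225, 250, 275, 300, 325]])
        assert dmax(c).status is Status.UNDEFINED_RULE

    def test_dmax_mod_start_point_on_worked_curve(self, worked):
        r = dmax_mod(worked)
        assert r.status is Status.OK
        # first rise >= 0.4 is 1.5 -> 2.1, start is the (225 W, 1.5) sample
        assert r.details["chord"][0] == (225.0, 1.5)
        assert r.details["chord"][1] == (325.0, 6.5)
        fit = fit_cubic(worked.powers, worked.lactates)
        expected = oracles.chord_gap_argmax(fit.coef, 225.0, 1.5, 325.0, 6.5,
                                            n=200_001)
        assert r.power == pytest.approx(expected, abs=0.01)

    def test_dmax_mod_reduces_to_dmax_when_first_rise_qualifies(self):
        c = make_curve([1.0, 1.6, 2.4, 3.4, 4.6, 6.0, 7.6])
        assert dmax_mod(c).power == pytest.approx(dmax(c).power, abs=1e-9)

    def test_dmax_mod_no_rise_not_reached(self):
        c = make_curve([1.00, 1.05, 1.11, 1.18, 1.26, 1.35, 1.45])
        assert dmax_mod(c).status is Status.NOT_REACHED


@pytest.fixture(scope="module")
def curves():
    return random_analysable_curves(25, seed=5)


class TestGridOracleAgreement:
    """Fitted-curve concepts agree with dense-grid oracles on random curves."""

    def test_dmax_and_mod_match_grid(self, curves):
        for c in curves:
            fit = fit_cubic(c.powers, c.lactates)
            r = dmax(c)
            if r.status is Status.OK:
                exp = oracles.chord_gap_argmax(
                    fit.coef, c.powers[0], c.lactates[0], c.powers[-1],
                    c.lactates[-1], n=400_001)
                assert r.power == pytest.approx(exp, abs=0.01)
            rm = dmax_mod(c)
            if rm.status is Status.OK:
                (x0, y0), (x1, y1) = rm.details["chord"]
                exp = oracles.chord_gap_argmax(fit.coef, x0, y0, x1, y1, n=400_001)
                assert rm.power == pytest.approx(exp, abs=0.01)

    def test_lt_4mmol_matches_bisection(self, curves):
        for c in curves:
            fit = fit_cubic(c.powers, c.lactates)
            r = lt_4mmol(c)
            exp = oracles.first_rising_crossing(fit.coef, 4.0, fit.domain_lo,
                                                fit.domain_hi, n=400_001)
            if r.status is Status.OK:
                assert exp is not None
                assert r.power == pytest.approx(exp, abs=0.01)
                assert abs(eval_fit(fit, r.power) - 4.0) <= 1e-6
            else:
                assert exp is None


class TestProperties:
    def test_thresholds_stay_inside_measured_range(self):
        for c in random_analysable_curves(15, seed=9):
            for concept, r in compute_all(c).items():
                if r.power is not None:
                    assert c.powers[0] - 1e-9 <= r.power <= c.powers[-1] + 1e-9

    def test_translation_invariance_of_shape_concepts(self):
        c = make_curve(WORKED_LACTATES, vo2s=[30, 33, 36, 39, 42, 45, 48])
        shift = 0.7
        shifted = make_curve([y + shift for y in WORKED_LACTATES],
                             vo2s=[30, 33, 36, 39, 42, 45, 48])
        assert dmax(shifted).power == pytest.approx(dmax(c).power, abs=1e-6)
        assert dmax_mod(shifted).power == pytest.approx(dmax_mod(c).power, abs=1e-6)
        # LT5 uses lactate/VO2, which is not translation invariant; the fixed
        # level concept shifts with the level raised by the same constant
        a = lt_4mmol(c, level=4.0)
        b = lt_4mmol(shifted, level=4.0 + shift)
        assert b.power == pytest.approx(a.power, abs=1e-6)


class TestComputeAll:
    def test_eight_results_and_expected_ordering(self):
        c = random_analysable_curves(1, seed=21)[0]
        res = compute_all(c)
        assert set(res) == {"LT1", "LT2", "LT3", "LT4", "LT5", "LT4mmol",
                            "Dmax", "DmaxMod"}
        usable = {k: r.power for k, r in res.items() if r.usable}
        if "LT5" in usable and "Dmax" in usable and "DmaxMod" in usable:
            assert usable["LT5"] <= usable["Dmax"] <= usable["DmaxMod"] + 1e-9

    def test_missing_vo2_isolated(self, worked):
        res = compute_all(worked)
        assert res["LT5"].status is Status.MISSING_VO2
        assert sum(r.status in (Status.OK, Status.BOUNDARY_MIN)
                   for r in res.values()) >= 6

    def test_flat_curve_no_crash(self):
        res = compute_all(make_curve([1.2] * 7))
        assert res["LT1"].status is Status.UNDEFINED_RULE
        assert res["LT2"].status is Status.UNDEFINED_RULE
        assert all(r.concept for r in res.values())

    def test_non_analysable_curve_refused(self):
        with pytest.raises(ValueError, match="not analysable"):
            compute_all(make_curve([1.2, 1.5, 2.2]))
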