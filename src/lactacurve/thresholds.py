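"""The eight blood-lactate-threshold concepts.

Each concept maps one analysable blood lactate curve (BLC) to a single power
in watts. Three concepts read the raw measurements (LT1, LT2, LT4); the
others work on a shared third-order polynomial fit of lactate versus power:

========  ==================================================================
LT1       first substantial rise above resting level (rater consensus when
          an annotation is supplied; otherwise a deterministic surrogate)
LT2       first measured lactate exceeding baseline + 1 mmol/L, baseline
          being the mean of the measurements before LT1
LT3       minimum lactate equivalent (lactate/power on the fitted BLC)
          plus 1.5 mmol/L, located back on the fitted BLC
LT4       measurement preceding the first rise >= 1 mmol/L whose following
          rise is also >= 1 mmol/L
LT5       minimum of a cubic fitted to lactate/VO2 against power
LT4mmol   fitted BLC crosses 4 mmol/L (OBLA)
Dmax      maximum perpendicular distance between the fitted BLC and the
          chord joining the first and last measurements
DmaxMod   as Dmax, with the chord starting at the measurement preceding the
          first rise >= 0.4 mmol/L
========  ==================================================================

Failures are reported per concept through ``status`` rather than raised, so
one degenerate curve never hides the other concepts' results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

from . import fitting
from .errors import InsufficientDataError, LevelNotReachedError
from .fitting import CubicFit, fit_cubic
from .io import BloodLactateCurve, validate_curve

CONCEPTS = ("LT1", "LT2", "LT3", "LT4", "LT5", "LT4mmol", "Dmax", "DmaxMod")


class Status(str, Enum):
    OK = "ok"
    NOT_REACHED = "not_reached"
    UNDEFINED_RULE = "undefined_rule"
    MISSING_VO2 = "missing_vo2"
    BOUNDARY_MIN = "boundary_min"

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: statuses that carry a usable threshold power
USABLE = (Status.OK, Status.BOUNDARY_MIN)


@dataclass
class ThresholdResult:
    concept: str
    power: Optional[float] = None
    lactate_at_threshold: Optional[float] = None
    status: Status = Status.OK
    details: dict = field(default_factory=dict)

    @property
    def usable(self) -> bool:
        return self.status in USABLE and self.power is not None


def _fail(concept: str, status: Status, **details) -> ThresholdResult:
    return ThresholdResult(concept=concept, power=None, status=status, details=details)


# ---------------------------------------------------------------------------
# raw-measurement concepts


def lt1(
    curve: BloodLactateCurve,
    annotation: Optional[float] = None,
    surrogate_delta: float = 0.5,
) -> ThresholdResult:
    """First substantial lactate rise above resting level.

    Originally a visual judgement by multiple raters. With ``annotation``
    (the consensus power) given, it is returned verbatim. The algorithmic
    surrogate takes resting level as the minimum lactate over the first
    three samples and returns the first sample at least
    ``surrogate_delta`` mmol/L above it.
    """
    la = curve.lactates
    pw = curve.powers
    if annotation is not None:
        lat = None
        for p, y in zip(pw, la):
            if math.isclose(p, annotation, abs_tol=1e-9):
                lat = y
                break
        return ThresholdResult(
            "LT1", power=float(annotation), lactate_at_threshold=lat,
            status=Status.OK, details={"mode": "annotation"},
        )
    resting = min(la[:3])
    target = resting + surrogate_delta
    for p, y in zip(pw, la):
        if y >= target:
            return ThresholdResult(
                "LT1", power=p, lactate_at_threshold=y, status=Status.OK,
                details={"mode": "surrogate", "resting": resting, "target": target},
            )
    return _fail("LT1", Status.UNDEFINED_RULE, mode="surrogate",
                 resting=resting, target=target)


def lt2(curve: BloodLactateCurve, lt1_power: float) -> ThresholdResult:
    """First measured lactate more than 1 mmol/L above the pre-LT1 baseline.

    Baseline is the mean lactate of all samples strictly before the LT1
    sample; the first sample from LT1 onward whose lactate exceeds
    baseline + 1 is LT2.
    """
    pw = curve.powers
    la = curve.lactates
    idx = next(
        (i for i, p in enumerate(pw) if math.isclose(p, lt1_power, abs_tol=1e-6)),
        None,
    )
    if idx is None:
        return _fail("LT2", Status.UNDEFINED_RULE,
                     reason=f"LT1 power {lt1_power} W matches no sample")
    if idx == 0:
        return _fail("LT2", Status.UNDEFINED_RULE,
                     reason="LT1 at first sample leaves an empty baseline")
    baseline = float(np.mean(la[:idx]))
    target = baseline + 1.0
    for p, y in zip(pw[idx:], la[idx:]):
        if y > target:
            return ThresholdResult(
                "LT2", power=p, lactate_at_threshold=y, status=Status.OK,
                details={"baseline": baseline, "target": target},
            )
    return _fail("LT2", Status.NOT_REACHED, baseline=baseline, target=target)


def lt4(curve: BloodLactateCurve) -> ThresholdResult:
    """Measurement preceding the first >=1 mmol/L rise followed by another.

    Scans consecutive rises d_i = bLa_{i+1} - bLa_i for the smallest i with
    d_i >= 1 and d_{i+1} >= 1; a qualifying rise in the last interval has no
    successor and does not count.
    """
    la = curve.lactates
    pw = curve.powers
    d = [b - a for a, b in zip(la, la[1:])]
    for i in range(len(d) - 1):
        if d[i] >= 1.0 and d[i + 1] >= 1.0:
            return ThresholdResult(
                "LT4", power=pw[i], lactate_at_threshold=la[i], status=Status.OK,
                details={"rise": d[i], "next_rise": d[i + 1]},
            )
    return _fail("LT4", Status.NOT_REACHED)


# ---------------------------------------------------------------------------
# fitted-curve concepts


def lt3(curve: BloodLactateCurve, fit: Optional[CubicFit] = None) -> ThresholdResult:
    """Minimum lactate equivalent plus 1.5 mmol/L, on the fitted BLC.

    The lactate equivalent e(x) = p(x)/x is minimised on the fitted cubic of
    the BLC itself; 1.5 mmol/L is added to the lactate there, and the power
    where the fitted BLC first rises through that level is LT3.
    """
    fit = fit or fit_cubic(curve.powers, curve.lactates)
    res = fitting.minimize_on(
        lambda x: fitting.eval_fit(fit, x, warn=False) / x,
        fit.domain_lo,
        fit.domain_hi,
        critical_points=fitting.equivalent_critical_points(fit),
    )
    target = fitting.eval_fit(fit, res.x, warn=False) + 1.5
    if res.x >= fit.domain_hi - 1e-9:
        # equivalent minimises at the top of the measured range: no room left
        # for the curve to rise another 1.5 mmol/L
        return _fail("LT3", Status.NOT_REACHED, equivalent_min_at=res.x, target=target)
    try:
        x = fitting.solve_level(fit, target, lo=res.x, hi=fit.domain_hi)
    except LevelNotReachedError:
        return _fail("LT3", Status.NOT_REACHED, equivalent_min_at=res.x, target=target)
    status = Status.BOUNDARY_MIN if res.boundary else Status.OK
    return ThresholdResult(
        "LT3", power=x, lactate_at_threshold=target, status=status,
        details={"equivalent_min_at": res.x, "equivalent_min": res.value,
                 "fit_r_squared": fit.r_squared},
    )


def lt5(curve: BloodLactateCurve) -> ThresholdResult:
    """Minimum of the cubic fitted to the lactate/VO2 equivalent.

    Requires the 30-s-average VO2 for every sample; any missing value skips
    the concept (status ``missing_vo2``), shrinking n as in studies where
    gas exchange occasionally failed.
    """
    if not curve.has_vo2:
        return _fail("LT5", Status.MISSING_VO2)
    ratio = [s.lactate / s.vo2 for s in curve.samples]
    try:
        fit = fit_cubic(curve.powers, ratio)
    except InsufficientDataError as e:
        return _fail("LT5", Status.UNDEFINED_RULE, reason=str(e))
    res = fitting.minimize_on(
        lambda x: fitting.eval_fit(fit, x, warn=False),
        fit.domain_lo,
        fit.domain_hi,
        critical_points=fitting.cubic_critical_points(fit),
    )
    status = Status.BOUNDARY_MIN if res.boundary else Status.OK
    return ThresholdResult(
        "LT5", power=res.x, lactate_at_threshold=None, status=status,
        details={"equivalent_min": res.value, "fit_r_squared": fit.r_squared},
    )


def lt_4mmol(
    curve: BloodLactateCurve,
    level: float = 4.0,
    fit: Optional[CubicFit] = None,
) -> ThresholdResult:
    """Power at which the fitted BLC reaches a fixed lactate level (OBLA)."""
    fit = fit or fit_cubic(curve.powers, curve.lactates)
    try:
        x = fitting.solve_level(fit, level)
    except LevelNotReachedError:
        return _fail("LT4mmol", Status.NOT_REACHED, level=level,
                     fit_r_squared=fit.r_squared)
    return ThresholdResult(
        "LT4mmol", power=x, lactate_at_threshold=level, status=Status.OK,
        details={"level": level, "fit_r_squared": fit.r_squared},
    )


def _max_chord_gap(
    fit: CubicFit, x0: float, y0: float, x1: float, y1: float
) -> tuple[float, float]:
    """Argmax and value of the perpendicular distance |p(x)-L(x)|/sqrt(1+m²).

    The chord L joins the two *measured* points (x0,y0)-(x1,y1). Stationary
    points of p - L solve p'(x) = m analytically (quadratic); endpoints are
    compared as well. With two in-domain roots the larger gap wins; an exact
    tie goes to the smaller power.
    """
    m = (y1 - y0) / (x1 - x0)
    scale = math.sqrt(1.0 + m * m)

    def gap(x: float) -> float:
        return abs(fitting.eval_fit(fit, x, warn=False) - (y0 + m * (x - x0))) / scale

    candidates = [x0, x1] + [
        float(r) for r in fitting.chord_tangent_points(fit, m) if x0 < r < x1
    ]
    best_x, best_g = None, -1.0
    for x in sorted(candidates):
        g = gap(x)
        if g > best_g + 1e-12:
            best_x, best_g = x, g
    return best_x, best_g


def dmax(curve: BloodLactateCurve, fit: Optional[CubicFit] = None) -> ThresholdResult:
    """Maximum perpendicular distance between fitted BLC and first-last chord."""
    fit = fit or fit_cubic(curve.powers, curve.lactates)
    x0, y0 = curve.powers[0], curve.lactates[0]
    x1, y1 = curve.powers[-1], curve.lactates[-1]
    if math.isclose(x0, x1, abs_tol=1e-9):
        return _fail("Dmax", Status.UNDEFINED_RULE, reason="chord endpoints coincide")
    x, g = _max_chord_gap(fit, x0, y0, x1, y1)
    if g < 1e-9:
        return _fail("Dmax", Status.UNDEFINED_RULE, reason="degenerate: fit equals chord",
                     gap=g)
    return ThresholdResult(
        "Dmax", power=x, lactate_at_threshold=fitting.eval_fit(fit, x, warn=False),
        status=Status.OK,
        details={"chord": ((x0, y0), (x1, y1)), "gap": g,
                 "fit_r_squared": fit.r_squared},
    )


def dmax_mod(
    curve: BloodLactateCurve,
    rise: float = 0.4,
    fit: Optional[CubicFit] = None,
) -> ThresholdResult:
    """Dmax with the chord starting where lactate first rises >= ``rise``.

    The start point is the measurement preceding the first consecutive rise
    of at least ``rise`` mmol/L (0.4 by default); the chord runs from that
    measured point to the last measurement.
    """
    la = curve.lactates
    pw = curve.powers
    start = next(
        (i for i in range(len(la) - 1) if la[i + 1] - la[i] >= rise), None
    )
    if start is None:
        return _fail("DmaxMod", Status.NOT_REACHED, rise=rise)
    if start == len(la) - 1:
        return _fail("DmaxMod", Status.UNDEFINED_RULE,
                     reason="start point is the last sample")
    fit = fit or fit_cubic(pw, la)
    x0, y0 = pw[start], la[start]
    x1, y1 = pw[-1], la[-1]
    x, g = _max_chord_gap(fit, x0, y0, x1, y1)
    if g < 1e-9:
        return _fail("DmaxMod", Status.UNDEFINED_RULE,
                     reason="degenerate: fit equals chord", gap=g)
    return ThresholdResult(
        "DmaxMod", power=x, lactate_at_threshold=fitting.eval_fit(fit, x, warn=False),
        status=Status.OK,
        details={"chord": ((x0, y0), (x1, y1)), "gap": g, "start_index": start,
                 "fit_r_squared": fit.r_squared},
    )


# ---------------------------------------------------------------------------
# dispatcher


def compute_all(
    curve: BloodLactateCurve,
    annotation: Optional[float] = None,
    surrogate_delta: float = 0.5,
    dmax_mod_rise: float = 0.4,
    fixed_level: float = 4.0,
) -> dict[str, ThresholdResult]:
    """All eight concepts on one analysable curve.

    LT2 consumes LT1's output. Each concept's failure is isolated: an
    unexpected error in one becomes its ``undefined_rule`` result while the
    others still compute.

    Raises ``ValueError`` (with the validation report) for non-analysable
    curves.
    """
    report = validate_curve(curve)
    if not report.analysable:
        raise ValueError(
            f"curve {curve.subject_id}/visit {curve.visit} is not analysable: "
            + "; ".join(report.violations)
        )
    try:
        fit = fit_cubic(curve.powers, curve.lactates)
    except Exception:
        fit = None

    results: dict[str, ThresholdResult] = {}

    def run(concept, fn):
        try:
            results[concept] = fn()
        except Exception as e:  # isolate concept failures
            results[concept] = _fail(concept, Status.UNDEFINED_RULE, error=str(e))

    run("LT1", lambda: lt1(curve, annotation=annotation, surrogate_delta=surrogate_delta))
    if results["LT1"].usable:
        run("LT2", lambda: lt2(curve, results["LT1"].power))
    else:
        results["LT2"] = _fail("LT2", Status.UNDEFINED_RULE, reason="LT1 unavailable")
    run("LT3", lambda: lt3(curve, fit=fit))
    run("LT4", lambda: lt4(curve))
    run("LT5", lambda: lt5(curve))
    run("LT4mmol", lambda: lt_4mmol(curve, level=fixed_level, fit=fit))
    run("Dmax", lambda: dmax(curve, fit=fit))
    run("DmaxMod", lambda: dmax_mod(curve, rise=dmax_mod_rise, fit=fit))
    return results
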