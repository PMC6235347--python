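"""Third-order polynomial fitting of blood lactate against power.

All curve-based threshold concepts share this layer: an ordinary
least-squares cubic ``p(x) = c0 + c1·x + c2·x² + c3·x³`` fitted to lactate
(or a lactate equivalent) versus power, together with evaluation, bounded
level crossing and bounded minimisation. Powers of order 10² make a raw
cubic Vandermonde ill-conditioned, so the fit is computed on a centred and
scaled abscissa and converted back; reported coefficients are in raw units
(mmol/L over powers of watts).

Searches never leave ``[domain_lo, domain_hi]`` — the interval actually
covered by measurements; thresholds are never extrapolated beyond the
intensities the athlete rode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq, minimize_scalar

from .errors import InsufficientDataError, LevelNotReachedError

#: absolute tolerance (W) for located roots and minima
X_TOL = 1e-6


@dataclass(frozen=True)
class CubicFit:
    """A fitted cubic with its fit domain and goodness of fit."""

    c0: float
    c1: float
    c2: float
    c3: float
    domain_lo: float
    domain_hi: float
    r_squared: float
    n_points: int
    degenerate: bool = False  # zero variance in the fitted values

    @property
    def coef(self) -> np.ndarray:
        """Coefficients in increasing order, raw units."""
        return np.array([self.c0, self.c1, self.c2, self.c3])

    def __call__(self, x):
        return eval_fit(self, x, warn=False)


def fit_cubic(xs: Sequence[float], ys: Sequence[float]) -> CubicFit:
    """Ordinary least-squares cubic of ``ys`` on ``xs``.

    Requires at least four strictly increasing abscissae. With exactly four
    points the cubic interpolates (all residuals zero, r² = 1). When ``ys``
    has zero variance the fit is the constant and r² is reported as 1 with
    the ``degenerate`` flag set.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ValueError("xs and ys must be 1-D arrays of equal length")
    if len(xs) < 4:
        raise InsufficientDataError(
            f"cubic fit needs at least 4 points, got {len(xs)}"
        )
    if not np.all(np.diff(xs) > 0):
        raise ValueError("xs must be strictly increasing")
    # fit on the mapped domain [-1, 1] for conditioning, convert to raw units
    p = Polynomial.fit(xs, ys, deg=3).convert()
    coef = np.zeros(4)
    coef[: len(p.coef)] = p.coef
    fitted = npoly.polyval(xs, coef)
    ss_res = float(np.sum((ys - fitted) ** 2))
    ss_tot = float(np.sum((ys - np.mean(ys)) ** 2))
    if ss_tot == 0.0:
        r2, degenerate = 1.0, True
    else:
        r2 = float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
        degenerate = False
    return CubicFit(
        c0=float(coef[0]),
        c1=float(coef[1]),
        c2=float(coef[2]),
        c3=float(coef[3]),
        domain_lo=float(xs[0]),
        domain_hi=float(xs[-1]),
        r_squared=r2,
        n_points=len(xs),
        degenerate=degenerate,
    )


def eval_fit(fit: CubicFit, x, warn: bool = True):
    """Evaluate the cubic at ``x`` (scalar or array), Horner form."""
    xa = np.asarray(x, dtype=float)
    if warn and np.any((xa < fit.domain_lo - 1e-9) | (xa > fit.domain_hi + 1e-9)):
        warnings.warn(
            f"evaluating cubic outside fit domain "
            f"[{fit.domain_lo}, {fit.domain_hi}] W (extrapolation)",
            stacklevel=2,
        )
    out = ((fit.c3 * xa + fit.c2) * xa + fit.c1) * xa + fit.c0
    return float(out) if np.isscalar(x) else out


def derivative(fit: CubicFit, x):
    xa = np.asarray(x, dtype=float)
    out = (3.0 * fit.c3 * xa + 2.0 * fit.c2) * xa + fit.c1
    return float(out) if np.isscalar(x) else out


def _real_roots(coef: np.ndarray) -> np.ndarray:
    """Real roots of a polynomial given increasing-order coefficients."""
    c = np.asarray(coef, dtype=float)
    scale = np.max(np.abs(c)) if np.any(c) else 0.0
    if scale == 0.0:
        return np.array([])
    # trim negligible leading (high-order) coefficients for a stable companion
    keep = len(c)
    while keep > 1 and abs(c[keep - 1]) < 1e-13 * scale:
        keep -= 1
    c = c[:keep]
    if len(c) <= 1:
        return np.array([])
    roots = npoly.polyroots(c)
    return np.sort(roots.real[np.abs(roots.imag) < 1e-8 * max(1.0, np.max(np.abs(roots)))])


def solve_level(
    fit: CubicFit,
    level: float,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
) -> float:
    """Smallest rising crossing of ``p(x) = level`` on ``[lo, hi]``.

    The cubic's real roots are found from the companion matrix, restricted to
    the interval, filtered to those where the curve is rising (p'(x) > 0) and
    polished with Brent's method so that ``|p(x) - level| <= 1e-6``. With a
    non-monotone fit crossing the level more than once, the smallest rising
    crossing is returned: the physiological rising limb reaches the level
    there first.

    Raises :class:`LevelNotReachedError` when no rising crossing exists.
    """
    lo = fit.domain_lo if lo is None else float(lo)
    hi = fit.domain_hi if hi is None else float(hi)
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")
    coef = fit.coef.copy()
    coef[0] -= level
    candidates = [
        float(r)
        for r in _real_roots(coef)
        if lo - 1e-7 <= r <= hi + 1e-7 and derivative(fit, float(r)) > 0.0
    ]
    if not candidates:
        raise LevelNotReachedError(
            f"level {level} has no rising crossing on [{lo:.1f}, {hi:.1f}] W"
        )
    x = min(max(min(candidates), lo), hi)
    x = _polish_root(fit, level, x, lo, hi)
    return x


def _polish_root(fit: CubicFit, level: float, x: float, lo: float, hi: float) -> float:
    f = lambda t: eval_fit(fit, t, warn=False) - level
    if abs(f(x)) <= 1e-9:
        return x
    # bracket around the companion-matrix root, then Brent
    h = max(1e-3, 1e-9 * max(abs(lo), abs(hi)))
    for _ in range(60):
        a, b = max(lo, x - h), min(hi, x + h)
        if f(a) == 0.0:
            return a
        if f(b) == 0.0:
            return b
        if f(a) * f(b) < 0:
            return float(brentq(f, a, b, xtol=X_TOL / 10))
        h *= 2.0
        if a == lo and b == hi:
            break
    return x


@dataclass(frozen=True)
class MinimizeResult:
    x: float
    value: float
    boundary: bool  # minimum sits at lo or hi


def minimize_on(
    fun: Callable[[np.ndarray], np.ndarray],
    lo: float,
    hi: float,
    critical_points: Optional[Iterable[float]] = None,
    n_grid: int = 2049,
) -> MinimizeResult:
    """Global minimum of a smooth scalar function on ``[lo, hi]``.

    When the caller knows the stationary points analytically (derivative
    roots of a cubic, or of a cubic-over-x lactate equivalent) they are
    passed via ``critical_points`` and compared against the endpoints.
    Otherwise candidate local minima are located on a dense grid and refined
    with bounded scalar minimisation to ~1e-6 W.

    Ties are broken toward the smaller power. A minimum within ``X_TOL`` of
    an endpoint is flagged ``boundary``.
    """
    lo, hi = float(lo), float(hi)
    if not lo < hi:
        raise ValueError(f"need lo < hi, got [{lo}, {hi}]")

    def f(x):
        return float(fun(np.asarray(x, dtype=float)))

    candidates: list[float] = [lo, hi]
    if critical_points is not None:
        candidates.extend(float(c) for c in critical_points if lo < c < hi)
    else:
        xs = np.linspace(lo, hi, n_grid)
        vals = np.asarray(fun(xs), dtype=float)
        interior = np.where(
            (vals[1:-1] <= vals[:-2]) & (vals[1:-1] <= vals[2:])
        )[0] + 1
        for i in interior:
            res = minimize_scalar(
                f,
                bounds=(xs[max(i - 1, 0)], xs[min(i + 1, n_grid - 1)]),
                method="bounded",
                options={"xatol": X_TOL / 10},
            )
            candidates.append(float(res.x))
    best_x, best_v = None, np.inf
    for x in sorted(candidates):
        v = f(x)
        if v < best_v - 1e-12:
            best_x, best_v = x, v
    boundary = best_x - lo <= X_TOL or hi - best_x <= X_TOL
    if boundary:
        best_x = lo if best_x - lo <= X_TOL else hi
        best_v = f(best_x)
    return MinimizeResult(x=float(best_x), value=float(best_v), boundary=boundary)


def cubic_critical_points(fit: CubicFit) -> np.ndarray:
    """Stationary points of the cubic itself (roots of p')."""
    return _real_roots(np.array([fit.c1, 2.0 * fit.c2, 3.0 * fit.c3]))


def equivalent_critical_points(fit: CubicFit) -> np.ndarray:
    """Stationary points of e(x) = p(x)/x.

    e'(x) = (x·p'(x) − p(x)) / x² whose numerator is
    2·c3·x³ + c2·x² − c0 (the linear term cancels).
    """
    return _real_roots(np.array([-fit.c0, 0.0, fit.c2, 2.0 * fit.c3]))


def chord_tangent_points(fit: CubicFit, slope: float) -> np.ndarray:
    """Solutions of p'(x) = slope — candidate maxima of the chord gap."""
    return _real_roots(np.array([fit.c1 - slope, 2.0 * fit.c2, 3.0 * fit.c3]))
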