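"""Independent oracles for the curve-based threshold computations.

Everything here is deliberately brute force — dense grids, sign-bracketing
with Brent's method, direct normal equations — so the analytic routes in
the package are checked against a method that shares none of their code.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def polyval(coef, x):
    return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float), coef)


def normal_equations_cubic(xs, ys):
    """Cubic LSQ coefficients from explicitly formed normal equations."""
    xs = np.asarray(xs, dtype=float)
    V = np.vander(xs, 4, increasing=True)
    return np.linalg.solve(V.T @ V, V.T @ np.asarray(ys, dtype=float))


def grid_argmin(fun, lo, hi, n=1_000_000):
    xs = np.linspace(lo, hi, n)
    vals = np.asarray(fun(xs))
    return float(xs[int(np.argmin(vals))])


def grid_argmax(fun, lo, hi, n=1_000_000):
    xs = np.linspace(lo, hi, n)
    vals = np.asarray(fun(xs))
    return float(xs[int(np.argmax(vals))])


def first_rising_crossing(coef, level, lo, hi, n=1_000_000):
    """Smallest x in [lo,hi] with p(x)=level on a rising limb, or None.

    Grid bracketing of sign changes from below to above, polished with
    Brent's method.
    """
    xs = np.linspace(lo, hi, n)
    vals = polyval(coef, xs) - level
    if vals[0] == 0.0 and vals[1] > 0:
        return float(xs[0])
    up = np.where((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if len(up) == 0:
        return None
    i = int(up[0])
    return float(brentq(lambda x: polyval(coef, x) - level, xs[i], xs[i + 1],
                        xtol=1e-10))


def chord_gap_argmax(coef, x0, y0, x1, y1, n=1_000_000):
    """Grid argmax of |p(x) − chord(x)| / sqrt(1+m²) over [x0, x1]."""
    m = (y1 - y0) / (x1 - x0)
    scale = np.sqrt(1.0 + m * m)
    return grid_argmax(
        lambda x: np.abs(polyval(coef, x) - (y0 + m * (x - x0))) / scale, x0, x1, n
    )


def lt3_oracle(coef, lo, hi, n=1_000_000):
    """Grid minimisation of p(x)/x, then bisection crossing of p = min+1.5."""
    xstar = grid_argmin(lambda x: polyval(coef, x) / x, lo, hi, n)
    target = float(polyval(coef, xstar)) + 1.5
    x = first_rising_crossing(coef, target, xstar, hi, n)
    return x, xstar, target
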