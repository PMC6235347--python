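"""Predictive validity of threshold powers against endurance performance.

Each concept's threshold from the GXT closest in time to an endurance test
is paired with that test's mean power: by default GXT 1 with the first
45-min time trial (TT1), GXT 4 with the second (TT2) and GXT 5 with the
road race (RR). Per (concept, test) pair the module reports the Pearson
correlation with its two-sided p-value, the mean difference
endurance − threshold with its SD (negative mean ⇔ threshold power above
endurance power), and the ordinary least-squares regression of endurance on
threshold whose r² equals the squared correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError, UndefinedStatisticError
from .io import ENDURANCE_TESTS, EnduranceResult
from .thresholds import CONCEPTS

DEFAULT_DESIGN = {"TT1": 1, "TT2": 4, "RR": 5}


@dataclass
class PairedSeries:
    """Per-subject (threshold, endurance) power pairs for one concept/test."""

    concept: str
    test_id: str
    threshold: np.ndarray  # watts
    endurance: np.ndarray  # watts
    subjects: list[str]

    @property
    def n(self) -> int:
        return len(self.threshold)


def pair_by_design(
    thresholds: pd.DataFrame,
    endurance: list[EnduranceResult] | pd.DataFrame,
    design: dict[str, int] | None = None,
) -> dict[tuple[str, str], PairedSeries]:
    """Pair thresholds with endurance powers per the test→visit design map.

    Only subjects having both members enter a series; thresholds without a
    usable power (status outside ok/boundary_min) are excluded, so per-
    concept n may differ (e.g. missing VO2 shrinks LT5).
    """
    design = dict(DEFAULT_DESIGN if design is None else design)
    unknown = [t for t in design if t not in ENDURANCE_TESTS]
    if unknown:
        raise ConfigError(
            f"unknown test_id(s) in design: {unknown}", fields=unknown
        )
    if isinstance(endurance, pd.DataFrame):
        endur_df = endurance
    else:
        endur_df = pd.DataFrame(
            [
                {"subject_id": r.subject_id, "test_id": r.test_id,
                 "mean_power_w": r.mean_power}
                for r in endurance
            ]
        )
    usable = thresholds["status"].isin(["ok", "boundary_min"]) & thresholds[
        "power_w"
    ].notna()
    thr = thresholds[usable]
    out: dict[tuple[str, str], PairedSeries] = {}
    for test_id, visit in design.items():
        e = endur_df[endur_df["test_id"] == test_id]
        e_pow = dict(zip(e["subject_id"], e["mean_power_w"]))
        for concept in CONCEPTS:
            t = thr[(thr["concept"] == concept) & (thr["visit"] == visit)]
            subjects, tv, ev = [], [], []
            for row in t.itertuples(index=False):
                if row.subject_id in e_pow:
                    subjects.append(row.subject_id)
                    tv.append(float(row.power_w))
                    ev.append(float(e_pow[row.subject_id]))
            out[(concept, test_id)] = PairedSeries(
                concept=concept,
                test_id=test_id,
                threshold=np.asarray(tv),
                endurance=np.asarray(ev),
                subjects=subjects,
            )
    return out


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value from the t distribution.

    p comes from t = r·sqrt((n-2)/(1-r²)) on n-2 degrees of freedom; a
    perfect correlation is reported with p at the machine floor rather
    than exactly zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"correlation needs n >= 3, got {n}")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("zero variance on one axis")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(np.sum(xc * yc) / math.sqrt(np.sum(xc**2) * np.sum(yc**2)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, float(np.finfo(float).tiny)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, max(float(p), float(np.finfo(float).tiny))


def mean_difference(threshold, endurance) -> tuple[float, float]:
    """Mean and sample SD of endurance − threshold power.

    A negative mean indicates the lactate threshold power is higher than the
    endurance test's average power.
    """
    t = np.asarray(threshold, dtype=float)
    e = np.asarray(endurance, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("mean difference SD needs n >= 2")
    d = e - t
    return float(np.mean(d)), float(np.std(d, ddof=1))


def fit_regression(threshold, endurance) -> tuple[float, float, float]:
    """OLS of endurance on threshold: (slope, intercept, r_squared)."""
    x = np.asarray(threshold, dtype=float)
    y = np.asarray(endurance, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("regression needs n >= 3")
    if np.var(x) == 0:
        raise UndefinedStatisticError("zero threshold variance")
    xc = x - x.mean()
    slope = float(np.sum(xc * (y - y.mean())) / np.sum(xc**2))
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else float(1.0 - np.sum(resid**2) / ss_tot)
    return slope, intercept, r2


def build_validity_report(
    series: dict[tuple[str, str], PairedSeries],
    significance_level: float = 0.0002,
) -> pd.DataFrame:
    """Long-format validity table per (concept, test).

    The ``significant`` flag marks p below ``significance_level`` (derived
    from the reported p-value, not a separate statistic). Series too small
    for a statistic carry NaN and a note.
    """
    rows = []
    for (concept, test_id), s in sorted(series.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        row = {
            "concept": concept, "test_id": test_id, "n": s.n,
            "pearson_r": np.nan, "p_value": np.nan, "significant": False,
            "mean_diff_w": np.nan, "sd_diff_w": np.nan,
            "slope": np.nan, "intercept": np.nan, "r_squared": np.nan,
            "note": "",
        }
        notes = []
        try:
            r, p = pearson_with_p(s.threshold, s.endurance)
            row.update(pearson_r=r, p_value=p, significant=bool(p < significance_level))
        except (InsufficientDataError, UndefinedStatisticError) as e:
            notes.append(f"pearson: {e}")
        try:
            md, sd = mean_difference(s.threshold, s.endurance)
            row.update(mean_diff_w=md, sd_diff_w=sd)
        except InsufficientDataError as e:
            notes.append(f"mean_diff: {e}")
        try:
            slope, intercept, r2 = fit_regression(s.threshold, s.endurance)
            row.update(slope=slope, intercept=intercept, r_squared=r2)
        except (InsufficientDataError, UndefinedStatisticError) as e:
            notes.append(f"regression: {e}")
        row["note"] = "; ".join(notes)
        rows.append(row)
    return pd.DataFrame(rows)
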