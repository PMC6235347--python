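"""Test-retest repeatability of threshold powers across repeated GXTs.

Two statistics per concept, computed on the subject-by-visit grid of
threshold powers (watts):

* **weighted intra-subject CV** — per-subject sample variances pooled with
  weights equal to the number of measurements per subject,
  ``V = sum(v_i * n_i) / sum(n_i)``, and CV = 100·sqrt(V) / grand mean.
  Correcting for missing values this way lets subjects with 2..k visits all
  contribute; subjects with fewer than two values are excluded from both
  sums and the grand mean.
* **Cronbach's alpha** — visits treated as items,
  ``alpha = k/(k-1) * (1 - sum_j var_j / var_total)`` with sample variances
  (n-1 denominator) and ``var_total`` the variance of per-subject row sums;
  95% CI by Feldt's F interval with (n-1, (n-1)(k-1)) degrees of freedom.
  Alpha needs a completed grid: complete-case by default (subjects with any
  missing visit dropped).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError
from .thresholds import CONCEPTS


@dataclass
class RepeatMatrix:
    """Subject × visit grid of threshold powers for one concept."""

    concept: str
    values: pd.DataFrame  # index subject_id, columns visit numbers, NaN = missing

    @property
    def n_subjects(self) -> int:
        return int((self.values.notna().sum(axis=1) > 0).sum())

    @property
    def n_measurements(self) -> int:
        return int(self.values.notna().sum().sum())


def weighted_intra_subject_cv(m: RepeatMatrix) -> float:
    """Pooled within-subject CV in percent (missing-value-corrected)."""
    rows = []
    for _, row in m.values.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if len(vals) >= 2:
            rows.append(vals)
    if len(rows) < 2:
        raise InsufficientDataError(
            f"{m.concept}: weighted CV needs >=2 subjects with >=2 measurements, "
            f"got {len(rows)}"
        )
    n_i = np.array([len(v) for v in rows])
    v_i = np.array([np.var(v, ddof=1) for v in rows])
    pooled = float(np.sum(v_i * n_i) / np.sum(n_i))
    grand_mean = float(np.mean(np.concatenate(rows)))
    return 100.0 * np.sqrt(pooled) / grand_mean


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    ci_lo: float
    ci_hi: float
    n_subjects: int
    k_items: int


def cronbach_alpha(
    m: RepeatMatrix, ci_level: float = 0.95, policy: str = "complete"
) -> AlphaResult:
    """Cronbach's alpha over visits with Feldt's F confidence interval.

    ``policy='complete'`` keeps only subjects observed at every visit;
    ``policy='available'`` additionally drops all-missing visit columns
    first, then goes complete-case on the rest.
    """
    grid = m.values
    if policy == "available":
        grid = grid.dropna(axis=1, how="all")
    elif policy != "complete":
        raise ValueError(f"unknown missing-data policy {policy!r}")
    grid = grid.dropna(axis=0, how="any")
    n, k = grid.shape
    if k < 2:
        raise InsufficientDataError(f"{m.concept}: alpha needs >=2 visits, got {k}")
    if n < 3:
        raise InsufficientDataError(
            f"{m.concept}: alpha needs >=3 complete subjects, got {n}"
        )
    x = grid.to_numpy(dtype=float)
    item_vars = np.var(x, axis=0, ddof=1)
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise UndefinedStatisticError(
            f"{m.concept}: zero variance of subject totals; alpha undefined"
        )
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    a = 1.0 - ci_level
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_hi = stats.f.ppf(1 - a / 2, df1, df2)
    f_lo = stats.f.ppf(1 - a / 2, df2, df1)
    ci_lo = 1.0 - (1.0 - alpha) * f_hi
    ci_hi = 1.0 - (1.0 - alpha) / f_lo
    return AlphaResult(float(alpha), float(ci_lo), float(ci_hi), n, k)


def build_repeat_matrices(
    thresholds: pd.DataFrame,
    arm_filter: str = "all",
    arms: dict[str, str] | None = None,
    n_visits: int = 5,
) -> dict[str, RepeatMatrix]:
    """One subject × visit matrix per concept from a tidy thresholds table.

    ``thresholds`` needs columns subject_id, visit, concept, power_w, status.
    Results whose status carries no usable power become missing cells. With
    ``arm_filter='placebo'`` only placebo subjects (per ``arms``) are kept;
    if no arm labels exist all subjects are used with a warning, since a
    single-arm dataset has nothing to filter.
    """
    df = thresholds.copy()
    if arm_filter not in ("all", "placebo", "active"):
        raise ValueError(f"unknown arm filter {arm_filter!r}")
    if arm_filter != "all":
        if not arms:
            warnings.warn(
                f"arm_filter={arm_filter!r} requested but no arm labels "
                "available; using all subjects",
                stacklevel=2,
            )
        else:
            keep = {s for s, a in arms.items() if a == arm_filter}
            df = df[df["subject_id"].isin(keep)]
    usable = df["status"].isin(["ok", "boundary_min"]) & df["power_w"].notna()
    df = df[usable]
    subjects = sorted(thresholds["subject_id"].unique())
    visits = list(range(1, n_visits + 1))
    out: dict[str, RepeatMatrix] = {}
    for concept in CONCEPTS:
        sub = df[df["concept"] == concept]
        grid = pd.DataFrame(np.nan, index=subjects, columns=visits, dtype=float)
        for row in sub.itertuples(index=False):
            if row.visit in grid.columns:
                grid.loc[row.subject_id, row.visit] = row.power_w
        if arm_filter != "all" and arms:
            keep = [s for s in subjects if arms.get(s) == arm_filter]
            grid = grid.loc[keep]
        out[concept] = RepeatMatrix(concept=concept, values=grid)
    return out


def build_reliability_report(
    matrices: dict[str, RepeatMatrix],
    ci_level: float = 0.95,
    policy: str = "complete",
) -> pd.DataFrame:
    """Long-format table: one row per concept with CV, alpha and CI.

    Concepts whose statistics are undefined on the given data appear with
    NaN values and the failure reason in ``note``.
    """
    rows = []
    for concept, m in matrices.items():
        row = {
            "concept": concept,
            "weighted_cv_pct": np.nan,
            "alpha": np.nan,
            "alpha_ci_lo": np.nan,
            "alpha_ci_hi": np.nan,
            "n_subjects": m.n_subjects,
            "n_measurements": m.n_measurements,
            "note": "",
        }
        notes = []
        try:
            row["weighted_cv_pct"] = weighted_intra_subject_cv(m)
        except (InsufficientDataError, UndefinedStatisticError) as e:
            notes.append(f"cv: {e}")
        try:
            a = cronbach_alpha(m, ci_level=ci_level, policy=policy)
            row.update(alpha=a.alpha, alpha_ci_lo=a.ci_lo, alpha_ci_hi=a.ci_hi)
        except (InsufficientDataError, UndefinedStatisticError) as e:
            notes.append(f"alpha: {e}")
        row["note"] = "; ".join(notes)
        rows.append(row)
    return pd.DataFrame(rows)
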