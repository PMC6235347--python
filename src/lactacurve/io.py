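"""Domain types and CSV input/output for graded-exercise-test (GXT) studies.

The data model mirrors a standard incremental cycling protocol: stages start
at 175 W and rise by 25 W every 5 minutes, with a blood-lactate sample late in
each stage and one final sample drawn immediately after the athlete stops
(the *terminal* sample, taken at the power held at termination).

Tables are plain CSV (UTF-8, decimal point, SI units in column names):

``gxt.csv``
    subject_id, visit, stage, power_w, lactate_mmol_l
    [, vo2_ml_min_kg, terminal]
``endurance.csv``
    subject_id, test_id, mean_power_w [, duration_s]
``annotations.csv``
    subject_id, visit, lt1_power_w
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .errors import FormatError, RowError

ENDURANCE_TESTS = ("TT1", "TT2", "RR")


@dataclass(frozen=True)
class Protocol:
    """Stage structure of the graded exercise test.

    The two-minute 75 W warm-up is not represented: the first modelled stage
    is ``start_power``.
    """

    start_power: float = 175.0
    increment: float = 25.0
    stage_seconds: float = 300.0


@dataclass(frozen=True)
class LactateSample:
    """One blood-lactate measurement within a GXT.

    ``terminal`` marks the sample drawn immediately after test termination;
    its ``power`` is the power held at termination, so it participates in
    curve fitting and serves as the chord's last measurement unless callers
    exclude terminal samples explicitly.
    """

    stage_index: int
    power: float
    lactate: float
    vo2: Optional[float] = None
    terminal: bool = False


@dataclass
class BloodLactateCurve:
    """Ordered lactate-vs-power measurements for one subject-visit."""

    subject_id: str
    visit: int
    samples: list[LactateSample] = field(default_factory=list)

    @property
    def powers(self) -> list[float]:
        return [s.power for s in self.samples]

    @property
    def lactates(self) -> list[float]:
        return [s.lactate for s in self.samples]

    @property
    def vo2s(self) -> list[Optional[float]]:
        return [s.vo2 for s in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def has_vo2(self) -> bool:
        return self.n_samples > 0 and all(s.vo2 is not None for s in self.samples)

    def without_terminal(self) -> "BloodLactateCurve":
        """Copy of the curve with any terminal sample removed."""
        return replace(self, samples=[s for s in self.samples if not s.terminal])

    @property
    def analysable(self) -> bool:
        return validate_curve(self).analysable


@dataclass(frozen=True)
class EnduranceResult:
    """Mean power of one endurance criterion test (45-min TT or road race)."""

    subject_id: str
    test_id: str
    mean_power: float
    duration: Optional[float] = None


@dataclass
class StudyDataset:
    """All records of one study: GXT curves, endurance tests, annotations."""

    curves: list[BloodLactateCurve] = field(default_factory=list)
    endurance: list[EnduranceResult] = field(default_factory=list)
    #: (subject_id, visit) -> manually annotated LT1 power (rater consensus)
    annotations: dict[tuple[str, int], float] = field(default_factory=dict)
    #: subject_id -> trial arm ("placebo" or "active")
    arm: dict[str, str] = field(default_factory=dict)

    def curve(self, subject_id: str, visit: int) -> Optional[BloodLactateCurve]:
        for c in self.curves:
            if c.subject_id == subject_id and c.visit == visit:
                return c
        return None


@dataclass
class ValidationReport:
    violations: list[str]
    analysable: bool

    def __bool__(self) -> bool:  # truthy iff clean
        return not self.violations


def _finite_pos(x) -> bool:
    try:
        return math.isfinite(float(x)) and float(x) > 0
    except (TypeError, ValueError):
        return False


def validate_curve(
    curve: BloodLactateCurve, protocol: Protocol = Protocol()
) -> ValidationReport:
    """Check a curve against the protocol invariants.

    Report-style: every violated invariant is listed; nothing raises. A curve
    is *analysable* iff it has at least four samples (tests with fewer
    lactate samples are excluded from analysis) with strictly increasing
    powers.
    """
    v: list[str] = []
    n = curve.n_samples
    if n < 4:
        v.append(f"fewer than four samples (n={n})")
    powers = curve.powers
    increasing = all(b > a for a, b in zip(powers, powers[1:]))
    if not increasing:
        v.append("non-increasing power across samples")
    for i, s in enumerate(curve.samples):
        if not _finite_pos(s.power):
            v.append(f"sample {i}: non-positive or non-finite power {s.power!r}")
        if not _finite_pos(s.lactate):
            v.append(f"sample {i}: non-positive or non-finite lactate {s.lactate!r}")
        if s.vo2 is not None and not _finite_pos(s.vo2):
            v.append(f"sample {i}: non-positive or non-finite vo2 {s.vo2!r}")
    terminals = [i for i, s in enumerate(curve.samples) if s.terminal]
    if len(terminals) > 1:
        v.append("more than one terminal sample")
    elif terminals and terminals[0] != n - 1:
        v.append("terminal sample is not the last sample")
    # non-terminal stage spacing must follow the protocol increment
    nonterm = [s for s in curve.samples if not s.terminal]
    for a, b in zip(nonterm, nonterm[1:]):
        if not math.isclose(b.power - a.power, protocol.increment, abs_tol=1e-9):
            v.append(
                f"non-terminal stage step {a.power}->{b.power} W differs from "
                f"increment {protocol.increment} W"
            )
            break
    analysable = n >= 4 and increasing
    return ValidationReport(violations=v, analysable=analysable)


# ---------------------------------------------------------------------------
# readers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _numeric_or_row_error(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    bad_lines: list[int] = []
    out = df.copy()
    for c in cols:
        coerced = pd.to_numeric(out[c], errors="coerce")
        bad = coerced.isna() & out[c].notna()
        # +2: 1-based with header line
        bad_lines.extend((out.index[bad] + 2).tolist())
        out[c] = coerced
    nan_lines = (out.index[out[cols].isna().any(axis=1)] + 2).tolist()
    bad_lines = sorted(set(bad_lines) | set(nan_lines))
    if bad_lines:
        raise RowError(
            f"{path}: non-numeric or missing values in {list(cols)} at "
            f"line(s) {bad_lines}",
            lines=bad_lines,
        )
    return out


def read_gxt_table(path, protocol: Protocol = Protocol()) -> list[BloodLactateCurve]:
    """Read a tidy GXT table into curves grouped by (subject, visit).

    Samples are sorted by power within each curve. Curves with fewer than
    four samples are loaded but will report ``analysable=False``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(
        df, ["subject_id", "visit", "stage", "power_w", "lactate_mmol_l"], path
    )
    df = _numeric_or_row_error(df, ["visit", "stage", "power_w", "lactate_mmol_l"], path)
    dup = df.duplicated(subset=["subject_id", "visit", "stage"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["subject_id", "visit", "stage"]]
            .drop_duplicates()
            .itertuples(index=False, name=None)
        )
        raise RowError(
            "duplicate (subject_id, visit, stage) key(s): "
            + ", ".join(map(str, keys)),
            lines=(df.index[dup] + 2).tolist(),
        )
    has_vo2 = "vo2_ml_min_kg" in df.columns
    has_term = "terminal" in df.columns
    curves: list[BloodLactateCurve] = []
    for (sid, visit), grp in df.groupby(["subject_id", "visit"], sort=True):
        grp = grp.sort_values("power_w")
        samples = []
        for row in grp.itertuples(index=False):
            vo2 = getattr(row, "vo2_ml_min_kg", None) if has_vo2 else None
            if vo2 is not None and pd.isna(vo2):
                vo2 = None
            term = bool(getattr(row, "terminal", False)) if has_term else False
            samples.append(
                LactateSample(
                    stage_index=int(row.stage),
                    power=float(row.power_w),
                    lactate=float(row.lactate_mmol_l),
                    vo2=None if vo2 is None else float(vo2),
                    terminal=term,
                )
            )
        curves.append(BloodLactateCurve(subject_id=str(sid), visit=int(visit), samples=samples))
    return curves


def read_endurance_table(path) -> list[EnduranceResult]:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, ["subject_id", "test_id", "mean_power_w"], path)
    df = _numeric_or_row_error(df, ["mean_power_w"], path)
    bad = ~df["test_id"].isin(ENDURANCE_TESTS)
    if bad.any():
        raise RowError(
            f"unknown test_id values {sorted(df.loc[bad, 'test_id'].unique())}; "
            f"expected one of {ENDURANCE_TESTS}",
            lines=(df.index[bad] + 2).tolist(),
        )
    dup = df.duplicated(subset=["subject_id", "test_id"], keep=False)
    if dup.any():
        raise RowError(
            "duplicate (subject_id, test_id) rows",
            lines=(df.index[dup] + 2).tolist(),
        )
    out = []
    for row in df.itertuples(index=False):
        dur = getattr(row, "duration_s", None)
        if dur is not None and pd.isna(dur):
            dur = None
        out.append(
            EnduranceResult(
                subject_id=str(row.subject_id),
                test_id=str(row.test_id),
                mean_power=float(row.mean_power_w),
                duration=None if dur is None else float(dur),
            )
        )
    return out


def read_annotation_table(path) -> dict[tuple[str, int], float]:
    """Manual LT1 annotations: rater-consensus powers overriding the surrogate."""
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    _require_columns(df, ["subject_id", "visit", "lt1_power_w"], path)
    df = _numeric_or_row_error(df, ["visit", "lt1_power_w"], path)
    return {
        (str(r.subject_id), int(r.visit)): float(r.lt1_power_w)
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# writers


def curves_to_frame(curves: Sequence[BloodLactateCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for s in c.samples:
            rows.append(
                {
                    "subject_id": c.subject_id,
                    "visit": c.visit,
                    "stage": s.stage_index,
                    "power_w": s.power,
                    "lactate_mmol_l": s.lactate,
                    "vo2_ml_min_kg": s.vo2,
                    "terminal": s.terminal,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "visit", "stage", "power_w",
            "lactate_mmol_l", "vo2_ml_min_kg", "terminal",
        ],
    )


def endurance_to_frame(results: Sequence[EnduranceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "test_id": r.test_id,
                "mean_power_w": r.mean_power,
                "duration_s": r.duration,
            }
            for r in results
        ],
        columns=["subject_id", "test_id", "mean_power_w", "duration_s"],
    )


def write_gxt_table(curves: Sequence[BloodLactateCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def write_endurance_table(results: Sequence[EnduranceResult], path) -> None:
    endurance_to_frame(results).to_csv(path, index=False)


def write_report_table(frame: pd.DataFrame, path) -> None:
    """Write any long-format report so that numeric fields round-trip exactly."""
    frame.to_csv(path, index=False)
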