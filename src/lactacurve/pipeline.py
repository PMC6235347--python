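"""End-to-end orchestration: data in (or simulated) → thresholds →
repeatability → predictive validity → report bundle.

The bundle mirrors the layout a reader of a threshold-comparison study
expects: a tidy per-curve thresholds table, a per-concept-per-visit summary
(mean, SD, range, overall simple and n-weighted means), a reliability table
(weighted intra-subject CV, Cronbach's alpha with 95% CI), a validity table
(Pearson r, mean difference, regression per concept × endurance test) and a
CONSORT-style accounting of every excluded test, plus a machine-readable
JSON sidecar of the run.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError
from .io import (
    Protocol,
    StudyDataset,
    read_annotation_table,
    read_endurance_table,
    read_gxt_table,
    validate_curve,
    write_endurance_table,
    write_gxt_table,
    write_report_table,
)
from .reliability import build_reliability_report, build_repeat_matrices
from .simulate import SyntheticStudyConfig, generate_study
from .thresholds import compute_all
from .validity import DEFAULT_DESIGN, build_validity_report, pair_by_design


@dataclass
class RunConfig:
    """One full analysis run: either input paths or a simulation config."""

    gxt_path: Optional[str] = None
    endurance_path: Optional[str] = None
    annotations_path: Optional[str] = None
    simulation: Optional[SyntheticStudyConfig] = None
    design: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DESIGN))
    arm_filter: str = "placebo"  # reliability is computed on this arm
    out_dir: str = "results"
    exclude_terminal: bool = False
    surrogate_delta: float = 0.5
    dmax_mod_rise: float = 0.4
    fixed_level: float = 4.0
    protocol: Protocol = field(default_factory=Protocol)

    def validate(self) -> None:
        has_paths = self.gxt_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ConfigError(
                "exactly one of gxt_path or simulation must be set",
                fields=["gxt_path", "simulation"],
            )


def compute_thresholds_table(
    dataset: StudyDataset,
    exclude_terminal: bool = False,
    surrogate_delta: float = 0.5,
    dmax_mod_rise: float = 0.4,
    fixed_level: float = 4.0,
    protocol: Protocol = Protocol(),
) -> tuple[pd.DataFrame, list[dict]]:
    """All eight concepts on every analysable curve.

    Returns the tidy thresholds table and the exclusion log (one entry per
    non-analysable curve with its violations).
    """
    rows, excluded = [], []
    for curve in dataset.curves:
        c = curve.without_terminal() if exclude_terminal else curve
        report = validate_curve(c, protocol)
        if not report.analysable:
            excluded.append(
                {
                    "subject_id": c.subject_id,
                    "visit": c.visit,
                    "violations": report.violations,
                }
            )
            continue
        annotation = dataset.annotations.get((c.subject_id, c.visit))
        results = compute_all(
            c,
            annotation=annotation,
            surrogate_delta=surrogate_delta,
            dmax_mod_rise=dmax_mod_rise,
            fixed_level=fixed_level,
        )
        for concept, r in results.items():
            rows.append(
                {
                    "subject_id": c.subject_id,
                    "visit": c.visit,
                    "concept": concept,
                    "power_w": r.power,
                    "lactate_mmol_l": r.lactate_at_threshold,
                    "status": str(r.status),
                }
            )
    cols = ["subject_id", "visit", "concept", "power_w", "lactate_mmol_l", "status"]
    return pd.DataFrame(rows, columns=cols), excluded


def summarize_thresholds(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Per-concept per-visit mean (SD; range) plus overall means.

    The ``overall`` rows carry both the simple mean of per-visit means and
    the n-weighted mean over all usable values; they differ only when
    per-visit n differ.
    """
    usable = thresholds[
        thresholds["status"].isin(["ok", "boundary_min"])
        & thresholds["power_w"].notna()
    ]
    rows = []
    for concept, grp in usable.groupby("concept"):
        visit_means = []
        for visit, g in grp.groupby("visit"):
            v = g["power_w"].to_numpy(dtype=float)
            rows.append(
                {
                    "concept": concept,
                    "visit": str(visit),
                    "n": len(v),
                    "mean_w": float(np.mean(v)),
                    "sd_w": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    "min_w": float(np.min(v)),
                    "max_w": float(np.max(v)),
                }
            )
            visit_means.append(float(np.mean(v)))
        allv = grp["power_w"].to_numpy(dtype=float)
        rows.append(
            {
                "concept": concept,
                "visit": "overall",
                "n": len(allv),
                "mean_w": float(np.mean(allv)),  # n-weighted
                "sd_w": float(np.std(allv, ddof=1)) if len(allv) > 1 else np.nan,
                "min_w": float(np.min(allv)),
                "max_w": float(np.max(allv)),
                "simple_mean_w": float(np.mean(visit_means)),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle to ``out_dir``.

    Returns the bundle as in-memory objects (frames keyed by name plus the
    accounting dict).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"lactacurve {__version__} on {platform.python_version()}"]

    if config.simulation is not None:
        dataset, truth = generate_study(config.simulation)
        log_lines.append(
            f"simulated study: {config.simulation.n_subjects} subjects x "
            f"{config.simulation.n_visits} visits, seed {config.simulation.seed}"
        )
        write_gxt_table(dataset.curves, out / "gxt.csv")
        write_endurance_table(dataset.endurance, out / "endurance.csv")
        write_report_table(truth.subjects, out / "truth_subjects.csv")
    else:
        curves = read_gxt_table(config.gxt_path, config.protocol)
        endurance = (
            read_endurance_table(config.endurance_path)
            if config.endurance_path
            else []
        )
        annotations = (
            read_annotation_table(config.annotations_path)
            if config.annotations_path
            else {}
        )
        dataset = StudyDataset(curves=curves, endurance=endurance,
                               annotations=annotations)
        log_lines.append(f"ingested {len(curves)} curves from {config.gxt_path}")

    thresholds, excluded = compute_thresholds_table(
        dataset,
        exclude_terminal=config.exclude_terminal,
        surrogate_delta=config.surrogate_delta,
        dmax_mod_rise=config.dmax_mod_rise,
        fixed_level=config.fixed_level,
        protocol=config.protocol,
    )
    write_report_table(thresholds, out / "thresholds.csv")
    n_curves = len(dataset.curves)
    log_lines.append(
        f"{n_curves} curves loaded, {len(excluded)} excluded as non-analysable"
    )
    for e in excluded:
        log_lines.append(
            f"  excluded {e['subject_id']} visit {e['visit']}: "
            + "; ".join(e["violations"])
        )
    status_counts = (
        thresholds.groupby(["concept", "status"]).size().to_dict()
        if len(thresholds)
        else {}
    )

    summary = summarize_thresholds(thresholds)
    write_report_table(summary, out / "summary.csv")

    n_visits = config.simulation.n_visits if config.simulation else 5
    matrices = build_repeat_matrices(
        thresholds, arm_filter=config.arm_filter, arms=dataset.arm,
        n_visits=n_visits,
    ) if len(thresholds) else {}
    reliability = build_reliability_report(matrices) if matrices else pd.DataFrame()
    write_report_table(reliability, out / "reliability.csv")
    if len(reliability) and reliability["note"].astype(bool).any():
        for row in reliability[reliability["note"].astype(bool)].itertuples():
            log_lines.append(f"  reliability {row.concept}: {row.note}")

    if dataset.endurance and len(thresholds):
        series = pair_by_design(thresholds, dataset.endurance, config.design)
        validity = build_validity_report(series)
        regression = validity[
            ["concept", "test_id", "n", "slope", "intercept", "r_squared"]
        ].copy()
    else:
        validity = pd.DataFrame()
        regression = pd.DataFrame()
        log_lines.append("no endurance data: validity stage skipped")
    write_report_table(validity, out / "validity.csv")
    write_report_table(regression, out / "regression.csv")

    accounting = {
        "package_version": __version__,
        "n_curves": n_curves,
        "n_excluded": len(excluded),
        "excluded": excluded,
        "n_threshold_rows": int(len(thresholds)),
        "status_counts": {f"{c}/{s}": int(n) for (c, s), n in status_counts.items()},
        "n_endurance": len(dataset.endurance),
        "arm_filter": config.arm_filter,
        "design": config.design,
    }
    if config.simulation is not None:
        accounting["seed"] = config.simulation.seed
    (out / "run.json").write_text(json.dumps(accounting, indent=2))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "thresholds": thresholds,
        "summary": summary,
        "reliability": reliability,
        "validity": validity,
        "regression": regression,
        "accounting": accounting,
    }
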