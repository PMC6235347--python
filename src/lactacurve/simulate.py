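"""Synthetic GXT-study generator with the trial's statistical structure.

The generator emulates a repeated-measures cycling study: a population of
well-trained male cyclists (weight ≈ 77 ± 9 kg, maximal power-to-weight
4.0–5.2 W/kg, VO2max ≈ 56 ± 5 mL/min/kg), five graded exercise tests per
subject on a 175 W + 25 W/5-min protocol, two 45-min time trials and one
road race whose mean power correlates with the latent threshold.

Curve family
    Blood lactate follows a baseline-plus-exponential in power,
    ``bLa(P) = b0 + (4 − b0)·exp((P − P4)/τ)``, parameterised so that the
    latent 4-mmol/L power ``P4`` is explicit: bLa(P4) = 4 exactly. The
    cubic used by the analysis is therefore a deliberate model mismatch,
    as with real curves. Visit-to-visit variation translates the whole
    curve (and the termination power) by one normal shift, producing
    concept-agnostic test-retest variance; multiplicative lognormal noise
    models lactate-analyser error.

Endurance tests
    mean power = intercept + slope·P4 + noise, with the noise SD derived
    at run time from the configured target correlation and the analytic
    between-subject SD of P4, and larger noise for the road race than for
    the ergometer time trials.

Every generated record is keyed back to its latent truth so recovery tests
can compare estimates with the parameters that produced the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .io import (
    BloodLactateCurve,
    EnduranceResult,
    LactateSample,
    Protocol,
    StudyDataset,
)


@dataclass
class SyntheticStudyConfig:
    """All knobs of the generator; defaults emulate the trial design."""

    n_subjects: int = 48
    n_visits: int = 5
    seed: int = 0
    # population (means/SDs/ranges of the study group)
    weight_mean: float = 76.9  # kg
    weight_sd: float = 9.0
    weight_lo: float = 59.2
    weight_hi: float = 95.6
    wpk_lo: float = 4.03  # maximal power per kg, W/kg, uniform
    wpk_hi: float = 5.18
    vo2max_mean: float = 55.7  # mL/min/kg
    vo2max_sd: float = 4.6
    vo2max_lo: float = 45.3
    vo2max_hi: float = 67.5
    # curve model
    baseline_lactate: float = 1.0  # b0, mmol/L
    tau: float = 45.0  # exponential steepness, W
    p4_fraction: float = 0.82  # latent 4-mmol power as fraction of max power
    p4_jitter_sd: float = 12.0  # between-subject jitter around that fraction, W
    # noise
    visit_shift_sd: float = 8.0  # W, translates curve + termination per visit
    lactate_meas_cv: float = 0.03  # multiplicative lognormal CV
    vo2_noise_sd: float = 1.0  # mL/min/kg
    # endurance linkage
    endurance_slope: float = 0.9
    endurance_intercept: float = 20.0  # W
    target_r_tt: float = 0.9
    target_r_rr: float = 0.7
    # missingness
    p_missing_gxt: float = 0.10
    p_missing_vo2: float = 0.05
    p_missing_rr: float = 0.20
    protocol: Protocol = field(default_factory=Protocol)

    def validate(self) -> None:
        bad = []
        for f in ("weight_sd", "vo2max_sd", "p4_jitter_sd", "visit_shift_sd",
                  "lactate_meas_cv", "vo2_noise_sd"):
            if getattr(self, f) < 0:
                bad.append(f)
        if not self.wpk_lo < self.wpk_hi:
            bad.append("wpk_lo/wpk_hi")
        for f in ("p_missing_gxt", "p_missing_vo2", "p_missing_rr"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                bad.append(f)
        for f, lo, hi in (("target_r_tt", 0.0, 1.0), ("target_r_rr", 0.0, 1.0)):
            if not lo < getattr(self, f) <= hi:
                bad.append(f)
        if self.n_subjects < 1 or self.n_visits < 1:
            bad.append("n_subjects/n_visits")
        if self.tau <= 0:
            bad.append("tau")
        if not 0 < self.baseline_lactate < 4:
            bad.append("baseline_lactate")
        if bad:
            raise ConfigError(f"invalid config field(s): {bad}", fields=bad)


@dataclass(frozen=True)
class SubjectParams:
    subject_id: str
    weight: float
    wpk: float
    max_power: float
    p4: float
    vo2max: float
    arm: str


@dataclass
class SyntheticTruth:
    """Latent parameters behind every generated record."""

    subjects: pd.DataFrame  # one row per subject
    visits: pd.DataFrame  # per (subject, visit): shifted P4 and max power
    endurance: pd.DataFrame  # per (subject, test): true mean power pre-noise


def _truncnorm(mean, sd, lo, hi):
    if sd == 0:
        return None
    return stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)


def latent_p4_sd(config: SyntheticStudyConfig) -> float:
    """Analytic between-subject SD of the latent 4-mmol power.

    max power = weight × W/kg with independent truncated-normal weight and
    uniform W/kg; P4 = fraction × max power + jitter.
    """
    tn = _truncnorm(config.weight_mean, config.weight_sd,
                    config.weight_lo, config.weight_hi)
    if tn is None:
        w_mean, w_var = config.weight_mean, 0.0
    else:
        w_mean, w_var = tn.stats(moments="mv")
    k_mean = (config.wpk_lo + config.wpk_hi) / 2.0
    k_var = (config.wpk_hi - config.wpk_lo) ** 2 / 12.0
    mp_var = (w_var + w_mean**2) * (k_var + k_mean**2) - (w_mean * k_mean) ** 2
    return math.sqrt(config.p4_fraction**2 * mp_var + config.p4_jitter_sd**2)


def endurance_noise_sd(config: SyntheticStudyConfig, target_r: float) -> float:
    """Noise SD giving the target correlation between endurance and P4."""
    sd_p4 = latent_p4_sd(config)
    return config.endurance_slope * sd_p4 * math.sqrt(1.0 / target_r**2 - 1.0)


def generate_subject(
    config: SyntheticStudyConfig, rng: np.random.Generator, index: int = 0
) -> SubjectParams:
    """Draw one subject's latent parameters (arm assigned separately)."""
    tn = _truncnorm(config.weight_mean, config.weight_sd,
                    config.weight_lo, config.weight_hi)
    weight = config.weight_mean if tn is None else float(tn.ppf(rng.uniform()))
    wpk = float(rng.uniform(config.wpk_lo, config.wpk_hi))
    tv = _truncnorm(config.vo2max_mean, config.vo2max_sd,
                    config.vo2max_lo, config.vo2max_hi)
    vo2max = config.vo2max_mean if tv is None else float(tv.ppf(rng.uniform()))
    max_power = weight * wpk
    p4 = config.p4_fraction * max_power + rng.normal(0.0, config.p4_jitter_sd)
    return SubjectParams(
        subject_id=f"S{index + 1:03d}",
        weight=weight, wpk=wpk, max_power=max_power, p4=float(p4),
        vo2max=vo2max, arm="",
    )


def true_lactate(P, p4: float, config: SyntheticStudyConfig):
    b0 = config.baseline_lactate
    return b0 + (4.0 - b0) * np.exp((np.asarray(P, dtype=float) - p4) / config.tau)


def generate_curve(
    subject: SubjectParams,
    visit: int,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> tuple[BloodLactateCurve, dict]:
    """One visit's curve plus its per-visit truth record.

    The visit shift translates max power and P4 together, so the whole
    curve moves along the power axis; the final stage carries the terminal
    sample. A subject whose shifted max power supports fewer than four
    stages yields a (flagged) non-analysable curve.
    """
    proto = config.protocol
    shift = float(rng.normal(0.0, config.visit_shift_sd))
    p4_v = subject.p4 + shift
    max_v = subject.max_power + shift
    n_stages = int(math.floor((max_v - proto.start_power) / proto.increment)) + 1
    n_stages = max(n_stages, 1)
    powers = proto.start_power + proto.increment * np.arange(n_stages)
    la_true = true_lactate(powers, p4_v, config)
    if config.lactate_meas_cv > 0:
        s = math.sqrt(math.log(1.0 + config.lactate_meas_cv**2))
        noise = rng.lognormal(mean=-s * s / 2.0, sigma=s, size=n_stages)
    else:
        noise = np.ones(n_stages)
    la = la_true * noise
    vo2 = (
        subject.vo2max * (0.30 + 0.70 * powers / max(max_v, powers[-1]))
        + rng.normal(0.0, config.vo2_noise_sd, size=n_stages)
    )
    vo2 = np.maximum(vo2, 1.0)
    samples = [
        LactateSample(
            stage_index=i,
            power=float(powers[i]),
            lactate=float(la[i]),
            vo2=float(vo2[i]),
            terminal=(i == n_stages - 1),
        )
        for i in range(n_stages)
    ]
    curve = BloodLactateCurve(subject_id=subject.subject_id, visit=visit,
                              samples=samples)
    truth = {
        "subject_id": subject.subject_id,
        "visit": visit,
        "p4_visit": p4_v,
        "max_power_visit": max_v,
        "n_stages": n_stages,
    }
    return curve, truth


def generate_endurance(
    subject: SubjectParams,
    config: SyntheticStudyConfig,
    rng: np.random.Generator,
) -> tuple[list[EnduranceResult], list[dict]]:
    """TT1, TT2 and RR mean powers linked to the subject's latent P4."""
    results, truths = [], []
    for test_id in ("TT1", "TT2", "RR"):
        target = config.target_r_rr if test_id == "RR" else config.target_r_tt
        noise_sd = endurance_noise_sd(config, target)
        true_mean = config.endurance_intercept + config.endurance_slope * subject.p4
        observed = true_mean + float(rng.normal(0.0, noise_sd))
        duration = 2700.0 if test_id != "RR" else float(rng.normal(5865.0, 760.0))
        results.append(
            EnduranceResult(subject_id=subject.subject_id, test_id=test_id,
                            mean_power=observed, duration=duration)
        )
        truths.append({
            "subject_id": subject.subject_id, "test_id": test_id,
            "true_mean_power": true_mean, "noise_sd": noise_sd,
        })
    return results, truths


def generate_study(
    config: SyntheticStudyConfig | None = None,
) -> tuple[StudyDataset, SyntheticTruth]:
    """Full study: curves, endurance tests, arms, missingness — seeded.

    Identical config (including seed) reproduces the dataset exactly.
    Whole GXTs are dropped with ``p_missing_gxt``; a curve's VO2 column
    with ``p_missing_vo2``; a subject's road-race power with
    ``p_missing_rr``. Half the subjects are labelled placebo.
    """
    config = config or SyntheticStudyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    subjects = [generate_subject(config, rng, i) for i in range(config.n_subjects)]
    order = rng.permutation(config.n_subjects)
    arms = {}
    half = config.n_subjects // 2
    for rank, idx in enumerate(order):
        arms[subjects[idx].subject_id] = "placebo" if rank < half else "active"

    curves: list[BloodLactateCurve] = []
    visit_truths: list[dict] = []
    endurance: list[EnduranceResult] = []
    endurance_truths: list[dict] = []
    for subj in subjects:
        for visit in range(1, config.n_visits + 1):
            curve, truth = generate_curve(subj, visit, config, rng)
            missing = rng.uniform() < config.p_missing_gxt
            truth["missing"] = missing
            visit_truths.append(truth)
            if missing:
                continue
            if rng.uniform() < config.p_missing_vo2:
                curve.samples = [
                    LactateSample(s.stage_index, s.power, s.lactate, None, s.terminal)
                    for s in curve.samples
                ]
            curves.append(curve)
        res, tr = generate_endurance(subj, config, rng)
        endurance_truths.extend(tr)
        for r in res:
            if r.test_id == "RR" and rng.uniform() < config.p_missing_rr:
                continue
            endurance.append(r)

    subj_df = pd.DataFrame(
        [{**asdict(s), "arm": arms[s.subject_id]} for s in subjects]
    )
    truth = SyntheticTruth(
        subjects=subj_df,
        visits=pd.DataFrame(visit_truths),
        endurance=pd.DataFrame(endurance_truths),
    )
    dataset = StudyDataset(curves=curves, endurance=endurance,
                           annotations={}, arm=arms)
    return dataset, truth
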