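import numpy as np
import pytest

from lactacurve.io import BloodLactateCurve, LactateSample
from lactacurve.simulate import SyntheticStudyConfig, generate_study

POWERS_7 = [175.0 + 25.0 * i for i in range(7)]
WORKED_LACTATES = [1.2, 1.3, 1.5, 2.1, 3.0, 4.4, 6.5]


def make_curve(lactates, powers=None, vo2s=None, subject="S001", visit=1,
               terminal_last=False):
    powers = POWERS_7[: len(lactates)] if powers is None else powers
    samples = []
    for i, (p, y) in enumerate(zip(powers, lactates)):
        samples.append(
            LactateSample(
                stage_index=i,
                power=float(p),
                lactate=float(y),
                vo2=None if vo2s is None else float(vo2s[i]),
                terminal=terminal_last and i == len(lactates) - 1,
            )
        )
    return BloodLactateCurve(subject_id=subject, visit=visit, samples=samples)


@pytest.fixture
def worked_curve():
    """The hand-computable 7-point curve used throughout the rule concepts."""
    return make_curve(WORKED_LACTATES)


@pytest.fixture
def quadratic_curve():
    """Noiseless samples of bLa = 0.00025·(P−175)² + 1 at 175..325 W."""
    ys = [0.00025 * (p - 175.0) ** 2 + 1.0 for p in POWERS_7]
    return make_curve(ys)


def random_analysable_curves(n, seed=0, with_vo2=True):
    """Analysable curves drawn from the synthetic study generator."""
    out = []
    batch = 0
    while len(out) < n:
        cfg = SyntheticStudyConfig(
            n_subjects=max(8, n), n_visits=1, seed=seed + 1000 * batch,
            p_missing_gxt=0.0, p_missing_vo2=0.0 if with_vo2 else 1.0,
        )
        ds, _ = generate_study(cfg)
        out.extend(c for c in ds.curves if c.analysable)
        batch += 1
    return out[:n]
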