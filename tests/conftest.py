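import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strokemarker import Cohort, PatientRecord, SimulationParams, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_cohort(age, nihss, recan, mrs, died=None, followup=None, mr_proadm=None):
    """Build a validated cohort from parallel sequences (test helper)."""
    n = len(age)
    died = died if died is not None else [m == 6 for m in mrs]
    followup = followup if followup is not None else [90] * n
    mr_proadm = mr_proadm if mr_proadm is not None else [0.7] * n
    records = [
        PatientRecord(
            patient_id=f"P{i:03d}", age=float(age[i]), nihss=int(nihss[i]),
            recanalization=bool(recan[i]), mr_proadm=float(mr_proadm[i]),
            mrs_90=int(mrs[i]), died_90=bool(died[i]), followup_days=int(followup[i]),
        )
        for i in range(n)
    ]
    for r in records:
        r.validate()
    return Cohort(records=records, provenance="test")


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """The default synthetic cohort (n = 168, default seed)."""
    return generate_cohort(SimulationParams())


@pytest.fixture(scope="session")
def toy20() -> Cohort:
    """Fixed 20-row cohort for logistic-likelihood oracle checks.

    Deterministic values spanning the covariate ranges, with outcomes chosen
    so the likelihood has an interior maximum (no separation).
    """
    rng = np.random.default_rng(424242)
    age = np.round(rng.uniform(40, 95, 20), 1)
    nihss = rng.integers(4, 26, 20)
    recan = rng.integers(0, 2, 20)
    bio = np.round(rng.lognormal(np.log(0.75), 0.4, 20), 3)
    # outcomes drawn from a moderate logistic signal, then frozen by the seed
    lp = -6.0 + 0.05 * age + 0.15 * nihss - 0.4 * recan + 1.0 * bio
    mrs = np.where(rng.random(20) < 1 / (1 + np.exp(-lp)), 4, 1)
    return make_cohort(age, nihss, recan, mrs, mr_proadm=bio)
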