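import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import survchart as sc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> sc.TrialCohort:
    """One default synthetic trial (246 control / 234 treatment), seed 42."""
    return sc.simulate_cohort(sc.SimConfig(seed=42))


@pytest.fixture(scope="session")
def control_arm(default_cohort) -> sc.TrialCohort:
    return default_cohort.subset(default_cohort.to_frame()["arm"] == "control")


@pytest.fixture(scope="session")
def treatment_arm(default_cohort) -> sc.TrialCohort:
    return default_cohort.subset(default_cohort.to_frame()["arm"] == "treatment")


@pytest.fixture(scope="session")
def phase1_fit(control_arm) -> sc.CoxFit:
    """Phase-I Cox model on the control arm (the chart's reference model)."""
    return sc.fit_cox(control_arm, ["ecog", "eod", "pi"])


def rng_seeds(root: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(root).spawn(n)]
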