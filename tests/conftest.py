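"""Shared fixtures: one default synthetic study and its full report.

Seeds are fixed once (study seed 0, master seed 0) so every
structure-recovery assertion is deterministic.
"""

import pytest
from hypothesis import HealthCheck, settings

import markcast as mc

settings.register_profile(
    "suite",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

STUDY_SEED = 0
MASTER_SEED = 0


@pytest.fixture(scope="session")
def default_study() -> mc.SyntheticStudy:
    """The default synthetic study: 4 x 10 Mb genome, 300 + 300 enhancers,
    six lineage stages (target 5.0), three other tissues, lam = 0.35."""
    return mc.simulate_study(mc.SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def full_report(default_study) -> mc.ExperimentReport:
    """The complete experiment grid on the default study."""
    return mc.run_report(default_study, master_seed=MASTER_SEED)


@pytest.fixture()
def small_genome() -> mc.Genome:
    return mc.Genome({"chr1": 1_000_000, "chr2": 500_000})
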