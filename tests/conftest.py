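import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirtarrank.survival import SurvivalRecord

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_records(genotype, death_days=(), censor_days=()):
    """Build SurvivalRecords from death and censoring days."""
    recs = []
    for i, t in enumerate(death_days):
        recs.append(SurvivalRecord(f"{genotype}-d{i}", genotype, float(t), True))
    for i, t in enumerate(censor_days):
        recs.append(SurvivalRecord(f"{genotype}-c{i}", genotype, float(t), False))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
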