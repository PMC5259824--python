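import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pathcontext as pc

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy():
    """The fixed six-pathway worked example."""
    return pc.worked_toy()


@pytest.fixture(scope="session")
def toy_results(toy):
    """Default fit (estimated Discovery rate) of the worked example."""
    model = pc.PathwayPriorityModel(toy.pvalues, toy.entity_tables, toy.prior)
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_instance(rng, n, zero_frac=0.3):
    """Random CS/IS-style universe used across integration tests."""
    ids = [f"P{i:03d}" for i in range(n)]
    cs_raw = rng.uniform(size=n)
    cs_raw[rng.uniform(size=n) < zero_frac] = 0.0
    total = cs_raw.sum()
    cs = cs_raw / total if total > 0 else cs_raw
    is_ = rng.uniform(size=n)
    return (
        pc.ContextScoreVector(values=dict(zip(ids, cs))),
        pc.ImpactScoreVector(values=dict(zip(ids, is_))),
    )
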