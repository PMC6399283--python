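import numpy as np
import pytest

import rfclust as rc


def scaled_specs(divisor: int = 20, min_n: int = 40):
    """Discovery cluster specs shrunk for fast tests (same structure)."""
    return [
        rc.ClusterSpec(**{**vars(s), "n": max(min_n, s.n // divisor)})
        for s in rc.default_discovery_spec()
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """~520-row discovery-style cohort with follow-up and biomarkers."""
    cfg = rc.SimulationConfig(specs=scaled_specs(), seed=11)
    t = rc.generate_cohort(cfg)
    t = rc.generate_followup(t, cfg)
    return rc.generate_biomarkers(t, cfg)


@pytest.fixture(scope="session")
def small_config():
    return rc.SimulationConfig(specs=scaled_specs(), seed=11)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Clustering fit of the small cohort, shared across tests."""
    return rc.RiskFactorClustering(small_cohort).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
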