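import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ascn_assoc import (
    ASCNProfile,
    AnalysisParams,
    EventMatrix,
    EventType,
    GenotypeTable,
    ProbeManifest,
)
from ascn_assoc.io import load_fixture_config_path
from ascn_assoc.simulate import load_sim_config, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_config():
    return load_sim_config(load_fixture_config_path())


@pytest.fixture(scope="session")
def small_cohort(fixture_config):
    """The packaged small synthetic cohort (16 samples, ~350 probes)."""
    return simulate_cohort(fixture_config, seed=11)


@pytest.fixture
def tiny_manifest():
    """6 probes: 4 on chr1, 2 on chrX."""
    return ProbeManifest.from_arrays(
        probe_ids=[f"pr{i}" for i in range(6)],
        chroms=["1", "1", "1", "1", "X", "X"],
        pos=[100, 200, 300, 400, 100, 200],
    )


def make_matrix(values, probe_ids=None, sample_ids=None, event=EventType.HD):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probe_ids = probe_ids or [f"pr{i}" for i in range(m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    return EventMatrix(event, pd.DataFrame(values, index=sample_ids, columns=probe_ids))


@pytest.fixture
def matrix_factory():
    return make_matrix
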