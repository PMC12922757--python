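import numpy as np
import pytest

from constrictaxis.device import DeviceGeometry
from constrictaxis.synthetic_data import (
    PhenotypeParams,
    generate_calcium_traces,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def geometry():
    return DeviceGeometry()


@pytest.fixture(scope="session")
def small_cohort(geometry):
    """A 40-cell control-like cohort with traces, shared across tests."""
    cohort = simulate_cohort(
        PhenotypeParams(label="fixture"), 40, geometry, seed=1234
    )
    return generate_calcium_traces(cohort, seed=4321)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
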