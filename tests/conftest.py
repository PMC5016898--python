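import numpy as np
import pytest

import odepsim as o

# Coarse but resolved working grid for the fast unit tests; the
# acceptance suite uses the production 5 um grid via its own fixtures.
COARSE_H = 20.0


@pytest.fixture(scope="session")
def geometry():
    return o.build_geometry(side_width=400.0, grid_spacing=COARSE_H)


@pytest.fixture(scope="session")
def field_1ul(geometry):
    return o.solve_flow(geometry, o.FlowConfig(flow_rate=1.0))


@pytest.fixture(scope="session")
def fields_by_rate(geometry, field_1ul):
    out = {1.0: field_1ul}
    for q in (2.5, 5.0):
        out[q] = o.solve_flow(geometry, o.FlowConfig(flow_rate=q))
    return out


@pytest.fixture(scope="session")
def force_model():
    return o.calibrate_force_model()


@pytest.fixture(scope="session")
def small_population():
    """50 cancer + 1000 leukocytes: enough for protocol-logic tests."""
    return o.generate_population(n_cancer=50, n_leukocyte=1000, seed=7)


@pytest.fixture(scope="session")
def default_population():
    """The full spiking scenario: 500 cancer + 1e4 leukocytes."""
    return o.generate_population(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
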