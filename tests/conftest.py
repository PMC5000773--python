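import numpy as np
import pytest

import placentaflux as pf


@pytest.fixture(scope="session")
def params():
    return pf.TransporterParams()


@pytest.fixture(scope="session")
def geometry():
    return pf.CompartmentGeometry()


@pytest.fixture(scope="session")
def tracer_pools():
    return pf.SubstratePools.tracer()


@pytest.fixture(scope="session")
def protocol():
    return pf.build_protocol()


@pytest.fixture(scope="session")
def transport_metab_trajectory(protocol, params, tracer_pools, geometry):
    """Full-protocol simulation of the default transport+metabolism model."""
    return pf.simulate(
        protocol, params, tracer_pools, geometry,
        pf.ModelVariant.transport_metabolism(),
    )
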