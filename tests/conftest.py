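import pytest

import cardioperf as cp

from _helpers import make_plateau_recording


@pytest.fixture
def variant_a_protocol() -> cp.ProtocolSpec:
    """Saline [0,4), compound [4,13.5), saline [13.5,22]."""
    return cp.continuous_protocol({"x": 1e-5})


@pytest.fixture
def control_protocol() -> cp.ProtocolSpec:
    return cp.saline_protocol()


@pytest.fixture
def basic_params() -> cp.PDParams:
    return cp.PDParams(potency={"x": cp.CompoundPD(-80.0, 1e-6, 1.5)}, k_on=1.2, k_off=0.4)


@pytest.fixture
def plateau_recording():
    return make_plateau_recording
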