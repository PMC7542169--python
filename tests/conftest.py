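import numpy as np
import pytest

from pacesim.model import GateSpec, ModelParams
from pacesim.synth import canonical_params


@pytest.fixture(scope="session")
def canonical():
    return canonical_params()


@pytest.fixture(scope="session")
def leak_only():
    """Pure leak model: linear ODE with closed-form relaxation."""
    gate = GateSpec(half_voltage=-50.0, slope=5.0, tau_base=1.0)
    igate = GateSpec(half_voltage=-50.0, slope=-5.0, tau_base=1.0)
    return ModelParams(
        G_Leak=0.2, G_Ca=0.0, G_Na=0.0, G_K=0.0,
        E_Leak=-65.0, E_Ca=100.0, E_Na=50.0, E_K=-90.0,
        b=gate, g=igate, m=gate, h=igate, n=gate, q=igate,
    )


@pytest.fixture(scope="session")
def canonical_trace(canonical):
    """A 200 ms canonical simulation shared across tests."""
    from pacesim.simulate import integrate
    return integrate(canonical, 200.0, dt=0.01, keep_gates=True)
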