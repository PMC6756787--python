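import numpy as np
import pytest

from gridlock import CoupledSystem, ModuleSpec, build_network, relax_to_bump

DT = 1e-4


@pytest.fixture(scope="session")
def ring_spec():
    return ModuleSpec(dims=1, N=200)


@pytest.fixture(scope="session")
def ring_net(ring_spec):
    return build_network(ring_spec)


@pytest.fixture(scope="session")
def ring_state(ring_net):
    return relax_to_bump(ring_net, T_relax=0.6, dt=DT)


@pytest.fixture(scope="session")
def coupled_pair(ring_spec):
    """Relaxed coupled m=2 system and its uncoupled twin (shared weights)."""
    coupled = CoupledSystem.build(2, spec=ring_spec).relax(dt=DT)
    uncoupled = CoupledSystem.build(2, spec=ring_spec, uncoupled=True)
    uncoupled.modules = coupled.modules
    uncoupled.states = [st.copy() for st in coupled.states]
    uncoupled.coupling.a = coupled.coupling.a
    return coupled, uncoupled


@pytest.fixture(scope="session")
def coupled_m3(ring_spec):
    return CoupledSystem.build(3, spec=ring_spec).relax(dt=DT)


@pytest.fixture(scope="session")
def torus_spec():
    return ModuleSpec(dims=2, N=12 * 12)


@pytest.fixture(scope="session")
def torus_net(torus_spec):
    return build_network(torus_spec)


@pytest.fixture(scope="session")
def torus_state(torus_net):
    return relax_to_bump(torus_net, T_relax=0.6, dt=DT)


@pytest.fixture(scope="session")
def calibrated_alpha(ring_net):
    from gridlock import calibrate_gain_alpha

    alpha, r2 = calibrate_gain_alpha(ring_net)
    assert r2 > 0.999
    return alpha
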