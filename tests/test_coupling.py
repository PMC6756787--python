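"""Velocity readout, input scaling, coupled drive assembly and runs."""

import numpy as np
import pytest

from gridlock import (
    LAMBDA_RATIO,
    CoupledSystem,
    CouplingSpec,
    ModuleSpec,
    assemble_coupled_drive,
    check_stability,
    compute_input_scaling_a,
    coupling_weight_matrix,
    linear_response_tensor,
    run_coupled,
    standard_coupling_parameters,
    velocity_readout,
)

DT = 1e-4


def test_readout_vanishes_at_symmetric_bump(ring_net, ring_state):
    assert velocity_readout(ring_state, ring_net) == pytest.approx(0.0, abs=1e-12)


def test_readout_sign_and_direction(coupled_pair):
    """Positive drive makes omega > 0 and moves the bump in +theta."""
    coupled, _ = coupled_pair
    n = int(0.2 / DT)
    b = np.zeros((n, 2, 1, 1))
    b[:, 0, 0, 0] = 0.012
    res = run_coupled(coupled, b, dt=DT, record_stride=20)
    assert np.mean(res.omegas[5:, 0, 0, 0]) > 0
    assert res.phases[-1, 0, 0, 0] > res.phases[0, 0, 0, 0]


def test_input_scaling_active_count(ring_net, ring_state):
    h = ring_net.recurrent_input(ring_state.s) + ring_net.spec.I0
    n_act = int(np.sum(h > 0))
    a = compute_input_scaling_a(ring_net, ring_state, beta=1.0)
    assert a == pytest.approx(ring_net.spec.tau / n_act)
    assert a > 0
    # doubling beta halves a
    assert compute_input_scaling_a(ring_net, ring_state, beta=2.0) == pytest.approx(a / 2)


def test_standard_parameters_m2_values():
    cs = standard_coupling_parameters(2)
    lam = LAMBDA_RATIO
    assert cs.C[0, 0] == cs.C[1, 1] == -20.0
    assert cs.C[0, 1] == pytest.approx(20.0 / lam)  # ~14.14
    assert cs.C[1, 0] == pytest.approx(20.0 * lam)  # ~28.28
    assert check_stability(cs.C).stable


def test_standard_parameters_m3_structure():
    cs = standard_coupling_parameters(3)
    assert cs.C[0, 2] == cs.C[2, 0] == 0.0  # coupling only between successive modules
    assert cs.C[1, 0] == cs.C[1, 2] == pytest.approx(9.4)
    assert check_stability(cs.C).stable
    with pytest.raises(ValueError):
        standard_coupling_parameters(4)


def test_drive_assembly_trivial_cases(coupled_pair):
    coupled, uncoupled = coupled_pair
    I0 = coupled.modules[0].spec.I0
    # no coupling, no input: every neuron receives exactly I0
    d = assemble_coupled_drive(uncoupled, np.zeros((2, 1)))
    assert np.all(d == I0)
    # at the symmetric steady state omega = 0, so coupling adds nothing
    d = assemble_coupled_drive(coupled, np.zeros((2, 1)))
    assert np.allclose(d, I0, atol=1e-12)


def test_drive_assembly_coupling_term_only(coupled_pair):
    """With input to module 1 only, module 2's drive deviates from I0 only
    through the coupling term a*C21*omega1."""
    coupled, _ = coupled_pair
    n = int(0.05 / DT)
    b = np.zeros((n, 2, 1, 1))
    b[:, 0, 0, 0] = 0.012
    res = run_coupled(coupled, b, dt=DT, record_stride=n)
    S = res.final_state[:, 0]
    sl2 = coupled.module_slices()[1]
    net2 = coupled.modules[1]
    om = coupled.omegas(S)
    drive = assemble_coupled_drive(coupled, np.array([[0.012], [0.0]]), S=S)
    expected_dev = coupled.coupling.a * (coupled.coupling.C[1] @ om[:, 0])
    dev = drive[sl2] - net2.spec.I0
    sgn = net2.channel_signs(0)
    assert np.allclose(dev, sgn * expected_dev, atol=1e-12)


def test_drive_equivalence_with_synaptic_form(coupled_m3):
    """The omega-based drive equals the explicit coupling-connectivity form."""
    system = coupled_m3
    rng = np.random.default_rng(0)
    S = system.stacked_state() * (1 + 0.1 * rng.standard_normal(system.n_neurons))
    b = rng.normal(0, 0.01, size=(3, 1))
    drive = assemble_coupled_drive(system, b, S=S)
    # explicit synaptic route: a * sum_rho C[mu,rho] * (Wc @ s_rho)
    a, beta, tau = system.coupling.a, system.coupling.beta, system.tau
    slices = system.module_slices()
    drive2 = np.empty_like(drive)
    for mu, (net, sl) in enumerate(zip(system.modules, slices)):
        acc = np.zeros(net.n_neurons)
        for rho, (pre, sl_r) in enumerate(zip(system.modules, slices)):
            Wc = coupling_weight_matrix(beta, tau, net, pre)
            acc += a * system.coupling.C[mu, rho] * (Wc @ S[sl_r])
        drive2[sl] = net.spec.I0 + net.channel_signs(0) * b[mu, 0] + acc
    assert np.allclose(drive, drive2, atol=1e-12)


def test_coupling_weight_matrix_structure(ring_spec):
    from gridlock import build_network

    small = build_network(ModuleSpec(dims=1, N=8))
    Wc = coupling_weight_matrix(1.0, small.spec.tau, small, small)
    # rank one: outer product of the +-1 polarity vectors
    svals = np.linalg.svd(Wc, compute_uv=False)
    assert svals[0] > 0 and np.all(svals[1:] < 1e-12)
    # all-to-all within the channel: no zero entries
    assert np.all(np.abs(Wc) == pytest.approx(1.0 / small.spec.tau))
    # swapping the pre-module's R/L labels negates the matrix
    flipped = np.hstack([Wc[:, 8:], Wc[:, :8]])
    assert np.allclose(flipped, -Wc)


def test_uncoupled_module2_unresponsive(coupled_pair):
    _, uncoupled = coupled_pair
    n = int(0.5 / DT)
    b = np.zeros((n, 2, 1, 1))
    b[:, 0, 0, 0] = 0.012
    res = run_coupled(uncoupled, b, dt=DT, record_stride=50)
    d1 = abs(res.phases[-1, 0, 0, 0] - res.phases[0, 0, 0, 0])
    d2 = abs(res.phases[-1, 1, 0, 0] - res.phases[0, 1, 0, 0])
    assert d1 > 0.1
    assert d2 < 0.01 * d1


def test_coupled_velocity_ratio_matches_response_tensor(coupled_pair, calibrated_alpha):
    """Input to module 1 only: theta2_dot/theta1_dot equals the ratio of the
    response-tensor column entries (close to, but not exactly, lambda)."""
    coupled, _ = coupled_pair
    n = int(1.0 / DT)
    b = np.zeros((n, 2, 1, 1))
    b[:, 0, 0, 0] = 0.012
    res = run_coupled(coupled, b, dt=DT, record_stride=50)
    half = res.phases.shape[0] // 2
    t = res.times[half:]
    v1 = np.polyfit(t, res.phases[half:, 0, 0, 0], 1)[0]
    v2 = np.polyfit(t, res.phases[half:, 1, 0, 0], 1)[0]
    X = linear_response_tensor(coupled.coupling.C, calibrated_alpha).X
    assert v2 / v1 == pytest.approx(X[1, 0] / X[0, 0], rel=0.01)
    assert v2 / v1 == pytest.approx(LAMBDA_RATIO, rel=0.06)


def test_zero_input_phases_constant(coupled_pair):
    coupled, _ = coupled_pair
    n = int(2.0 / DT)
    res = run_coupled(coupled, np.zeros((n, 2, 1, 1)), dt=DT, record_stride=200)
    drift = np.abs(res.phases[-1] - res.phases[0]).max()
    assert drift < 1e-4


def test_instability_guard():
    spec = ModuleSpec(dims=1, N=64)
    bad = CouplingSpec(C=np.array([[5.0, 0.0], [0.0, 5.0]]))  # eigenvalue 5 > 1
    system = CoupledSystem.build(2, spec=spec, coupling=bad).relax()
    n = int(0.3 / DT)
    b = np.zeros((n, 2, 1, 1))
    b[:, :, 0, 0] = 0.01
    with pytest.raises(RuntimeError, match="check_stability"):
        run_coupled(system, b, dt=DT, record_stride=10, s_ceiling=1e4)


def test_dt_stiffness_guard(coupled_pair):
    coupled, _ = coupled_pair
    with pytest.raises(ValueError, match="stiff"):
        run_coupled(coupled, np.zeros((10, 2, 1, 1)), dt=9e-4)


def test_beta_invariance(ring_spec):
    """beta only rescales omega; with a recomputed, trajectories agree to 1e-10."""
    results = []
    for beta in (1.0, 7.3):
        cs = standard_coupling_parameters(2)
        cs.beta = beta
        system = CoupledSystem.build(2, spec=ring_spec, coupling=cs).relax(dt=DT)
        n = int(0.2 / DT)
        b = np.zeros((n, 2, 1, 1))
        b[:, 0, 0, 0] = 0.015
        results.append(run_coupled(system, b, dt=DT, record_stride=20).phases)
    assert np.allclose(results[0], results[1], atol=1e-10)


def test_readout_approximates_phase_velocity(coupled_pair, calibrated_alpha):
    """The readout estimates the phase velocity: alpha*a*omega ~ theta_dot
    within 5% across constant drives spanning the linear range.

    alpha*a is the natural readout normalization (a drive of a*omega moves
    a receiving module at alpha*a*omega, which the coupling theory equates
    with the sender's phase velocity).
    """
    coupled, _ = coupled_pair
    scale = calibrated_alpha * coupled.coupling.a
    for level in (0.006, 0.012, 0.024):
        n = int(0.6 / DT)
        b = np.zeros((n, 2, 1, 1))
        b[:, :, 0, 0] = level * np.array([1.0, LAMBDA_RATIO])
        res = run_coupled(coupled, b, dt=DT, record_stride=20)
        half = res.phases.shape[0] // 2
        t = res.times[half:]
        for mu in range(2):
            vel = np.polyfit(t, res.phases[half:, mu, 0, 0], 1)[0]
            om_avg = np.mean(res.omegas[half:, mu, 0, 0])
            assert scale * om_avg == pytest.approx(vel, rel=0.05)
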