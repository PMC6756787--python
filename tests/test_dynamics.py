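"""Single-module dynamics: bump formation, integration, spiking."""

import numpy as np
import pytest

from gridlock import (
    ModuleSpec,
    SynapticState,
    build_network,
    estimate_phase,
    relax_to_bump,
    step_poisson_dynamics,
    step_rate_dynamics,
)
from gridlock.dynamics import gaussian_bump_state, transfer

DT = 1e-4


def test_zero_state_zero_drive_is_fixed_point(ring_net):
    st = SynapticState(s=np.zeros(ring_net.n_neurons))
    st2, r = step_rate_dynamics(ring_net, st, np.zeros(ring_net.n_neurons), DT)
    assert np.all(st2.s == 0) and np.all(r == 0)


def test_single_neuron_converges_to_tau_phi_I0():
    # with W = 0 the fixed point is s* = tau * phi(I0) = I0 on the active side
    spec = ModuleSpec(dims=1, N=4, I0=3.0)
    net = build_network(spec)
    net.W_row = np.zeros_like(net.W_row)
    st = SynapticState(s=np.zeros(net.n_neurons))
    ff = np.full(net.n_neurons, spec.I0)
    for _ in range(int(0.2 / DT)):
        st, _ = step_rate_dynamics(net, st, ff, DT)
    assert np.allclose(st.s, 3.0, atol=1e-6)


def test_dt_guard():
    spec = ModuleSpec(dims=1, N=8)
    net = build_network(spec)
    st = SynapticState(s=np.zeros(net.n_neurons))
    with pytest.raises(ValueError):
        step_rate_dynamics(net, st, 0.0, spec.tau / 2)


def test_relaxed_state_is_fixed_point(ring_net, ring_state):
    # fixed-point identity r = s/tau, and a further step barely moves s
    h = ring_net.recurrent_input(ring_state.s) + ring_net.spec.I0
    r = transfer(h, ring_net.spec.tau)
    assert np.max(np.abs(r - ring_state.s / ring_net.spec.tau)) < 1e-8
    st2, _ = step_rate_dynamics(ring_net, ring_state, np.full(ring_net.n_neurons, ring_net.spec.I0), DT)
    assert np.max(np.abs(st2.s - ring_state.s)) < DT * 1e-6


def test_bump_phase_stationary_without_input(ring_net, ring_state):
    st = ring_state.copy()
    ff = np.full(ring_net.n_neurons, ring_net.spec.I0)
    p0 = estimate_phase(st, ring_net)
    for _ in range(int(1.0 / DT)):
        st, _ = step_rate_dynamics(ring_net, st, ff, DT)
    assert estimate_phase(st, ring_net) == pytest.approx(p0, abs=1e-4)


def test_relax_preserves_requested_phase(ring_net):
    st = relax_to_bump(ring_net, T_relax=0.6, dt=DT, phase=0.6)
    assert estimate_phase(st, ring_net) == pytest.approx(0.6, abs=1e-3)


def test_bump_shape_unique_up_to_translation(ring_net, ring_state):
    other = relax_to_bump(ring_net, T_relax=0.6, dt=DT, phase=0.8)
    assert np.allclose(np.sort(ring_state.s), np.sort(other.s), atol=1e-6)


def test_no_bump_error_when_connectivity_too_weak():
    spec = ModuleSpec(dims=1, N=64, A=1.0)
    net = build_network(spec)
    with pytest.raises(RuntimeError, match="no bump"):
        relax_to_bump(net, T_relax=0.6, dt=DT)


def test_estimate_phase_symmetric_bump(ring_net):
    from gridlock import periodic_distance_1d

    d = periodic_distance_1d(ring_net.preferred_phase - 0.25)
    st = SynapticState(s=np.exp(-(d**2) / (2 * 0.01)))  # narrow symmetric bump
    assert estimate_phase(st, ring_net) == pytest.approx(0.25, abs=1e-9)


def test_estimate_phase_lattice_shift_equivariance(ring_net, ring_state):
    N = ring_net.spec.N
    rolled = np.concatenate([np.roll(ring_state.s[:N], 3), np.roll(ring_state.s[N:], 3)])
    p0 = estimate_phase(ring_state, ring_net)
    p1 = estimate_phase(SynapticState(s=rolled), ring_net)
    assert (p1 - p0) % 1.0 == pytest.approx(3.0 / N, abs=1e-9)


def test_translation_equivariance_of_dynamics(ring_net, ring_state):
    """Rotating drive and state by k sites rotates the solution exactly."""
    N, k = ring_net.spec.N, 7
    ff = np.full(ring_net.n_neurons, ring_net.spec.I0)
    ff[: N // 4] += 0.1  # asymmetric drive pattern
    roll = lambda v: np.concatenate([np.roll(v[:N], k), np.roll(v[N:], k)])
    st_a = ring_state.copy()
    st_b = SynapticState(s=roll(ring_state.s))
    for _ in range(50):
        st_a, _ = step_rate_dynamics(ring_net, st_a, ff, DT)
        st_b, _ = step_rate_dynamics(ring_net, st_b, roll(ff), DT)
    assert np.allclose(roll(st_a.s), st_b.s, atol=1e-13)


def test_constant_drive_gives_constant_odd_velocity(ring_net, ring_state):
    """Velocity integration: constant phase speed, odd in the drive sign."""

    def vel(dI):
        st = ring_state.copy()
        ff = np.full(ring_net.n_neurons, ring_net.spec.I0)
        ff[ring_net.subpop_slice("R")] += dI
        ff[ring_net.subpop_slice("L")] -= dI
        phases = []
        for k in range(int(0.8 / DT)):
            st, _ = step_rate_dynamics(ring_net, st, ff, DT)
            if k % 200 == 0:
                phases.append(estimate_phase(st, ring_net))
        d = np.diff(phases)
        d -= np.round(d)
        v_inst = d / (200 * DT)
        tail = v_inst[len(v_inst) // 2 :]
        assert np.std(tail) / np.abs(np.mean(tail)) < 0.02  # constant speed
        return np.sum(d[len(d) // 2 :])

    assert vel(-0.012) == pytest.approx(-vel(0.012), abs=1e-3)


def test_poisson_zero_rate_decays(ring_net):
    rng = np.random.default_rng(0)
    st = SynapticState(s=np.full(ring_net.n_neurons, 2.0))
    tau = ring_net.spec.tau
    for _ in range(100):
        st, counts = step_poisson_dynamics(ring_net, st, -1e3, DT, rng)  # strongly negative drive
        assert counts.sum() == 0
    assert np.allclose(st.s, 2.0 * (1 - DT / tau) ** 100, rtol=1e-12)


def test_poisson_requires_rng(ring_net, ring_state):
    with pytest.raises(ValueError):
        step_poisson_dynamics(ring_net, ring_state, 0.0, DT, None)


def test_poisson_counts_match_rate(ring_net, ring_state):
    """Time-averaged spike count of a clamped-rate neuron obeys the Poisson law."""
    rng = np.random.default_rng(1)
    tau = ring_net.spec.tau
    h = ring_net.recurrent_input(ring_state.s) + ring_net.spec.I0
    rates = transfer(h, tau)
    i = int(np.argmax(rates))
    T, n_steps = 10.0, int(10.0 / 1e-3)
    counts = rng.poisson(rates[i] * 1e-3, size=n_steps).sum()
    expect = rates[i] * T
    assert abs(counts - expect) < 3 * np.sqrt(expect)


def test_poisson_ensemble_tracks_rate_solution():
    """Mean spiking s stays within fluctuation bands of the rate solution."""
    spec = ModuleSpec(dims=1, N=100)
    net = build_network(spec)
    st0 = relax_to_bump(net, T_relax=0.6, dt=DT)
    rng = np.random.default_rng(2)
    trials = 50
    S = np.repeat(st0.s[:, None], trials, axis=1)
    st = SynapticState(s=S)
    ff = np.full(net.n_neurons, spec.I0)
    for _ in range(int(0.5 / DT)):
        st, _ = step_poisson_dynamics(net, st, ff[:, None], DT, rng)
    mean_profile = np.sort(st.s.mean(axis=1))
    ref = np.sort(st0.s)
    # agreement of the sorted mean profile within a tolerance set by the
    # trial-to-trial fluctuation scale
    scale = np.std(st.s, axis=1).mean() / np.sqrt(trials)
    assert np.max(np.abs(mean_profile - ref)) < 12 * scale


def test_poisson_diffusion_decreases_with_rate_scale():
    """Scaling rates up (and increments down) reduces phase diffusion."""
    spec = ModuleSpec(dims=1, N=100)
    net = build_network(spec)
    st0 = relax_to_bump(net, T_relax=0.6, dt=DT)
    tau = spec.tau
    variances = []
    for scale in (1.0, 4.0, 16.0):
        rng = np.random.default_rng(3)
        trials = 40
        S = np.repeat(st0.s[:, None], trials, axis=1)
        phases0 = estimate_phase(SynapticState(s=S), net)
        ff = np.full((net.n_neurons, 1), spec.I0)
        for _ in range(int(0.5 / DT)):
            h = net.recurrent_input(S) + ff
            r = transfer(h, tau)
            counts = rng.poisson(r * scale * DT) / scale
            S = S * (1 - DT / tau) + counts
        d = (estimate_phase(SynapticState(s=S), net) - phases0 + 0.5) % 1.0 - 0.5
        variances.append(np.var(d))
    assert variances[0] > variances[1] > variances[2]
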