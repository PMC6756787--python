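"""Rate and Poisson-spiking dynamics of a single attractor module.

The synaptic activation s_i of neuron i follows

    tau * ds_i/dt = -s_i + tau * r_i,      r_i = phi(sum_j W_ij s_j + h_i),

with the rectified-linear transfer function phi(x) = max(x, 0) / tau and
feedforward drive h_i (constant I0 plus velocity terms).  In Poisson mode
the rate term is replaced by a spike train: each spike increments s_i by 1
and spike counts per step are Poisson with mean r_i * dt.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import AttractorNetwork

__all__ = [
    "SynapticState",
    "SpikeRaster",
    "transfer",
    "step_rate_dynamics",
    "step_poisson_dynamics",
    "relax_to_bump",
    "estimate_phase",
    "bump_contrast",
]


@dataclass
class SynapticState:
    """Synaptic activations of one module (or a batch of trials).

    ``s`` has shape (n_neurons,) or (n_neurons, n_batch); ``t`` is the
    simulation time in seconds.
    """

    s: np.ndarray
    t: float = 0.0

    def copy(self) -> "SynapticState":
        return SynapticState(s=self.s.copy(), t=self.t)


@dataclass
class SpikeRaster:
    """Spike times in coordinate form: parallel arrays (neuron_ids, times)."""

    neuron_ids: np.ndarray
    times: np.ndarray
    n_neurons: int
    duration: float

    def spike_times(self, i: int) -> np.ndarray:
        return np.sort(self.times[self.neuron_ids == i])

    def counts(self) -> np.ndarray:
        return np.bincount(self.neuron_ids, minlength=self.n_neurons)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.neuron_ids, "spike_time_s": self.times})


def transfer(x: np.ndarray, tau: float) -> np.ndarray:
    """phi(x) = max(x, 0) / tau; firing rate in Hz for drive x."""
    return np.maximum(x, 0.0) / tau


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.argmax(~np.isfinite(arr).reshape(-1)))
        raise FloatingPointError(f"non-finite {what} first at flat index {bad}")


def step_rate_dynamics(net: AttractorNetwork, state: SynapticState, feedforward, dt: float):
    """One explicit-Euler step of the rate dynamics.

    Returns ``(new_state, r)`` where ``r`` is the firing-rate vector used
    for the update.  ``feedforward`` is the per-neuron drive (broadcastable
    against ``state.s``).  Requires dt <= tau/10.
    """
    tau = net.spec.tau
    if dt > tau / 10 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau/10 = {tau / 10}")
    h = net.recurrent_input(state.s)
    h += np.broadcast_to(feedforward, h.shape)
    r = transfer(h, tau)
    s = state.s + dt * (r - state.s / tau)
    _check_finite(s, "synaptic activation")
    return SynapticState(s=s, t=state.t + dt), r


def step_poisson_dynamics(net: AttractorNetwork, state: SynapticState, feedforward, dt: float, rng):
    """One Euler step of the Poisson-spiking dynamics.

    Spike counts per neuron are Poisson with mean r_i*dt; each spike
    increments s_i by one while s decays with time constant tau.  Returns
    ``(new_state, counts)``.
    """
    if rng is None:
        raise ValueError("Poisson dynamics require a seeded numpy Generator")
    tau = net.spec.tau
    h = net.recurrent_input(state.s)
    h += np.broadcast_to(feedforward, h.shape)
    r = transfer(h, tau)
    counts = rng.poisson(r * dt)
    s = state.s * (1.0 - dt / tau) + counts
    _check_finite(s, "synaptic activation")
    return SynapticState(s=s, t=state.t + dt), counts


def bump_contrast(net: AttractorNetwork, s: np.ndarray) -> float:
    """max/mean activity ratio, used to detect whether a bump has formed."""
    m = float(np.mean(s))
    if m <= 0:
        return 0.0
    return float(np.max(s)) / m


def estimate_phase(state: SynapticState, net: AttractorNetwork):
    """Population-vector estimate of the bump phase.

    1D: scalar phase in [0, 1).  2D: the pair of lattice phase coordinates
    (c1, c2), each in [0, 1); the Cartesian bump position is
    ``c1 * u1 + c2 * u2``.  Raises if the activity profile is flat
    (max/mean < 1.5), in which case no bump phase is defined.
    """
    s = state.s
    if bump_contrast(net, s if s.ndim == 1 else s[:, 0]) < 1.5:
        raise RuntimeError("no bump formed: activity profile is flat")
    coords = net.lattice_coords
    if net.spec.dims == 1:
        z = np.tensordot(np.exp(2j * np.pi * coords), s, axes=(0, 0))
        return np.mod(np.angle(z) / (2 * np.pi), 1.0)
    out = []
    for k in range(2):
        z = np.tensordot(np.exp(2j * np.pi * coords[:, k]), s, axes=(0, 0))
        out.append(np.mod(np.angle(z) / (2 * np.pi), 1.0))
    return np.array(out) if np.ndim(out[0]) == 0 else np.stack(out)


def gaussian_bump_state(net: AttractorNetwork, phase=0.25, amplitude: float = 1.0) -> SynapticState:
    """Initial condition: Gaussian activity profile of width sigma at ``phase``."""
    from .networks import periodic_distance_1d, periodic_distance_2d, LATTICE_U1, LATTICE_U2

    sigma = np.sqrt(net.spec.sigma2)
    if net.spec.dims == 1:
        d = periodic_distance_1d(net.preferred_phase - phase)
    else:
        c1, c2 = np.broadcast_to(phase, (2,))
        center = c1 * LATTICE_U1 + c2 * LATTICE_U2
        d = periodic_distance_2d(net.preferred_phase - center)
    return SynapticState(s=amplitude * np.exp(-(d**2) / (2 * sigma**2)), t=0.0)


def relax_to_bump(
    net: AttractorNetwork,
    init=None,
    T_relax: float = 0.6,
    dt: float = 1e-4,
    phase=0.25,
    drift_tol: float = 1e-4,
) -> SynapticState:
    """Integrate the rate dynamics at zero velocity input to a steady bump.

    ``init`` may be a SynapticState or None (Gaussian profile at ``phase``).
    The bump phase measured over the last 10% of the relaxation must drift
    by less than ``drift_tol`` phase units; a flat final profile raises
    "no bump formed".
    """
    spec = net.spec
    if T_relax < 50 * spec.tau:
        raise ValueError("T_relax must be at least 50 tau")
    state = init.copy() if init is not None else gaussian_bump_state(net, phase=phase)
    n_steps = int(round(T_relax / dt))
    n_tail = max(1, n_steps // 10)
    ff = np.full(net.n_neurons, spec.I0)
    phase_at_tail = None
    for k in range(n_steps):
        state, _ = step_rate_dynamics(net, state, ff, dt)
        if k == n_steps - n_tail:
            if bump_contrast(net, state.s) < 1.5:
                raise RuntimeError("no bump formed: connectivity too weak to sustain a bump")
            phase_at_tail = estimate_phase(state, net)
    final_phase = estimate_phase(state, net)
    from .networks import periodic_distance_1d

    drift = np.max(periodic_distance_1d(np.atleast_1d(final_phase) - np.atleast_1d(phase_at_tail)))
    if drift > drift_tol:
        raise RuntimeError(f"bump phase still drifting ({drift:.2e} phase units) after T_relax")
    state.t = 0.0
    return state
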