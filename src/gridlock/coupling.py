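"""Velocity-readout coupling of several attractor modules.

Each module broadcasts a linear readout of its own phase velocity,

    omega_mu,q = (beta / tau) * (sum_{i in R} s_i - sum_{i in L} s_i)

(x channel; U/D for the y channel), and receives the readouts of the other
modules, scaled by a coupling matrix C, as an additional velocity input:

    r_{mu,i} = phi( sum_j W_ij s_{mu,j} + I0 +- b_mu,q +- a * sum_rho C_{mu rho} omega_rho,q )

The coupling depends on phase *velocities* only, never on phases, so every
combination of module phases remains a steady state: coordination is
enforced without sacrificing the combinatorial capacity of the code.
Because omega is a fixed linear functional of the synaptic activations, the
coupling is equivalent to all-to-all synaptic connectivity between modules
with uniform magnitudes and sub-population-dependent signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import SpikeRaster, SynapticState, relax_to_bump, transfer
from .networks import AttractorNetwork, ModuleSpec, build_network

__all__ = [
    "CouplingSpec",
    "CoupledSystem",
    "RunResult",
    "velocity_readout",
    "compute_input_scaling_a",
    "assemble_coupled_drive",
    "coupling_weight_matrix",
    "standard_coupling_parameters",
    "run_coupled",
    "LAMBDA_RATIO",
]

#: Grid-spacing ratio between successive modules.  The shipped couplings are
#: built from it: C1 = -Cs/lambda, C2 = -Cs*lambda with Cs = -20.
LAMBDA_RATIO = float(np.sqrt(2.0))


@dataclass
class CouplingSpec:
    """Coupling matrix and readout scale for an m-module system.

    ``C[mu, rho]`` is the coupling strength from module rho to module mu;
    the diagonal holds the (negative) self couplings.  ``beta`` only fixes
    the units of omega and drops out of the dynamics once the input scaling
    ``a`` (computed from the steady state) is applied.
    """

    C: np.ndarray
    beta: float = 1.0
    a: float | None = None

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be square")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("C must be finite")

    @property
    def m(self) -> int:
        return self.C.shape[0]


def standard_coupling_parameters(m: int, C_s: float = -20.0) -> CouplingSpec:
    """The shipped coupling matrices for two or three modules.

    m=2: off-diagonal couplings -Cs/lambda (~14.14) and -Cs*lambda (~28.28).
    m=3: tridiagonal (coupling only between successive modules) with
    C12 = -Cs/lambda, C21 = C23 = 9.4, C32 = -Cs*lambda, C13 = C31 = 0.
    Other module counts require a user-supplied matrix.
    """
    lam = LAMBDA_RATIO
    if m == 2:
        C = np.array([[C_s, -C_s / lam], [-C_s * lam, C_s]])
    elif m == 3:
        C = np.array(
            [
                [C_s, -C_s / lam, 0.0],
                [9.4, C_s, 9.4],
                [0.0, -C_s * lam, C_s],
            ]
        )
    else:
        raise ValueError(f"no shipped coupling parameters for m={m}; supply a CouplingSpec")
    return CouplingSpec(C=C)


def velocity_readout(state: SynapticState, net: AttractorNetwork, beta: float = 1.0):
    """Linear phase-velocity estimate omega of one module.

    Returns a scalar (1D module) or an array of two channel values (2D);
    batched states return an extra trailing axis.
    """
    out = []
    for q in range(net.spec.dims):
        out.append(beta / net.spec.tau * (net.channel_signs(q) @ state.s))
    return out[0] if net.spec.dims == 1 else np.stack(out)


def compute_input_scaling_a(net: AttractorNetwork, relaxed_state: SynapticState, beta: float = 1.0) -> float:
    """Input scaling a = [beta * sum_i phi'(W s_bar + I0)_i]^{-1}.

    phi'(x) = 1/tau for x > 0 and 0 for x <= 0, so a = tau / (beta * n_act)
    with n_act the number of neurons with positive net input at the steady
    bump.  The product a*omega is independent of beta.
    """
    h = net.recurrent_input(relaxed_state.s) + net.spec.I0
    n_act = int(np.count_nonzero(h > 0))
    if n_act == 0:
        raise RuntimeError("no active neurons at the provided state; cannot scale couplings")
    return net.spec.tau / (beta * n_act)


@dataclass
class CoupledSystem:
    """m attractor modules plus their velocity coupling."""

    modules: list[AttractorNetwork]
    coupling: CouplingSpec
    states: list[SynapticState] = field(default_factory=list)

    def __post_init__(self) -> None:
        dims = {net.spec.dims for net in self.modules}
        taus = {net.spec.tau for net in self.modules}
        if len(dims) != 1 or len(taus) != 1:
            raise ValueError("all modules must share dims and tau")
        if len(self.modules) != self.coupling.m:
            raise ValueError("coupling matrix size must match module count")

    @classmethod
    def build(
        cls,
        m: int,
        spec: ModuleSpec | None = None,
        coupling: CouplingSpec | None = None,
        uncoupled: bool = False,
    ) -> "CoupledSystem":
        """Build m identical modules with the shipped coupling parameters.

        ``uncoupled=True`` zeroes every coupling (including self coupling),
        the control condition used throughout the analyses.
        """
        spec = spec or ModuleSpec()
        if coupling is None:
            coupling = CouplingSpec(C=np.zeros((m, m))) if uncoupled else standard_coupling_parameters(m)
        net = build_network(spec)
        # identical architecture: share the realized weights across modules
        modules = [net] * m
        return cls(modules=modules, coupling=coupling)

    @property
    def m(self) -> int:
        return len(self.modules)

    @property
    def dims(self) -> int:
        return self.modules[0].spec.dims

    @property
    def tau(self) -> float:
        return self.modules[0].spec.tau

    @property
    def n_neurons(self) -> int:
        return sum(net.n_neurons for net in self.modules)

    def module_slices(self) -> list[slice]:
        out, start = [], 0
        for net in self.modules:
            out.append(slice(start, start + net.n_neurons))
            start += net.n_neurons
        return out

    def relax(self, phases=None, T_relax: float = 0.6, dt: float = 1e-4) -> "CoupledSystem":
        """Relax every module (uncoupled, zero velocity input) to its bump.

        At a symmetric steady bump each omega vanishes, so the stack of
        single-module steady states is a steady state of the coupled system
        as well.  ``phases`` optionally places each module's bump.
        Computes and stores the input scaling ``a`` from module 0.
        """
        if phases is None:
            phases = [0.25] * self.m
        states = []
        relaxed_by_phase: dict = {}
        for net, ph in zip(self.modules, phases):
            key = (id(net), tuple(np.atleast_1d(np.asarray(ph, dtype=float)).tolist()))
            if key not in relaxed_by_phase:
                relaxed_by_phase[key] = relax_to_bump(net, T_relax=T_relax, dt=dt, phase=ph)
            states.append(relaxed_by_phase[key].copy())
        self.states = states
        if self.coupling.a is None:
            self.coupling.a = compute_input_scaling_a(self.modules[0], states[0], self.coupling.beta)
        return self

    def stacked_state(self, n_batch: int | None = None) -> np.ndarray:
        if not self.states:
            raise RuntimeError("system not relaxed: call .relax() first")
        s = np.concatenate([st.s for st in self.states])
        if n_batch is not None:
            s = np.repeat(s[:, None], n_batch, axis=1)
        return s

    def omegas(self, S: np.ndarray) -> np.ndarray:
        """Velocity readouts from a stacked state, shape (m, dims[, batch])."""
        beta, tau = self.coupling.beta, self.tau
        out = np.empty((self.m, self.dims) + S.shape[1:])
        for mu, (net, sl) in enumerate(zip(self.modules, self.module_slices())):
            for q in range(self.dims):
                out[mu, q] = beta / tau * (net.channel_signs(q) @ S[sl])
        return out


def assemble_coupled_drive(system: CoupledSystem, b, S: np.ndarray | None = None, omegas: np.ndarray | None = None):
    """Per-neuron feedforward drive for every module.

    ``b`` holds the external velocity inputs, shape (m, dims) (or
    broadcastable against it; an extra trailing batch axis is allowed when
    ``S`` is batched).  Returns the stacked drive vector: neuron i of module
    mu in the positive (negative) sub-population of channel q receives
    ``I0 +- (b[mu, q] + a * sum_rho C[mu, rho] * omega[rho, q])``.
    """
    if system.coupling.a is None:
        raise RuntimeError("input scaling a not set: relax the system first")
    if omegas is None:
        if S is None:
            S = system.stacked_state()
        omegas = system.omegas(S)
    b = np.asarray(b, dtype=float)
    want = omegas.shape
    if b.shape != want:
        b = np.broadcast_to(b.reshape(b.shape + (1,) * (len(want) - b.ndim)), want)
    if b.shape[0] != system.m:
        raise ValueError("b must provide one entry per module")
    a, C = system.coupling.a, system.coupling.C
    vel = b + a * np.einsum("mr,rq...->mq...", C, omegas)
    batch_shape = omegas.shape[2:]
    drive = np.empty((system.n_neurons,) + batch_shape)
    for mu, (net, sl) in enumerate(zip(system.modules, system.module_slices())):
        d = np.full((net.n_neurons,) + batch_shape, net.spec.I0)
        for q in range(system.dims):
            sgn = net.channel_signs(q)
            d += sgn.reshape((-1,) + (1,) * len(batch_shape)) * vel[mu, q]
        drive[sl] = d
    return drive


def coupling_weight_matrix(beta: float, tau: float, post_net: AttractorNetwork, pre_net: AttractorNetwork) -> np.ndarray:
    """Explicit synaptic form of the velocity coupling between two modules.

    Entries are +-beta/tau, the sign given by the product of the pre- and
    post-synaptic sub-population polarities within a channel (R/L for x,
    U/D for y); entries across channels vanish.  Multiplying this matrix by
    the presynaptic state vector reproduces ``sign_post * omega_pre``.
    """
    W = np.zeros((post_net.n_neurons, pre_net.n_neurons))
    for q in range(post_net.spec.dims):
        W += np.outer(post_net.channel_signs(q), pre_net.channel_signs(q))
    return beta / tau * W


@dataclass
class RunResult:
    """Output of :func:`run_coupled`.

    ``phases`` are unwrapped (continuity across the periodic boundary is
    resolved by nearest image), shape (n_rec, m, dims, n_batch); ``omegas``
    likewise.  ``raster`` is populated only when spikes were generated for a
    single trial and ``record_spikes`` was requested.
    """

    times: np.ndarray
    phases: np.ndarray
    omegas: np.ndarray
    final_state: np.ndarray
    raster: SpikeRaster | None = None
    decoder_output: object = None

    def phase_trajectory(self, mu: int, q: int = 0, trial: int = 0) -> np.ndarray:
        return self.phases[:, mu, q, trial]


def _unwrap_phases(ph: np.ndarray) -> np.ndarray:
    """Unwrap along axis 0 by nearest-image continuity (period 1)."""
    d = np.diff(ph, axis=0)
    d -= np.round(d)
    return ph[0] + np.concatenate([np.zeros((1,) + ph.shape[1:]), np.cumsum(d, axis=0)])


def run_coupled(
    system: CoupledSystem,
    b,
    dt: float,
    mode: str = "rate",
    rng=None,
    record_stride: int = 10,
    n_batch: int | None = None,
    readout_spikes: bool = False,
    record_spikes: bool = False,
    decoder=None,
    spike_stride: int = 1,
    s_ceiling: float = 1e6,
    omega_drive_ceiling: float = 0.3,
    initial_state: np.ndarray | None = None,
):
    """Integrate the coupled system under external velocity inputs ``b``.

    Parameters
    ----------
    b : ndarray
        External velocity inputs per step: shape (n_steps, m, dims) for a
        single trial or (n_steps, m, dims, n_batch) for batched trials.
    mode : {"rate", "poisson"}
        Deterministic rate dynamics, or Poisson-spiking dynamics (each
        spike increments s by 1; counts per step ~ Poisson(r*dt)).
    readout_spikes : bool
        In rate mode, additionally draw Poisson spikes from the
        instantaneous rates for the readout only (they do not feed back
        into the dynamics); required when ``decoder`` is given in rate mode.
    decoder : OnlineDecoder, optional
        Consumes spike counts each step and decodes at its own stride.
    spike_stride : int
        Draw spikes every ``spike_stride`` steps with mean r*dt*stride
        (exact for piecewise-constant rates); reduces sampling cost.

    Returns a :class:`RunResult` with phases and readouts recorded every
    ``record_stride`` steps (unwrapped).
    """
    b = np.asarray(b, dtype=float)
    if b.ndim == 3:
        b = b[..., None]
    if b.ndim != 4 or b.shape[1] != system.m or b.shape[2] != system.dims:
        raise ValueError("b must have shape (n_steps, m, dims[, n_batch])")
    if n_batch is None:
        n_batch = b.shape[3]
        if initial_state is not None and initial_state.ndim == 2:
            n_batch = max(n_batch, initial_state.shape[1])
    if b.shape[3] not in (1, n_batch):
        raise ValueError("batch axis of b incompatible with n_batch")
    n_steps = b.shape[0]
    tau, I0s = system.tau, [net.spec.I0 for net in system.modules]
    if dt > tau / 10 + 1e-12:
        raise ValueError(f"dt={dt} too coarse; need dt <= tau/10")
    rho_C = float(np.max(np.abs(np.linalg.eigvals(system.coupling.C))))
    dt_max = 1.6 * tau / (1.0 + rho_C)
    if dt > dt_max:
        raise ValueError(
            f"dt={dt} cannot resolve the stiff coupling mode at ~(1+{rho_C:.1f})/tau; "
            f"use dt <= {dt_max:.2e}"
        )
    if mode not in ("rate", "poisson"):
        raise ValueError("mode must be 'rate' or 'poisson'")
    want_spikes = mode == "poisson" or readout_spikes or decoder is not None or record_spikes
    if want_spikes and rng is None:
        raise ValueError("spike generation requires a seeded numpy Generator")
    if system.coupling.a is None:
        raise RuntimeError("input scaling a not set: relax the system first")

    S = initial_state if initial_state is not None else system.stacked_state(n_batch)
    if S.ndim == 1:
        S = S[:, None]
    S = S.astype(float).copy()
    if S.shape[1] == 1 and n_batch > 1:
        S = np.repeat(S, n_batch, axis=1)

    slices = system.module_slices()
    a, C, beta = system.coupling.a, system.coupling.C, system.coupling.beta
    # precomputed per module: channel sign matrices and phase-readout vectors
    signs = [np.stack([net.channel_signs(q) for q in range(system.dims)]) for net in system.modules]
    expvecs = []
    for net in system.modules:
        coords = net.lattice_coords
        coords = coords[:, None] if coords.ndim == 1 else coords
        expvecs.append(np.exp(2j * np.pi * coords.T))  # (dims, n_neurons)

    n_rec = n_steps // record_stride + 1
    rec_t = np.empty(n_rec)
    rec_ph = np.empty((n_rec, system.m, system.dims, n_batch))
    rec_om = np.empty((n_rec, system.m, system.dims, n_batch))
    spike_ids, spike_ts = [], []

    pending_rate = None  # accumulated for spike_stride > 1
    t = 0.0
    k_rec = 0

    def record(idx, t):
        nonlocal k_rec
        rec_t[idx] = t
        for mu, sl in enumerate(slices):
            z = expvecs[mu] @ S[sl]
            rec_ph[idx, mu] = np.mod(np.angle(z) / (2 * np.pi), 1.0)
            rec_om[idx, mu] = beta / tau * (signs[mu] @ S[sl])

    record(0, 0.0)
    for k in range(n_steps):
        # velocity inputs: external + coupling
        om = np.empty((system.m, system.dims, n_batch))
        for mu, sl in enumerate(slices):
            om[mu] = beta / tau * (signs[mu] @ S[sl])
        vel = b[k] + a * np.einsum("mr,rqk->mqk", C, om)
        R = np.empty_like(S)
        for mu, sl in enumerate(slices):
            net = system.modules[mu]
            h = net.recurrent_input(S[sl])
            h += I0s[mu]
            h += np.einsum("qn,qk->nk", signs[mu], vel[mu])
            R[sl] = transfer(h, tau)
        counts = None
        if mode == "poisson":
            counts = rng.poisson(R * dt)
            S *= 1.0 - dt / tau
            S += counts
        else:
            S += dt * (R - S / tau)
            if want_spikes:
                pending_rate = R.copy() if pending_rate is None else pending_rate + R
                if (k + 1) % spike_stride == 0:
                    counts = rng.poisson(pending_rate * dt)
                    pending_rate = None
        t += dt
        if counts is not None:
            if decoder is not None:
                elapsed = dt if mode == "poisson" else dt * spike_stride
                decoder.advance(counts, t, elapsed)
            if record_spikes and n_batch == 1:
                nz = np.nonzero(counts[:, 0])[0]
                for i in nz:
                    spike_ids.extend([i] * int(counts[i, 0]))
                    spike_ts.extend([t] * int(counts[i, 0]))
        if (k + 1) % record_stride == 0:
            idx = (k + 1) // record_stride
            record(idx, t)
            # divergence shows either as runaway activity or as runaway
            # readout velocity (the attractor bounds |s| even when the
            # velocity loop is unstable, but a*omega then saturates far
            # beyond any physical velocity drive)
            too_fast = a * np.max(np.abs(rec_om[idx])) > omega_drive_ceiling
            if too_fast or not np.all(np.abs(S[:, 0]) < s_ceiling):
                raise RuntimeError(
                    "run diverged (runaway activity or phase velocity); the coupling "
                    "matrix is likely unstable -- screen it with response.check_stability "
                    "(for legitimately fast runs, record more densely)"
                )

    raster = None
    if record_spikes and n_batch == 1:
        raster = SpikeRaster(
            neuron_ids=np.array(spike_ids, dtype=int),
            times=np.array(spike_ts),
            n_neurons=system.n_neurons,
            duration=t,
        )
    return RunResult(
        times=rec_t,
        phases=_unwrap_phases(rec_ph),
        omegas=rec_om,
        final_state=S,
        raster=raster,
        decoder_output=decoder.result() if decoder is not None else None,
    )
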