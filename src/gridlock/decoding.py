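"""Spike-based maximum-likelihood position readout.

Each module represents position through its phase, theta_mu = ((x - x_ref)
/ lambda_mu + psi_ref) mod 1 per coordinate, so a single module is
ambiguous (periodic likelihood); the joint readout over modules with
incommensurate spacings is unambiguous over a large range.  The decoder
forms, per neuron, an exponentially weighted effective spike count

    n_i(t) = sum_chi exp(-(t - t_i^chi) / tau_d),   t_i^chi <= t,

and reads out x_hat(t) = argmax_x sum_i n_i(t) ln rbar_i(x), where
rbar_i(x) is the neuron's receptive field measured from the steady state of
the network.  Small incompatible phase drifts across modules can make the
argmax jump to a distant location -- a catastrophic readout error -- which
is scored as a discontinuity of the decoded path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .coupling import CoupledSystem
from .dynamics import SpikeRaster, estimate_phase, transfer
from .networks import LATTICE_U1, LATTICE_U2

__all__ = [
    "ReceptiveFieldMap",
    "DecodedPath",
    "DriftMetrics",
    "measure_receptive_fields",
    "OnlineDecoder",
    "decode_position",
    "detect_discontinuities",
    "success_and_error_curves",
    "phase_msd_mse",
]


@dataclass
class ReceptiveFieldMap:
    """Per-neuron mean firing rate on a position grid.

    ``grid`` has shape (G, dims) (2D grids are flattened C-order over
    ``grid_shape``); ``rates`` has shape (n_neurons, G) with the rate floor
    already applied; ``log_rates`` is its logarithm, the decoder template.
    """

    grid: np.ndarray
    grid_shape: tuple
    rates: np.ndarray
    log_rates: np.ndarray
    spacings: np.ndarray
    arena_lo: np.ndarray
    arena_hi: np.ndarray
    eps_frac: float

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]


def _module_rest_profile(system: CoupledSystem, idx: int):
    """Rest-state rate field of one sub-population and the bump phase.

    At the symmetric steady state all sub-populations of a module carry the
    same profile, so one sheet/ring suffices.
    """
    net, st = system.modules[idx], system.states[idx]
    h = net.recurrent_input(st.s) + net.spec.I0
    rates = transfer(h, net.spec.tau)
    psi = estimate_phase(st, net)
    N = net.spec.N
    if net.spec.dims == 1:
        return rates[:N], np.atleast_1d(psi)
    n_side = round(N**0.5)
    return rates[:N].reshape(n_side, n_side), np.atleast_1d(psi)


_LATTICE_M = np.stack([LATTICE_U1, LATTICE_U2])  # rows u1, u2
_LATTICE_MINV = np.linalg.inv(_LATTICE_M)


def measure_receptive_fields(
    system: CoupledSystem,
    spacings,
    arena_lo,
    arena_hi,
    grid_step: float | None = None,
    ref_position=None,
    eps_frac: float = 1e-4,
    max_grid_2d: int = 200,
) -> ReceptiveFieldMap:
    """Receptive fields of every neuron over a position grid.

    For each grid position the bump of module mu is placed at the phase
    corresponding to that position (a translation of the relaxed state by
    ``(x - ref_position) / lambda_mu`` away from its current phase) and the
    steady rates are read off by periodic linear interpolation of the
    rest-state profile.  ``ref_position`` anchors the phase-position map to
    the system's current (relaxed) phases; it defaults to the arena center.

    Rates are floored at ``eps_frac`` times each neuron's maximum so the
    log template is finite everywhere.
    """
    if not system.states:
        raise RuntimeError("system must be relaxed before measuring receptive fields")
    spacings = np.asarray(spacings, dtype=float)
    dims = system.dims
    lo = np.broadcast_to(np.asarray(arena_lo, dtype=float), (dims,))
    hi = np.broadcast_to(np.asarray(arena_hi, dtype=float), (dims,))
    lam_min = spacings.min()
    if grid_step is None:
        grid_step = lam_min / 50.0
    if grid_step > lam_min / 10.0:
        import warnings

        warnings.warn("grid step coarser than lambda_min/10: decoder resolution limited")
    axes = []
    for q in range(dims):
        n_pts = max(2, int(np.floor((hi[q] - lo[q]) / grid_step)) + 1)
        if dims == 2:
            n_pts = min(n_pts, max_grid_2d)
        axes.append(np.linspace(lo[q], hi[q], n_pts))
    if dims == 1:
        grid = axes[0][:, None]
        grid_shape = (len(axes[0]),)
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        grid_shape = gx.shape
    x_ref = (lo + hi) / 2.0 if ref_position is None else np.broadcast_to(np.asarray(ref_position, float), (dims,))

    rates_all = []
    for mu, net in enumerate(system.modules):
        profile, psi0 = _module_rest_profile(system, mu)
        N = net.spec.N
        if dims == 1:
            # bump displacement from the reference phase when the animal is
            # at x; the profile is indexed by preferred phase at the
            # reference bump position, so only the displacement shifts it
            dpsi = (grid[:, 0] - x_ref[0]) / spacings[mu]
            offs = np.mod(net.coords[:, None] - dpsi[None, :], 1.0)  # (N, G)
            r_unit = map_coordinates(profile, offs.reshape(1, -1) * N, order=1, mode="grid-wrap")
            r_unit = r_unit.reshape(N, -1)
        else:
            # bump displacement in lattice coordinates
            dc = ((grid - x_ref) / spacings[mu]) @ _LATTICE_MINV  # (G, 2)
            n_side = round(N**0.5)
            o1 = np.mod(net.coords[:, 0][:, None] - dc[:, 0][None, :], 1.0) * n_side
            o2 = np.mod(net.coords[:, 1][:, None] - dc[:, 1][None, :], 1.0) * n_side
            r_unit = map_coordinates(profile, [o1.ravel(), o2.ravel()], order=1, mode="grid-wrap")
            r_unit = r_unit.reshape(N, -1)
        rates_all.append(np.tile(r_unit, (net.spec.n_subpops, 1)))
    rates = np.vstack(rates_all)
    floor = eps_frac * rates.max(axis=1, keepdims=True)
    floor[floor <= 0] = eps_frac
    rates = np.maximum(rates, floor)
    return ReceptiveFieldMap(
        grid=grid,
        grid_shape=grid_shape,
        rates=rates,
        log_rates=np.log(rates),
        spacings=spacings,
        arena_lo=lo,
        arena_hi=hi,
        eps_frac=eps_frac,
    )


@dataclass
class DecodedPath:
    """Decoder output on a common time grid.

    ``positions`` has shape (n_samples, dims) or (n_samples, dims,
    n_trials).  ``valid`` marks samples at or after the first spike (the
    decoder is undefined before any spike arrived).
    """

    times: np.ndarray
    positions: np.ndarray
    log_likelihood: np.ndarray
    valid: np.ndarray

    @property
    def n_trials(self) -> int:
        return 1 if self.positions.ndim == 2 else self.positions.shape[2]


class OnlineDecoder:
    """Streaming exponential-kernel ML decoder.

    Feed spike counts with :meth:`advance`; the decoder maintains the
    per-neuron effective counts (running update ``n <- n * exp(-dt/tau_d) +
    counts``, exactly the exponential-kernel sum) and decodes every
    ``stride`` seconds.  Ties in the likelihood argmax resolve to the
    lowest grid index.
    """

    def __init__(self, rf: ReceptiveFieldMap, n_batch: int = 1, tau_d: float = 0.010, stride: float = 0.010):
        self.rf = rf
        self.tau_d = tau_d
        self.stride = stride
        self.n_eff = np.zeros((rf.n_neurons, n_batch))
        self._seen_spike = np.zeros(n_batch, dtype=bool)
        self._next_decode = stride
        self._times, self._pos, self._ll, self._valid = [], [], [], []

    def advance(self, counts: np.ndarray, t_now: float, elapsed: float) -> None:
        if counts.ndim == 1:
            counts = counts[:, None]
        self.n_eff *= np.exp(-elapsed / self.tau_d)
        self.n_eff += counts
        self._seen_spike |= counts.any(axis=0)
        if t_now + 1e-12 >= self._next_decode:
            ll = self.n_eff.T @ self.rf.log_rates  # (batch, G)
            best = np.argmax(ll, axis=1)
            self._times.append(t_now)
            self._pos.append(self.rf.grid[best])
            self._ll.append(ll[np.arange(ll.shape[0]), best])
            self._valid.append(self._seen_spike.copy())
            self._next_decode += self.stride

    def result(self) -> DecodedPath:
        pos = np.stack(self._pos)  # (n_samples, batch, dims)
        return DecodedPath(
            times=np.array(self._times),
            positions=np.moveaxis(pos, 1, 2),  # (n_samples, dims, batch)
            log_likelihood=np.stack(self._ll),
            valid=np.stack(self._valid),
        )


def decode_position(spikes: SpikeRaster, rf: ReceptiveFieldMap, tau_d: float, sample_times) -> DecodedPath:
    """Decode a stored spike raster at the given sample times.

    Equivalent to the running-update decoder: per sample, the effective
    count of neuron i is the exponentially discounted sum over its past
    spikes.  Samples before the first spike are flagged invalid.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    order = np.argsort(spikes.times, kind="stable")
    ts, ids = spikes.times[order], spikes.neuron_ids[order]
    n_eff = np.zeros(rf.n_neurons)
    out_pos, out_ll, out_valid = [], [], []
    t_prev = 0.0
    ptr = 0
    first_spike = ts[0] if len(ts) else np.inf
    for t in sample_times:
        # absorb spikes up to t with their individual decays
        k = np.searchsorted(ts, t, side="right")
        if k > ptr:
            n_eff *= np.exp(-(t - t_prev) / tau_d)
            w = np.exp(-(t - ts[ptr:k]) / tau_d)
            np.add.at(n_eff, ids[ptr:k], w)
            ptr = k
        else:
            n_eff *= np.exp(-(t - t_prev) / tau_d)
        t_prev = t
        ll = rf.log_rates.T @ n_eff
        best = int(np.argmax(ll))
        out_pos.append(rf.grid[best])
        out_ll.append(ll[best])
        out_valid.append(t >= first_spike)
    return DecodedPath(
        times=sample_times,
        positions=np.asarray(out_pos),
        log_likelihood=np.asarray(out_ll),
        valid=np.asarray(out_valid),
    )


def detect_discontinuities(positions: np.ndarray, threshold: float, valid=None) -> np.ndarray:
    """Indices k where ||x(t_k) - x(t_{k-1})|| exceeds the threshold.

    ``positions`` is (n_samples, dims[, n_trials]); returns a boolean event
    array of shape (n_samples, [n_trials]) with the first sample False.
    Jumps from or to invalid samples are not counted.
    """
    d = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    ev = d > threshold
    pad = np.zeros((1,) + ev.shape[1:], dtype=bool)
    ev = np.concatenate([pad, ev], axis=0)
    if valid is not None:
        ok = valid & np.concatenate([pad, valid[:-1]], axis=0)
        ev &= ok
    return ev


@dataclass
class DriftMetrics:
    """Trial-averaged drift and readout-quality curves."""

    times: np.ndarray
    success: np.ndarray | None = None  # fraction of discontinuity-free trials
    mse: np.ndarray | None = None  # (n_samples,) or (n_samples, m), m^2
    mse_slopes: np.ndarray | None = None  # least-squares slope(s), m^2/s
    msd_pairs: dict = field(default_factory=dict)  # (mu, rho) -> MSD curve
    random_guess_mse: np.ndarray | None = None
    n_trials: int = 0


def success_and_error_curves(path: DecodedPath, true_positions: np.ndarray, threshold: float, arena_lo=None, arena_hi=None) -> DriftMetrics:
    """Success(t) and MSE(t) of a batch of decoded trials.

    A trial is a success at time t if no discontinuity (jump above
    ``threshold`` between consecutive decoded samples) occurred in (0, t].
    The random-guess baseline is the expected squared distance between the
    true position and a uniform point in the arena.
    """
    pos = path.positions if path.positions.ndim == 3 else path.positions[..., None]
    n_t, dims, n_tr = pos.shape
    if n_tr < 2:
        raise ValueError("need at least 2 trials for trial-averaged curves")
    true_positions = np.asarray(true_positions, dtype=float).reshape(n_t, dims)
    valid = path.valid if path.valid.ndim == 2 else path.valid[:, None]
    ev = detect_discontinuities(pos, threshold, valid=valid)
    failed = np.cumsum(ev, axis=0) > 0
    success = 1.0 - failed.mean(axis=1)
    err = pos - true_positions[:, :, None]
    mse = np.mean(np.sum(err**2, axis=1), axis=1)
    baseline = None
    if arena_lo is not None and arena_hi is not None:
        lo = np.broadcast_to(np.asarray(arena_lo, float), (dims,))
        hi = np.broadcast_to(np.asarray(arena_hi, float), (dims,))
        mid, span = (lo + hi) / 2.0, hi - lo
        baseline = np.sum(span**2) / 12.0 + np.sum((true_positions - mid) ** 2, axis=1)
    slope = _ls_slope(path.times, mse)
    return DriftMetrics(
        times=path.times,
        success=success,
        mse=mse,
        mse_slopes=np.array([slope]),
        random_guess_mse=baseline,
        n_trials=n_tr,
    )


def _ls_slope(t, y):
    tc = t - t.mean()
    return float(tc @ (y - y.mean(axis=0)) / (tc @ tc)) if y.ndim == 1 else (tc @ (y - y.mean(axis=0))) / (tc @ tc)


def phase_msd_mse(times, phases, spacings, true_positions) -> DriftMetrics:
    """Drift coordination metrics from (unwrapped) phase trajectories.

    ``phases``: (n_samples, m, n_trials) unwrapped phases along one
    direction.  Each module's path in meters is its phase times its
    spacing, anchored at the true start.  Reports pairwise mean square
    displacement between the scaled module paths, the per-module MSE
    against the true path, and the least-squares MSE slopes.
    """
    phases = np.asarray(phases, dtype=float)
    if np.any(np.abs(np.diff(phases, axis=0)) > 0.5):
        raise ValueError("phases look wrapped (successive jump > 0.5); unwrap before calling")
    spacings = np.asarray(spacings, dtype=float)
    n_t, m, n_tr = phases.shape
    true_positions = np.asarray(true_positions, dtype=float).reshape(n_t)
    pos = spacings[None, :, None] * (phases - phases[0]) + true_positions[0]
    msd = {}
    for mu in range(m):
        for rho in range(mu + 1, m):
            msd[(mu, rho)] = np.mean((pos[:, mu] - pos[:, rho]) ** 2, axis=1)
    err2 = (pos - true_positions[:, None, None]) ** 2
    mse = err2.mean(axis=2)  # (n_t, m)
    slopes = _ls_slope(times, mse)
    return DriftMetrics(times=times, mse=mse, mse_slopes=np.asarray(slopes), msd_pairs=msd, n_trials=n_tr)
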