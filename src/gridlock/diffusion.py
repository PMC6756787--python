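"""Phase diffusion of the Poisson-spiking coupled system.

With spiking neurons the attractor phases perform a random walk.  Around a
steady state s_bar the drift of the coupled dynamics is linearized,

    J = -I/tau + diag(phi'(h)) (W_blockdiag + K),

where K is the rank-limited inter-module coupling (omega is a linear
functional of s, so it enters the Jacobian through s only).  J has one
near-zero eigenvalue per module and direction -- the attractor manifold.
The diffusion tensor of the phases is

    D_{mu rho} = 1/2 sum_i nu_{mu,i} nu_{rho,i} rbar_i,

where nu_mu is the left null eigenvector of J for a phase shift of module
mu, bi-orthonormalized against the manifold tangents (nu_mu . T_rho =
delta_{mu rho}), and rbar_i are the steady-state firing rates.  Its
eigen-decomposition separates coordinated drift (D+) from relative drift
(D-); the velocity coupling makes D+/D- large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.linalg import LinearOperator, eigs

from .coupling import CoupledSystem, run_coupled
from .dynamics import transfer

__all__ = [
    "DiffusionTensor",
    "coupled_steady_state_and_jacobian",
    "phase_tangents",
    "null_left_eigenvectors",
    "diffusion_tensor",
    "phase_diffusion_tensor",
    "empirical_diffusion",
]


@dataclass
class DiffusionTensor:
    """Symmetric m x m phase diffusion tensor (phase^2 / second)."""

    D: np.ndarray
    eigenvalues: np.ndarray  # descending, D+ first
    eigenvectors: np.ndarray  # columns matching eigenvalues
    reference_phases: np.ndarray | None = None

    @property
    def anisotropy(self) -> float:
        """D+ / D-."""
        return float(self.eigenvalues[0] / self.eigenvalues[-1])

    @property
    def principal_angle_deg(self) -> float:
        """Angle of the major axis in the (theta_1, theta_2) plane (m=2)."""
        v = self.eigenvectors[:, 0]
        return float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)


def _steady_drive(system: CoupledSystem, s_bar: np.ndarray) -> np.ndarray:
    """Net input h at the steady state (coupling terms vanish: omega = 0)."""
    h = np.empty_like(s_bar)
    for net, sl in zip(system.modules, system.module_slices()):
        h[sl] = net.recurrent_input(s_bar[sl]) + net.spec.I0
    return h


def coupled_steady_state_and_jacobian(
    system: CoupledSystem,
    zero_tol_factor: float = 0.1,
    gap_factor: float = 10.0,
    check_manifold: bool = True,
):
    """Steady state and Jacobian of the coupled drift at zero input.

    Returns ``(s_bar, J)``.  The system must be relaxed; the stack of
    single-module bumps is a steady state of the coupled system because
    every velocity readout vanishes there.  When ``check_manifold`` is on,
    verifies that J has exactly m*dims eigenvalues with magnitude below
    ``zero_tol_factor / tau``, separated by ``gap_factor`` from the rest.

    The soft (attractor-manifold) eigenvalues are not exactly zero at
    finite N: the rectification boundary of the bump breaks continuous
    translation symmetry, leaving soft modes at a few percent of 1/tau
    that shrink with network size while the first relaxation mode stays
    near 1/tau -- hence a tolerance of 0.1/tau with a x10 spectral gap.
    """
    tau = system.tau
    s_bar = system.stacked_state()
    h = _steady_drive(system, s_bar)
    act = (h > 0).astype(float)
    a, beta, C = system.coupling.a, system.coupling.beta, system.coupling.C
    n = system.n_neurons
    slices = system.module_slices()
    M = np.zeros((n, n))
    for net, sl in zip(system.modules, slices):
        M[sl, sl] = net.full_weight_matrix()
    for q in range(system.dims):
        sgns = [net.channel_signs(q) for net in system.modules]
        for mu, sl_mu in enumerate(slices):
            for rho, sl_rho in enumerate(slices):
                if C[mu, rho] != 0.0:
                    M[sl_mu, sl_rho] += a * beta / tau * C[mu, rho] * np.outer(sgns[mu], sgns[rho])
    J = M * (act / tau)[:, None]
    J[np.diag_indices(n)] -= 1.0 / tau
    if check_manifold:
        expected = system.m * system.dims
        lam = _smallest_eigenvalues(J, k=expected + 2)
        mags = np.sort(np.abs(lam))
        tol = zero_tol_factor / tau
        n_zero = int(np.sum(mags < tol))
        if n_zero < expected or mags[expected] < gap_factor * mags[expected - 1]:
            raise RuntimeError(
                f"attractor manifold not found: {n_zero} near-zero eigenvalues "
                f"(expected {expected}); |eig| magnitudes {mags}"
            )
    return s_bar, J


def _lu_operator(J: np.ndarray, trans: int):
    lu = scipy.linalg.lu_factor(J)
    n = J.shape[0]
    return LinearOperator((n, n), matvec=lambda x: scipy.linalg.lu_solve(lu, x, trans=trans))


def _smallest_eigenvalues(J: np.ndarray, k: int) -> np.ndarray:
    """Eigenvalues of J closest to zero via shift-invert (deterministic start)."""
    op = _lu_operator(J, trans=0)
    n = J.shape[0]
    v0 = np.full(n, 1.0 / np.sqrt(n))
    mu = eigs(op, k=k, which="LM", return_eigenvectors=False, v0=v0)
    return 1.0 / mu


def phase_tangents(system: CoupledSystem) -> np.ndarray:
    """Attractor-manifold tangents ds_bar/dtheta, shape (n, m*dims).

    Computed by central finite differences of the steady state translated
    by one lattice site in each module and direction, scaled to a unit
    phase step.  Translating module mu leaves the other modules steady, so
    each tangent is supported on one module block.
    """
    s_bar = system.stacked_state()
    n = system.n_neurons
    cols = []
    for net, sl in zip(system.modules, system.module_slices()):
        s_mod = s_bar[sl]
        if system.dims == 1:
            N = net.spec.N
            parts_p = [np.roll(s_mod[i * N:(i + 1) * N], 1) for i in range(net.spec.n_subpops)]
            parts_m = [np.roll(s_mod[i * N:(i + 1) * N], -1) for i in range(net.spec.n_subpops)]
            d = (np.concatenate(parts_p) - np.concatenate(parts_m)) * (N / 2.0)
            col = np.zeros(n)
            col[sl] = d
            cols.append(col)
        else:
            N = net.spec.N
            n_side = round(N**0.5)
            for axis in range(2):
                parts_p, parts_m = [], []
                for i in range(net.spec.n_subpops):
                    grid = s_mod[i * N:(i + 1) * N].reshape(n_side, n_side)
                    parts_p.append(np.roll(grid, 1, axis=axis).ravel())
                    parts_m.append(np.roll(grid, -1, axis=axis).ravel())
                d = (np.concatenate(parts_p) - np.concatenate(parts_m)) * (n_side / 2.0)
                col = np.zeros(n)
                col[sl] = d
                cols.append(col)
    return np.column_stack(cols)


def null_left_eigenvectors(J: np.ndarray, tangents: np.ndarray, cond_max: float = 1e8) -> np.ndarray:
    """Left null eigenvectors of J, bi-orthonormalized against the tangents.

    Returns ``nu`` of shape (n, k) with ``nu[:, mu] @ tangents[:, rho] =
    delta_{mu rho}``; nu is in units of phase per unit synaptic activation
    and is invariant to the arbitrary scaling of the raw eigenvector output.
    """
    k = tangents.shape[1]
    # deterministic block inverse iteration on J^T: converges to the span of
    # the left eigenvectors with the smallest |eigenvalue| (the spectral gap
    # between soft and relaxation modes makes this converge in a few steps);
    # any basis of that subspace suffices since the tangents fix the mixing
    lu = scipy.linalg.lu_factor(J)
    rng = np.random.default_rng(12345)
    V = rng.standard_normal((J.shape[0], k))
    for _ in range(25):
        V = scipy.linalg.lu_solve(lu, V, trans=1)
        V, _ = np.linalg.qr(V)
    M = V.T @ tangents
    if np.linalg.cond(M) > cond_max:
        raise RuntimeError("bi-orthonormalization ill-conditioned; manifold tangents degenerate")
    return V @ np.linalg.inv(M).T


def diffusion_tensor(nu: np.ndarray, rates: np.ndarray, reference_phases=None) -> DiffusionTensor:
    """Evaluate D = 1/2 sum_i nu_mu,i nu_rho,i rbar_i from nu and rates."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    D = 0.5 * (nu.T * rates) @ nu
    asym = np.max(np.abs(D - D.T)) / max(np.max(np.abs(D)), 1e-300)
    if asym > 1e-10:
        raise RuntimeError("diffusion tensor asymmetric beyond numerical tolerance")
    D = 0.5 * (D + D.T)
    w, U = np.linalg.eigh(D)
    order = np.argsort(-w)
    ref = None if reference_phases is None else np.asarray(reference_phases)
    return DiffusionTensor(D=D, eigenvalues=w[order], eigenvectors=U[:, order], reference_phases=ref)


def phase_diffusion_tensor(system: CoupledSystem, **jac_kwargs) -> DiffusionTensor:
    """Full pipeline: Jacobian -> left null vectors -> diffusion tensor."""
    from .dynamics import estimate_phase

    s_bar, J = coupled_steady_state_and_jacobian(system, **jac_kwargs)
    T = phase_tangents(system)
    nu = null_left_eigenvectors(J, T)
    rates = transfer(_steady_drive(system, s_bar), system.tau)
    ref = np.array([np.atleast_1d(estimate_phase(st, net))[0] for st, net in zip(system.states, system.modules)])
    return diffusion_tensor(nu, rates, reference_phases=ref)


@dataclass
class EmpiricalDiffusion:
    """Monte-Carlo estimate of the diffusion tensor from spiking runs."""

    D: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    times: np.ndarray
    cov_curves: np.ndarray  # (n_rec, m, m) phase covariance across trials
    r_squared: float
    n_trials: int


def empirical_diffusion(
    system: CoupledSystem,
    T: float,
    trials: int,
    rng,
    dt: float = 1e-4,
    record_stride: int = 50,
    fit_start_frac: float = 0.2,
    n_boot: int = 200,
) -> EmpiricalDiffusion:
    """Estimate D from the growth of the phase covariance in Poisson runs.

    Runs ``trials`` independent spiking simulations at zero external input
    and fits cov(theta_mu, theta_rho)(t) ~ 2 D_{mu rho} t over
    [fit_start_frac*T, T].  Returns the estimate with bootstrap 95% CIs.
    A poor linear fit of the leading variance curve (R^2 < 0.9) issues a
    warning (the CI is widened by the bootstrap anyway).
    """
    n_steps = int(round(T / dt))
    b = np.zeros((n_steps, system.m, system.dims, 1))
    res = run_coupled(system, b, dt=dt, mode="poisson", rng=rng, record_stride=record_stride, n_batch=trials)
    th = res.phases[:, :, 0, :]  # (n_rec, m, trials); 1D systems
    th = th - th[0]
    t = res.times
    dev = th - th.mean(axis=2, keepdims=True)
    cov = np.einsum("tmk,trk->tmr", dev, dev) / (trials - 1)
    mask = t >= fit_start_frac * T
    tt = t[mask]

    def fit_D(cov_curves):
        # affine fit cov(t) ~ c + 2 D t; the intercept absorbs the constant
        # variance floor (phase-estimator jitter, sub-tau free diffusion)
        x = 2.0 * tt
        xc = x - x.mean()
        y = cov_curves[mask]
        return np.einsum("t,tmr->mr", xc, y - y.mean(axis=0)) / (xc @ xc)

    D = fit_D(cov)
    var_lead = cov[mask, 0, 0]
    pred = var_lead.mean() + 2.0 * D[0, 0] * (tt - tt.mean())
    ss = np.sum((var_lead - pred) ** 2)
    tot = np.sum((var_lead - var_lead.mean()) ** 2)
    r2 = 1.0 - ss / tot if tot > 0 else 0.0
    if r2 < 0.9:
        warnings.warn(f"phase variance growth not linear (R^2={r2:.3f}); treat CI with caution")
    boots = np.empty((n_boot,) + D.shape)
    for i in range(n_boot):
        idx = rng.integers(0, trials, size=trials)
        d = th[:, :, idx] - th[:, :, idx].mean(axis=2, keepdims=True)
        boots[i] = fit_D(np.einsum("tmk,trk->tmr", d, d) / (trials - 1))
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return EmpiricalDiffusion(
        D=D, ci_low=lo, ci_high=hi, times=t, cov_curves=cov, r_squared=float(r2), n_trials=trials
    )
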