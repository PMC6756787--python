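"""Linear response theory of the coupled modules.

In the slow-input limit the module phases obey ``theta_dot = X b`` with the
linear response tensor ``X = alpha (I - C)^{-1}``; away from that limit the
phases follow the reduced dynamics

    theta_dot = alpha * b(t) + C (f * theta_dot),

where f is the unit-area exponential filter of time scale tau (the synaptic
activations themselves act as the low-pass filter carried by the velocity
readout).  The single-module gain alpha (phase velocity per unit velocity
input) is calibrated numerically from the rate network.

This module also houses the stability screen (all eigenvalues of C must lie
below unity), the grid-spacing predictions lambda_mu = 1 / (X gamma)_mu,
and the module-removal experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling import CoupledSystem, CouplingSpec, run_coupled
from .networks import AttractorNetwork, ModuleSpec, build_network

__all__ = [
    "ResponseTensor",
    "StabilityReport",
    "PhaseReductionRun",
    "SpacingReport",
    "calibrate_gain_alpha",
    "linear_response_tensor",
    "check_stability",
    "integrate_phase_reduction",
    "predicted_spacings",
    "module_removal_prediction",
]


@dataclass
class ResponseTensor:
    """X = alpha (I - C)^{-1} and its eigenstructure."""

    X: np.ndarray
    alpha: float
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    #: for m=2 with equal self couplings: gains along the symmetric /
    #: antisymmetric input combinations, X+- = alpha / (1 - (Cs +- sqrt(C12 C21)))
    X_plus: float | None = None
    X_minus: float | None = None

    @property
    def anisotropy(self) -> float:
        """Ratio of largest to smallest response eigenvalue magnitude."""
        mags = np.sort(np.abs(self.eigenvalues))
        return float(mags[-1] / mags[0])


@dataclass
class StabilityReport:
    stable: bool
    eigenvalues: np.ndarray

    def __bool__(self) -> bool:
        return self.stable


def check_stability(C) -> StabilityReport:
    """Stable iff every eigenvalue of C has real part below 1.

    Above unity the positive velocity feedback outruns the exponential
    filter and the coupled dynamics diverge.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    eig = np.linalg.eigvals(C)
    return StabilityReport(stable=bool(np.all(eig.real < 1.0)), eigenvalues=eig)


def linear_response_tensor(C, alpha: float) -> ResponseTensor:
    """Evaluate X = alpha (I - C)^{-1} and its eigen-decomposition."""
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m = C.shape[0]
    I_C = np.eye(m) - C
    if abs(np.linalg.det(I_C)) < 1e-12 * max(1.0, np.linalg.norm(C)):
        raise np.linalg.LinAlgError(
            "I - C is singular: C has an eigenvalue at 1, violating the "
            "stability constraint (all eigenvalues of C must be below unity)"
        )
    X = alpha * np.linalg.inv(I_C)
    eigval, eigvec = np.linalg.eig(X)
    order = np.argsort(-np.abs(eigval))
    tensor = ResponseTensor(X=X, alpha=alpha, eigenvalues=eigval[order], eigenvectors=eigvec[:, order])
    if m == 2 and np.isclose(C[0, 0], C[1, 1]) and C[0, 1] * C[1, 0] >= 0:
        root = np.sqrt(C[0, 1] * C[1, 0])
        tensor.X_plus = alpha / (1.0 - (C[0, 0] + root))
        tensor.X_minus = alpha / (1.0 - (C[0, 0] - root))
    return tensor


def _measure_phase_velocity(system: CoupledSystem, b_level: float, T: float, dt: float) -> float:
    n = int(round(T / dt))
    b = np.zeros((n, 1, 1, 1))
    b[:, 0, 0, 0] = b_level
    res = run_coupled(system, b, dt=dt, record_stride=max(1, n // 200))
    t, ph = res.times, res.phases[:, 0, 0, 0]
    half = len(t) // 2  # discard the transient
    return float(np.polyfit(t[half:], ph[half:], 1)[0])


def calibrate_gain_alpha(
    net: AttractorNetwork,
    levels=None,
    T: float = 0.4,
    dt: float = 1e-4,
    r2_min: float = 0.999,
):
    """Numerical calibration of the single-module velocity gain alpha.

    Runs the uncoupled rate network at several constant velocity-input
    levels spanning the linear regime, measures the steady phase velocity
    of each, and fits ``theta_dot = alpha * b`` through the origin by least
    squares.  Returns ``(alpha, r_squared)``; an R^2 below ``r2_min``
    raises, indicating the input range has left the linear regime.
    """
    if levels is None:
        levels = np.array([-0.02, -0.012, -0.004, 0.004, 0.012, 0.02])
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 5:
        raise ValueError("need at least 5 input levels for the calibration fit")
    system = CoupledSystem(modules=[net], coupling=CouplingSpec(C=np.zeros((1, 1))))
    system.relax(T_relax=0.6, dt=dt)
    vels = np.array([_measure_phase_velocity(system, b, T, dt) for b in levels])
    alpha = float(levels @ vels / (levels @ levels))
    ss_res = float(np.sum((vels - alpha * levels) ** 2))
    ss_tot = float(np.sum((vels - vels.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    if r2 < r2_min:
        raise RuntimeError(
            f"velocity response nonlinear over the chosen range (R^2={r2:.5f}); "
            "calibrate with smaller input levels"
        )
    return alpha, r2


def default_gain_alpha(spec: ModuleSpec | None = None) -> float:
    """Calibrated alpha for a (possibly reduced) standard module."""
    net = build_network(spec or ModuleSpec(dims=1, N=200))
    return calibrate_gain_alpha(net)[0]


@dataclass
class PhaseReductionRun:
    """Trajectory of the reduced phase dynamics."""

    times: np.ndarray
    theta: np.ndarray  # (n_rec, m, ...) unwrapped phases
    b: np.ndarray
    tau: float


def integrate_phase_reduction(C, alpha: float, b, tau: float, dt: float, theta0=None, record_stride: int = 1) -> PhaseReductionRun:
    """Integrate theta_dot = alpha b + C (f * theta_dot) by explicit Euler.

    The convolution with the exponential filter f is removed by the
    auxiliary variable z = f * theta_dot with z_dot = (theta_dot - z)/tau,
    giving the delay-free system theta_dot = alpha b + C z.

    ``b`` has shape (n_steps, m) or (n_steps, m, ...extra axes...) for
    batched channels/trials; theta is returned on the same trailing shape.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    m = C.shape[0]
    if dt > tau / 10 + 1e-12:
        raise ValueError("dt must satisfy dt <= tau/10")
    verdict = check_stability(C)
    if not verdict.stable:
        raise RuntimeError("unstable coupling matrix (eigenvalue of C above 1)")
    # the filter loop has modes at (eig(C) - 1)/tau; explicit Euler needs to
    # resolve the stiffest of them
    dt_max = 1.6 * tau / (1.0 + np.max(np.abs(verdict.eigenvalues)))
    if dt > dt_max:
        raise ValueError(f"dt={dt} unstable for this C (stiff coupling mode); need dt <= {dt_max:.2e}")
    b = np.asarray(b, dtype=float)
    if b.shape[1] != m:
        raise ValueError("b must have one column per module")
    n_steps = b.shape[0]
    tail = b.shape[2:]
    theta = np.zeros((m,) + tail) if theta0 is None else np.broadcast_to(np.asarray(theta0, float), (m,) + tail).copy()
    z = np.zeros_like(theta)
    n_rec = n_steps // record_stride + 1
    rec = np.empty((n_rec,) + theta.shape)
    times = np.empty(n_rec)
    rec[0], times[0] = theta, 0.0
    for k in range(n_steps):
        tdot = alpha * b[k] + np.einsum("mr,r...->m...", C, z)
        theta = theta + dt * tdot
        z = z + dt * (tdot - z) / tau
        if (k + 1) % record_stride == 0:
            idx = (k + 1) // record_stride
            rec[idx] = theta
            times[idx] = (k + 1) * dt
    return PhaseReductionRun(times=times, theta=rec, b=b, tau=tau)


@dataclass
class SpacingReport:
    """Predicted grid spacings in the slow-input limit."""

    gains: np.ndarray  # (X gamma)_mu, phase velocity per unit speed
    spacings: np.ndarray  # meters per full phase cycle, 1 / gains
    joint_motion_residual: float  # how far u (prop. to 1/spacing) is from an eigenvector of X

    @property
    def spacing_ratios(self) -> np.ndarray:
        """Ratios of successive spacings lambda_mu / lambda_{mu+1}."""
        return self.spacings[:-1] / self.spacings[1:]


def predicted_spacings(gamma, C, alpha: float) -> SpacingReport:
    """Grid spacings from the slow-input response: lambda_mu = 1/(X gamma)_mu.

    For a slowly varying common velocity V, module mu moves at phase
    velocity (X gamma)_mu * V, i.e. one full cycle per 1/(X gamma)_mu
    meters.  Also reports how close the joint-motion vector u (components
    proportional to 1/lambda_mu) is to an eigenvector of X.
    """
    gamma = np.asarray(gamma, dtype=float)
    tensor = linear_response_tensor(C, alpha)
    gains = tensor.X @ gamma
    if np.any(gains <= 0):
        raise RuntimeError("non-positive predicted velocity gain; check C and gamma")
    spacings = 1.0 / gains
    u = gains / np.linalg.norm(gains)
    Xu = tensor.X @ u
    resid = float(np.linalg.norm(Xu - (u @ Xu) * u) / np.linalg.norm(Xu))
    return SpacingReport(gains=gains, spacings=spacings, joint_motion_residual=resid)


def module_removal_prediction(C, gamma, alpha: float, removed: int):
    """Spacings after disconnecting one module from the others.

    Removal zeroes the couplings to and from the removed module but leaves
    every self coupling (the diagonal) intact.  Returns
    ``(before, after)`` spacing reports; the removed module, having lost
    its positive input couplings while keeping its negative self coupling,
    weakens its velocity response and its grid spacing grows.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float)).copy()
    before = predicted_spacings(gamma, C, alpha)
    C_cut = C.copy()
    for k in range(C.shape[0]):
        if k != removed:
            C_cut[removed, k] = 0.0
            C_cut[k, removed] = 0.0
    if not check_stability(C_cut).stable:
        raise RuntimeError("coupling matrix unstable after removal")
    after = predicted_spacings(gamma, C_cut, alpha)
    return before, after
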