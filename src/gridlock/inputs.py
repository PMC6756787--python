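"""Synthetic trajectories and noisy velocity drives.

The trajectory generator emulates the statistics of a foraging rodent in a
bounded arena: an Ornstein-Uhlenbeck velocity process (smooth heading, a
configurable mean speed of order 0.1-0.5 m/s, direction persistence of
order a second) whose integrated path is kept inside the arena by
reflecting walls.  It stands in for a measured animal trajectory; any
externally recorded path can be supplied as a plain (time, x[, y]) table
instead.

The velocity drive to module mu along direction q is

    b_mu,q(t) = gamma_mu * (V_q(t) + eta_mu,q(t)),

with white noise of intensity eta (units m * s^-1/2): discrete samples are
Gaussian with standard deviation eta / sqrt(dt), independent across
modules, directions and trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "VelocityDrive",
    "generate_trajectory",
    "make_velocity_drive",
    "project_trajectory_1d",
    "standard_gammas",
]


def standard_gammas(m: int = 3, gamma1: float = 0.06) -> np.ndarray:
    """Velocity gains gamma_mu = gamma1 * lambda^(mu-1), lambda = sqrt(2).

    Successive modules receive stronger velocity modulation, which by
    itself (uncoupled) already produces the target spacing ratio.
    """
    from .coupling import LAMBDA_RATIO

    return gamma1 * LAMBDA_RATIO ** np.arange(m)


@dataclass
class Trajectory:
    """A position-time path.

    ``positions`` has shape (n_samples, dims) in meters; ``velocities`` has
    shape (n_samples - 1, dims) and is exactly the finite difference of
    successive positions over dt (piecewise-constant velocity per step).
    """

    times: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray
    arena: np.ndarray  # (dims,) arena edge lengths, meters

    @property
    def dims(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def mean_speed(self) -> float:
        return float(np.mean(np.linalg.norm(self.velocities, axis=1)))

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.times}
        for q, name in zip(range(self.dims), ("x", "y")):
            cols[name] = self.positions[:, q]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, arena=None) -> "Trajectory":
        """Build from a (t, x[, y]) table; velocities by finite difference."""
        pos_cols = [c for c in ("x", "y") if c in df.columns]
        t = df["t"].to_numpy(dtype=float)
        pos = df[pos_cols].to_numpy(dtype=float)
        dt = np.diff(t)
        vel = np.diff(pos, axis=0) / dt[:, None]
        if arena is None:
            arena = pos.max(axis=0) - pos.min(axis=0)
        return cls(times=t, positions=pos, velocities=vel, arena=np.asarray(arena, float))


def _reflect_fold(x: np.ndarray, L: float) -> np.ndarray:
    """Fold an unbounded coordinate into [0, L] by billiard reflection."""
    y = np.mod(x, 2 * L)
    return np.where(y > L, 2 * L - y, y)


def generate_trajectory(
    T: float,
    dt: float,
    dims: int = 2,
    arena=1.0,
    mean_speed: float = 0.2,
    persistence_time: float = 1.0,
    wall_margin_frac: float = 0.12,
    seed=None,
    start=None,
) -> Trajectory:
    """Smooth bounded random foraging path.

    Velocity components follow independent Ornstein-Uhlenbeck processes
    with correlation time ``persistence_time`` whose stationary scale is
    set so the mean speed matches ``mean_speed``.  Walls are avoided
    smoothly: inside a margin of ``wall_margin_frac`` times the arena edge
    the mean of the velocity process is biased inward, so the animal
    decelerates and turns like a real forager instead of bouncing with a
    velocity discontinuity; hard reflection remains only as a safety net
    for the rare tail excursion.  Deterministic given ``seed``.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    arena = np.broadcast_to(np.asarray(arena, dtype=float), (dims,)).copy()
    n = int(round(T / dt))
    if np.any(arena <= mean_speed * dt):
        raise ValueError("arena smaller than a single step")
    rng = np.random.default_rng(seed)
    # stationary per-component sigma from the mean-speed target:
    # 1D: E|v| = sigma*sqrt(2/pi); 2D: speed is Rayleigh, E = sigma*sqrt(pi/2)
    sigma = mean_speed * np.sqrt(np.pi / 2.0) if dims == 1 else mean_speed / np.sqrt(np.pi / 2.0)
    x0 = arena / 2.0 if start is None else np.broadcast_to(np.asarray(start, float), (dims,)).copy()
    pos = np.empty((n + 1, dims))
    pos[0] = x0
    if mean_speed == 0.0:
        pos[:] = x0
        vel = np.zeros((n, dims))
        return Trajectory(times=dt * np.arange(n + 1), positions=pos, velocities=vel, arena=arena)
    decay = np.exp(-dt / persistence_time)
    kick = sigma * np.sqrt(1.0 - decay**2)
    margin = wall_margin_frac * arena
    # inward acceleration able to turn the fastest plausible approach
    # (~3 sigma) within the margin: a ~ v^2 / margin, with headroom
    a_max = 2.0 * (3.0 * sigma) ** 2 / margin.min()
    steps = rng.normal(0.0, 1.0, size=(n, dims))
    v = rng.normal(0.0, sigma, size=dims)
    x = x0.copy()
    for k in range(n):
        # soft wall avoidance: repulsive acceleration ramps up in the margin
        lo_pen = np.clip((margin - x) / margin, 0.0, 1.0)
        hi_pen = np.clip((margin - (arena - x)) / margin, 0.0, 1.0)
        v = decay * v + kick * steps[k] + dt * a_max * (lo_pen - hi_pen)
        x = x + v * dt
        for q in range(dims):  # safety net; velocity flip is exact reflection
            if x[q] < 0.0:
                x[q] = -x[q]
                v[q] = -v[q]
            elif x[q] > arena[q]:
                x[q] = 2 * arena[q] - x[q]
                v[q] = -v[q]
        pos[k + 1] = x
    vel = np.diff(pos, axis=0) / dt
    return Trajectory(times=dt * np.arange(n + 1), positions=pos, velocities=vel, arena=arena)


def project_trajectory_1d(traj: Trajectory, axis: int = 0) -> Trajectory:
    """One coordinate of a 2D path as a 1D trajectory.

    The x component of a 2D foraging path is itself a valid reflected 1D
    path, and it carries the per-channel speed statistics a 2D network
    channel would see (each channel of the torus network integrates one
    velocity component).  One-dimensional surrogate experiments use this
    projection so that per-module drive amplitudes match the 2D setting.
    """
    if traj.dims != 2:
        raise ValueError("projection requires a 2D trajectory")
    return Trajectory(
        times=traj.times,
        positions=traj.positions[:, axis : axis + 1],
        velocities=traj.velocities[:, axis : axis + 1],
        arena=traj.arena[axis : axis + 1],
    )


@dataclass
class VelocityDrive:
    """Per-module, per-direction velocity inputs b_mu,q(t).

    ``b`` has shape (n_steps, m, dims) or (n_steps, m, dims, n_trials);
    ready to feed to :func:`gridlock.coupling.run_coupled`.
    """

    b: np.ndarray
    gammas: np.ndarray
    eta: float
    dt: float
    seed: object = None

    @property
    def m(self) -> int:
        return self.b.shape[1]

    def to_frame(self) -> pd.DataFrame:
        if self.b.ndim != 3:
            raise ValueError("tidy export supports single-trial drives only")
        n, m, q = self.b.shape
        t = self.dt * np.arange(n)
        rows = {
            "t": np.repeat(t, m * q),
            "module": np.tile(np.repeat(np.arange(m), q), n),
            "direction": np.tile(np.arange(q), n * m),
            "b": self.b.reshape(-1),
        }
        return pd.DataFrame(rows)


def make_velocity_drive(
    traj: Trajectory,
    gammas,
    eta: float = 0.0,
    seed=None,
    n_trials: int | None = None,
) -> VelocityDrive:
    """Noisy velocity drive b_mu,q = gamma_mu (V_q + eta_mu,q).

    The white-noise term has per-sample standard deviation eta/sqrt(dt), so
    its integral over one second has variance eta^2 (the continuum
    correlator <eta(t) eta(t')> = eta^2 delta(t - t')).  Noise streams are
    independent across modules, directions and trials, and are drawn from
    ``seed`` independently of the trajectory's own randomness.
    """
    gammas = np.asarray(gammas, dtype=float)
    if np.any(gammas < 0) or eta < 0:
        raise ValueError("gammas and eta must be nonnegative")
    m = len(gammas)
    V = traj.velocities  # (n, dims)
    n, dims = V.shape
    shape = (n, m, dims) if n_trials is None else (n, m, dims, n_trials)
    V_exp = V[:, None, :] if n_trials is None else V[:, None, :, None]
    if eta > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, eta / np.sqrt(traj.dt), size=shape)
    else:
        noise = np.zeros(shape)
    g = gammas[None, :, None] if n_trials is None else gammas[None, :, None, None]
    b = g * (V_exp + noise)
    return VelocityDrive(b=b, gammas=gammas, eta=eta, dt=traj.dt, seed=seed)
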