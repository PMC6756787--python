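"""Config-driven reproductions of the model's computational experiments.

Four scenarios, each with a coupled system and its uncoupled twin:

``velocity_tracking``
    Two 1D modules, velocity input to module 1 only: uncoupled, module 2
    is unresponsive; coupled, both track with the phase-velocity ratio
    predicted by the linear response tensor (close to lambda).
``drift_coordination``
    Three modules with independent velocity-input noise: pairwise drift
    (MSD) between scaled module paths and MSE against the true path; the
    coupling reduces the MSE slope by about the number of modules.
``readout_success``
    Rate dynamics with Poisson spikes drawn for the readout only; the ML
    decoder's success (no catastrophic discontinuity up to t) and MSE
    curves, coupled vs uncoupled.
``intrinsic_noise``
    Poisson-spiking dynamics: the phase diffusion tensor (theory and
    optionally Monte-Carlo) and its anisotropy, coupled vs uncoupled.

Scale presets: ``desk`` (reduced sizes for interactive use and tests) and
``full`` (the reference sizes: N=1000 per 1D sub-population).  Every
stochastic element is seeded; rate-mode results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import LAMBDA_RATIO, CoupledSystem, run_coupled
from .decoding import (
    DriftMetrics,
    OnlineDecoder,
    measure_receptive_fields,
    phase_msd_mse,
    success_and_error_curves,
)
from .diffusion import empirical_diffusion, phase_diffusion_tensor
from .inputs import generate_trajectory, make_velocity_drive, project_trajectory_1d, standard_gammas
from .networks import ModuleSpec
from .response import calibrate_gain_alpha, integrate_phase_reduction

__all__ = [
    "ExperimentConfig",
    "velocity_tracking",
    "drift_coordination",
    "readout_success",
    "intrinsic_noise",
    "SCENARIOS",
]

_PRESETS = {
    "desk": dict(N=200, N_2d=16 * 16, dt=2.5e-4, trials=12, T=20.0),
    "full": dict(N=1000, N_2d=64 * 64, dt=1e-4, trials=100, T=20.0),
}


@dataclass
class ExperimentConfig:
    """Resolved settings for one scenario run."""

    scenario: str
    scale: str = "desk"
    seed: int = 0
    m: int = 3
    dims: int = 1
    N: int | None = None
    dt: float | None = None
    T: float | None = None
    trials: int | None = None
    eta: float = 0.02
    mean_speed: float = 0.2
    arena: float = 1.0
    gamma1: float = 0.06
    tau_d: float = 0.010
    decode_stride: float = 0.010
    backend: str = "network"  # drift_coordination: "network" or "reduction"
    out_dir: str | None = None

    def __post_init__(self) -> None:
        preset = _PRESETS[self.scale]
        for key in ("dt", "T", "trials"):
            if getattr(self, key) is None:
                setattr(self, key, preset[key])
        if self.N is None:
            self.N = preset["N"] if self.dims == 1 else preset["N_2d"]

    def manifest(self) -> dict:
        d = asdict(self)
        d["lambda_ratio"] = LAMBDA_RATIO
        return d


def _write_curves(cfg: ExperimentConfig, name: str, df: pd.DataFrame) -> None:
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / f"{name}.csv", index=False)
        pd.Series(cfg.manifest()).to_json(out / "manifest.json")


def _build_pair(cfg: ExperimentConfig, m: int):
    """Coupled system and its uncoupled twin, relaxed, sharing weights."""
    spec = ModuleSpec(dims=cfg.dims, N=cfg.N)
    coupled = CoupledSystem.build(m, spec=spec).relax()
    uncoupled = CoupledSystem(
        modules=coupled.modules,
        coupling=type(coupled.coupling)(C=np.zeros((m, m)), beta=coupled.coupling.beta),
    )
    uncoupled.states = [st.copy() for st in coupled.states]
    uncoupled.coupling.a = coupled.coupling.a
    return coupled, uncoupled


def measure_spacings(system: CoupledSystem, gammas, T_cal: float = 4.0, dt: float | None = None, speed: float = 0.2) -> np.ndarray:
    """Grid spacings measured from the network's own velocity response.

    Drives the coupled system with a noiseless constant-speed input and
    regresses each module's unwrapped phase on the traversed distance; the
    spacing is the distance per phase cycle.  This is the operational
    counterpart of reading spacings off the simulated rate maps.
    """
    dt = dt or system.modules[0].spec.tau / 20.0
    n = int(round(T_cal / dt))
    gammas = np.asarray(gammas, dtype=float)
    b = np.zeros((n, system.m, system.dims, 1))
    b[:, :, 0, 0] = gammas[None, :] * speed  # drive the x channel only
    res = run_coupled(system, b, dt=dt, record_stride=max(1, n // 400))
    x = speed * res.times
    half = len(x) // 4
    slopes = []
    for mu in range(system.m):
        if system.dims == 1:
            th = res.phases[:, mu, 0, 0]
        else:
            # lattice coords -> Cartesian x component of the bump phase
            from .networks import LATTICE_U1, LATTICE_U2

            th = res.phases[:, mu, :, 0] @ np.stack([LATTICE_U1, LATTICE_U2])[:, 0]
        slopes.append(np.polyfit(x[half:], th[half:], 1)[0])
    return 1.0 / np.asarray(slopes)


def velocity_tracking(cfg: ExperimentConfig) -> dict:
    """Two coupled 1D modules, velocity input to module 1 only."""
    coupled, uncoupled = _build_pair(cfg, m=2)
    gammas = np.array([cfg.gamma1, 0.0])
    traj = generate_trajectory(min(cfg.T, 10.0), cfg.dt, dims=1, arena=cfg.arena, mean_speed=cfg.mean_speed, seed=cfg.seed)
    drive = make_velocity_drive(traj, gammas, eta=0.0)
    out = {}
    for label, system in (("coupled", coupled), ("uncoupled", uncoupled)):
        res = run_coupled(system, drive.b, dt=cfg.dt, record_stride=20)
        th = res.phases[:, :, 0, 0]
        disp = th[-1] - th[0]
        # LS slope of theta2 against theta1 over the run
        d1, d2 = th[:, 0] - th[0, 0], th[:, 1] - th[0, 1]
        ratio = float(d1 @ d2 / (d1 @ d1)) if d1 @ d1 > 0 else np.nan
        out[label] = {"displacement": disp, "velocity_ratio_2_over_1": ratio, "times": res.times, "phases": th}
    df = pd.DataFrame(
        {
            "t": out["coupled"]["times"],
            "theta1_coupled": out["coupled"]["phases"][:, 0],
            "theta2_coupled": out["coupled"]["phases"][:, 1],
            "theta1_uncoupled": out["uncoupled"]["phases"][:, 0],
            "theta2_uncoupled": out["uncoupled"]["phases"][:, 1],
        }
    )
    _write_curves(cfg, "velocity_tracking", df)
    return out


def drift_coordination(cfg: ExperimentConfig) -> dict:
    """Coupled vs uncoupled m=3 drift under independent input noise."""
    gammas = standard_gammas(cfg.m, cfg.gamma1)
    traj = generate_trajectory(cfg.T, cfg.dt, dims=1, arena=cfg.arena, mean_speed=cfg.mean_speed, seed=cfg.seed)
    drive = make_velocity_drive(traj, gammas, eta=cfg.eta, seed=cfg.seed + 1, n_trials=cfg.trials)
    out = {"gammas": gammas}
    if cfg.backend == "reduction":
        spec = ModuleSpec(dims=1, N=cfg.N)
        from .networks import build_network

        alpha, _ = calibrate_gain_alpha(build_network(spec))
        from .coupling import standard_coupling_parameters

        C = standard_coupling_parameters(cfg.m).C
        stride = max(1, int(round(cfg.decode_stride / cfg.dt)))
        for label, Cmat in (("coupled", C), ("uncoupled", np.zeros_like(C))):
            run = integrate_phase_reduction(Cmat, alpha, drive.b[:, :, 0, :], tau=spec.tau, dt=cfg.dt, record_stride=stride)
            spacings = 1.0 / (np.linalg.inv(np.eye(cfg.m) - Cmat) @ gammas * alpha)
            true_pos = np.interp(run.times, traj.times, traj.positions[:, 0])
            out[label] = phase_msd_mse(run.times, run.theta, spacings, true_pos)
    else:
        coupled, uncoupled = _build_pair(cfg, m=cfg.m)
        for label, system in (("coupled", coupled), ("uncoupled", uncoupled)):
            spacings = measure_spacings(system, gammas, dt=cfg.dt)
            res = run_coupled(system, drive.b, dt=cfg.dt, record_stride=max(1, int(round(cfg.decode_stride / cfg.dt))), n_batch=cfg.trials)
            true_pos = np.interp(res.times, traj.times, traj.positions[:, 0])
            out[label] = phase_msd_mse(res.times, res.phases[:, :, 0, :], spacings, true_pos)
    out["mse_slope_ratio"] = float(np.mean(out["uncoupled"].mse_slopes) / np.mean(out["coupled"].mse_slopes))
    rows = []
    for label in ("coupled", "uncoupled"):
        dm: DriftMetrics = out[label]
        for (mu, rho), curve in dm.msd_pairs.items():
            rows.append(pd.DataFrame({"t": dm.times, "curve": f"msd_{mu}{rho}_{label}", "value": curve}))
        for mu in range(dm.mse.shape[1]):
            rows.append(pd.DataFrame({"t": dm.times, "curve": f"mse_{mu}_{label}", "value": dm.mse[:, mu]}))
    _write_curves(cfg, "drift_coordination", pd.concat(rows, ignore_index=True))
    return out


def readout_success(cfg: ExperimentConfig, mode: str = "rate", conditions=("coupled", "uncoupled")) -> dict:
    """Decoding success and MSE, coupled vs uncoupled.

    ``mode="rate"``: deterministic network dynamics, Poisson spikes drawn
    from the instantaneous rates for the readout only (input-noise case).
    ``mode="poisson"``: spiking dynamics throughout (intrinsic-noise case).
    """
    gammas = standard_gammas(cfg.m, cfg.gamma1)
    coupled, uncoupled = _build_pair(cfg, m=cfg.m)
    traj = generate_trajectory(cfg.T, cfg.dt, dims=2, arena=cfg.arena, mean_speed=cfg.mean_speed, seed=cfg.seed)
    if cfg.dims == 1:
        # x channel of the 2D foraging path: the 1D surrogate then sees the
        # per-channel speed statistics one channel of the 2D network would
        traj = project_trajectory_1d(traj)
    eta = cfg.eta if mode == "rate" else 0.0
    drive = make_velocity_drive(traj, gammas, eta=eta, seed=cfg.seed + 1, n_trials=cfg.trials)
    out = {"gammas": gammas}
    for label, system in (("coupled", coupled), ("uncoupled", uncoupled)):
        if label not in conditions:
            continue
        spacings = measure_spacings(system, gammas, dt=cfg.dt)
        rf = measure_receptive_fields(
            system,
            spacings,
            arena_lo=0.0,
            arena_hi=cfg.arena,
            grid_step=float(spacings.min() / (25.0 if cfg.dims == 1 else 20.0)),
            ref_position=traj.positions[0],
        )
        dec = OnlineDecoder(rf, n_batch=cfg.trials, tau_d=cfg.tau_d, stride=cfg.decode_stride)
        rng = np.random.default_rng(cfg.seed + (17 if label == "coupled" else 31))
        res = run_coupled(
            system,
            drive.b,
            dt=cfg.dt,
            mode=mode,
            rng=rng,
            readout_spikes=(mode == "rate"),
            decoder=dec,
            record_stride=max(1, int(round(cfg.decode_stride / cfg.dt))),
            n_batch=cfg.trials,
        )
        path = res.decoder_output
        true_pos = np.column_stack(
            [np.interp(path.times, traj.times, traj.positions[:, q]) for q in range(cfg.dims)]
        )
        threshold = float(spacings.min() / 2.0)
        metrics = success_and_error_curves(path, true_pos, threshold, arena_lo=0.0, arena_hi=cfg.arena)
        out[label] = {"metrics": metrics, "spacings": spacings, "threshold": threshold, "path": path}
    rows = []
    for label in conditions:
        mtr: DriftMetrics = out[label]["metrics"]
        rows.append(pd.DataFrame({"t": mtr.times, "curve": f"success_{label}", "value": mtr.success}))
        rows.append(pd.DataFrame({"t": mtr.times, "curve": f"mse_{label}", "value": mtr.mse}))
    first = out[conditions[0]]["metrics"]
    rows.append(pd.DataFrame({"t": first.times, "curve": "mse_random_guess", "value": first.random_guess_mse}))
    _write_curves(cfg, f"readout_success_{mode}", pd.concat(rows, ignore_index=True))
    return out


def intrinsic_noise(cfg: ExperimentConfig, empirical: bool = False) -> dict:
    """Phase diffusion tensors of the spiking system, coupled vs uncoupled."""
    coupled, uncoupled = _build_pair(cfg, m=2)
    out = {}
    for label, system in (("coupled", coupled), ("uncoupled", uncoupled)):
        tensor = phase_diffusion_tensor(system)
        entry = {"tensor": tensor}
        if empirical:
            rng = np.random.default_rng(cfg.seed + (3 if label == "coupled" else 5))
            entry["empirical"] = empirical_diffusion(system, T=min(cfg.T, 10.0), trials=cfg.trials, rng=rng, dt=min(cfg.dt, 2e-4))
        out[label] = entry
    rows = []
    for label in ("coupled", "uncoupled"):
        t = out[label]["tensor"]
        rows.append(
            pd.DataFrame(
                {
                    "quantity": ["D11", "D12", "D22", "D_plus", "D_minus", "angle_deg"],
                    "value": [t.D[0, 0], t.D[0, 1], t.D[1, 1], t.eigenvalues[0], t.eigenvalues[-1], t.principal_angle_deg],
                    "condition": label,
                }
            )
        )
    _write_curves(cfg, "intrinsic_noise", pd.concat(rows, ignore_index=True))
    return out


SCENARIOS = {
    "velocity_tracking": velocity_tracking,
    "drift_coordination": drift_coordination,
    "readout_success": readout_success,
    "intrinsic_noise": intrinsic_noise,
}
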