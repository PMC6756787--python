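"""Serialization helpers: HDF5 snapshots and tidy CSV tables."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import SpikeRaster, SynapticState
from .networks import AttractorNetwork, ModuleSpec

__all__ = [
    "save_network",
    "load_network",
    "save_raster_csv",
    "load_raster_csv",
    "save_coupling_csv",
    "load_coupling_csv",
    "save_receptive_fields",
    "load_receptive_fields",
    "diffusion_report",
    "spacing_report",
    "run_to_frame",
]

_SPEC_FIELDS = ("dims", "N", "tau", "I0", "A", "sigma2", "phi_shift", "gamma")


def save_network(path, net: AttractorNetwork, state: SynapticState | None = None) -> None:
    """Write a network (and optionally a state snapshot) to HDF5.

    Layout: /spec (scalar attrs), /W (full dense weight matrix),
    /state/s and /state/t when a state is given.
    """
    with h5py.File(path, "w") as f:
        g = f.create_group("spec")
        for name in _SPEC_FIELDS:
            g.attrs[name] = getattr(net.spec, name)
        f.create_dataset("W", data=net.full_weight_matrix(), compression="gzip")
        if state is not None:
            f.create_dataset("state/s", data=state.s)
            f["state"].attrs["t"] = state.t


def load_network(path):
    """Read a network saved by :func:`save_network`.

    Returns ``(net, state_or_None)``; weights are rebuilt from the spec and
    verified against the stored matrix.
    """
    from .networks import build_network

    with h5py.File(path, "r") as f:
        kw = {name: f["spec"].attrs[name] for name in _SPEC_FIELDS}
        kw["dims"] = int(kw["dims"])
        kw["N"] = int(kw["N"])
        spec = ModuleSpec(**kw)
        net = build_network(spec)
        W_stored = f["W"][...]
        if not np.allclose(net.full_weight_matrix(), W_stored, atol=1e-12):
            raise ValueError("stored weight matrix inconsistent with its spec")
        state = None
        if "state" in f:
            state = SynapticState(s=f["state/s"][...], t=float(f["state"].attrs["t"]))
    return net, state


def save_raster_csv(path, raster: SpikeRaster) -> None:
    raster.to_frame().to_csv(path, index=False)


def load_raster_csv(path, n_neurons: int, duration: float) -> SpikeRaster:
    df = pd.read_csv(path)
    return SpikeRaster(
        neuron_ids=df["neuron_id"].to_numpy(dtype=int),
        times=df["spike_time_s"].to_numpy(dtype=float),
        n_neurons=n_neurons,
        duration=duration,
    )


def save_coupling_csv(path, C: np.ndarray) -> None:
    """m x m coupling matrix as CSV, row = postsynaptic module."""
    pd.DataFrame(np.atleast_2d(C)).to_csv(path, index=False, header=False)


def load_coupling_csv(path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def save_receptive_fields(path, rf) -> None:
    """Receptive-field map to HDF5: grid axes plus per-neuron rate stacks."""
    with h5py.File(path, "w") as f:
        f.create_dataset("grid", data=rf.grid)
        f.create_dataset("rates", data=rf.rates, compression="gzip")
        f.create_dataset("spacings", data=rf.spacings)
        f.attrs["grid_shape"] = rf.grid_shape
        f.attrs["arena_lo"] = rf.arena_lo
        f.attrs["arena_hi"] = rf.arena_hi
        f.attrs["eps_frac"] = rf.eps_frac


def load_receptive_fields(path):
    from .decoding import ReceptiveFieldMap

    with h5py.File(path, "r") as f:
        rates = f["rates"][...]
        return ReceptiveFieldMap(
            grid=f["grid"][...],
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"]),
            rates=rates,
            log_rates=np.log(rates),
            spacings=f["spacings"][...],
            arena_lo=np.atleast_1d(f.attrs["arena_lo"]),
            arena_hi=np.atleast_1d(f.attrs["arena_hi"]),
            eps_frac=float(f.attrs["eps_frac"]),
        )


def diffusion_report(tensor) -> pd.DataFrame:
    """Tidy table of a diffusion tensor: entries, eigenvalues, axis angle."""
    m = tensor.D.shape[0]
    rows = [
        {"quantity": f"D{mu + 1}{rho + 1}", "value": tensor.D[mu, rho]}
        for mu in range(m)
        for rho in range(mu, m)
    ]
    for k, w in enumerate(tensor.eigenvalues):
        rows.append({"quantity": f"eigenvalue_{k + 1}", "value": w})
    if m == 2:
        rows.append({"quantity": "principal_angle_deg", "value": tensor.principal_angle_deg})
    return pd.DataFrame(rows)


def spacing_report(report) -> pd.DataFrame:
    """Tidy table of predicted gains and grid spacings per module."""
    return pd.DataFrame(
        {
            "module": np.arange(1, len(report.spacings) + 1),
            "gain_per_speed": report.gains,
            "spacing_m": report.spacings,
        }
    )


def run_to_frame(result) -> pd.DataFrame:
    """Tidy (t, module, direction, trial, phase, omega) table of a run."""
    times, ph, om = result.times, result.phases, result.omegas
    n_t, m, dims, k = ph.shape
    idx = np.indices((n_t, m, dims, k))
    return pd.DataFrame(
        {
            "t": times[idx[0].ravel()],
            "module": idx[1].ravel(),
            "direction": idx[2].ravel(),
            "trial": idx[3].ravel(),
            "phase": ph.ravel(),
            "omega": om.ravel(),
        }
    )


def write_run_csv(path, result) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    run_to_frame(result).to_csv(path, index=False)
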