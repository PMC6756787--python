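"""Receptive fields, the exponential-kernel ML decoder, and drift metrics."""

import numpy as np
import pytest

from gridlock import (
    CoupledSystem,
    ModuleSpec,
    OnlineDecoder,
    SpikeRaster,
    decode_position,
    detect_discontinuities,
    measure_receptive_fields,
    phase_msd_mse,
    success_and_error_curves,
)
from gridlock.decoding import DecodedPath
from gridlock.experiments import measure_spacings
from gridlock.inputs import standard_gammas

DT = 1e-4


@pytest.fixture(scope="module")
def decoding_setup():
    spec = ModuleSpec(dims=1, N=200)
    system = CoupledSystem.build(3, spec=spec).relax(dt=DT)
    gammas = standard_gammas(3)
    spacings = measure_spacings(system, gammas, dt=2e-4)
    rf = measure_receptive_fields(
        system, spacings, arena_lo=0.0, arena_hi=0.75, grid_step=float(spacings.min() / 25), ref_position=0.375
    )
    return system, spacings, rf


def test_fields_periodic_with_spacing(decoding_setup):
    system, spacings, rf = decoding_setup
    x = rf.grid[:, 0]
    dx = x[1] - x[0]
    # neuron of module 0 with a field peak inside the arena
    r = rf.rates[30]
    lag = int(round(spacings[0] / dx))
    # max circular cross-correlation at a shift of one spacing
    n = len(r) - lag
    c = np.corrcoef(r[:n], r[lag:])[0, 1]
    assert c > 0.98


def test_field_translation_by_full_period_identical(decoding_setup):
    system, spacings, rf = decoding_setup
    x = rf.grid[:, 0]
    # evaluate the same neurons at x and x + lambda via a fresh map whose
    # arena is shifted by exactly one period of module 0
    rf2 = measure_receptive_fields(
        system,
        spacings,
        arena_lo=0.0 + spacings[0],
        arena_hi=0.75 + spacings[0],
        grid_step=float(spacings.min() / 25),
        ref_position=0.375 + spacings[0],
    )
    N = system.modules[0].spec.N
    assert np.allclose(rf.rates[: 2 * N], rf2.rates[: 2 * N], atol=1e-10)


def test_decoder_self_consistency_on_grid(decoding_setup):
    """Noise-free rates substituted for spikes recover every test position."""
    _, _, rf = decoding_setup
    G = rf.grid.shape[0]
    idx = np.arange(0, G, max(1, G // 30))
    ll = rf.rates[:, idx].T @ rf.log_rates
    best = np.argmax(ll, axis=1)
    assert np.array_equal(best, idx)


def test_single_module_likelihood_periodic_ambiguity(decoding_setup):
    """One module alone cannot disambiguate positions one spacing apart;
    the exact tie resolves to the lowest grid index."""
    system, spacings, _ = decoding_setup
    # grid step an exact divisor of the spacing: aliases are exact grid ties
    rf = measure_receptive_fields(
        system,
        spacings,
        arena_lo=0.0,
        arena_hi=2.5 * spacings[0],
        grid_step=spacings[0] / 40,
        ref_position=0.0,
    )
    N = system.modules[0].spec.N
    sl = slice(0, 2 * N)
    lag = 40  # one full period of module 0 in grid steps
    i_true = 2 * lag
    ll = rf.rates[sl, i_true] @ rf.log_rates[sl]
    assert ll[i_true - lag] == pytest.approx(ll[i_true], rel=1e-9)
    assert ll[i_true - 2 * lag] == pytest.approx(ll[i_true], rel=1e-9)
    best = int(np.argmax(ll))
    assert best == i_true - 2 * lag  # lowest-index alias wins the tie


def test_online_and_batch_decoders_agree():
    """Running-update effective counts equal the batch exponential sum."""
    rng = np.random.default_rng(5)
    n_neurons, G = 40, 30
    log_rf = rng.normal(size=(n_neurons, G))
    rf = _FakeRF(grid=np.linspace(0, 1, G)[:, None], log_rates=log_rf, n_neurons=n_neurons)
    tau_d, dt = 0.01, 1e-3
    n_steps = 200
    counts = rng.poisson(0.3, size=(n_steps, n_neurons))
    dec = OnlineDecoder(rf, n_batch=1, tau_d=tau_d, stride=dt)
    for k in range(n_steps):
        dec.advance(counts[k][:, None], (k + 1) * dt, dt)
    # batch route through a raster
    ids = np.repeat(np.arange(n_neurons)[None, :], n_steps, axis=0)
    t_sp = np.repeat((np.arange(n_steps) + 1)[:, None] * dt, n_neurons, axis=1)
    mask = counts > 0
    raster = SpikeRaster(
        neuron_ids=np.repeat(ids[mask], counts[mask]),
        times=np.repeat(t_sp[mask], counts[mask]),
        n_neurons=n_neurons,
        duration=n_steps * dt,
    )
    sample_times = (np.arange(n_steps) + 1) * dt
    path = decode_position(raster, rf, tau_d, sample_times)
    online = dec.result()
    assert np.allclose(path.positions[:, 0], online.positions[:, 0, 0], atol=1e-12)
    assert np.allclose(path.log_likelihood, online.log_likelihood[:, 0], atol=1e-9)


class _FakeRF:
    def __init__(self, grid, log_rates, n_neurons):
        self.grid = grid
        self.log_rates = log_rates
        self.n_neurons = n_neurons


def test_decoder_invalid_before_first_spike():
    rng = np.random.default_rng(0)
    rf = _FakeRF(grid=np.linspace(0, 1, 10)[:, None], log_rates=rng.normal(size=(5, 10)), n_neurons=5)
    dec = OnlineDecoder(rf, n_batch=1, tau_d=0.01, stride=0.01)
    dec.advance(np.zeros((5, 1)), 0.01, 0.01)
    dec.advance(np.array([0, 1, 0, 0, 0])[:, None], 0.02, 0.01)
    out = dec.result()
    assert not out.valid[0, 0] and out.valid[1, 0]


def test_discontinuity_detection_examples():
    t = np.arange(50) * 0.01
    const = np.zeros((50, 1))
    assert detect_discontinuities(const, threshold=0.1).sum() == 0
    tele = const.copy()
    tele[30:, 0] = 0.3  # one teleport of 3 thresholds
    ev = detect_discontinuities(tele, threshold=0.1)
    assert ev.sum() == 1 and bool(ev[30, ])
    # smooth path below the kinematic bound never triggers
    smooth = np.cumsum(np.full((50, 1), 0.0009), axis=0)  # v*dt < threshold
    assert detect_discontinuities(smooth, threshold=0.001).sum() == 0


def test_success_curves_properties():
    times = np.arange(100) * 0.01
    rng = np.random.default_rng(1)
    pos = np.cumsum(rng.normal(0, 1e-4, size=(100, 1, 8)), axis=0)
    path = DecodedPath(times=times, positions=pos, log_likelihood=np.zeros((100, 8)), valid=np.ones((100, 8), bool))
    true_pos = np.zeros((100, 1))
    m = success_and_error_curves(path, true_pos, threshold=0.5, arena_lo=0.0, arena_hi=1.0)
    assert np.all(m.success == 1.0)  # event-free trials
    pos2 = pos.copy()
    pos2[60:, 0, 2] += 0.9
    path2 = DecodedPath(times=times, positions=pos2, log_likelihood=np.zeros((100, 8)), valid=np.ones((100, 8), bool))
    m2 = success_and_error_curves(path2, true_pos, threshold=0.5, arena_lo=0.0, arena_hi=1.0)
    assert np.all(np.diff(m2.success) <= 1e-12)  # nonincreasing
    assert m2.success[-1] == pytest.approx(7 / 8)
    # random-guess baseline for the uniform arena: L^2/12 + (x - L/2)^2
    assert m2.random_guess_mse[0] == pytest.approx(1 / 12 + 0.25)


def test_phase_msd_identical_trajectories_zero():
    times = np.arange(50) * 0.01
    ph = np.cumsum(np.full((50, 2, 4), 1e-3), axis=0)
    m = phase_msd_mse(times, ph, np.array([1.0, 1.0]), np.zeros(50))
    assert np.allclose(m.msd_pairs[(0, 1)], 0.0)


def test_phase_msd_brownian_slope():
    """Independent random walks: pairwise MSD slope = 2 * (2D) * scale^2."""
    rng = np.random.default_rng(2)
    n_t, trials, dt = 400, 400, 0.01
    D = 0.05
    steps = rng.normal(0, np.sqrt(2 * D * dt), size=(n_t, 2, trials))
    ph = np.cumsum(steps, axis=0) * 0.1  # keep increments below the wrap guard
    times = np.arange(n_t) * dt
    lam = 2.0
    m = phase_msd_mse(times, ph, np.array([lam, lam]), np.zeros(n_t))
    msd = m.msd_pairs[(0, 1)]
    slope = np.polyfit(times, msd, 1)[0]
    expect = 2 * (2 * D * 0.01) * lam**2
    assert slope == pytest.approx(expect, rel=0.2)


def test_phase_msd_rejects_wrapped_input():
    ph = np.zeros((10, 2, 3))
    ph[5] += 0.8
    with pytest.raises(ValueError, match="unwrap"):
        phase_msd_mse(np.arange(10.0), ph, np.ones(2), np.zeros(10))


def test_hexagonal_firing_fields_2d():
    """A 2D neuron's firing field peaks form a triangular (hexagonal) lattice."""
    spec = ModuleSpec(dims=2, N=16 * 16)
    system = CoupledSystem.build(1, spec=spec, uncoupled=True, coupling=None).relax(dt=2e-4)
    system.coupling.a = system.coupling.a or 1.0
    lam = 0.3
    rf = measure_receptive_fields(
        system, [lam], arena_lo=0.0, arena_hi=3.2 * lam, grid_step=lam / 25, ref_position=0.0
    )
    nx, ny = rf.grid_shape
    field = rf.rates[10].reshape(nx, ny)
    # autocorrelation peaks: the six nearest neighbors of the center sit at
    # 60-degree multiples, one spacing away
    from scipy.signal import fftconvolve

    f = field - field.mean()
    ac = fftconvolve(f, f[::-1, ::-1], mode="same")
    ci, cj = nx // 2, ny // 2
    # find local maxima excluding the center
    peaks, strengths = [], []
    for i in range(2, nx - 2):
        for j in range(2, ny - 2):
            win = ac[i - 2:i + 3, j - 2:j + 3]
            if ac[i, j] == win.max() and (i, j) != (ci, cj):
                peaks.append((i, j))
                strengths.append(ac[i, j])
    dx = rf.grid[ny, 0] - rf.grid[0, 0]  # grid step along x (C-order: j fast)
    vecs = np.array([((i - ci) * dx, (j - cj) * dx) for i, j in peaks])
    dists = np.linalg.norm(vecs, axis=1)
    ring = (dists > 0.7 * lam) & (dists < 1.3 * lam)
    assert ring.sum() >= 6
    # keep the six strongest peaks on the ring (weak side lobes of the
    # windowed autocorrelation are discarded)
    order = np.argsort(np.asarray(strengths)[ring])[::-1][:6]
    near = vecs[ring][order]
    angles = np.sort(np.degrees(np.arctan2(near[:, 1], near[:, 0])) % 360)
    diffs = np.diff(np.concatenate([angles, [angles[0] + 360]]))
    # six-fold symmetry: successive peak angles separated by ~60 degrees
    assert np.allclose(diffs, 60.0, atol=7.0)
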