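"""Single-module continuous attractor networks.

A grid-cell module is modeled as a continuous attractor: a double-ring
network in one dimension (two sub-populations, R and L, with oppositely
shifted outgoing weights) or a four-population twisted-torus network in two
dimensions (R, L, U, D on a rhombic sheet with periodic boundaries).
Differential feedforward drive to the opposing sub-populations moves the
activity bump, implementing velocity integration.

Connectivity is purely inhibitory apart from a vanishing inhibition at zero
offset: ``w(theta) = amp * (exp(-theta^2 / 2 sigma^2) - 1) <= 0``, evaluated
on the periodic distance between preferred phases, with the outgoing weights
of each sub-population shifted by ``phi_shift`` in its preferred direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModuleSpec",
    "AttractorNetwork",
    "periodic_distance_1d",
    "periodic_distance_2d",
    "build_ring_weights",
    "build_torus_weights",
    "build_network",
    "LATTICE_U1",
    "LATTICE_U2",
]

#: Rhombus generators of the 2D phase lattice (unit cell of the hexagonal grid).
LATTICE_U1 = np.array([1.0, 0.0])
LATTICE_U2 = np.array([0.5, np.sqrt(3.0) / 2.0])

# Sub-population order conventions; R/L integrate the x velocity channel,
# U/D (2D only) the y channel.
SUBPOPS_1D = ("R", "L")
SUBPOPS_2D = ("R", "L", "U", "D")


@dataclass(frozen=True)
class ModuleSpec:
    """Architecture and gain parameters of one grid-cell module.

    Parameters
    ----------
    dims : int
        1 for the double-ring, 2 for the twisted-torus network.
    N : int
        Neurons per sub-population (2D: must be a perfect square; the
        neurons of each sub-population sit on a sqrt(N) x sqrt(N) lattice).
    tau : float
        Synaptic time constant in seconds.
    I0 : float
        Constant feedforward drive (dimensionless drive units).
    A : float
        Connectivity amplitude.
    sigma2 : float
        Squared width of the connectivity profile, in phase units squared.
    phi_shift : float
        Outgoing-weight phase offset of each sub-population.
    gamma : float
        External velocity gain (drive units per m/s).
    """

    dims: int = 1
    N: int = 1000
    tau: float = 0.010
    I0: float = 3.0
    A: float = 200.0
    sigma2: float = 0.1
    phi_shift: float = 0.2
    gamma: float = 0.06

    def __post_init__(self) -> None:
        if self.dims not in (1, 2):
            raise ValueError("dims must be 1 or 2")
        if self.N < 4:
            raise ValueError("need N >= 4 neurons per sub-population")
        if self.dims == 2 and round(self.N**0.5) ** 2 != self.N:
            raise ValueError("2D modules need N to be a perfect square")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0 < self.phi_shift < 0.5:
            raise ValueError("phi_shift must lie in (0, 0.5)")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")

    @property
    def n_subpops(self) -> int:
        return 2 * self.dims

    @property
    def n_neurons(self) -> int:
        """Total neurons in the module (all sub-populations)."""
        return self.n_subpops * self.N


def periodic_distance_1d(x):
    """Minimal distance on the unit ring, ``min(|x| mod 1, 1 - |x| mod 1)``.

    Accepts any real array; the result lies in [0, 0.5].
    """
    a = np.mod(np.abs(x), 1.0)
    return np.minimum(a, 1.0 - a)


def periodic_distance_2d(v, window: int = 2):
    """Minimal Euclidean distance on the rhombic torus.

    The torus is the plane modulo the lattice generated by ``LATTICE_U1`` and
    ``LATTICE_U2``; the distance is minimized over integer lattice shifts in
    ``{-window..window}^2``, which is sufficient for the unit rhombus.

    Parameters
    ----------
    v : array_like, shape (..., 2)
        Phase-difference vectors.
    """
    v = np.asarray(v, dtype=float)
    ks = np.arange(-window, window + 1)
    shifts = (ks[:, None, None] * LATTICE_U1 + ks[None, :, None] * LATTICE_U2).reshape(-1, 2)
    d = np.linalg.norm(v[..., None, :] - shifts, axis=-1)
    return d.min(axis=-1)


def _weight_profile(dist, A, sigma2, n_total):
    """w(theta) = (A / n_total) * (exp(-theta^2 / 2 sigma^2) - 1), all <= 0."""
    return (A / n_total) * (np.exp(-(dist**2) / (2.0 * sigma2)) - 1.0)


def build_ring_weights(spec: ModuleSpec) -> np.ndarray:
    """Block-row of the double-ring weight matrix, shape (N, 2N).

    Column blocks are the presynaptic R and L sub-populations, with outgoing
    weights shifted by +phi (R) and -phi (L) along the ring.  The full
    recurrent matrix consists of two identical copies of this block-row (the
    recurrent input to a neuron does not depend on its own sub-population);
    see :meth:`AttractorNetwork.full_weight_matrix`.
    """
    if spec.dims != 1:
        raise ValueError("build_ring_weights requires a 1D spec")
    theta = np.arange(spec.N) / spec.N
    diff = theta[:, None] - theta[None, :]
    w_r = _weight_profile(periodic_distance_1d(diff - spec.phi_shift), spec.A, spec.sigma2, 2 * spec.N)
    w_l = _weight_profile(periodic_distance_1d(diff + spec.phi_shift), spec.A, spec.sigma2, 2 * spec.N)
    return np.hstack([w_r, w_l])


def build_torus_weights(spec: ModuleSpec) -> np.ndarray:
    """Block-row of the twisted-torus weight matrix, shape (N, 4N).

    Presynaptic column blocks follow the R, L, U, D order with outgoing
    shifts +-(phi, 0) for R/L and +-(0, phi) for U/D in Cartesian phase
    coordinates; distances are measured on the rhombic torus.
    """
    if spec.dims != 2:
        raise ValueError("build_torus_weights requires a 2D spec")
    coords = _lattice_coords(spec.N)
    phases = coords @ np.stack([LATTICE_U1, LATTICE_U2])
    diff = phases[:, None, :] - phases[None, :, :]
    n_total = 4 * spec.N
    blocks = []
    for shift in (
        np.array([spec.phi_shift, 0.0]),
        np.array([-spec.phi_shift, 0.0]),
        np.array([0.0, spec.phi_shift]),
        np.array([0.0, -spec.phi_shift]),
    ):
        dist = periodic_distance_2d(diff - shift)
        blocks.append(_weight_profile(dist, spec.A, spec.sigma2, n_total))
    return np.hstack(blocks)


def _lattice_coords(N: int) -> np.ndarray:
    """Deterministic sqrt(N) x sqrt(N) lattice coordinates (x_i, y_i) in [0, 1)."""
    n_side = round(N**0.5)
    g = np.arange(n_side) / n_side
    xx, yy = np.meshgrid(g, g, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class AttractorNetwork:
    """A realized single-module attractor network.

    Attributes
    ----------
    spec : ModuleSpec
    W_row : ndarray, shape (N, n_subpops * N)
        One block-row of the recurrent weight matrix; all block-rows of the
        full matrix are identical.
    coords : ndarray
        Preferred phases.  1D: shape (N,), the ring phase of each neuron of
        one sub-population (all sub-populations share the arrangement).
        2D: shape (N, 2), lattice coordinates (x_i, y_i) of one sheet.
    """

    spec: ModuleSpec
    W_row: np.ndarray = field(repr=False)
    coords: np.ndarray = field(repr=False)

    @property
    def n_neurons(self) -> int:
        return self.spec.n_neurons

    @property
    def subpop_names(self):
        return SUBPOPS_1D if self.spec.dims == 1 else SUBPOPS_2D

    @property
    def subpop_labels(self) -> np.ndarray:
        """Per-neuron sub-population label over the full module state vector."""
        return np.repeat(np.array(self.subpop_names), self.spec.N)

    def subpop_slice(self, name: str) -> slice:
        i = self.subpop_names.index(name)
        return slice(i * self.spec.N, (i + 1) * self.spec.N)

    @property
    def preferred_phase(self) -> np.ndarray:
        """Preferred phase per neuron of the full state vector.

        1D: shape (n_neurons,).  2D: shape (n_neurons, 2), Cartesian phase
        positions ``x_i * u1 + y_i * u2``.
        """
        if self.spec.dims == 1:
            return np.tile(self.coords, self.spec.n_subpops)
        cart = self.coords @ np.stack([LATTICE_U1, LATTICE_U2])
        return np.tile(cart, (self.spec.n_subpops, 1))

    @property
    def lattice_coords(self) -> np.ndarray:
        """Lattice (c1, c2) coordinates per neuron of the full state vector.

        1D: alias of :attr:`preferred_phase`.
        """
        if self.spec.dims == 1:
            return self.preferred_phase
        return np.tile(self.coords, (self.spec.n_subpops, 1))

    def full_weight_matrix(self) -> np.ndarray:
        """Assemble the full (n_subpops*N) x (n_subpops*N) recurrent matrix."""
        return np.tile(self.W_row, (self.spec.n_subpops, 1))

    def recurrent_input(self, s: np.ndarray) -> np.ndarray:
        """W @ s for the full state vector, exploiting the repeated block-row.

        ``s`` may be (n_neurons,) or (n_neurons, n_batch).
        """
        h_unit = self.W_row @ s
        reps = (self.spec.n_subpops,) + (1,) * (h_unit.ndim - 1)
        return np.tile(h_unit, reps)

    #: signed channel vectors used by the velocity readout, see coupling.py
    def channel_signs(self, channel: int) -> np.ndarray:
        """+1/-1/0 vector over neurons: +1 for the positive sub-population of
        the channel (R for x, U for y), -1 for the negative one, 0 elsewhere."""
        sign = np.zeros(self.n_neurons)
        pos, neg = ("R", "L") if channel == 0 else ("U", "D")
        sign[self.subpop_slice(pos)] = 1.0
        sign[self.subpop_slice(neg)] = -1.0
        return sign


def build_network(spec: ModuleSpec) -> AttractorNetwork:
    """Build the realized network (weights + preferred phases) for a spec."""
    if spec.dims == 1:
        theta = np.arange(spec.N) / spec.N
        return AttractorNetwork(spec=spec, W_row=build_ring_weights(spec), coords=theta)
    return AttractorNetwork(spec=spec, W_row=build_torus_weights(spec), coords=_lattice_coords(spec.N))
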