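"""Desk-scale bead-chain molecular model and its canonical samplers.

A :class:`ToySystem` is a chain of beads interacting through

* harmonic bonds ``0.5 * k * (r - r0)**2``,
* a C6/C12 Lennard-Jones term ``C12/r**12 - C6/r**6`` with geometric
  combination of the per-particle square-root coefficients
  (``C6_ab = sqrt_c6_a * sqrt_c6_b``), and
* a Coulomb term ``COULOMB * q_a * q_b / r``.

Units throughout: nm, kJ/mol, elementary charge, Kelvin.  First bonded
neighbours (1-2 pairs) are excluded from the non-bonded sums; no cutoff is
applied.  The default sampler is single-particle-displacement Metropolis
Monte Carlo, which is all the replica-exchange machinery requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .constants import BOLTZMANN, COULOMB

__all__ = [
    "Particle",
    "Bond",
    "ParameterSet",
    "ToySystem",
    "Conformation",
    "Trajectory",
    "MetropolisWalker",
    "pair_energy",
    "total_energy",
    "pairwise_energy_matrix",
    "sample",
    "generate_fixture",
    "packaged_fixture",
    "double_well_dimer",
    "dimer_radial_potential",
]


@dataclass(frozen=True)
class Particle:
    """One bead: its identity and non-bonded parameters."""

    index: int
    residue_id: int
    charge: float
    sqrt_c6: float
    sqrt_c12: float

    def __post_init__(self) -> None:
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        if self.sqrt_c6 < 0:
            raise ValueError(f"sqrt_c6 must be >= 0, got {self.sqrt_c6}")
        if self.sqrt_c12 < 0:
            raise ValueError(f"sqrt_c12 must be >= 0, got {self.sqrt_c12}")


@dataclass(frozen=True)
class Bond:
    """Harmonic bond between particles ``i`` and ``j``."""

    i: int
    j: int
    r0: float
    k: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"bond endpoints must differ, got ({self.i}, {self.j})")


@dataclass
class ParameterSet:
    """Per-particle non-bonded parameters as flat arrays.

    Separating parameters from the :class:`ToySystem` makes Hamiltonian
    scaling a pure array operation: a scaled replica shares the system's
    topology but carries its own :class:`ParameterSet`.
    """

    charge: np.ndarray
    sqrt_c6: np.ndarray
    sqrt_c12: np.ndarray

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.sqrt_c6 = np.asarray(self.sqrt_c6, dtype=float)
        self.sqrt_c12 = np.asarray(self.sqrt_c12, dtype=float)
        n = len(self.charge)
        if len(self.sqrt_c6) != n or len(self.sqrt_c12) != n:
            raise ValueError("parameter arrays must have equal length")
        if np.any(self.sqrt_c6 < 0) or np.any(self.sqrt_c12 < 0):
            raise ValueError("sqrt_c6 and sqrt_c12 must be non-negative")

    @classmethod
    def from_particles(cls, particles: Sequence[Particle]) -> "ParameterSet":
        return cls(
            charge=np.array([p.charge for p in particles]),
            sqrt_c6=np.array([p.sqrt_c6 for p in particles]),
            sqrt_c12=np.array([p.sqrt_c12 for p in particles]),
        )

    def copy(self) -> "ParameterSet":
        return ParameterSet(self.charge.copy(), self.sqrt_c6.copy(), self.sqrt_c12.copy())

    def __len__(self) -> int:
        return len(self.charge)

    def allclose(self, other: "ParameterSet", atol: float = 0.0, rtol: float = 1e-12) -> bool:
        return (
            np.allclose(self.charge, other.charge, atol=atol, rtol=rtol)
            and np.allclose(self.sqrt_c6, other.sqrt_c6, atol=atol, rtol=rtol)
            and np.allclose(self.sqrt_c12, other.sqrt_c12, atol=atol, rtol=rtol)
        )


@dataclass
class Conformation:
    """A single set of particle coordinates, shape ``(n_particles, 3)`` nm."""

    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames stored every ``frame_interval`` sampler steps."""

    frames: list[Conformation]
    frame_interval: int = 1

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        n = self.frames[0].n_particles
        for idx, fr in enumerate(self.frames):
            if fr.n_particles != n:
                raise ValueError(
                    f"frame {idx} has {fr.n_particles} particles, expected {n}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles

    def coordinates(self) -> np.ndarray:
        """Stack all frames into a ``(n_frames, n_particles, 3)`` array."""
        return np.stack([fr.coords for fr in self.frames])


@dataclass
class ToySystem:
    """Bead-chain topology plus native coordinates and temperature."""

    particles: list[Particle]
    bonds: list[Bond]
    native_coords: np.ndarray
    temperature: float
    residue_count: int

    def __post_init__(self) -> None:
        self.native_coords = np.asarray(self.native_coords, dtype=float)
        n = len(self.particles)
        if self.native_coords.shape != (n, 3):
            raise ValueError(
                f"native_coords must have shape ({n}, 3), got {self.native_coords.shape}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i}, {b.j}) references missing particles")
        seen = {p.residue_id for p in self.particles}
        if seen != set(range(1, self.residue_count + 1)):
            raise ValueError(
                "every residue_id in 1..residue_count must appear at least once"
            )
        self._exclusion: np.ndarray | None = None

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def residue_ids(self) -> np.ndarray:
        return np.array([p.residue_id for p in self.particles], dtype=int)

    @property
    def native_params(self) -> ParameterSet:
        return ParameterSet.from_particles(self.particles)

    @property
    def exclusion_mask(self) -> np.ndarray:
        """Boolean (n, n) mask of pairs excluded from non-bonded sums.

        Diagonal (self) and 1-2 bonded pairs are excluded.
        """
        if self._exclusion is None:
            n = self.n_particles
            mask = np.eye(n, dtype=bool)
            for b in self.bonds:
                mask[b.i, b.j] = mask[b.j, b.i] = True
            self._exclusion = mask
        return self._exclusion

    def bond_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if not self.bonds:
            z = np.zeros(0)
            return z.astype(int), z.astype(int), z, z
        i = np.array([b.i for b in self.bonds], dtype=int)
        j = np.array([b.j for b in self.bonds], dtype=int)
        r0 = np.array([b.r0 for b in self.bonds])
        k = np.array([b.k for b in self.bonds])
        return i, j, r0, k


# ---------------------------------------------------------------------------
# Energy kernels
# ---------------------------------------------------------------------------


def pair_energy(p_a: Particle, p_b: Particle, r: float) -> float:
    """Non-bonded energy of one particle pair at separation ``r`` (nm).

    Returns ``C12_ab/r**12 - C6_ab/r**6 + COULOMB*q_a*q_b/r`` with geometric
    combination ``C6_ab = sqrt_c6_a*sqrt_c6_b``, ``C12_ab = sqrt_c12_a*sqrt_c12_b``.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    c6 = p_a.sqrt_c6 * p_b.sqrt_c6
    c12 = p_a.sqrt_c12 * p_b.sqrt_c12
    inv_r6 = 1.0 / r**6
    return c12 * inv_r6 * inv_r6 - c6 * inv_r6 + COULOMB * (p_a.charge * p_b.charge) / r


def _nonbonded_matrix(
    coords: np.ndarray, params: ParameterSet, excl: np.ndarray
) -> np.ndarray:
    """Particle-pair non-bonded energy matrix with excluded entries zeroed."""
    delta = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", delta, delta)
    r2 = np.where(excl, 1.0, r2)  # placeholder on excluded entries, zeroed below
    with np.errstate(divide="ignore"):
        inv_r2 = 1.0 / r2
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    e = (
        np.outer(params.sqrt_c12, params.sqrt_c12) * inv_r6 * inv_r6
        - np.outer(params.sqrt_c6, params.sqrt_c6) * inv_r6
        + COULOMB * np.outer(params.charge, params.charge) * np.sqrt(inv_r2)
    )
    e[excl] = 0.0
    return e


def _energy_and_grad(
    system: ToySystem,
    coords: np.ndarray,
    params: ParameterSet,
    confine: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Potential energy and its analytic gradient, used by the minimizer.

    ``confine`` adds a harmonic well toward the instantaneous centroid,
    which collapses the chain during the staged native-structure search.
    """
    n = coords.shape[0]
    excl = system.exclusion_mask
    delta = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", delta, delta)
    r2 = np.where(excl, 1.0, r2)
    with np.errstate(divide="ignore"):
        inv_r2 = 1.0 / r2
    inv_r6 = inv_r2 * inv_r2 * inv_r2
    inv_r = np.sqrt(inv_r2)
    c6 = np.outer(params.sqrt_c6, params.sqrt_c6)
    c12 = np.outer(params.sqrt_c12, params.sqrt_c12)
    qq = COULOMB * np.outer(params.charge, params.charge)
    e_mat = c12 * inv_r6 * inv_r6 - c6 * inv_r6 + qq * inv_r
    e_mat[excl] = 0.0
    # (1/r) dV/dr per pair
    g_scal = (
        -12.0 * c12 * inv_r6 * inv_r6 * inv_r2
        + 6.0 * c6 * inv_r6 * inv_r2
        - qq * inv_r2 * inv_r
    )
    g_scal[excl] = 0.0
    grad = np.einsum("ij,ijk->ik", g_scal, delta)
    energy = 0.5 * float(e_mat.sum())

    bi, bj, r0, k = system.bond_arrays()
    if len(bi):
        dvec = coords[bi] - coords[bj]
        r = np.linalg.norm(dvec, axis=1)
        energy += float(np.sum(0.5 * k * (r - r0) ** 2))
        coef = (k * (r - r0) / r)[:, None] * dvec
        np.add.at(grad, bi, coef)
        np.add.at(grad, bj, -coef)
    if confine > 0:
        centred = coords - coords.mean(axis=0)
        energy += confine * float(np.sum(centred**2))
        grad = grad + 2.0 * confine * centred
    return energy, grad


def _bonded_energy(system: ToySystem, coords: np.ndarray) -> float:
    bi, bj, r0, k = system.bond_arrays()
    if len(bi) == 0:
        return 0.0
    r = np.linalg.norm(coords[bi] - coords[bj], axis=1)
    return float(np.sum(0.5 * k * (r - r0) ** 2))


def _full_energy(system: ToySystem, coords: np.ndarray, params: ParameterSet) -> float:
    nb = _nonbonded_matrix(coords, params, system.exclusion_mask)
    return _bonded_energy(system, coords) + 0.5 * float(nb.sum())


def total_energy(
    system: ToySystem, conf: Conformation, params: ParameterSet | None = None
) -> float:
    """Potential energy: bonded harmonic terms plus all non-excluded pair terms."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if coords.shape[0] != system.n_particles:
        raise ValueError(
            f"conformation has {coords.shape[0]} particles, "
            f"system has {system.n_particles}"
        )
    if params is None:
        params = system.native_params
    return _full_energy(system, coords, params)


def pairwise_energy_matrix(
    system: ToySystem, conf: Conformation, params: ParameterSet | None = None
) -> np.ndarray:
    """Per-particle-pair non-bonded energies (excluded pairs zero)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if params is None:
        params = system.native_params
    return _nonbonded_matrix(coords, params, system.exclusion_mask)


# ---------------------------------------------------------------------------
# Metropolis sampler
# ---------------------------------------------------------------------------


class MetropolisWalker:
    """Single-particle-displacement Metropolis MC walker.

    The walker owns a coordinate array and a parameter set; replica exchange
    swaps parameter sets between walkers via :meth:`set_parameters`.
    """

    def __init__(
        self,
        system: ToySystem,
        params: ParameterSet | None = None,
        coords: np.ndarray | None = None,
        *,
        step_size: float = 0.03,
        temperature: float | None = None,
    ) -> None:
        if temperature is None:
            temperature = system.temperature
        if temperature <= 0:
            raise ValueError(f"temperature must be positive, got {temperature}")
        self.system = system
        self.params = params if params is not None else system.native_params
        self.coords = np.array(
            coords if coords is not None else system.native_coords, dtype=float
        )
        self.step_size = float(step_size)
        self.beta = 1.0 / (BOLTZMANN * temperature)
        self.n = system.n_particles
        self.n_accepted = 0
        self.n_moves = 0
        # per-particle bond adjacency for O(partners) local bond energy
        self._bond_partners: list[np.ndarray] = [np.zeros(0, int) for _ in range(self.n)]
        self._bond_r0: list[np.ndarray] = [np.zeros(0) for _ in range(self.n)]
        self._bond_k: list[np.ndarray] = [np.zeros(0) for _ in range(self.n)]
        adj: list[list[tuple[int, float, float]]] = [[] for _ in range(self.n)]
        for b in system.bonds:
            adj[b.i].append((b.j, b.r0, b.k))
            adj[b.j].append((b.i, b.r0, b.k))
        for p, entries in enumerate(adj):
            if entries:
                self._bond_partners[p] = np.array([e[0] for e in entries], int)
                self._bond_r0[p] = np.array([e[1] for e in entries])
                self._bond_k[p] = np.array([e[2] for e in entries])
        self._excl = system.exclusion_mask

    def set_parameters(self, params: ParameterSet) -> None:
        self.params = params

    def total_energy(self) -> float:
        return _full_energy(self.system, self.coords, self.params)

    def _local_energy(self, k: int, pos: np.ndarray) -> float:
        p = self.params
        delta = self.coords - pos
        r2 = np.einsum("ij,ij->i", delta, delta)
        mask = self._excl[k]
        r2 = np.where(mask, 1.0, r2)
        inv_r2 = 1.0 / r2
        inv_r6 = inv_r2 * inv_r2 * inv_r2
        e = (
            p.sqrt_c12[k] * p.sqrt_c12 * inv_r6 * inv_r6
            - p.sqrt_c6[k] * p.sqrt_c6 * inv_r6
            + COULOMB * p.charge[k] * p.charge * np.sqrt(inv_r2)
        )
        e_nb = float(np.sum(np.where(mask, 0.0, e)))
        partners = self._bond_partners[k]
        if len(partners):
            r = np.linalg.norm(self.coords[partners] - pos, axis=1)
            e_nb += float(np.sum(0.5 * self._bond_k[k] * (r - self._bond_r0[k]) ** 2))
        return e_nb

    def step(self, rng: np.random.Generator) -> bool:
        k = int(rng.integers(self.n))
        old = self.coords[k].copy()
        disp = rng.normal(0.0, self.step_size, 3) if self.step_size > 0 else np.zeros(3)
        new = old + disp
        d_e = self._local_energy(k, new) - self._local_energy(k, old)
        self.n_moves += 1
        if d_e <= 0 or rng.random() < math.exp(-self.beta * d_e):
            self.coords[k] = new
            self.n_accepted += 1
            return True
        return False

    def advance(self, n_moves: int, rng: np.random.Generator) -> None:
        for _ in range(n_moves):
            self.step(rng)


def sample(
    system: ToySystem,
    params: ParameterSet | None = None,
    n_steps: int = 1000,
    seed: int = 0,
    *,
    step_size: float = 0.03,
    frame_interval: int = 10,
    initial: Conformation | None = None,
    temperature: float | None = None,
) -> Trajectory:
    """Run Metropolis MC and return stored frames (including the start).

    Deterministic for a fixed seed.  ``frame_interval`` is measured in MC
    moves; the returned trajectory has ``n_steps // frame_interval + 1``
    frames.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = np.random.default_rng(seed)
    coords0 = initial.coords if initial is not None else None
    walker = MetropolisWalker(
        system, params, coords0, step_size=step_size, temperature=temperature
    )
    frames = [Conformation(walker.coords.copy())]
    done = 0
    while done < n_steps:
        chunk = min(frame_interval, n_steps - done)
        walker.advance(chunk, rng)
        done += chunk
        frames.append(Conformation(walker.coords.copy()))
    return Trajectory(frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

# Background bead: sigma ~0.34 nm, well depth ~0.05 kJ/mol (nearly ideal chain).
_BG_SQRT_C6 = 0.0176
_BG_SQRT_C12 = 6.9e-4
_BG_CHARGE = 0.03
_BOND_R0 = 0.38
_BOND_K = 4000.0


def generate_fixture(
    n_residues: int,
    hotspot_ids: Iterable[int],
    strength: float,
    seed: int,
    *,
    temperature: float = 300.0,
    background_scale: float = 1.0,
    beads_per_residue: int = 1,
) -> ToySystem:
    """Build a bead chain with planted strongly interacting residues.

    Each residue has one backbone bead (plus ``beads_per_residue - 1``
    pendant beads bonded to it).  Background beads carry weak Lennard-Jones
    parameters and small alternating charges; the backbone beads of residues
    listed in ``hotspot_ids`` have ``sqrt_c6`` and charge multiplied by
    ``strength``, making their mutual attractions dominate the
    interaction-energy matrix.  Pendant beads always carry background
    parameters: they contribute potential-energy fluctuations (histogram
    width, standing in for the solvent/degrees-of-freedom bath of an
    all-atom system) without deepening the planted interactions.
    ``background_scale`` multiplies every bead's ``sqrt_c6`` uniformly,
    stiffening the whole native basin without changing the hot-spot to
    background contrast.  Native coordinates are produced by locally
    minimising the potential from a compact helical start.
    """
    hotspots = list(hotspot_ids)
    if len(set(hotspots)) != len(hotspots):
        raise ValueError(f"duplicate hotspot ids: {sorted(hotspots)}")
    if not set(hotspots) <= set(range(1, n_residues + 1)):
        raise ValueError(
            f"hotspot ids {sorted(hotspots)} not within 1..{n_residues}"
        )
    if strength < 1:
        raise ValueError(f"strength must be >= 1, got {strength}")
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if beads_per_residue < 1:
        raise ValueError("beads_per_residue must be >= 1")
    rng = np.random.default_rng(seed)
    hot = np.zeros(n_residues, dtype=bool)
    hot[np.array(hotspots, dtype=int) - 1] = True

    n_particles = n_residues * beads_per_residue
    jit6 = 1.0 + 0.05 * rng.uniform(-1, 1, n_particles)
    jit12 = 1.0 + 0.05 * rng.uniform(-1, 1, n_particles)
    # heterogeneous hot-spot boosts (exponent spread around 1) give the
    # planted interactions a range of depths, so a scaled-Hamiltonian ladder
    # peels them off progressively instead of in one cooperative step
    boost6_res = np.ones(n_residues)
    m = len(hotspots)
    exps = np.linspace(0.85, 1.15, m) if m > 1 else np.array([1.0])
    for e, rid in zip(exps, sorted(hotspots)):
        boost6_res[rid - 1] = strength**e

    particles: list[Particle] = []
    bonds: list[Bond] = []
    backbone: list[int] = []
    for res in range(n_residues):
        bb = len(particles)
        backbone.append(bb)
        sign = 1.0 if res % 2 == 0 else -1.0
        particles.append(
            Particle(
                index=bb,
                residue_id=res + 1,
                charge=float(sign * _BG_CHARGE * (strength if hot[res] else 1.0)),
                sqrt_c6=float(
                    _BG_SQRT_C6 * background_scale * jit6[bb] * boost6_res[res]
                ),
                sqrt_c12=float(_BG_SQRT_C12 * jit12[bb]),
            )
        )
        if res > 0:
            bonds.append(Bond(backbone[res - 1], bb, _BOND_R0, _BOND_K))
        for _ in range(beads_per_residue - 1):
            side = len(particles)
            particles.append(
                Particle(
                    index=side,
                    residue_id=res + 1,
                    charge=float(-sign * _BG_CHARGE),
                    sqrt_c6=float(_BG_SQRT_C6 * background_scale * jit6[side]),
                    sqrt_c12=float(_BG_SQRT_C12 * jit12[side]),
                )
            )
            bonds.append(Bond(bb, side, 0.30, 2000.0))

    # compact helical start + local minimisation -> native geometry
    turns = np.arange(n_residues) * 1.7
    bb_start = np.stack(
        [0.22 * np.cos(turns), 0.22 * np.sin(turns), 0.14 * np.arange(n_residues)],
        axis=1,
    )
    start = np.zeros((n_particles, 3))
    for res in range(n_residues):
        start[backbone[res]] = bb_start[res]
        radial = bb_start[res] - np.array([0.0, 0.0, bb_start[res, 2]])
        norm = np.linalg.norm(radial) or 1.0
        for j in range(beads_per_residue - 1):
            start[backbone[res] + 1 + j] = bb_start[res] + (0.30 + 0.05 * j) * radial / norm
    start += rng.normal(0.0, 0.01, start.shape)
    system = ToySystem(
        particles=particles,
        bonds=bonds,
        native_coords=start,
        temperature=temperature,
        residue_count=n_residues,
    )

    # staged minimisation: a decaying centroid confinement collapses the
    # chain so every hot-spot pair comes within interaction range before the
    # final unconstrained polish
    params = system.native_params
    x = start.ravel()
    for confine in (30.0, 5.0, 0.5, 0.0):

        def objective(flat: np.ndarray, w: float = confine):
            e, g = _energy_and_grad(system, flat.reshape(-1, 3), params, confine=w)
            return e, g.ravel()

        res = minimize(objective, x, method="L-BFGS-B", jac=True,
                       options={"maxiter": 3000})
        x = res.x
    system.native_coords = x.reshape(-1, 3)
    return system


def packaged_fixture() -> ToySystem:
    """The package's reference fixture: 20 residues, hot spots {2, 6, 10, 14, 18}.

    Three beads per residue: the pendant beads form the fluctuation bath
    that widens per-rung energy histograms, mirroring the role of the
    many unperturbed degrees of freedom in an all-atom solvated system.
    """
    return generate_fixture(
        20, (2, 6, 10, 14, 18), strength=5.0, seed=42, beads_per_residue=3
    )


def double_well_dimer(
    temperature: float = 300.0,
    *,
    bond_r0: float = 0.70,
    bond_k: float = 400.0,
    sigma: float = 0.25,
    epsilon: float = 46.0,
) -> ToySystem:
    """Two beads whose interparticle-distance potential has two minima.

    The short-range LJ well (around ``2**(1/6) * sigma``) and a harmonic
    restraint centred at ``bond_r0`` compete, producing a double well in the
    bead separation.  Exact Boltzmann expectations follow from 1-D
    quadrature over ``r**2 * exp(-beta * V(r))`` (see
    :func:`dimer_radial_potential`), which makes this system the package's
    analytic sampling oracle.
    """
    # The LJ pair must stay in the non-bonded sum, so the restraint is
    # registered *after* the exclusion mask is built: it contributes bonded
    # energy without excluding the pair.
    sqrt_c6 = math.sqrt(4 * epsilon * sigma**6)
    sqrt_c12 = math.sqrt(4 * epsilon * sigma**12)
    particles = [
        Particle(0, 1, 0.0, sqrt_c6, sqrt_c12),
        Particle(1, 2, 0.0, sqrt_c6, sqrt_c12),
    ]
    native = np.array([[0.0, 0.0, 0.0], [2 ** (1 / 6) * sigma, 0.0, 0.0]])
    system = ToySystem(
        particles=particles,
        bonds=[],
        native_coords=native,
        temperature=temperature,
        residue_count=2,
    )
    # restraint implemented via a bond that is NOT added to the exclusion
    # mask: build the mask first, then register the bond.
    _ = system.exclusion_mask
    system.bonds.append(Bond(0, 1, bond_r0, bond_k))
    return system


def dimer_radial_potential(system: ToySystem) -> Callable[[np.ndarray], np.ndarray]:
    """Radial potential V(r) of a two-particle system, for quadrature oracles."""
    if system.n_particles != 2:
        raise ValueError("radial potential is defined for two-particle systems only")

    p0, p1 = system.particles
    c6 = p0.sqrt_c6 * p1.sqrt_c6
    c12 = p0.sqrt_c12 * p1.sqrt_c12
    qq = p0.charge * p1.charge
    excluded = bool(system.exclusion_mask[0, 1])
    bi, bj, r0, k = system.bond_arrays()

    def potential(r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        v = np.zeros_like(r)
        if not excluded:
            inv_r6 = 1.0 / r**6
            v = v + c12 * inv_r6**2 - c6 * inv_r6 + COULOMB * qq / r
        for rr0, kk in zip(r0, k):
            v = v + 0.5 * kk * (r - rr0) ** 2
        return v

    return potential
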