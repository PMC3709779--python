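"""Residue interaction-energy matrix, its spectrum, and hot-spot selection.

The trajectory-averaged residue-residue non-bonded energy matrix ``M`` is
diagonalized as ``M_ij = sum_k lambda_k * w_i^k * w_j^k`` with eigenvalues
sorted ascending (``lambda_1`` most negative).  Writing
``W_k = (sum_i w_i^k)**2``, the total non-bonded energy satisfies
``E_nb = sum_ij M_ij = sum_k lambda_k W_k`` and is approximated by the first
mode, ``lambda_1 * W_1``.  Residues whose first-eigenvector component
magnitude strictly exceeds the flat-vector threshold ``1/sqrt(N)`` are the
fold-stabilizing hot spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np

from .toy_system import ToySystem, Trajectory, ParameterSet, pairwise_energy_matrix

__all__ = [
    "InteractionMatrix",
    "EnergySpectrum",
    "HotspotSet",
    "build_matrix",
    "decompose",
    "approximation_quality",
    "select_hotspots",
]

#: Eigenvalues closer than this are treated as a degenerate first mode.
DEGENERACY_TOL = 1e-12


@dataclass
class InteractionMatrix:
    """Symmetric residue-residue mean interaction-energy matrix (kJ/mol).

    Diagonal entries (self interactions) are identically zero.
    """

    matrix: np.ndarray
    residue_labels: tuple[int, ...]
    n_frames_averaged: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix must be square, got {self.matrix.shape}")
        if len(self.residue_labels) != n:
            raise ValueError("one residue label per matrix row is required")

    @property
    def n_residues(self) -> int:
        return self.matrix.shape[0]


@dataclass
class EnergySpectrum:
    """Eigen-decomposition of an :class:`InteractionMatrix`.

    ``eigenvectors[:, k]`` is the unit eigenvector of ``eigenvalues[k]``;
    eigenvalues are ascending so column 0 is the first (most negative) mode.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    weights: np.ndarray
    e_nb: float
    e_app: float
    residue_labels: tuple[int, ...]

    @property
    def n_residues(self) -> int:
        return len(self.eigenvalues)

    @property
    def first_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


@dataclass
class HotspotSet:
    """Residues selected by the flat-eigenvector threshold ``1/sqrt(N)``."""

    residue_ids: tuple[int, ...]
    threshold: float
    components: dict[int, float] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.residue_ids)

    def __len__(self) -> int:
        return len(self.residue_ids)


def build_matrix(
    trajectory: Trajectory,
    system: ToySystem,
    skip_frames: int | None = None,
    params: ParameterSet | None = None,
) -> InteractionMatrix:
    """Average residue-pair non-bonded energies over the equilibrated frames.

    ``skip_frames`` frames are dropped from the start (default: the first
    quarter of the trajectory, mirroring equilibration removal).  Entry
    ``(i, j)`` sums every retained non-excluded particle pair with one
    particle in residue ``i`` and the other in residue ``j``; the diagonal
    is set to zero.
    """
    if skip_frames is None:
        skip_frames = len(trajectory) // 4
    if skip_frames < 0:
        raise ValueError(f"skip_frames must be >= 0, got {skip_frames}")
    frames = trajectory.frames[skip_frames:]
    if not frames:
        raise ValueError(
            f"no frames left after skipping {skip_frames} of {len(trajectory)}"
        )
    if trajectory.n_particles != system.n_particles:
        raise ValueError("trajectory and system particle counts differ")

    n_res = system.residue_count
    # indicator: residues x particles, aggregates the particle-pair matrix
    indicator = np.zeros((n_res, system.n_particles))
    indicator[system.residue_ids - 1, np.arange(system.n_particles)] = 1.0

    acc = np.zeros((n_res, n_res))
    for fr in frames:
        e_pp = pairwise_energy_matrix(system, fr, params)
        acc += indicator @ e_pp @ indicator.T
    acc /= len(frames)
    np.fill_diagonal(acc, 0.0)
    acc = 0.5 * (acc + acc.T)  # symmetric up to rounding; make it exact
    return InteractionMatrix(
        matrix=acc,
        residue_labels=tuple(range(1, n_res + 1)),
        n_frames_averaged=len(frames),
    )


def _as_matrix(matrix: InteractionMatrix | np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    if isinstance(matrix, InteractionMatrix):
        return matrix.matrix, matrix.residue_labels
    m = np.asarray(matrix, dtype=float)
    return m, tuple(range(1, m.shape[0] + 1))


def decompose(
    matrix: InteractionMatrix | np.ndarray, *, symmetry_tol: float = 1e-8
) -> EnergySpectrum:
    """Spectral decomposition with ascending eigenvalue order.

    Raises ``ValueError`` if the input is asymmetric beyond ``symmetry_tol``.
    """
    m, labels = _as_matrix(matrix)
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > symmetry_tol:
        raise ValueError(f"matrix asymmetry {asym:.3e} exceeds tolerance {symmetry_tol}")
    m = 0.5 * (m + m.T)
    eigenvalues, eigenvectors = np.linalg.eigh(m)  # ascending order
    weights = eigenvectors.sum(axis=0) ** 2
    e_nb = float(m.sum())
    e_app = float(eigenvalues[0] * weights[0])
    return EnergySpectrum(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        weights=weights,
        e_nb=e_nb,
        e_app=e_app,
        residue_labels=labels,
    )


def approximation_quality(spectrum: EnergySpectrum) -> float:
    """Fraction of the total non-bonded energy carried by the first mode."""
    if spectrum.e_nb == 0:
        raise ValueError("approximation quality undefined: total non-bonded energy is 0")
    return spectrum.e_app / spectrum.e_nb


def _first_mode_index(spectrum: EnergySpectrum) -> int:
    """Index of the mode used for selection, resolving degenerate lambda_1."""
    lam = spectrum.eigenvalues
    scale = max(1.0, abs(lam[0]))
    tied = np.flatnonzero(np.abs(lam - lam[0]) <= DEGENERACY_TOL * scale)
    if len(tied) > 1:
        warnings.warn(
            "degenerate first eigenvalue; selecting the tied mode with the most "
            "negative lambda_k * W_k",
            stacklevel=3,
        )
        contrib = lam[tied] * spectrum.weights[tied]
        return int(tied[np.argmin(contrib)])
    return 0


def select_hotspots(spectrum: EnergySpectrum) -> HotspotSet:
    """Residues whose first-eigenvector component magnitude exceeds ``1/sqrt(N)``.

    The eigenvector sign is canonicalized so its largest-magnitude component
    is positive; selection itself compares magnitudes, so it is
    sign-invariant.  The comparison is strict: a perfectly flat eigenvector
    selects nothing.
    """
    n = spectrum.n_residues
    if n < 1:
        raise ValueError("spectrum must cover at least one residue")
    mode = _first_mode_index(spectrum)
    vec = spectrum.eigenvectors[:, mode].copy()
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    threshold = 1.0 / np.sqrt(n)
    magnitudes = np.abs(vec)
    # strict inequality with a relative guard so an exactly flat eigenvector
    # (components == threshold up to eigensolver rounding) selects nothing
    selected = np.flatnonzero(magnitudes > threshold * (1.0 + 1e-9))
    labels = spectrum.residue_labels
    ids = tuple(sorted(labels[i] for i in selected))
    components = {labels[i]: float(magnitudes[i]) for i in selected}
    return HotspotSet(residue_ids=ids, threshold=float(threshold), components=components)
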