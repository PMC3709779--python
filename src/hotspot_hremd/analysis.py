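"""Observables on the unscaled-ensemble trajectory.

Superposed RMSD and folded/unfolded classification, radius of gyration,
2-D free-energy landscapes over (RMSD, Rgyr), neighbour-counting
conformational clustering, and potential-energy histogram overlap between
ladder rungs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import BOLTZMANN
from .toy_system import Conformation, Trajectory

__all__ = [
    "FELGrid",
    "ClusterSet",
    "HistogramSet",
    "rmsd",
    "classify_folded",
    "radius_of_gyration",
    "free_energy_landscape",
    "cluster_conformations",
    "energy_histograms",
    "rmsd_trace",
    "rgyr_trace",
    "count_threshold_crossings",
]

FOLDED_THRESHOLD = 0.2  # nm


def _coords(obj) -> np.ndarray:
    return np.asarray(getattr(obj, "coords", obj), dtype=float)


def rmsd(
    conf: Conformation | np.ndarray,
    reference: Conformation | np.ndarray,
    selection: Sequence[int] | None = None,
) -> float:
    """Minimal RMSD (nm) after optimal rigid superposition (Kabsch).

    ``selection`` restricts both structures to the given particle indices.
    """
    x = _coords(conf)
    y = _coords(reference)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        x = x[sel]
        y = y[sel]
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    n = x.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 particles")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    cov = xc.T @ yc
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(u @ vt))
    s[-1] *= sign
    msd = (np.sum(xc**2) + np.sum(yc**2) - 2.0 * np.sum(s)) / n
    return float(np.sqrt(max(msd, 0.0)))


def classify_folded(rmsd_value: float, threshold: float = FOLDED_THRESHOLD) -> bool:
    """True iff ``rmsd_value`` is strictly below the folded threshold."""
    if rmsd_value < 0:
        raise ValueError(f"RMSD must be non-negative, got {rmsd_value}")
    return rmsd_value < threshold


def radius_of_gyration(
    conf: Conformation | np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted RMS distance (nm) from the centre of mass."""
    x = _coords(conf)
    if x.shape[0] < 1:
        raise ValueError("need at least one particle")
    if masses is None:
        masses = np.ones(x.shape[0])
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * x).sum(axis=0) / total
    sq = np.sum(masses * np.sum((x - com) ** 2, axis=1)) / total
    return float(np.sqrt(sq))


def rmsd_trace(
    trajectory: Trajectory,
    reference: Conformation | np.ndarray,
    selection: Sequence[int] | None = None,
) -> np.ndarray:
    return np.array([rmsd(fr, reference, selection) for fr in trajectory.frames])


def rgyr_trace(
    trajectory: Trajectory, masses: np.ndarray | None = None
) -> np.ndarray:
    return np.array([radius_of_gyration(fr, masses) for fr in trajectory.frames])


def count_threshold_crossings(
    values: np.ndarray, threshold: float = FOLDED_THRESHOLD
) -> tuple[int, int]:
    """(upward, downward) crossings of ``threshold`` along a series.

    Upward = folded to unfolded (value rises through the threshold);
    downward = unfolded back to folded.
    """
    values = np.asarray(values, dtype=float)
    below = values < threshold
    up = int(np.sum(below[:-1] & ~below[1:]))
    down = int(np.sum(~below[:-1] & below[1:]))
    return up, down


@dataclass
class FELGrid:
    """Free energy (kJ/mol) over RMSD x Rgyr bins; NaN marks empty bins."""

    rmsd_edges: np.ndarray
    rgyr_edges: np.ndarray
    free_energy: np.ndarray  # shape (n_rmsd_bins, n_rgyr_bins)
    temperature: float

    @property
    def minimum(self) -> float:
        return float(np.nanmin(self.free_energy))


def free_energy_landscape(
    trajectory: Trajectory,
    reference: Conformation | np.ndarray,
    temperature: float,
    bins: int | tuple[int, int] = 32,
    *,
    masses: np.ndarray | None = None,
    selection: Sequence[int] | None = None,
) -> FELGrid:
    """Boltzmann-invert the (RMSD, Rgyr) histogram: ``-kT ln(p / p_max)``.

    The global minimum is shifted to zero; unvisited bins are NaN.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    r = rmsd_trace(trajectory, reference, selection)
    g = rgyr_trace(trajectory, masses)
    counts, rmsd_edges, rgyr_edges = np.histogram2d(r, g, bins=bins)
    p = counts / counts.sum()
    with np.errstate(divide="ignore"):
        fe = -BOLTZMANN * temperature * np.log(p / p.max())
    fe[counts == 0] = np.nan
    return FELGrid(
        rmsd_edges=rmsd_edges,
        rgyr_edges=rgyr_edges,
        free_energy=fe,
        temperature=temperature,
    )


@dataclass
class ClusterSet:
    """Frame-to-cluster assignments from neighbour-counting clustering."""

    assignments: np.ndarray  # frame index -> cluster id (0-based, by size order)
    representatives: tuple[int, ...]  # central frame per cluster
    populations: tuple[int, ...]

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_conformations(
    trajectory: Trajectory,
    cutoff: float = 0.1,
    selection: Sequence[int] | None = None,
) -> ClusterSet:
    """Neighbour-counting (GROMOS-style) clustering on pairwise RMSD.

    Repeatedly pick the unassigned frame with the most unassigned
    neighbours within ``cutoff`` (ties broken by lowest frame index) as a
    representative, assign its neighbourhood to a new cluster, and repeat.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    n = len(trajectory)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = rmsd(trajectory.frames[i], trajectory.frames[j], selection)
            dist[i, j] = dist[j, i] = d
    neighbour = dist <= cutoff  # includes self

    assignments = np.full(n, -1, dtype=int)
    representatives: list[int] = []
    populations: list[int] = []
    unassigned = np.ones(n, dtype=bool)
    cluster_id = 0
    while unassigned.any():
        counts = (neighbour & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        rep = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(neighbour[rep] & unassigned)
        assignments[members] = cluster_id
        representatives.append(rep)
        populations.append(len(members))
        unassigned[members] = False
        cluster_id += 1
    return ClusterSet(
        assignments=assignments,
        representatives=tuple(representatives),
        populations=tuple(populations),
    )


@dataclass
class HistogramSet:
    """Per-rung potential-energy histograms on a common grid."""

    edges: np.ndarray
    probabilities: np.ndarray  # shape (n_rungs, n_bins); NaN rows for empty rungs
    overlaps: dict[tuple[int, int], float]
    excluded: tuple[int, ...] = field(default_factory=tuple)


def energy_histograms(
    energies_by_rung: Sequence[np.ndarray], n_bins: int = 50
) -> HistogramSet:
    """Common-grid histograms and neighbour overlap ``sum(min(p_a, p_b))``.

    Empty rungs are flagged in ``excluded`` and skipped in the overlap
    computation rather than treated as zero-overlap.
    """
    if len(energies_by_rung) < 2:
        raise ValueError("need at least two rungs")
    arrays = [np.asarray(e, dtype=float).ravel() for e in energies_by_rung]
    excluded = tuple(i for i, a in enumerate(arrays) if a.size == 0)
    valid = [a for a in arrays if a.size]
    if not valid:
        raise ValueError("all rungs are empty")
    lo = min(a.min() for a in valid)
    hi = max(a.max() for a in valid)
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    probs = np.full((len(arrays), n_bins), np.nan)
    for i, a in enumerate(arrays):
        if a.size:
            counts, _ = np.histogram(a, bins=edges)
            probs[i] = counts / counts.sum()
    overlaps: dict[tuple[int, int], float] = {}
    for i in range(len(arrays) - 1):
        if i in excluded or (i + 1) in excluded:
            continue
        overlaps[(i, i + 1)] = float(np.minimum(probs[i], probs[i + 1]).sum())
    return HistogramSet(edges=edges, probabilities=probs, overlaps=overlaps, excluded=excluded)
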