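"""Scaled-Hamiltonian ladders: hot-spot parameter scaling and acceptance tuning.

Rung ``k`` multiplies the charge, ``sqrt_c6`` and ``sqrt_c12`` of every
particle belonging to a hot-spot residue by a factor ``f_k <= 1``.  Because
pair coefficients combine geometrically, a hotspot-hotspot pair energy at a
fixed configuration scales exactly by ``f**2`` and a hotspot-background
pair by ``f``.  Factors are spaced geometrically from 1 down to ``f_min``;
``tune_ladder`` adjusts ``f_min`` by bisection on the mean neighbour
acceptance measured in short trial exchange runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .energy_decomposition import HotspotSet
from .toy_system import ParameterSet, ToySystem

__all__ = [
    "HamiltonianLadder",
    "scale_system",
    "build_ladder",
    "tune_ladder",
]


@dataclass
class HamiltonianLadder:
    """Strictly decreasing scaling factors and the parameter sets they induce."""

    factors: tuple[float, ...]
    hotspot_ids: tuple[int, ...]
    scaled_params: list[ParameterSet]
    tuning_history: list[dict] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("ladder needs at least one factor")
        if self.factors[0] != 1.0:
            raise ValueError(f"first factor must be exactly 1.0, got {self.factors[0]}")
        for a, b in zip(self.factors, self.factors[1:]):
            if not b < a:
                raise ValueError(f"factors must be strictly decreasing, got {self.factors}")
        if not all(0 < f <= 1 for f in self.factors):
            raise ValueError(f"factors must lie in (0, 1], got {self.factors}")
        if len(self.scaled_params) != len(self.factors):
            raise ValueError("one parameter set per factor is required")

    @property
    def n_replicas(self) -> int:
        return len(self.factors)


def _hotspot_ids(hotspots: HotspotSet | Iterable[int]) -> tuple[int, ...]:
    if isinstance(hotspots, HotspotSet):
        return tuple(hotspots.residue_ids)
    return tuple(sorted(set(int(h) for h in hotspots)))


def scale_system(
    system: ToySystem, hotspots: HotspotSet | Iterable[int], f: float
) -> ParameterSet:
    """Multiply charge, sqrt_c6 and sqrt_c12 of hot-spot particles by ``f``.

    All other particles, and all bonded terms, are untouched.
    """
    if not 0 < f <= 1:
        raise ValueError(f"scaling factor must be in (0, 1], got {f}")
    ids = _hotspot_ids(hotspots)
    params = system.native_params.copy()
    mask = np.isin(system.residue_ids, ids)
    params.charge[mask] *= f
    params.sqrt_c6[mask] *= f
    params.sqrt_c12[mask] *= f
    return params


def _ladder_from_factors(
    system: ToySystem, ids: tuple[int, ...], factors: tuple[float, ...]
) -> HamiltonianLadder:
    params = [scale_system(system, ids, f) for f in factors]
    return HamiltonianLadder(factors=factors, hotspot_ids=ids, scaled_params=params)


def build_ladder(
    system: ToySystem,
    hotspots: HotspotSet | Iterable[int],
    n_replicas: int,
    f_min: float,
) -> HamiltonianLadder:
    """Geometric factor progression from 1 down to ``f_min``.

    Replica 0 always carries the unmodified Hamiltonian.
    """
    if n_replicas < 1:
        raise ValueError(f"n_replicas must be >= 1, got {n_replicas}")
    if not 0 < f_min <= 1:
        raise ValueError(f"f_min must be in (0, 1], got {f_min}")
    ids = _hotspot_ids(hotspots)
    if n_replicas == 1:
        if f_min < 1:
            warnings.warn("single replica: f_min ignored, ladder is (1.0,)", stacklevel=2)
        factors = (1.0,)
    else:
        if f_min == 1.0:
            raise ValueError("f_min must be < 1 for more than one replica")
        exponents = np.arange(n_replicas) / (n_replicas - 1)
        factors = tuple(float(f_min**e) for e in exponents)
        factors = (1.0,) + factors[1:]  # force exact unity on rung 0
    params = [scale_system(system, ids, f) for f in factors]
    return HamiltonianLadder(factors=factors, hotspot_ids=ids, scaled_params=params)


def tune_ladder(
    system: ToySystem,
    hotspots: HotspotSet | Iterable[int],
    n_replicas: int,
    f_min_init: float = 0.5,
    target_acceptance: float = 0.2,
    trial_steps: int = 800,
    seed: int = 0,
    *,
    steps_per_sweep: int = 10,
    step_size: float = 0.03,
    tolerance: float = 0.03,
    max_rounds: int = 14,
    equalize_rounds: int = 0,
) -> HamiltonianLadder:
    """Bisect ``f_min`` until trial-run mean neighbour acceptance hits the target.

    Each round builds a geometric ladder, runs a short exchange trial of
    ``trial_steps`` sweeps, and measures the mean neighbour acceptance over
    the final two thirds of the trial (the first third equilibrates the
    scaled rungs).  Acceptance increases monotonically (in expectation) with
    ``f_min``; the search brackets the target, then bisects in
    ``log f_min``.  If the band ``target +/- tolerance`` is not reached
    within ``max_rounds`` trials the closest ladder is returned with
    ``converged=False``.  Deterministic for a fixed seed.

    With ``equalize_rounds > 0`` the geometric result is refined by
    per-pair spacing adjustment (the exact factor values are tuned, not
    just the endpoint): each round measures per-pair acceptances and
    rescales every ``ln f`` interval toward the spacing that would put that
    pair at the target, keeping the factors strictly decreasing.
    """
    from .remd_controller import run_hremd  # local import: avoids a module cycle

    if not 0 < target_acceptance < 1:
        raise ValueError(f"target_acceptance must be in (0, 1), got {target_acceptance}")
    if n_replicas < 2:
        raise ValueError("tuning needs at least two replicas")
    ids = _hotspot_ids(hotspots)
    seq = np.random.SeedSequence(seed)
    trial_seeds = [
        int(s.generate_state(1)[0]) for s in seq.spawn(max_rounds + equalize_rounds)
    ]
    history: list[dict] = []

    def measure_ladder(
        ladder: HamiltonianLadder, round_idx: int, initial=None
    ) -> dict:
        result = run_hremd(
            system,
            ladder,
            n_sweeps=trial_steps,
            steps_per_sweep=steps_per_sweep,
            seed=trial_seeds[round_idx],
            step_size=step_size,
            frame_interval=max(1, trial_steps // 10),
            initial=initial,
        )
        skip = trial_steps // 3
        per_pair: dict[tuple[int, int], list[int]] = {}
        for rec in result.log.records:
            if rec.sweep > skip:
                per_pair.setdefault(rec.pair, []).append(int(rec.accepted))
        fractions = {pair: float(np.mean(v)) for pair, v in per_pair.items()}
        return {
            "mean": float(np.mean(list(fractions.values()))),
            "per_pair": fractions,
            "result": result,
        }

    def measure(f_min: float, round_idx: int) -> float:
        ladder = build_ladder(system, ids, n_replicas, f_min)
        acc = measure_ladder(ladder, round_idx)["mean"]
        history.append({"round": round_idx, "f_min": f_min, "acceptance": acc})
        return acc

    f_lo = None  # acceptance below target (smaller f_min)
    f_hi = None  # acceptance above target
    f_cur = float(f_min_init)
    best: tuple[float, float] | None = None  # (|acc-target|, f_min)
    converged = False
    for round_idx in range(max_rounds):
        acc = measure(f_cur, round_idx)
        gap = abs(acc - target_acceptance)
        if best is None or gap < best[0]:
            best = (gap, f_cur)
        if gap <= tolerance:
            converged = True
            break
        if acc > target_acceptance:
            f_hi = f_cur
        else:
            f_lo = f_cur
        if f_hi is None:
            # acceptance too low everywhere tried: raise f_min toward 1
            f_cur = math.sqrt(f_lo)
            if f_cur > 0.999:
                f_cur = 0.999
                if f_lo >= 0.999:
                    break
        elif f_lo is None:
            # acceptance too high: push f_min down (floored; at very small
            # f_min acceptance is no longer monotone, so searching further
            # down cannot help)
            f_cur = f_hi * f_hi
            if f_cur < 0.02:
                break
        else:
            f_cur = math.exp(0.5 * (math.log(f_lo) + math.log(f_hi)))

    assert best is not None
    ladder = build_ladder(system, ids, n_replicas, best[1])

    if equalize_rounds and n_replicas > 1:
        # refine the individual factor values: shrink intervals whose pair
        # is harder than the target, widen easier ones (damped, in ln f)
        log_target = -math.log(target_acceptance)
        gaps = -np.diff(np.log(ladder.factors))
        best_eq: tuple[float, HamiltonianLadder] | None = None
        for eq_round in range(equalize_rounds):
            stats = measure_ladder(ladder, max_rounds + eq_round)
            accs = np.array(
                [
                    np.clip(stats["per_pair"].get((h, h + 1), 1.0), 1e-3, 0.999)
                    for h in range(n_replicas - 1)
                ]
            )
            history.append(
                {
                    "round": max_rounds + eq_round,
                    "factors": [float(f) for f in ladder.factors],
                    "acceptance": stats["mean"],
                    "per_pair": {f"{h}-{h+1}": float(a) for h, a in enumerate(accs)},
                }
            )
            gap_measure = abs(stats["mean"] - target_acceptance) + float(
                np.max(np.abs(accs - target_acceptance))
            )
            if best_eq is None or gap_measure < best_eq[0]:
                best_eq = (gap_measure, ladder)
            if abs(stats["mean"] - target_acceptance) <= tolerance and np.all(
                np.abs(accs - target_acceptance) <= 2 * tolerance + 0.05
            ):
                converged = True
                break
            difficulty = -np.log(accs)
            gaps = np.clip(gaps * (log_target / difficulty) ** 0.6, 1e-4, 3.0)
            factors = np.exp(-np.concatenate([[0.0], np.cumsum(gaps)]))
            factors[0] = 1.0
            ladder = _ladder_from_factors(system, ids, tuple(float(f) for f in factors))
        if not converged and best_eq is not None:
            ladder = best_eq[1]

    ladder.tuning_history = history
    ladder.converged = converged
    if not converged:
        warnings.warn(
            f"ladder tuning did not reach {target_acceptance}+/-{tolerance} in "
            f"{max_rounds} rounds; returning closest ladder (f_min={best[1]:.4f})",
            stacklevel=2,
        )
    return ladder
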