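"""Replica-exchange orchestration and Metropolis exchange criteria.

Replicas run independent Metropolis MC under their current Hamiltonian; at
the end of every sweep, neighbouring ladder rungs attempt a swap.  For
Hamiltonian exchange at a single temperature the criterion is

    delta = beta * [(E_i(r_j) - E_i(r_i)) - (E_j(r_j) - E_j(r_i))]
    w     = min(1, exp(-delta))

and for temperature exchange ``delta = (beta_i - beta_j) * (E(r_j) - E(r_i))``.
Swaps exchange Hamiltonian assignments between replicas; the log records
both the replica view (occupancy trace) and the rung view (demultiplexed
trajectories).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .constants import BOLTZMANN
from .toy_system import (
    Conformation,
    MetropolisWalker,
    ToySystem,
    Trajectory,
    _full_energy,
)

if TYPE_CHECKING:  # pragma: no cover
    from .hamiltonian_scaling import HamiltonianLadder

__all__ = [
    "ReplicaState",
    "ExchangeRecord",
    "ExchangeLog",
    "AcceptanceSummary",
    "HREMDResult",
    "metropolis_weight",
    "hamiltonian_delta",
    "temperature_delta",
    "run_hremd",
    "acceptance_summary",
    "rung_ordered_conformations",
]


def metropolis_weight(delta: float) -> float:
    """Exchange probability ``min(1, exp(-delta))``."""
    if math.isnan(delta):
        raise ValueError("delta must not be NaN")
    if delta <= 0:
        return 1.0
    return math.exp(-delta)


def hamiltonian_delta(
    e_i_ri: float, e_i_rj: float, e_j_ri: float, e_j_rj: float, beta: float
) -> float:
    """Dimensionless exchange argument for two Hamiltonians at one temperature."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    for e in (e_i_ri, e_i_rj, e_j_ri, e_j_rj):
        if not math.isfinite(e):
            raise ValueError("all energies must be finite")
    return beta * ((e_i_rj - e_i_ri) - (e_j_rj - e_j_ri))


def temperature_delta(e_ri: float, e_rj: float, beta_i: float, beta_j: float) -> float:
    """Dimensionless exchange argument for two temperatures, one Hamiltonian."""
    if beta_i <= 0 or beta_j <= 0:
        raise ValueError("betas must be positive")
    return (beta_i - beta_j) * (e_rj - e_ri)


@dataclass
class ReplicaState:
    """Final state of one replica after a run."""

    replica_index: int
    current_hamiltonian_index: int
    conformation: Conformation
    potential_energy: float


@dataclass(frozen=True)
class ExchangeRecord:
    sweep: int
    pair: tuple[int, int]  # (rung h, rung h+1)
    delta: float
    accepted: bool


@dataclass
class ExchangeLog:
    """Raw swap records plus per-pair tallies and the occupancy trace."""

    n_replicas: int
    records: list[ExchangeRecord] = field(default_factory=list)
    attempts: dict[tuple[int, int], int] = field(default_factory=dict)
    accepts: dict[tuple[int, int], int] = field(default_factory=dict)
    #: occupancy[s, r] = Hamiltonian index held by replica r after sweep s
    occupancy: np.ndarray | None = None

    def record(self, sweep: int, pair: tuple[int, int], delta: float, accepted: bool) -> None:
        if not math.isfinite(delta):
            raise ValueError("delta must be finite")
        self.records.append(ExchangeRecord(sweep, pair, delta, accepted))
        self.attempts[pair] = self.attempts.get(pair, 0) + 1
        if accepted:
            self.accepts[pair] = self.accepts.get(pair, 0) + 1


@dataclass
class AcceptanceSummary:
    """Accepted/attempted fraction per neighbour pair; None when unattempted."""

    per_pair: dict[tuple[int, int], float | None]
    mean: float


def acceptance_summary(log: ExchangeLog) -> AcceptanceSummary:
    """Per-pair acceptance fractions and their mean over attempted pairs."""
    if not log.records:
        raise ValueError("exchange log is empty")
    per_pair: dict[tuple[int, int], float | None] = {}
    for h in range(log.n_replicas - 1):
        pair = (h, h + 1)
        att = log.attempts.get(pair, 0)
        per_pair[pair] = (log.accepts.get(pair, 0) / att) if att else None
    defined = [v for v in per_pair.values() if v is not None]
    mean = float(np.mean(defined)) if defined else float("nan")
    return AcceptanceSummary(per_pair=per_pair, mean=mean)


@dataclass
class HREMDResult:
    """Demultiplexed per-rung trajectories, the exchange log, and energy traces."""

    trajectories: list[Trajectory]
    log: ExchangeLog
    #: energies[t, h] = potential energy of the configuration at rung h
    #: (under Hamiltonian h) at stored frame t
    energies: np.ndarray
    final_states: list[ReplicaState]

    def __iter__(self):
        # allows ``trajectories, log = run_hremd(...)``
        return iter((self.trajectories, self.log))


def rung_ordered_conformations(result: "HREMDResult") -> list[Conformation]:
    """Final conformations ordered by Hamiltonian rung.

    Suitable as ``initial`` for a follow-up :func:`run_hremd` call, so a
    production run can continue from an equilibrated exchange run.
    """
    ordered = sorted(result.final_states, key=lambda s: s.current_hamiltonian_index)
    return [s.conformation for s in ordered]


def run_hremd(
    system: ToySystem,
    ladder: "HamiltonianLadder",
    n_sweeps: int,
    steps_per_sweep: int,
    seed: int,
    *,
    step_size: float = 0.03,
    frame_interval: int = 1,
    initial: Sequence[Conformation] | None = None,
) -> HREMDResult:
    """Hamiltonian replica exchange with even/odd alternating neighbour swaps.

    Each sweep advances every replica by ``steps_per_sweep`` MC moves and
    then attempts swaps on even rung pairs (0-1, 2-3, ...) or odd rung pairs
    (1-2, 3-4, ...), alternating sweep by sweep.  Cross energies are
    recomputed exactly at swap time.  One RNG stream per replica plus one
    for swap decisions are derived from the master seed, so results are
    reproducible and independent of scheduling.
    """
    if n_sweeps < 1:
        raise ValueError(f"n_sweeps must be >= 1, got {n_sweeps}")
    params_sets = ladder.scaled_params
    n_rep = len(params_sets)
    if any(len(p) != system.n_particles for p in params_sets):
        raise ValueError("ladder parameter sets do not match the system size")
    if initial is not None and len(initial) != n_rep:
        raise ValueError("one initial conformation per replica is required")

    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_rep + 1)
    replica_rngs = [np.random.default_rng(s) for s in children[:n_rep]]
    swap_rng = np.random.default_rng(children[n_rep])
    beta = 1.0 / (BOLTZMANN * system.temperature)

    walkers = [
        MetropolisWalker(
            system,
            params_sets[r],
            initial[r].coords if initial is not None else None,
            step_size=step_size,
        )
        for r in range(n_rep)
    ]
    replica_of_ham = np.arange(n_rep)
    ham_of_replica = np.arange(n_rep)

    log = ExchangeLog(n_replicas=n_rep)
    occupancy = np.empty((n_sweeps + 1, n_rep), dtype=int)
    occupancy[0] = ham_of_replica

    frames_per_rung: list[list[Conformation]] = [[] for _ in range(n_rep)]
    energy_rows: list[list[float]] = []

    def store() -> None:
        row = []
        for h in range(n_rep):
            w = walkers[replica_of_ham[h]]
            frames_per_rung[h].append(Conformation(w.coords.copy()))
            row.append(w.total_energy())
        energy_rows.append(row)

    store()
    for sweep in range(1, n_sweeps + 1):
        for r in range(n_rep):
            walkers[r].advance(steps_per_sweep, replica_rngs[r])
        start = 0 if (sweep - 1) % 2 == 0 else 1
        for h in range(start, n_rep - 1, 2):
            ra = int(replica_of_ham[h])
            rb = int(replica_of_ham[h + 1])
            wa, wb = walkers[ra], walkers[rb]
            e_i_ri = _full_energy(system, wa.coords, params_sets[h])
            e_j_rj = _full_energy(system, wb.coords, params_sets[h + 1])
            e_i_rj = _full_energy(system, wb.coords, params_sets[h])
            e_j_ri = _full_energy(system, wa.coords, params_sets[h + 1])
            delta = hamiltonian_delta(e_i_ri, e_i_rj, e_j_ri, e_j_rj, beta)
            accepted = swap_rng.random() < metropolis_weight(delta)
            log.record(sweep, (h, h + 1), delta, accepted)
            if accepted:
                replica_of_ham[h], replica_of_ham[h + 1] = rb, ra
                ham_of_replica[ra], ham_of_replica[rb] = h + 1, h
                wa.set_parameters(params_sets[h + 1])
                wb.set_parameters(params_sets[h])
        occupancy[sweep] = ham_of_replica
        if sweep % frame_interval == 0:
            store()
    log.occupancy = occupancy

    trajectories = [
        Trajectory(frames, frame_interval=frame_interval * steps_per_sweep)
        for frames in frames_per_rung
    ]
    final_states = [
        ReplicaState(
            replica_index=r,
            current_hamiltonian_index=int(ham_of_replica[r]),
            conformation=Conformation(walkers[r].coords.copy()),
            potential_energy=walkers[r].total_energy(),
        )
        for r in range(n_rep)
    ]
    return HREMDResult(
        trajectories=trajectories,
        log=log,
        energies=np.asarray(energy_rows),
        final_states=final_states,
    )
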