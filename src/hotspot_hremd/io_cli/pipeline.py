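"""End-to-end pipeline: fixture -> decomposition -> ladder -> exchange -> analysis.

Every stage writes its artifacts under the configured output directory and
contributes to a JSON manifest that contains everything needed to reproduce
the run (settings, seeds, hot spots, ladder factors, acceptance summary).
The manifest deliberately excludes wall-clock information so that two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .. import __version__
from ..analysis import (
    classify_folded,
    cluster_conformations,
    energy_histograms,
    free_energy_landscape,
    rgyr_trace,
    rmsd_trace,
)
from ..energy_decomposition import build_matrix, decompose, select_hotspots
from ..hamiltonian_scaling import build_ladder, tune_ladder
from ..remd_controller import acceptance_summary, run_hremd
from ..toy_system import Conformation, generate_fixture, sample
from .config import RunConfig
from .formats import load_system, save_system, write_coordinates, write_topology

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("hotspot_hremd.pipeline")


class PipelineError(RuntimeError):
    """Failure wrapper naming the stage that aborted the pipeline."""

    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _seed_for(master: int, stage: str) -> int:
    offsets = {"native": 1, "tune": 2, "exchange": 3}
    return int(master * 10_007 + offsets[stage])


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns (and writes) the manifest dict."""
    out = Path(config.output_directory)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "system"
    try:
        if config.system_kind == "fixture":
            system = generate_fixture(
                config.n_residues,
                config.hotspots,
                config.strength,
                config.seed,
                temperature=config.temperature,
                beads_per_residue=config.beads_per_residue,
                background_scale=config.background_scale,
            )
        else:
            system = load_system(config.system_directory)
        save_system(system, out / "system")
        manifest["stages"]["system"] = {
            "kind": config.system_kind,
            "n_particles": system.n_particles,
            "n_residues": system.residue_count,
        }
        logger.info("stage system: %d particles", system.n_particles)

        stage = "native_sampling"
        native_traj = sample(
            system,
            n_steps=config.native_steps,
            seed=_seed_for(config.seed, "native"),
            step_size=config.step_size,
            frame_interval=config.native_frame_interval,
        )
        write_coordinates(native_traj, out / "native_sampling.pdb", system=system)
        manifest["stages"]["native_sampling"] = {
            "n_frames": len(native_traj),
            "seed": _seed_for(config.seed, "native"),
        }

        stage = "decomposition"
        matrix = build_matrix(native_traj, system, skip_frames=config.skip_frames)
        spectrum = decompose(matrix)
        hotspots = select_hotspots(spectrum)
        np.savetxt(out / "interaction_matrix.csv", matrix.matrix, delimiter=",")
        pd.DataFrame(
            {
                "residue_id": spectrum.residue_labels,
                "first_eigenvector": spectrum.eigenvectors[:, 0],
            }
        ).to_csv(out / "first_eigenvector.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "residue_id": sorted(hotspots.residue_ids),
                "component": [hotspots.components[r] for r in sorted(hotspots.residue_ids)],
            }
        ).to_csv(out / "hotspots.tsv", sep="\t", index=False)
        manifest["stages"]["decomposition"] = {
            "hotspots": list(hotspots.residue_ids),
            "threshold": hotspots.threshold,
            "n_frames_averaged": matrix.n_frames_averaged,
        }
        logger.info("stage decomposition: hot spots %s", hotspots.residue_ids)

        stage = "ladder"
        if config.n_replicas == 1:
            ladder = build_ladder(system, hotspots, 1, 1.0)
        elif config.tune:
            ladder = tune_ladder(
                system,
                hotspots,
                config.n_replicas,
                target_acceptance=config.target_acceptance,
                trial_steps=config.trial_sweeps,
                seed=_seed_for(config.seed, "tune"),
                steps_per_sweep=config.steps_per_sweep,
                step_size=config.step_size,
            )
        else:
            ladder = build_ladder(system, hotspots, config.n_replicas, config.f_min)
        for k, params in enumerate(ladder.scaled_params):
            write_topology(system, out / f"ladder_rung_{k}.particles.tsv", params)
        with open(out / "ladder.json", "w") as fh:
            json.dump(
                {
                    "factors": list(ladder.factors),
                    "hotspot_ids": list(ladder.hotspot_ids),
                    "tuning_history": ladder.tuning_history,
                    "converged": ladder.converged,
                },
                fh,
                indent=2,
            )
        manifest["stages"]["ladder"] = {
            "factors": list(ladder.factors),
            "converged": ladder.converged,
            "seed": _seed_for(config.seed, "tune") if config.tune else None,
        }
        logger.info("stage ladder: factors %s", [round(f, 4) for f in ladder.factors])

        stage = "exchange"
        result = run_hremd(
            system,
            ladder,
            n_sweeps=config.sweeps,
            steps_per_sweep=config.steps_per_sweep,
            seed=_seed_for(config.seed, "exchange"),
            step_size=config.step_size,
            frame_interval=config.exchange_frame_interval,
        )
        pd.DataFrame(
            [
                {
                    "sweep": r.sweep,
                    "pair_lo": r.pair[0],
                    "pair_hi": r.pair[1],
                    "delta": r.delta,
                    "accepted": int(r.accepted),
                }
                for r in result.log.records
            ]
        ).to_csv(out / "exchange_log.tsv", sep="\t", index=False)
        np.savetxt(out / "occupancy.tsv", result.log.occupancy, fmt="%d", delimiter="\t")
        for h, traj in enumerate(result.trajectories):
            write_coordinates(traj, out / f"rung_{h}.pdb", system=system)
        summary = (
            acceptance_summary(result.log) if result.log.records else None
        )
        manifest["stages"]["exchange"] = {
            "sweeps": config.sweeps,
            "seed": _seed_for(config.seed, "exchange"),
            "mean_acceptance": summary.mean if summary else None,
            "per_pair_acceptance": {
                f"{a}-{b}": v for (a, b), v in summary.per_pair.items()
            }
            if summary
            else {},
        }

        stage = "analysis"
        reference = Conformation(system.native_coords)
        traj0 = result.trajectories[0]
        r_trace = rmsd_trace(traj0, reference)
        g_trace = rgyr_trace(traj0)
        pd.DataFrame(
            {
                "frame": np.arange(len(traj0)),
                "rmsd_nm": r_trace,
                "rgyr_nm": g_trace,
                "folded": [int(classify_folded(v)) for v in r_trace],
            }
        ).to_csv(out / "observables.tsv", sep="\t", index=False)
        fel = free_energy_landscape(
            traj0, reference, system.temperature, bins=config.fel_bins
        )
        np.savetxt(out / "fel.csv", fel.free_energy, delimiter=",")
        clusters = cluster_conformations(traj0, cutoff=config.cluster_cutoff)
        pd.DataFrame(
            {
                "cluster": np.arange(clusters.n_clusters),
                "representative_frame": clusters.representatives,
                "population": clusters.populations,
            }
        ).to_csv(out / "clusters.tsv", sep="\t", index=False)
        hist_summary = None
        if result.energies.shape[1] >= 2:
            hists = energy_histograms(
                [result.energies[:, h] for h in range(result.energies.shape[1])],
                n_bins=config.histogram_bins,
            )
            pd.DataFrame(
                hists.probabilities.T,
                columns=[f"rung_{h}" for h in range(result.energies.shape[1])],
            ).to_csv(out / "energy_histograms.tsv", sep="\t", index=False)
            hist_summary = {f"{a}-{b}": v for (a, b), v in hists.overlaps.items()}
        manifest["stages"]["analysis"] = {
            "n_clusters": clusters.n_clusters,
            "folded_fraction": float(np.mean(r_trace < 0.2)),
            "histogram_overlaps": hist_summary,
        }
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
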