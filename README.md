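# hotspot-hremd

Energy-decomposition-guided Hamiltonian replica exchange, at desk scale.

The package implements, end to end on a built-in bead-chain model:

1. **Energy decomposition** — average the residue-residue non-bonded
   interaction-energy matrix over a native-state trajectory, diagonalize it
   (`M_ij = Σ_k λ_k w_i^k w_j^k`, eigenvalues ascending so λ₁ is the most
   negative), and select fold-stabilizing **hot spots**: residues whose
   first-eigenvector component magnitude exceeds the flat-vector threshold
   `1/√N`.
2. **Hamiltonian scaling** — build a ladder of modified parameter sets by
   multiplying the charges and the √C6/√C12 Lennard-Jones terms of hot-spot
   particles by replica-specific factors `f ≤ 1`, spaced geometrically and
   optionally tuned to a target exchange acceptance (~20 %).
3. **Replica exchange** — run parallel Metropolis MC replicas across the
   ladder, attempting neighbour swaps with
   `Δ = β[(E_i(r_j) − E_i(r_i)) − (E_j(r_j) − E_j(r_i))]`,
   `w = min(1, e^{−Δ})`, logging per-pair acceptance and occupancy, and
   demultiplexing per-rung trajectories.
4. **Analysis** — superposed RMSD and 0.2 nm folded/unfolded classification,
   radius of gyration, 2-D free-energy landscapes over (RMSD, Rgyr),
   GROMOS-style neighbour-counting clustering, and per-rung potential-energy
   histograms with neighbour overlap coefficients. All analyses read the
   unscaled (f = 1) ensemble.

Units: nm, kJ/mol, elementary charge, Kelvin (k_B = 0.0083144621 kJ/mol/K).

## CLI

```bash
# generate a planted-hot-spot fixture (topology TSVs + native XYZ bundle)
hotspot-hremd generate --n-residues 20 --hotspots 2,6,10,14,18 \
    --strength 5 --seed 42 --out sys/

# detect hot spots from a trajectory
hotspot-hremd decompose --traj traj.pdb --topology sys/particles.tsv \
    --bonds sys/bonds.tsv --out-prefix dec

# build or tune a scaling ladder
hotspot-hremd ladder tune --system-dir sys/ --hotspots 2,6,10,14,18 \
    --replicas 6 --target-acc 0.2 --seed 1 --out ladder.json

# full pipeline from a TOML config (see src/hotspot_hremd/io_cli/config.py
# for the schema); `run` and `pipeline` are aliases
hotspot-hremd run --config run.toml --seed 5 --out results/

# observables
hotspot-hremd analyze rmsd --traj rung_0.pdb --ref sys/native.xyz --out rmsd.tsv
hotspot-hremd analyze fel --traj rung_0.pdb --ref sys/native.xyz --out fel.csv
```

Minimal `run.toml`:

```toml
seed = 5

[system]
kind = "fixture"
n_residues = 20
hotspots = [2, 6, 10, 14, 18]
strength = 5.0

[ladder]
n_replicas = 6
tune = true
target_acceptance = 0.2

[exchange]
sweeps = 2000
frame_interval = 10
```

## Layout

```
src/hotspot_hremd/
  toy_system.py            bead-chain model, MC sampler, fixture generators
  energy_decomposition.py  interaction matrix, spectrum, hot-spot selection
  hamiltonian_scaling.py   parameter scaling, ladder construction & tuning
  remd_controller.py       exchange criteria, H-REMD orchestration, logs
  analysis.py              RMSD/Rgyr/FEL/clustering/histogram overlap
  io_cli/                  TSV/PDB/XYZ formats, TOML config, pipeline, CLI
```

The controller is sampler-agnostic at the interface level: replicas expose
advance/energy/parameter-swap operations, so an external MD backend could be
slotted in behind the same exchange logic (not implemented here).
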