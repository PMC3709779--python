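"""TOML run configuration for the end-to-end pipeline.

Schema (all sections optional unless noted)::

    seed = 1                      # master seed, required

    [system]                      # required
    kind = "fixture"              # or "files"
    n_residues = 20               # fixture
    hotspots = [2, 6, 10, 14, 18] # fixture: planted residues
    strength = 5.0                # fixture
    temperature = 300.0
    beads_per_residue = 1
    background_scale = 1.0
    directory = "sys/"            # files: save_system() bundle

    [decomposition]
    native_steps = 4000           # MC moves of the preliminary native run
    frame_interval = 20
    skip_frames = -1              # -1: default (first quarter)

    [ladder]
    n_replicas = 6
    f_min = 0.3                   # used when tune = false
    tune = true
    target_acceptance = 0.2
    trial_sweeps = 800

    [sampler]
    step_size = 0.03
    steps_per_sweep = 10

    [exchange]
    sweeps = 2000
    frame_interval = 10

    [analysis]
    fel_bins = 32
    cluster_cutoff = 0.1
    histogram_bins = 50

    [output]
    directory = "out"
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int
    system_kind: str = "fixture"
    n_residues: int = 20
    hotspots: tuple[int, ...] = (2, 6, 10, 14, 18)
    strength: float = 5.0
    temperature: float = 300.0
    beads_per_residue: int = 1
    background_scale: float = 1.0
    system_directory: str | None = None

    native_steps: int = 4000
    native_frame_interval: int = 20
    skip_frames: int | None = None

    n_replicas: int = 6
    f_min: float = 0.3
    tune: bool = True
    target_acceptance: float = 0.2
    trial_sweeps: int = 800

    step_size: float = 0.03
    steps_per_sweep: int = 10

    sweeps: int = 2000
    exchange_frame_interval: int = 10

    fel_bins: int = 32
    cluster_cutoff: float = 0.1
    histogram_bins: int = 50

    output_directory: str = "out"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        if self.system_kind not in ("fixture", "files"):
            raise ValueError(f"system.kind must be 'fixture' or 'files', got {self.system_kind!r}")
        if self.system_kind == "files":
            if self.system_directory is None:
                raise ValueError("system.kind='files' requires system.directory")
            if not Path(self.system_directory).is_dir():
                raise ValueError(f"system directory not found: {self.system_directory}")
        if self.n_replicas < 1:
            raise ValueError("ladder.n_replicas must be >= 1")
        if not 0 < self.f_min <= 1:
            raise ValueError("ladder.f_min must be in (0, 1]")
        if not 0 < self.target_acceptance < 1:
            raise ValueError("ladder.target_acceptance must be in (0, 1)")
        for name in ("native_steps", "sweeps", "steps_per_sweep", "trial_sweeps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["hotspots"] = list(self.hotspots)
        return d


def load_config(path: Path | str, **overrides) -> RunConfig:
    """Load a TOML config; keyword overrides win over file values."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    def sec(name: str) -> dict:
        return raw.get(name, {}) or {}

    values: dict = {}
    if "seed" not in raw:
        raise ValueError(f"{path}: top-level 'seed' is required")
    values["seed"] = raw["seed"]
    system = sec("system")
    values["system_kind"] = system.get("kind", "fixture")
    for key, dest in (
        ("n_residues", "n_residues"),
        ("hotspots", "hotspots"),
        ("strength", "strength"),
        ("temperature", "temperature"),
        ("beads_per_residue", "beads_per_residue"),
        ("background_scale", "background_scale"),
        ("directory", "system_directory"),
    ):
        if key in system:
            values[dest] = system[key]
    dec = sec("decomposition")
    if "native_steps" in dec:
        values["native_steps"] = dec["native_steps"]
    if "frame_interval" in dec:
        values["native_frame_interval"] = dec["frame_interval"]
    if "skip_frames" in dec and dec["skip_frames"] >= 0:
        values["skip_frames"] = dec["skip_frames"]
    ladder = sec("ladder")
    for key in ("n_replicas", "f_min", "tune", "target_acceptance", "trial_sweeps"):
        if key in ladder:
            values[key] = ladder[key]
    sampler = sec("sampler")
    for key in ("step_size", "steps_per_sweep"):
        if key in sampler:
            values[key] = sampler[key]
    exchange = sec("exchange")
    if "sweeps" in exchange:
        values["sweeps"] = exchange["sweeps"]
    if "frame_interval" in exchange:
        values["exchange_frame_interval"] = exchange["frame_interval"]
    analysis = sec("analysis")
    for key in ("fel_bins", "cluster_cutoff", "histogram_bins"):
        if key in analysis:
            values[key] = analysis[key]
    output = sec("output")
    if "directory" in output:
        values["output_directory"] = output["directory"]

    values.update(overrides)
    if "hotspots" in values:
        values["hotspots"] = tuple(int(h) for h in values["hotspots"])
    return RunConfig(**values)
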