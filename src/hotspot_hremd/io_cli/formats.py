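"""Readers and writers: topology TSV, bond TSV, PDB and XYZ coordinates.

Topology dialect: tab-separated with a header line
``index  residue_id  charge  sqrt_c6  sqrt_c12``; bonds use
``i  j  r0  k``.  Coordinates travel as single- or multi-model PDB (via
biotite; 0.001 A precision) or as plain XYZ in nm at full float precision.
``save_system``/``load_system`` bundle the three files plus a small JSON
sidecar for exact round trips.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from ..toy_system import Bond, Conformation, Particle, ToySystem, Trajectory

__all__ = [
    "TopologyParseError",
    "read_topology",
    "write_topology",
    "read_bonds",
    "write_bonds",
    "read_coordinates",
    "write_coordinates",
    "save_system",
    "load_system",
]

_PARTICLE_COLUMNS = ("index", "residue_id", "charge", "sqrt_c6", "sqrt_c12")
_BOND_COLUMNS = ("i", "j", "r0", "k")


class TopologyParseError(ValueError):
    """Raised with a file name and 1-based line number on malformed input."""

    def __init__(self, path: Path | str, line: int, message: str) -> None:
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def _parse_table(path: Path | str, columns: tuple[str, ...]) -> list[tuple[int, list[str]]]:
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TopologyParseError(path, 1, "empty file")
    header = lines[0].split("\t")
    if header != list(columns):
        raise TopologyParseError(
            path, 1, f"expected header {list(columns)}, got {header}"
        )
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(columns):
            raise TopologyParseError(
                path, lineno, f"expected {len(columns)} fields, got {len(fields)}"
            )
        rows.append((lineno, fields))
    return rows


def write_topology(system: ToySystem, path: Path | str, params=None) -> None:
    """Write the particle table as TSV.

    ``params`` (a :class:`~hotspot_hremd.toy_system.ParameterSet`) overrides
    the native per-particle parameters, which is how scaled ladder rungs are
    exported in the same dialect.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(_PARTICLE_COLUMNS) + "\n")
        for p in system.particles:
            if params is None:
                charge, sqrt_c6, sqrt_c12 = p.charge, p.sqrt_c6, p.sqrt_c12
            else:
                charge = params.charge[p.index]
                sqrt_c6 = params.sqrt_c6[p.index]
                sqrt_c12 = params.sqrt_c12[p.index]
            fh.write(
                f"{p.index}\t{p.residue_id}\t{float(charge)!r}"
                f"\t{float(sqrt_c6)!r}\t{float(sqrt_c12)!r}\n"
            )


def read_particles(path: Path | str) -> list[Particle]:
    particles: list[Particle] = []
    seen: set[int] = set()
    for lineno, fields in _parse_table(path, _PARTICLE_COLUMNS):
        try:
            index = int(fields[0])
            residue_id = int(fields[1])
            charge, sqrt_c6, sqrt_c12 = (float(x) for x in fields[2:])
        except ValueError as exc:
            raise TopologyParseError(path, lineno, f"non-numeric field ({exc})") from None
        if index in seen:
            raise TopologyParseError(path, lineno, f"duplicate particle index {index}")
        seen.add(index)
        try:
            particles.append(Particle(index, residue_id, charge, sqrt_c6, sqrt_c12))
        except ValueError as exc:
            raise TopologyParseError(path, lineno, str(exc)) from None
    if not particles:
        raise TopologyParseError(path, 2, "no particles")
    particles.sort(key=lambda p: p.index)
    if [p.index for p in particles] != list(range(len(particles))):
        raise TopologyParseError(path, 2, "particle indices must be 0..n-1")
    return particles


def write_bonds(system: ToySystem, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_BOND_COLUMNS) + "\n")
        for b in system.bonds:
            fh.write(f"{b.i}\t{b.j}\t{b.r0!r}\t{b.k!r}\n")


def read_bonds(path: Path | str) -> list[Bond]:
    bonds: list[Bond] = []
    for lineno, fields in _parse_table(path, _BOND_COLUMNS):
        try:
            i, j = int(fields[0]), int(fields[1])
            r0, k = float(fields[2]), float(fields[3])
        except ValueError as exc:
            raise TopologyParseError(path, lineno, f"non-numeric field ({exc})") from None
        try:
            bonds.append(Bond(i, j, r0, k))
        except ValueError as exc:
            raise TopologyParseError(path, lineno, str(exc)) from None
    return bonds


def read_topology(
    particles_path: Path | str,
    bonds_path: Path | str | None = None,
    *,
    coords_path: Path | str | None = None,
    temperature: float = 300.0,
) -> ToySystem:
    """Assemble a :class:`ToySystem` from TSV tables (+ optional coordinates).

    Without ``coords_path`` the native geometry defaults to a straight chain
    at 0.38 nm spacing.
    """
    particles = read_particles(particles_path)
    bonds = read_bonds(bonds_path) if bonds_path is not None else []
    if coords_path is not None:
        native = read_coordinates(coords_path).frames[0].coords
    else:
        native = np.zeros((len(particles), 3))
        native[:, 0] = 0.38 * np.arange(len(particles))
    return ToySystem(
        particles=particles,
        bonds=bonds,
        native_coords=native,
        temperature=temperature,
        residue_count=max(p.residue_id for p in particles),
    )


# ---------------------------------------------------------------------------
# Coordinates
# ---------------------------------------------------------------------------


def _frames_of(obj: Trajectory | Conformation) -> list[Conformation]:
    if isinstance(obj, Trajectory):
        return obj.frames
    if isinstance(obj, Conformation):
        return [obj]
    return [Conformation(np.asarray(obj, dtype=float))]


def _write_xyz(frames: Sequence[Conformation], path: Path | str) -> None:
    with open(path, "w") as fh:
        for idx, fr in enumerate(frames):
            fh.write(f"{fr.n_particles}\n")
            fh.write(f"frame {idx} (coordinates in nm)\n")
            for x, y, z in fr.coords:
                fh.write(f"X {float(x)!r} {float(y)!r} {float(z)!r}\n")


def _read_xyz(path: Path | str) -> list[Conformation]:
    frames: list[Conformation] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise ValueError(
                f"{path}: expected an atom count at line {pos + 1} "
                f"(frame {len(frames)})"
            ) from None
        block = lines[pos + 2 : pos + 2 + natoms]
        if len(block) < natoms:
            raise ValueError(
                f"{path}: truncated frame {len(frames)} (model {len(frames) + 1}): "
                f"expected {natoms} atom lines, found {len(block)}"
            )
        coords = np.array(
            [[float(v) for v in line.split()[1:4]] for line in block]
        )
        frames.append(Conformation(coords))
        pos += 2 + natoms
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _write_pdb(
    frames: Sequence[Conformation], path: Path | str, system: ToySystem | None
) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = frames[0].n_particles
    coords = np.stack([fr.coords for fr in frames]) * 10.0  # nm -> Angstrom
    stack = struc.AtomArrayStack(len(frames), n)
    stack.coord = coords
    stack.chain_id = np.full(n, "A")
    if system is not None:
        stack.res_id = system.residue_ids
    else:
        stack.res_id = np.arange(1, n + 1)
    stack.res_name = np.full(n, "BEA")
    stack.atom_name = np.full(n, "CA")
    stack.element = np.full(n, "C")
    stack.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _read_pdb(path: Path | str) -> list[Conformation]:
    from biotite.structure.io.pdb import PDBFile

    try:
        stack = PDBFile.read(str(path)).get_structure()
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse PDB ({exc})") from exc
    coords = np.atleast_3d(stack.coord) / 10.0  # Angstrom -> nm
    if coords.ndim == 2:
        coords = coords[None]
    return [Conformation(c) for c in coords]


def write_coordinates(
    obj: Trajectory | Conformation,
    path: Path | str,
    *,
    system: ToySystem | None = None,
) -> None:
    """Write a conformation or trajectory as PDB (multi-model) or XYZ."""
    frames = _frames_of(obj)
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        _write_xyz(frames, path)
    elif suffix == ".pdb":
        _write_pdb(frames, path, system)
    else:
        raise ValueError(f"unsupported coordinate format: {suffix!r}")


def read_coordinates(path: Path | str) -> Trajectory:
    """Read PDB or XYZ coordinates into a trajectory (frame_interval=1)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".xyz":
        frames = _read_xyz(path)
    elif suffix == ".pdb":
        frames = _read_pdb(path)
    else:
        raise ValueError(f"unsupported coordinate format: {suffix!r}")
    return Trajectory(frames, frame_interval=1)


# ---------------------------------------------------------------------------
# Whole-system bundles
# ---------------------------------------------------------------------------


def save_system(system: ToySystem, directory: Path | str) -> dict[str, str]:
    """Write particles.tsv, bonds.tsv, native.xyz and system.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "particles": str(directory / "particles.tsv"),
        "bonds": str(directory / "bonds.tsv"),
        "native": str(directory / "native.xyz"),
        "meta": str(directory / "system.json"),
    }
    write_topology(system, paths["particles"])
    write_bonds(system, paths["bonds"])
    write_coordinates(Conformation(system.native_coords), paths["native"])
    with open(paths["meta"], "w") as fh:
        json.dump(
            {
                "temperature": system.temperature,
                "residue_count": system.residue_count,
            },
            fh,
            indent=2,
        )
    return paths


def load_system(directory: Path | str) -> ToySystem:
    directory = Path(directory)
    with open(directory / "system.json") as fh:
        meta = json.load(fh)
    system = read_topology(
        directory / "particles.tsv",
        directory / "bonds.tsv",
        coords_path=directory / "native.xyz",
        temperature=meta["temperature"],
    )
    if system.residue_count != meta["residue_count"]:
        raise ValueError(
            f"{directory}: residue_count mismatch between tables and system.json"
        )
    return system
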