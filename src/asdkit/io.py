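"""Readers and writers for the supported on-disk formats.

Three plain-text formats are supported:

* **GRO coordinate series** — standard fixed-column GROMACS GRO with multiple
  concatenated frames; the title line must contain ``t=`` followed by the
  frame time in ps.  Velocities, if present, are ignored.
* **Extended-XYZ dialect** — line 1: atom count; line 2: ``key=value`` pairs
  including ``Lattice`` (9 floats, row-major; only the diagonal is used) and
  ``Time`` (ps); then one ``element x y z`` line per atom, coordinates in nm.
* **Topology sidecar** — a tab-separated table, one row per atom, with a
  fixed header (see :data:`TOPOLOGY_COLUMNS`).  Atom order defines atom ids;
  indices in the file are 1-based.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .model import (
    Atom,
    Frame,
    Molecule,
    ParseError,
    StructuralError,
    Topology,
    TopologyError,
    Trajectory,
)

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "TOPOLOGY_COLUMNS",
]

FORMATS = ("gro_series", "extxyz")

TOPOLOGY_COLUMNS = (
    "molecule_id",
    "kind",
    "residue_label",
    "residue_index",
    "name",
    "element",
    "mass",
    "roles",
    "donor_of",
)


def read_trajectory(path, format: str, topology: Topology | None = None) -> Trajectory:
    """Read a trajectory file under the named dialect.

    Coordinates are returned in nm (both dialects store nm natively) and are
    wrapped into the box.  ``topology``, if given, is attached and its atom
    count checked against the frames.
    """
    path = Path(path)
    if format == "extxyz":
        frames, names = _read_extxyz(path)
    elif format == "gro_series":
        frames, names = _read_gro(path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}; expected one of {FORMATS}")
    traj = Trajectory(frames, topology=topology)
    traj.atom_names = names  # labels from the file, for writers without topology
    return traj


def write_trajectory(trajectory: Trajectory, path, format: str) -> None:
    """Write a trajectory under the named dialect (positions to 6 decimals
    for extxyz, GRO's fixed 3 decimals for gro_series)."""
    path = Path(path)
    names = _atom_labels(trajectory)
    if format == "extxyz":
        _write_extxyz(trajectory, path, names)
    elif format == "gro_series":
        _write_gro(trajectory, path, names)
    else:
        raise ValueError(f"unknown trajectory format {format!r}; expected one of {FORMATS}")


def _atom_labels(trajectory: Trajectory) -> list:
    if trajectory.topology is not None:
        return [a.element or a.name for a in trajectory.topology.atoms]
    names = getattr(trajectory, "atom_names", None)
    if names is not None:
        return list(names)
    return ["X"] * trajectory.frames[0].n_atoms


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\w+)=("([^"]*)"|\S+)')


def _read_extxyz(path: Path):
    frames = []
    names: list | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    frame_index = 0
    n_total = len(lines)
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        lineno = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: expected atom count for frame "
                f"{frame_index + 1}, got {lines[i].strip()!r}"
            )
        if i + 1 >= n_total:
            raise ParseError(f"{path}: line {lineno}: frame {frame_index + 1} missing comment line")
        header = lines[i + 1]
        kv = {m.group(1): (m.group(3) if m.group(3) is not None else m.group(2)) for m in _KV_RE.finditer(header)}
        if "Lattice" not in kv:
            raise ParseError(f"{path}: line {i + 2}: frame {frame_index + 1} header lacks Lattice")
        if "Time" not in kv:
            raise ParseError(f"{path}: line {i + 2}: frame {frame_index + 1} header lacks Time")
        lattice = np.fromstring(kv["Lattice"], sep=" ")
        if lattice.size != 9:
            raise ParseError(
                f"{path}: line {i + 2}: Lattice must have 9 floats, got {lattice.size}"
            )
        box = lattice.reshape(3, 3).diagonal().copy()
        time = float(kv["Time"])
        if i + 1 + n_atoms >= n_total:
            raise ParseError(
                f"{path}: frame {frame_index + 1} truncated: expected {n_atoms} atom "
                f"lines after line {i + 2}"
            )
        frame_names = []
        pos = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: malformed atom line in frame {frame_index + 1}"
                )
            frame_names.append(parts[0])
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: non-numeric coordinate in frame {frame_index + 1}"
                )
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise StructuralError(
                f"{path}: frame {frame_index + 1} has {len(frame_names)} atoms, expected {len(names)}"
            )
        frames.append(Frame(time=time, box=box, positions=pos))
        i += 2 + n_atoms
        frame_index += 1
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames, names


def _write_extxyz(trajectory: Trajectory, path: Path, names) -> None:
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            b = frame.box
            lattice = f"{b[0]:.6f} 0.0 0.0 0.0 {b[1]:.6f} 0.0 0.0 0.0 {b[2]:.6f}"
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f'Lattice="{lattice}" Time={frame.time:.4f} Properties=species:S:1:pos:R:3\n'
            )
            for name, p in zip(names, frame.positions):
                fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# GRO series
# ---------------------------------------------------------------------------

_GRO_TIME_RE = re.compile(r"t=\s*([-+0-9.eE]+)")


def _read_gro(path: Path):
    frames = []
    names: list | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    frame_index = 0
    n_total = len(lines)
    while i < n_total:
        if not lines[i].strip():
            i += 1
            continue
        frame_index += 1
        title = lines[i]
        m = _GRO_TIME_RE.search(title)
        if m is None:
            raise ParseError(
                f"{path}: line {i + 1}: frame {frame_index} title lacks 't=<time>'"
            )
        time = float(m.group(1))
        if i + 1 >= n_total:
            raise ParseError(f"{path}: frame {frame_index} truncated after title line")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError:
            raise ParseError(
                f"{path}: line {i + 2}: frame {frame_index}: expected atom count, "
                f"got {lines[i + 1].strip()!r}"
            )
        if i + 2 + n_atoms >= n_total:
            raise ParseError(
                f"{path}: frame {frame_index} truncated: expected {n_atoms} atom lines "
                f"plus a box line after line {i + 2}"
            )
        frame_names = []
        pos = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            line = lines[i + 2 + j]
            if len(line.rstrip("\n")) < 44:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: frame {frame_index}: atom line too short"
                )
            frame_names.append(line[10:15].strip())
            try:
                pos[j] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: frame {frame_index}: non-numeric coordinate"
                )
        box_parts = lines[i + 2 + n_atoms].split()
        if len(box_parts) < 3:
            raise ParseError(
                f"{path}: line {i + 3 + n_atoms}: frame {frame_index}: malformed box line"
            )
        box = np.array([float(x) for x in box_parts[:3]])
        if names is None:
            names = frame_names
        elif len(frame_names) != len(names):
            raise StructuralError(
                f"{path}: frame {frame_index} has {len(frame_names)} atoms, expected {len(names)}"
            )
        frames.append(Frame(time=time, box=box, positions=pos))
        i += 3 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames, names


def _write_gro(trajectory: Trajectory, path: Path, names) -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"asdkit t= {frame.time:.4f}\n")
            fh.write(f"{frame.n_atoms:5d}\n")
            for k, p in enumerate(frame.positions):
                if top is not None:
                    atom = top.atoms[k]
                    resid = (int(top.molecule_of_atom[k]) + 1) % 100000
                    resname = atom.residue_label[:5]
                    name = atom.name[:5]
                else:
                    resid = 1
                    resname = "MOL"
                    name = names[k][:5]
                fh.write(
                    f"{resid:5d}{resname:<5s}{name:>5s}{(k + 1) % 100000:5d}"
                    f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}\n"
                )
            b = frame.box
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Topology sidecar
# ---------------------------------------------------------------------------


def write_topology(topology: Topology, path) -> None:
    """Write the tab-separated topology sidecar (1-based indices on disk)."""
    donor_of = {h: d for d, h in topology.donor_hydrogen_pairs}
    with open(path, "w") as fh:
        fh.write("\t".join(TOPOLOGY_COLUMNS) + "\n")
        for atom in topology.atoms:
            mol_id = int(topology.molecule_of_atom[atom.atom_id])
            kind = topology.molecule(mol_id).kind
            roles = ",".join(sorted(atom.roles)) if atom.roles else "-"
            dof = str(donor_of[atom.atom_id] + 1) if atom.atom_id in donor_of else "-"
            fh.write(
                f"{mol_id + 1}\t{kind}\t{atom.residue_label}\t{atom.residue_index + 1}\t"
                f"{atom.name}\t{atom.element}\t{atom.mass:.4f}\t{roles}\t{dof}\n"
            )


def read_topology(path) -> Topology:
    """Read a topology sidecar written by :func:`write_topology`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TOPOLOGY_COLUMNS:
            raise ParseError(
                f"{path}: line 1: bad header; expected {list(TOPOLOGY_COLUMNS)}, got {header}"
            )
        atoms: list = []
        mol_atoms: dict = {}
        mol_kind: dict = {}
        pairs: list = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(TOPOLOGY_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected {len(TOPOLOGY_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            mol_id_1, kind, res_label, res_idx_1, name, element, mass, roles, donor_of = parts
            atom_id = len(atoms)
            try:
                mol_id = int(mol_id_1) - 1
                res_idx = int(res_idx_1) - 1
                mass_f = float(mass)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}")
            role_set = frozenset() if roles == "-" else frozenset(roles.split(","))
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    name=name,
                    element=element,
                    mass=mass_f,
                    roles=role_set,
                    residue_label=res_label,
                    residue_index=res_idx,
                )
            )
            mol_atoms.setdefault(mol_id, []).append(atom_id)
            if mol_id in mol_kind and mol_kind[mol_id] != kind:
                raise TopologyError(
                    f"{path}: line {lineno}: molecule {mol_id + 1} has conflicting kinds"
                )
            mol_kind[mol_id] = kind
            if donor_of != "-":
                pairs.append((int(donor_of) - 1, atom_id))
    molecules = [
        Molecule(molecule_id=mid, kind=mol_kind[mid], atom_ids=tuple(aids))
        for mid, aids in sorted(mol_atoms.items())
    ]
    return Topology(atoms=atoms, molecules=molecules, donor_hydrogen_pairs=pairs)
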