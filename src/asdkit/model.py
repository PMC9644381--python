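"""Core data model for periodic molecular systems.

Holds topologies (atoms, molecules, donor/hydrogen pairing) and trajectories
(time-ordered frames of wrapped coordinates in an orthorhombic box), together
with the periodic-geometry primitives everything downstream relies on:
minimum-image displacements/distances, molecule re-wholing under periodic
boundaries, and centers of mass.

Internal unit conventions (fixed package-wide):

* length  — nanometres
* time    — picoseconds
* mass    — daltons
* diffusivity — reported in units of 1e-9 cm^2/s (see :data:`NM2_PER_PS_IN_REPORT_UNITS`)

Atom indices are 0-based internally; on-disk formats use 1-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ROLE_DONOR",
    "ROLE_POLAR_HYDROGEN",
    "ROLE_ACCEPTOR",
    "KIND_PROTEIN",
    "KIND_DRUG",
    "KIND_WATER",
    "NM2_PER_PS_IN_REPORT_UNITS",
    "REPORT_UNITS_IN_NM2_PER_PS",
    "AsdkitError",
    "ParseError",
    "StructuralError",
    "IntegrityError",
    "TopologyError",
    "DomainError",
    "Atom",
    "Molecule",
    "Topology",
    "Frame",
    "Trajectory",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_positions",
    "unwrap_molecule",
    "center_of_mass",
]

# Atom roles.  An atom may carry several roles (e.g. a hydroxyl oxygen is both
# donor and acceptor); roles are stored as a frozenset.
ROLE_DONOR = "donor"
ROLE_POLAR_HYDROGEN = "polar_hydrogen"
ROLE_ACCEPTOR = "acceptor"

# Molecule kinds.
KIND_PROTEIN = "protein"
KIND_DRUG = "drug"
KIND_WATER = "water"

#: Conversion of a diffusivity in nm^2/ps into the reporting unit 1e-9 cm^2/s.
#: 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s = 1e7 x (1e-9 cm^2/s).
NM2_PER_PS_IN_REPORT_UNITS = 1.0e7
#: Inverse conversion: 1 (1e-9 cm^2/s) = 1e-7 nm^2/ps.
REPORT_UNITS_IN_NM2_PER_PS = 1.0e-7


class AsdkitError(Exception):
    """Base class for all package errors."""


class ParseError(AsdkitError):
    """A file could not be parsed under the declared dialect."""


class StructuralError(AsdkitError):
    """Frames/topology are individually valid but mutually inconsistent."""


class IntegrityError(AsdkitError):
    """A geometric precondition is violated (e.g. molecule not whole)."""


class TopologyError(AsdkitError):
    """Topology annotations are missing or contradictory."""


class DomainError(AsdkitError):
    """An argument is outside the operation's domain."""


@dataclass(frozen=True)
class Atom:
    """A single atom with its H-bonding role annotations.

    ``roles`` is a (possibly empty) frozenset drawn from
    {donor, polar_hydrogen, acceptor}.
    """

    atom_id: int
    name: str
    element: str
    mass: float
    roles: frozenset = frozenset()
    residue_label: str = "UNK"
    residue_index: int = 0

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise TopologyError(f"atom {self.atom_id}: mass must be > 0, got {self.mass}")
        bad = set(self.roles) - {ROLE_DONOR, ROLE_POLAR_HYDROGEN, ROLE_ACCEPTOR}
        if bad:
            raise TopologyError(f"atom {self.atom_id}: unknown roles {sorted(bad)}")


@dataclass(frozen=True)
class Molecule:
    """A molecule: a kind label plus an ordered list of atom ids."""

    molecule_id: int
    kind: str
    atom_ids: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_ids", tuple(int(i) for i in self.atom_ids))
        if not self.atom_ids:
            raise TopologyError(f"molecule {self.molecule_id}: empty atom list")
        if self.kind not in (KIND_PROTEIN, KIND_DRUG, KIND_WATER):
            raise TopologyError(f"molecule {self.molecule_id}: unknown kind {self.kind!r}")
        if self.kind == KIND_WATER and len(self.atom_ids) != 3:
            raise TopologyError(
                f"molecule {self.molecule_id}: water must have exactly 3 atoms, "
                f"got {len(self.atom_ids)}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)


class Topology:
    """Static description of a system: atoms, molecules, donor-H pairing.

    Parameters
    ----------
    atoms
        All atoms, ordered by ``atom_id`` (ids must be 0..N-1).
    molecules
        Molecules whose ``atom_ids`` partition the atom set.
    donor_hydrogen_pairs
        Explicit covalent pairing ``(donor_atom_id, hydrogen_atom_id)``.
        Every polar hydrogen must appear in exactly one pair; a donor may
        carry several hydrogens.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        molecules: Sequence[Molecule],
        donor_hydrogen_pairs: Iterable[tuple] = (),
    ) -> None:
        self.atoms = list(atoms)
        self.molecules = list(molecules)
        self.donor_hydrogen_pairs = [(int(d), int(h)) for d, h in donor_hydrogen_pairs]
        self._validate()
        self.masses = np.array([a.mass for a in self.atoms], dtype=float)
        # molecule_of_atom[i] -> molecule_id owning atom i
        self.molecule_of_atom = np.empty(len(self.atoms), dtype=int)
        for mol in self.molecules:
            self.molecule_of_atom[list(mol.atom_ids)] = mol.molecule_id
        self._mol_by_id = {m.molecule_id: m for m in self.molecules}

    def _validate(self) -> None:
        n = len(self.atoms)
        for i, a in enumerate(self.atoms):
            if a.atom_id != i:
                raise TopologyError(f"atom ids must be 0..N-1 in order; position {i} has id {a.atom_id}")
        seen: set = set()
        for mol in self.molecules:
            overlap = seen.intersection(mol.atom_ids)
            if overlap:
                raise TopologyError(f"atoms {sorted(overlap)} appear in more than one molecule")
            seen.update(mol.atom_ids)
        if seen != set(range(n)):
            missing = sorted(set(range(n)) - seen)
            raise TopologyError(f"atoms not covered by any molecule: {missing[:10]}")
        ids = [m.molecule_id for m in self.molecules]
        if len(ids) != len(set(ids)):
            raise TopologyError("duplicate molecule ids")

        hydrogens_paired: set = set()
        for d, h in self.donor_hydrogen_pairs:
            if not (0 <= d < n and 0 <= h < n):
                raise TopologyError(f"donor/hydrogen pair ({d},{h}) out of range")
            if h in hydrogens_paired:
                raise TopologyError(f"hydrogen {h} paired to more than one donor")
            hydrogens_paired.add(h)
            if ROLE_DONOR not in self.atoms[d].roles:
                raise TopologyError(f"atom {d} in donor_hydrogen_pairs lacks the donor role")
            if ROLE_POLAR_HYDROGEN not in self.atoms[h].roles:
                raise TopologyError(f"atom {h} in donor_hydrogen_pairs lacks the polar_hydrogen role")
        for a in self.atoms:
            if ROLE_POLAR_HYDROGEN in a.roles and a.atom_id not in hydrogens_paired:
                raise TopologyError(f"polar hydrogen {a.atom_id} has no paired donor")

    # -- convenience ------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def molecule(self, molecule_id: int) -> Molecule:
        return self._mol_by_id[molecule_id]

    def molecules_of_kind(self, kind: str) -> list:
        return [m for m in self.molecules if m.kind == kind]

    def molar_mass(self, molecule: Molecule) -> float:
        return float(self.masses[list(molecule.atom_ids)].sum())

    def protein_atom_ids(self) -> np.ndarray:
        ids: list = []
        for m in self.molecules_of_kind(KIND_PROTEIN):
            ids.extend(m.atom_ids)
        return np.array(sorted(ids), dtype=int)

    def acceptor_atom_ids(self) -> np.ndarray:
        return np.array(
            [a.atom_id for a in self.atoms if ROLE_ACCEPTOR in a.roles], dtype=int
        )


@dataclass
class Frame:
    """One trajectory frame: time, orthorhombic box edges, wrapped positions.

    Positions are wrapped into ``[0, edge)`` per axis at construction.
    """

    time: float
    box: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if not np.all(self.box > 0):
            raise DomainError(f"box edges must be positive, got {self.box}")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise StructuralError(f"positions must be (N, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise IntegrityError("non-finite coordinates in frame")
        self.positions = wrap_positions(self.positions, self.box)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """Time-ordered frames sharing one topology (topology may be None for
    bare coordinate streams read without a sidecar)."""

    def __init__(self, frames: Sequence[Frame], topology: Topology | None = None) -> None:
        self.frames = list(frames)
        self.topology = topology
        if not self.frames:
            raise StructuralError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise StructuralError(
                    f"frame {k} has {f.n_atoms} atoms, expected {n0} (frame 0)"
                )
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise StructuralError("frame times must be strictly increasing")
        if topology is not None and topology.n_atoms != n0:
            raise StructuralError(
                f"topology has {topology.n_atoms} atoms but frames have {n0}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    @property
    def frame_stride(self) -> float:
        """Median frame spacing in ps (0 for single-frame trajectories)."""
        t = self.times
        return float(np.median(np.diff(t))) if len(t) > 1 else 0.0

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# Periodic geometry primitives
# ---------------------------------------------------------------------------


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, edge)`` per axis (orthorhombic box)."""
    box = np.asarray(box, dtype=float)
    wrapped = np.mod(positions, box)
    # mod can return exactly `edge` for tiny negative inputs; fold it back.
    wrapped = np.where(wrapped >= box, wrapped - box, wrapped)
    return wrapped


def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map a displacement (or array of displacements) to its minimum image.

    Ties at exactly half a box edge are resolved toward the negative image.
    Works on any (..., 3)-shaped array.
    """
    d = np.asarray(d, dtype=float)
    box = np.asarray(box, dtype=float)
    return d - box * np.floor(d / box + 0.5)


def minimum_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> float:
    """Smallest distance between ``p`` and any periodic image of ``q``.

    Symmetric in its two position arguments; supports broadcasting over
    leading axes (returns an array in that case).
    """
    box = np.asarray(box, dtype=float)
    if not np.all(box > 0):
        raise DomainError(f"box edges must be positive, got {box}")
    d = minimum_image_displacement(np.asarray(q, float) - np.asarray(p, float), box)
    return np.sqrt(np.sum(d * d, axis=-1))


def unwrap_molecule(frame: Frame, molecule: Molecule) -> np.ndarray:
    """Return whole-molecule coordinates for one molecule of a frame.

    Each atom is placed at the periodic image nearest its predecessor in the
    molecule's stored atom order (a deterministic chain traversal); the first
    atom keeps its wrapped position.  Raises :class:`IntegrityError` if the
    re-wholed molecule's diameter reaches half the smallest box edge, since
    the nearest-image chain is then ambiguous.
    """
    idx = list(molecule.atom_ids)
    coords = frame.positions[idx].copy()
    out = np.empty_like(coords)
    out[0] = coords[0]
    for i in range(1, len(idx)):
        out[i] = out[i - 1] + minimum_image_displacement(coords[i] - out[i - 1], frame.box)
    if len(idx) > 1:
        diameter = _max_extent(out)
        if diameter >= 0.5 * float(np.min(frame.box)):
            raise IntegrityError(
                f"molecule {molecule.molecule_id}: diameter {diameter:.3f} nm reaches "
                f"half the smallest box edge ({0.5 * float(np.min(frame.box)):.3f} nm)"
            )
    return out


def _max_extent(coords: np.ndarray) -> float:
    """Largest intra-set pair distance (plain Euclidean, no PBC)."""
    if len(coords) < 2:
        return 0.0
    diff = coords[:, None, :] - coords[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=-1)).max())


def center_of_mass(
    frame: Frame,
    molecule: Molecule,
    topology: Topology,
    coords: np.ndarray | None = None,
) -> np.ndarray:
    """Mass-weighted mean position of a whole molecule.

    The molecule must already be whole; pass ``coords`` from
    :func:`unwrap_molecule` to guarantee this, otherwise the frame's wrapped
    coordinates are used and checked.
    """
    if coords is None:
        coords = frame.positions[list(molecule.atom_ids)]
    if len(coords) > 1:
        if _max_extent(coords) >= 0.5 * float(np.min(frame.box)):
            raise IntegrityError(
                f"molecule {molecule.molecule_id} is not whole; call unwrap_molecule first"
            )
    masses = topology.masses[list(molecule.atom_ids)]
    return np.asarray(coords, float).T @ masses / masses.sum()
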