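"""Geometric hydrogen-bond analysis.

Detection uses the geometric criterion: donor-acceptor minimum-image distance
<= 0.35 nm combined with a 30 degree angular cutoff.  Two angle-vertex
conventions are supported, since analysis tools differ and published work
rarely states which one was used:

* ``vertex="donor"`` (default): the angle at the donor between the
  donor->hydrogen and donor->acceptor directions must be <= the cutoff.
* ``vertex="hydrogen"``: the donor-hydrogen-acceptor angle must be >= 180
  degrees minus the cutoff (supplementary-angle form of the same tolerance).

Bonds are identified across frames by their atom triple (donor, hydrogen,
acceptor), not the molecule pair: two donors on one molecule give two
distinct bonds.  Occupancy bookkeeping, stability thresholds (strict "more
than" semantics), breadth-first generation tracing from the protein
molecules, and per-residue aggregation all build on that triple identity.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import (
    KIND_DRUG,
    KIND_PROTEIN,
    KIND_WATER,
    ROLE_DONOR,
    DomainError,
    Frame,
    Topology,
    TopologyError,
    Trajectory,
    minimum_image_displacement,
)

__all__ = [
    "PAIR_PROTEIN_DRUG",
    "PAIR_DRUG_DRUG",
    "PAIR_PROTEIN_PROTEIN",
    "PAIR_WATER",
    "HBondTriple",
    "HBondExistenceMatrix",
    "detect_hbonds_frame",
    "build_existence_matrix",
    "classify_stable",
    "assign_generations",
    "rank_residues",
    "write_existence_matrix",
]

PAIR_PROTEIN_DRUG = "protein-drug"
PAIR_DRUG_DRUG = "drug-drug"
PAIR_PROTEIN_PROTEIN = "protein-protein"
PAIR_WATER = "water-involved"

#: Default geometric criterion.
D_CUT_NM = 0.35
ANGLE_CUT_DEG = 30.0

#: Strict-occupancy stability thresholds by pair class.
THRESHOLD_PROTEIN_DRUG = 0.80
THRESHOLD_OTHER = 0.50


@dataclass(frozen=True, order=True)
class HBondTriple:
    """One donor-hydrogen-acceptor triple with its molecule-level context."""

    donor_atom_id: int
    hydrogen_atom_id: int
    acceptor_atom_id: int
    donor_molecule_id: int
    acceptor_molecule_id: int
    pair_class: str

    @property
    def key(self) -> tuple:
        """Frame-stable identity: the atom triple."""
        return (self.donor_atom_id, self.hydrogen_atom_id, self.acceptor_atom_id)


def _pair_class(kind_a: str, kind_b: str) -> str:
    if KIND_WATER in (kind_a, kind_b):
        return PAIR_WATER
    kinds = {kind_a, kind_b}
    if kinds == {KIND_PROTEIN, KIND_DRUG}:
        return PAIR_PROTEIN_DRUG
    if kinds == {KIND_DRUG}:
        return PAIR_DRUG_DRUG
    return PAIR_PROTEIN_PROTEIN


def detect_hbonds_frame(
    frame: Frame,
    topology: Topology,
    d_cut: float = D_CUT_NM,
    angle_cut: float = ANGLE_CUT_DEG,
    vertex: str = "donor",
) -> set:
    """Detect all hydrogen bonds in one frame.

    A triple (D, H, A) is detected iff the minimum-image D-A distance is
    <= ``d_cut`` and the angular criterion under the chosen ``vertex``
    convention holds.  Intramolecular pairs are excluded.
    """
    if vertex not in ("donor", "hydrogen"):
        raise ValueError(f"vertex must be 'donor' or 'hydrogen', got {vertex!r}")
    pairs = topology.donor_hydrogen_pairs
    paired_donors = {d for d, _ in pairs}
    for atom in topology.atoms:
        if ROLE_DONOR in atom.roles and atom.atom_id not in paired_donors:
            raise TopologyError(f"donor atom {atom.atom_id} has no paired hydrogen")
    if not pairs:
        return set()
    acceptors = topology.acceptor_atom_ids()
    if acceptors.size == 0:
        return set()

    donor_ids = np.array([d for d, _ in pairs], dtype=int)
    hyd_ids = np.array([h for _, h in pairs], dtype=int)
    box = frame.box
    d_pos = frame.positions[donor_ids]
    h_pos = frame.positions[hyd_ids]
    a_pos = frame.positions[acceptors]

    # (n_pairs, n_acceptors, 3) minimum-image D->A displacements
    da = minimum_image_displacement(a_pos[None, :, :] - d_pos[:, None, :], box)
    dist = np.sqrt((da * da).sum(axis=-1))
    d_mol = topology.molecule_of_atom[donor_ids]
    a_mol = topology.molecule_of_atom[acceptors]
    mask = (dist <= d_cut) & (d_mol[:, None] != a_mol[None, :])
    mask &= donor_ids[:, None] != acceptors[None, :]
    mask &= hyd_ids[:, None] != acceptors[None, :]
    if not mask.any():
        return set()

    dh = minimum_image_displacement(h_pos - d_pos, box)  # (n_pairs, 3)
    cos_cut = np.cos(np.deg2rad(angle_cut))
    pi_idx, ai_idx = np.nonzero(mask)
    da_sel = da[pi_idx, ai_idx]
    if vertex == "donor":
        u = dh[pi_idx]
        v = da_sel
    else:
        # angle at the hydrogen between H->D and H->A; criterion is
        # angle >= 180 - cut, i.e. cos(angle) <= -cos(cut)
        ha = da_sel - dh[pi_idx]
        u = -dh[pi_idx]
        v = ha
    norms = np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", u, v) / norms
    if vertex == "donor":
        ok = cosang >= cos_cut - 1e-12
    else:
        ok = cosang <= -cos_cut + 1e-12

    out = set()
    for pi, ai, good in zip(pi_idx, ai_idx, ok):
        if not good:
            continue
        d_id = int(donor_ids[pi])
        a_id = int(acceptors[ai])
        dm = int(topology.molecule_of_atom[d_id])
        am = int(topology.molecule_of_atom[a_id])
        out.add(
            HBondTriple(
                donor_atom_id=d_id,
                hydrogen_atom_id=int(hyd_ids[pi]),
                acceptor_atom_id=a_id,
                donor_molecule_id=dm,
                acceptor_molecule_id=am,
                pair_class=_pair_class(
                    topology.molecule(dm).kind, topology.molecule(am).kind
                ),
            )
        )
    return out


class HBondExistenceMatrix:
    """Boolean occupancy of each detected triple across analysis frames."""

    def __init__(
        self,
        triples: Sequence[HBondTriple],
        occupancy: np.ndarray,
        frame_times: np.ndarray,
    ) -> None:
        self.triples = list(triples)
        self.occupancy = np.asarray(occupancy, dtype=bool)
        self.frame_times = np.asarray(frame_times, dtype=float)
        if self.occupancy.shape != (len(self.triples), len(self.frame_times)):
            raise DomainError(
                f"occupancy shape {self.occupancy.shape} does not match "
                f"({len(self.triples)}, {len(self.frame_times)})"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def row_means(self) -> np.ndarray:
        return self.occupancy.mean(axis=1) if len(self.triples) else np.empty(0)

    def occupancy_of(self, triple: HBondTriple) -> float:
        for i, t in enumerate(self.triples):
            if t.key == triple.key:
                return float(self.occupancy[i].mean())
        raise KeyError(f"triple {triple.key} not present in matrix")

    def per_frame_counts(self) -> np.ndarray:
        return self.occupancy.sum(axis=0)


def build_existence_matrix(
    trajectory: Trajectory,
    window: Sequence[int] | None = None,
    d_cut: float = D_CUT_NM,
    angle_cut: float = ANGLE_CUT_DEG,
    vertex: str = "donor",
) -> HBondExistenceMatrix:
    """Detect bonds in every window frame and assemble the occupancy matrix.

    ``window`` is an iterable of frame indices (default: all frames).  The
    triple set is the union over the window; occupancy is keyed by the atom
    triple.
    """
    if trajectory.topology is None:
        raise TopologyError("trajectory has no topology attached")
    frames_idx = list(range(trajectory.n_frames)) if window is None else list(window)
    if not frames_idx:
        raise DomainError("empty analysis window")
    per_frame: list = []
    key_to_triple: dict = {}
    for fi in frames_idx:
        found = detect_hbonds_frame(
            trajectory.frames[fi], trajectory.topology, d_cut, angle_cut, vertex
        )
        keys = set()
        for t in found:
            key_to_triple.setdefault(t.key, t)
            keys.add(t.key)
        per_frame.append(keys)
    triples = [key_to_triple[k] for k in sorted(key_to_triple)]
    occ = np.zeros((len(triples), len(frames_idx)), dtype=bool)
    index = {t.key: i for i, t in enumerate(triples)}
    for col, keys in enumerate(per_frame):
        for k in keys:
            occ[index[k], col] = True
    times = trajectory.times[frames_idx]
    return HBondExistenceMatrix(triples, occ, times)


def classify_stable(
    matrix: HBondExistenceMatrix,
    threshold_protein_drug: float = THRESHOLD_PROTEIN_DRUG,
    threshold_other: float = THRESHOLD_OTHER,
) -> set:
    """Triples whose occupancy strictly exceeds their class threshold."""
    means = matrix.row_means()
    stable = set()
    for triple, mean in zip(matrix.triples, means):
        thr = (
            threshold_protein_drug
            if triple.pair_class == PAIR_PROTEIN_DRUG
            else threshold_other
        )
        if mean > thr:
            stable.add(triple)
    return stable


def assign_generations(
    stable_bonds: Iterable[HBondTriple],
    topology: Topology,
    max_generation: int | None = None,
    include_water: bool = False,
) -> dict:
    """Breadth-first generation tracing on the molecule-level bond graph.

    Nodes are molecules, edges are stable bonds, sources are all protein
    molecules; a drug molecule's generation is its BFS depth.  Water-involved
    bonds are ignored unless ``include_water`` is set, in which case water
    molecules participate as bridge nodes (and contribute depth).  Returns
    ``{drug_molecule_id: generation or None}`` covering every drug molecule.
    """
    adj: dict = {}
    included_kinds = {KIND_PROTEIN, KIND_DRUG} | ({KIND_WATER} if include_water else set())
    for b in stable_bonds:
        ka = topology.molecule(b.donor_molecule_id).kind
        kb = topology.molecule(b.acceptor_molecule_id).kind
        if ka not in included_kinds or kb not in included_kinds:
            continue
        adj.setdefault(b.donor_molecule_id, set()).add(b.acceptor_molecule_id)
        adj.setdefault(b.acceptor_molecule_id, set()).add(b.donor_molecule_id)

    depth: dict = {}
    queue: deque = deque()
    for mol in topology.molecules_of_kind(KIND_PROTEIN):
        depth[mol.molecule_id] = 0
        queue.append(mol.molecule_id)
    while queue:
        node = queue.popleft()
        for nb in adj.get(node, ()):
            if nb not in depth:
                depth[nb] = depth[node] + 1
                queue.append(nb)

    out: dict = {}
    for mol in topology.molecules_of_kind(KIND_DRUG):
        g = depth.get(mol.molecule_id)
        if g is not None and (max_generation is None or g <= max_generation):
            out[mol.molecule_id] = g
        else:
            out[mol.molecule_id] = None
    return out


def rank_residues(
    bonds: Iterable[HBondTriple] | HBondExistenceMatrix,
    topology: Topology,
    stable_only: bool = False,
    weight_by_occupancy: bool = True,
    major_cut: float = 0.10,
) -> list:
    """Aggregate protein-drug bonds by the protein-side residue label.

    Accepts either a plain bond collection (each triple counted once) or an
    existence matrix (triples weighted by occupancy unless
    ``weight_by_occupancy`` is off).  Returns rows sorted alphabetically by
    label: ``(label, count, fraction, major)`` where ``major`` flags
    contributions above ``major_cut`` of the total.
    """
    weighted: list = []
    if isinstance(bonds, HBondExistenceMatrix):
        matrix = bonds
        triples = matrix.triples
        means = matrix.row_means()
        if stable_only:
            stable_keys = {t.key for t in classify_stable(matrix)}
        for t, m in zip(triples, means):
            if stable_only and t.key not in stable_keys:
                continue
            weighted.append((t, float(m) if weight_by_occupancy else 1.0))
    else:
        weighted = [(t, 1.0) for t in bonds]

    counts: dict = {}
    for t, w in weighted:
        if t.pair_class != PAIR_PROTEIN_DRUG:
            continue
        protein_side = (
            t.donor_atom_id
            if topology.molecule(t.donor_molecule_id).kind == KIND_PROTEIN
            else t.acceptor_atom_id
        )
        label = topology.atoms[protein_side].residue_label
        counts[label] = counts.get(label, 0.0) + w

    total = sum(counts.values())
    rows = []
    for label in sorted(counts):
        frac = counts[label] / total if total > 0 else 0.0
        rows.append((label, counts[label], frac, frac > major_cut))
    return rows


def write_existence_matrix(matrix: HBondExistenceMatrix, topology: Topology, tsv_path, index_path) -> None:
    """Serialize the matrix as annotated TSV plus a JSON index file."""
    with open(tsv_path, "w") as fh:
        header = [
            "donor_atom",
            "hydrogen_atom",
            "acceptor_atom",
            "donor_molecule",
            "acceptor_molecule",
            "pair_class",
            "donor_residue",
            "acceptor_residue",
            "occupancy_mean",
        ] + [f"t={t:g}" for t in matrix.frame_times]
        fh.write("\t".join(header) + "\n")
        means = matrix.row_means()
        for i, t in enumerate(matrix.triples):
            row = [
                str(t.donor_atom_id + 1),
                str(t.hydrogen_atom_id + 1),
                str(t.acceptor_atom_id + 1),
                str(t.donor_molecule_id + 1),
                str(t.acceptor_molecule_id + 1),
                t.pair_class,
                topology.atoms[t.donor_atom_id].residue_label,
                topology.atoms[t.acceptor_atom_id].residue_label,
                f"{means[i]:.6f}",
            ] + ["1" if v else "0" for v in matrix.occupancy[i]]
            fh.write("\t".join(row) + "\n")
    index = {
        "n_triples": len(matrix.triples),
        "n_frames": matrix.n_frames,
        "frame_times_ps": [float(t) for t in matrix.frame_times],
        "triples": [
            {
                "donor_atom": t.donor_atom_id + 1,
                "hydrogen_atom": t.hydrogen_atom_id + 1,
                "acceptor_atom": t.acceptor_atom_id + 1,
                "pair_class": t.pair_class,
            }
            for t in matrix.triples
        ],
    }
    with open(index_path, "w") as fh:
        json.dump(index, fh, indent=1)
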