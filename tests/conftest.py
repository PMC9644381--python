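"""Shared fixtures: tiny hand-built topologies and random-system factories."""

from __future__ import annotations

import numpy as np
import pytest

from asdkit.model import (
    KIND_DRUG,
    KIND_PROTEIN,
    KIND_WATER,
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_POLAR_HYDROGEN,
    Atom,
    Frame,
    Molecule,
    Topology,
    Trajectory,
)


def make_atom(atom_id, roles=frozenset(), mass=12.0, label="UNK", res_idx=0, element="C"):
    return Atom(
        atom_id=atom_id,
        name=f"X{atom_id}",
        element=element,
        mass=mass,
        roles=roles,
        residue_label=label,
        residue_index=res_idx,
    )


def single_site_molecules(kinds):
    """Minimal molecules, one per kind entry (water gets its required 3 atoms);
    returns a Topology whose molecule ids match list positions."""
    atoms = []
    mols = []
    for i, k in enumerate(kinds):
        n = 3 if k == KIND_WATER else 1
        ids = tuple(range(len(atoms), len(atoms) + n))
        atoms.extend(make_atom(a) for a in ids)
        mols.append(Molecule(molecule_id=i, kind=k, atom_ids=ids))
    return Topology(atoms, mols)


@pytest.fixture
def donor_acceptor_topology():
    """Two molecules: a donor-H pair (drug) and an acceptor (protein)."""
    atoms = [
        make_atom(0, frozenset({ROLE_DONOR}), mass=16.0, label="IND", element="O"),
        make_atom(1, frozenset({ROLE_POLAR_HYDROGEN}), mass=1.0, label="IND", element="H"),
        make_atom(2, frozenset({ROLE_ACCEPTOR}), mass=16.0, label="GLU", element="O"),
    ]
    mols = [
        Molecule(molecule_id=0, kind=KIND_DRUG, atom_ids=(0, 1)),
        Molecule(molecule_id=1, kind=KIND_PROTEIN, atom_ids=(2,)),
    ]
    return Topology(atoms, mols, donor_hydrogen_pairs=[(0, 1)])


def geometry_frame(topology, positions, box=(4.0, 4.0, 4.0), time=0.0):
    return Frame(time=time, box=np.asarray(box, float), positions=np.asarray(positions, float))


def random_hbond_system(rng, n_atoms=50, box_edge=2.0):
    """Random topology + frame for oracle comparison.

    Atoms are split into random molecules; each molecule gets a random mix of
    donor(+H)/acceptor/plain atoms placed uniformly in a small box so the
    0.35 nm criterion fires often and wrapping matters.
    """
    atoms = []
    molecules = []
    pairs = []
    i = 0
    mol_id = 0
    while i < n_atoms:
        size = int(rng.integers(2, 8))
        size = min(size, n_atoms - i)
        if size == 1 and i + 1 < n_atoms:
            size = 2
        ids = list(range(i, i + size))
        j = 0
        while j < size:
            aid = ids[j]
            roll = rng.random()
            if roll < 0.35 and j + 1 < size:
                atoms.append(make_atom(aid, frozenset({ROLE_DONOR}), element="O"))
                atoms.append(
                    make_atom(ids[j + 1], frozenset({ROLE_POLAR_HYDROGEN}), mass=1.0, element="H")
                )
                pairs.append((aid, ids[j + 1]))
                j += 2
            elif roll < 0.75:
                atoms.append(make_atom(aid, frozenset({ROLE_ACCEPTOR}), element="N"))
                j += 1
            else:
                atoms.append(make_atom(aid, element="C"))
                j += 1
        molecules.append(
            Molecule(
                molecule_id=mol_id,
                kind=KIND_DRUG if mol_id % 2 else KIND_PROTEIN,
                atom_ids=tuple(ids),
            )
        )
        mol_id += 1
        i += size
    atoms.sort(key=lambda a: a.atom_id)
    topology = Topology(atoms, molecules, pairs)
    positions = rng.uniform(0.0, box_edge, size=(n_atoms, 3))
    # put each hydrogen near its donor so angles are physical
    for d, h in pairs:
        positions[h] = positions[d] + rng.normal(0.0, 0.05, 3)
    frame = Frame(time=0.0, box=np.array([box_edge] * 3), positions=positions)
    return topology, frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
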