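import numpy as np
import pytest

from _oracles import brute_force_hbonds, generation_oracle
from asdkit.hbond import (
    HBondExistenceMatrix,
    HBondTriple,
    PAIR_DRUG_DRUG,
    PAIR_PROTEIN_DRUG,
    assign_generations,
    build_existence_matrix,
    classify_stable,
    detect_hbonds_frame,
    rank_residues,
)
from asdkit.model import (
    KIND_DRUG,
    KIND_PROTEIN,
    KIND_WATER,
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_POLAR_HYDROGEN,
    DomainError,
    Frame,
    Molecule,
    Topology,
    TopologyError,
    Trajectory,
)
from conftest import geometry_frame, make_atom, random_hbond_system, single_site_molecules


def place(topology, donor, hydrogen, acceptor, box=(4.0, 4.0, 4.0)):
    pos = np.zeros((3, 3))
    pos[0], pos[1], pos[2] = donor, hydrogen, acceptor
    return Frame(time=0.0, box=np.asarray(box, float), positions=pos)


class TestDetection:
    def test_collinear_detected(self, donor_acceptor_topology):
        frame = place(donor_acceptor_topology, [1, 1, 1], [1.1, 1, 1], [1.30, 1, 1])
        found = detect_hbonds_frame(frame, donor_acceptor_topology)
        assert {t.key for t in found} == {(0, 1, 2)}
        (t,) = found
        assert t.pair_class == PAIR_PROTEIN_DRUG

    def test_just_past_distance_cutoff(self, donor_acceptor_topology):
        frame = place(donor_acceptor_topology, [1, 1, 1], [1.1, 1, 1], [1.351, 1, 1])
        assert detect_hbonds_frame(frame, donor_acceptor_topology) == set()

    @pytest.mark.parametrize("angle_deg,expect", [(29.0, True), (31.0, False)])
    def test_angle_cutoff_vertex_donor(self, donor_acceptor_topology, angle_deg, expect):
        a = np.deg2rad(angle_deg)
        acceptor = np.array([1, 1, 1]) + 0.3 * np.array([np.cos(a), np.sin(a), 0.0])
        frame = place(donor_acceptor_topology, [1, 1, 1], [1.1, 1, 1], acceptor)
        found = detect_hbonds_frame(frame, donor_acceptor_topology, vertex="donor")
        assert bool(found) is expect

    @pytest.mark.parametrize("dha_deg,expect", [(165.0, True), (140.0, False)])
    def test_angle_cutoff_vertex_hydrogen(self, donor_acceptor_topology, dha_deg, expect):
        # place acceptor so the D-H-A angle is dha_deg, D-A distance small
        a = np.deg2rad(180.0 - dha_deg)
        h = np.array([1.1, 1.0, 1.0])
        acceptor = h + 0.15 * np.array([np.cos(a), np.sin(a), 0.0])
        frame = place(donor_acceptor_topology, [1, 1, 1], h, acceptor)
        found = detect_hbonds_frame(frame, donor_acceptor_topology, vertex="hydrogen")
        assert bool(found) is expect

    def test_detects_across_periodic_boundary(self, donor_acceptor_topology):
        # acceptor's nearest image is across the -x boundary; H points that way
        frame = place(donor_acceptor_topology, [0.05, 1, 1], [3.95, 1, 1], [3.80, 1, 1])
        found = detect_hbonds_frame(frame, donor_acceptor_topology)
        assert {t.key for t in found} == {(0, 1, 2)}

    def test_intramolecular_excluded(self):
        atoms = [
            make_atom(0, frozenset({ROLE_DONOR}), element="O"),
            make_atom(1, frozenset({ROLE_POLAR_HYDROGEN}), mass=1.0, element="H"),
            make_atom(2, frozenset({ROLE_ACCEPTOR}), element="O"),
        ]
        mol = Molecule(molecule_id=0, kind=KIND_DRUG, atom_ids=(0, 1, 2))
        top = Topology(atoms, [mol], donor_hydrogen_pairs=[(0, 1)])
        frame = place(top, [1, 1, 1], [1.1, 1, 1], [1.3, 1, 1])
        assert detect_hbonds_frame(frame, top) == set()

    def test_donor_without_hydrogen_raises(self):
        atoms = [
            make_atom(0, frozenset({ROLE_DONOR}), element="O"),
            make_atom(1, frozenset({ROLE_ACCEPTOR}), element="O"),
        ]
        mols = [
            Molecule(molecule_id=0, kind=KIND_DRUG, atom_ids=(0,)),
            Molecule(molecule_id=1, kind=KIND_DRUG, atom_ids=(1,)),
        ]
        top = Topology(atoms, mols)
        frame = geometry_frame(top, [[1, 1, 1], [1.2, 1, 1]])
        with pytest.raises(TopologyError):
            detect_hbonds_frame(frame, top)

    @pytest.mark.parametrize("vertex", ["donor", "hydrogen"])
    def test_matches_brute_force_oracle(self, rng, vertex):
        for _ in range(100):
            top, frame = random_hbond_system(rng)
            fast = {t.key for t in detect_hbonds_frame(frame, top, vertex=vertex)}
            slow = brute_force_hbonds(frame, top, vertex=vertex)
            assert fast == slow


class TestExistenceMatrix:
    def test_frozen_single_bond(self, donor_acceptor_topology):
        frames = [
            place(donor_acceptor_topology, [1, 1, 1], [1.1, 1, 1], [1.3, 1, 1])
            for _ in range(5)
        ]
        for i, f in enumerate(frames):
            f.time = float(i)
        traj = Trajectory(frames, topology=donor_acceptor_topology)
        m = build_existence_matrix(traj)
        assert len(m.triples) == 1
        assert m.occupancy.all()
        assert m.row_means()[0] == 1.0

    def test_column_sums_match_per_frame_counts(self, rng):
        top, _ = random_hbond_system(rng)
        frames = []
        for i in range(6):
            pos = rng.uniform(0, 2.0, size=(top.n_atoms, 3))
            for d, h in top.donor_hydrogen_pairs:
                pos[h] = pos[d] + rng.normal(0, 0.05, 3)
            frames.append(Frame(time=float(i), box=np.array([2.0] * 3), positions=pos))
        traj = Trajectory(frames, topology=top)
        m = build_existence_matrix(traj)
        for col, frame in enumerate(frames):
            n = len(detect_hbonds_frame(frame, top))
            assert m.per_frame_counts()[col] == n

    def test_empty_window_raises(self, donor_acceptor_topology):
        frame = place(donor_acceptor_topology, [1, 1, 1], [1.1, 1, 1], [1.3, 1, 1])
        traj = Trajectory([frame], topology=donor_acceptor_topology)
        with pytest.raises(DomainError):
            build_existence_matrix(traj, window=[])


def _matrix_with(pair_class, n_true, n_frames):
    triple = HBondTriple(0, 1, 2, 0, 1, pair_class)
    occ = np.zeros((1, n_frames), dtype=bool)
    occ[0, :n_true] = True
    return HBondExistenceMatrix([triple], occ, np.arange(n_frames, dtype=float)), triple


class TestStability:
    def test_protein_drug_strict_threshold(self):
        m80, _ = _matrix_with(PAIR_PROTEIN_DRUG, 80, 100)
        assert classify_stable(m80) == set()
        m81, t = _matrix_with(PAIR_PROTEIN_DRUG, 81, 100)
        assert classify_stable(m81) == {t}

    def test_drug_drug_strict_threshold(self):
        m50, _ = _matrix_with(PAIR_DRUG_DRUG, 50, 100)
        assert classify_stable(m50) == set()
        m51, t = _matrix_with(PAIR_DRUG_DRUG, 51, 100)
        assert classify_stable(m51) == {t}

    def test_all_zero_matrix(self):
        m, _ = _matrix_with(PAIR_PROTEIN_DRUG, 0, 10)
        assert classify_stable(m) == set()

    def test_invariant_to_frame_permutation(self, rng):
        m, t = _matrix_with(PAIR_PROTEIN_DRUG, 85, 100)
        perm = rng.permutation(100)
        shuffled = HBondExistenceMatrix([t], m.occupancy[:, perm], m.frame_times)
        assert classify_stable(shuffled) == classify_stable(m)


def _bond(mol_a, mol_b, pair_class=PAIR_DRUG_DRUG):
    return HBondTriple(0, 1, 2, mol_a, mol_b, pair_class)


class TestGenerations:
    def test_chain(self):
        top = single_site_molecules([KIND_PROTEIN, KIND_DRUG, KIND_DRUG, KIND_DRUG])
        bonds = {
            _bond(0, 1, PAIR_PROTEIN_DRUG),
            _bond(1, 2),
            _bond(2, 3),
        }
        assert assign_generations(bonds, top) == {1: 1, 2: 2, 3: 3}

    def test_shortest_path_wins(self):
        top = single_site_molecules([KIND_PROTEIN, KIND_DRUG, KIND_DRUG])
        bonds = {
            _bond(0, 1, PAIR_PROTEIN_DRUG),
            _bond(0, 2, PAIR_PROTEIN_DRUG),
            _bond(1, 2),
        }
        assert assign_generations(bonds, top) == {1: 1, 2: 1}

    def test_unreachable_is_none(self):
        top = single_site_molecules([KIND_PROTEIN, KIND_DRUG, KIND_DRUG])
        bonds = {_bond(1, 2)}
        assert assign_generations(bonds, top) == {1: None, 2: None}

    def test_max_generation_cap(self):
        top = single_site_molecules([KIND_PROTEIN, KIND_DRUG, KIND_DRUG, KIND_DRUG])
        bonds = {_bond(0, 1, PAIR_PROTEIN_DRUG), _bond(1, 2), _bond(2, 3)}
        got = assign_generations(bonds, top, max_generation=2)
        assert got == {1: 1, 2: 2, 3: None}

    def test_water_excluded_by_default(self):
        top = single_site_molecules([KIND_PROTEIN, KIND_WATER, KIND_DRUG])
        # protein-water-drug chain: bridge only counts with include_water
        bonds = {
            HBondTriple(0, 1, 2, 0, 1, "water-involved"),
            HBondTriple(3, 4, 5, 1, 2, "water-involved"),
        }
        assert assign_generations(bonds, top) == {2: None}
        assert assign_generations(bonds, top, include_water=True) == {2: 2}

    def test_matches_shortest_path_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 100))
            kinds = [
                KIND_PROTEIN if rng.random() < 0.2 else KIND_DRUG for _ in range(n)
            ]
            if KIND_PROTEIN not in kinds:
                kinds[0] = KIND_PROTEIN
            top = single_site_molecules(kinds)
            n_edges = int(rng.integers(0, 3 * n))
            edges = set()
            for _ in range(n_edges):
                a, b = rng.integers(0, n, 2)
                if a != b:
                    edges.add((int(min(a, b)), int(max(a, b))))
            bonds = {_bond(a, b) for a, b in edges}
            got = assign_generations(bonds, top)
            protein_nodes = [i for i, k in enumerate(kinds) if k == KIND_PROTEIN]
            drug_nodes = [i for i, k in enumerate(kinds) if k == KIND_DRUG]
            expected = generation_oracle(protein_nodes, edges, drug_nodes)
            assert got == expected

    def test_removing_bond_never_decreases_generation(self, rng):
        kinds = [KIND_PROTEIN] + [KIND_DRUG] * 15
        top = single_site_molecules(kinds)
        edges = set()
        while len(edges) < 20:
            a, b = rng.integers(0, 16, 2)
            if a != b:
                edges.add((int(min(a, b)), int(max(a, b))))
        bonds = {_bond(a, b) for a, b in edges}
        base = assign_generations(bonds, top)
        for removed in list(bonds):
            got = assign_generations(bonds - {removed}, top)
            for mol, g in got.items():
                if base[mol] is not None and g is not None:
                    assert g >= base[mol]


class TestRankResidues:
    def _protein_drug_system(self, labels):
        """One protein with len(labels) acceptor sites, one drug donor."""
        atoms = []
        for i, lab in enumerate(labels):
            atoms.append(make_atom(i, frozenset({ROLE_ACCEPTOR}), label=lab, res_idx=i))
        d = len(labels)
        atoms.append(make_atom(d, frozenset({ROLE_DONOR}), label="IND", element="O"))
        atoms.append(make_atom(d + 1, frozenset({ROLE_POLAR_HYDROGEN}), mass=1.0, label="IND"))
        mols = [
            Molecule(molecule_id=0, kind=KIND_PROTEIN, atom_ids=tuple(range(d))),
            Molecule(molecule_id=1, kind=KIND_DRUG, atom_ids=(d, d + 1)),
        ]
        top = Topology(atoms, mols, donor_hydrogen_pairs=[(d, d + 1)])
        bonds = [
            HBondTriple(d, d + 1, i, 1, 0, PAIR_PROTEIN_DRUG) for i in range(len(labels))
        ]
        return top, bonds

    def test_single_class(self):
        top, bonds = self._protein_drug_system(["GLU"] * 10)
        rows = rank_residues(bonds, top)
        assert rows == [("GLU", 10.0, 1.0, True)]

    def test_six_four_split(self):
        top, bonds = self._protein_drug_system(["GLU"] * 6 + ["ASP"] * 4)
        rows = rank_residues(bonds, top)
        assert [r[0] for r in rows] == ["ASP", "GLU"]  # alphabetical
        assert rows[0][2] == pytest.approx(0.4)
        assert rows[1][2] == pytest.approx(0.6)
        assert all(r[3] for r in rows)

    def test_fractions_sum_to_one(self, rng):
        labels = [str(rng.choice(["ALA", "GLU", "LYS", "SER"])) for _ in range(17)]
        top, bonds = self._protein_drug_system(labels)
        rows = rank_residues(bonds, top)
        assert sum(r[2] for r in rows) == pytest.approx(1.0, abs=1e-12)

    def test_minor_contributor_flag(self):
        top, bonds = self._protein_drug_system(["GLU"] * 19 + ["ASP"])
        rows = rank_residues(bonds, top)
        by_label = {r[0]: r for r in rows}
        assert by_label["ASP"][3] is False  # 5% < 10%
        assert by_label["GLU"][3] is True
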