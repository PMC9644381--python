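"""Brownian-dynamics synthetic trajectories with planted ground truth.

The generator stands in for an MD engine: rigid quasi-spherical "protein"
bodies carry labelled surface donor/acceptor sites, small rigid "drug"
molecules (one donor, four acceptors, one neutral site) undergo overdamped
translational Brownian motion with assigned diffusivities, and optional
3-site waters diffuse freely.  On top of the free dynamics the generator can
plant

* harmonic tethers pulling selected drugs toward protein surface sites,
* a deterministic protein drift (recorded frame by frame),
* drugs that co-move exactly with the protein,
* hydrogen bonds realized by geometric steering: the scheduled
  donor-hydrogen-acceptor triple is placed inside the detection criterion for
  an exact, seed-deterministic fraction of frames.

Everything planted is returned in a :class:`GroundTruth` record so analysis
modules can be validated against exact answers.

Molecule-id layout is deterministic: proteins get ids ``0..P-1``, drugs
``P..P+D-1``, waters after that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composition import SystemPlan
from .model import (
    KIND_DRUG,
    KIND_PROTEIN,
    KIND_WATER,
    REPORT_UNITS_IN_NM2_PER_PS,
    ROLE_ACCEPTOR,
    ROLE_DONOR,
    ROLE_POLAR_HYDROGEN,
    Atom,
    DomainError,
    Frame,
    Molecule,
    Topology,
    Trajectory,
    wrap_positions,
)

__all__ = [
    "MoleculeTemplate",
    "HBondSchedule",
    "GeneratorConfig",
    "GroundTruth",
    "build_pseudo_protein",
    "build_drug_template",
    "build_water_template",
    "simulate",
    "make_two_layer_fixture",
]

#: Ideal planted donor-acceptor distance (nm), comfortably inside the 0.35 cutoff.
BOND_DISTANCE_NM = 0.29
#: Boltzmann factor k_B*T at 300 K in kJ/mol, for the overdamped tether force.
KT_KJ_MOL = 2.494

DEFAULT_PALETTE = ("ASN", "ASP", "GLN", "GLU", "LYS", "SER", "THR", "TYR")


@dataclass
class MoleculeTemplate:
    """Rigid-body blueprint: local coordinates plus atom annotations."""

    kind: str
    names: list
    elements: list
    masses: np.ndarray
    coords: np.ndarray
    roles: list
    residue_labels: list
    residue_indices: list
    dh_pairs: list  # local (donor_index, hydrogen_index)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def com(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n well-separated unit vectors (golden-spiral construction)."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit vector u onto unit vector v (Rodrigues)."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        k = _skew(axis)
        return np.eye(3) + 2.0 * k @ k
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    k = _skew(axis / s)
    return np.eye(3) + s * k + (1.0 - c) * (k @ k)


def _skew(a: np.ndarray) -> np.ndarray:
    return np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]], dtype=float)


def build_pseudo_protein(
    n_sites: int = 24,
    radius: float = 0.8,
    residue_palette: Sequence[str] = DEFAULT_PALETTE,
    seed: int = 0,
) -> MoleculeTemplate:
    """Rigid quasi-spherical shell of labelled donor/acceptor surface sites.

    Each site is a heavy atom on a sphere of the given radius; donor sites
    carry a hydrogen 0.1 nm further out along the radial direction, so the
    site's donor->hydrogen axis points away from the body.  Residue labels
    are drawn from the palette; site index doubles as residue index.
    """
    if n_sites < 4:
        raise DomainError(f"need at least 4 sites, got {n_sites}")
    if radius <= 0:
        raise DomainError(f"radius must be positive, got {radius}")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_sphere(n_sites)
    names, elements, roles, labels, res_idx, dh_pairs = [], [], [], [], [], []
    coords: list = []
    masses: list = []
    for s in range(n_sites):
        role_kind = rng.choice(["donor", "acceptor", "both"], p=[0.3, 0.4, 0.3])
        label = str(rng.choice(list(residue_palette)))
        heavy_idx = len(coords)
        coords.append(dirs[s] * radius)
        masses.append(110.0)
        names.append(f"S{s + 1}")
        elements.append("N" if role_kind == "donor" else "O")
        labels.append(label)
        res_idx.append(s)
        if role_kind == "donor":
            roles.append(frozenset({ROLE_DONOR}))
        elif role_kind == "acceptor":
            roles.append(frozenset({ROLE_ACCEPTOR}))
        else:
            roles.append(frozenset({ROLE_DONOR, ROLE_ACCEPTOR}))
        if role_kind in ("donor", "both"):
            coords.append(dirs[s] * (radius + 0.1))
            masses.append(1.008)
            names.append(f"H{s + 1}")
            elements.append("H")
            labels.append(label)
            res_idx.append(s)
            roles.append(frozenset({ROLE_POLAR_HYDROGEN}))
            dh_pairs.append((heavy_idx, heavy_idx + 1))
    return MoleculeTemplate(
        kind=KIND_PROTEIN,
        names=names,
        elements=elements,
        masses=np.array(masses),
        coords=np.array(coords),
        roles=roles,
        residue_labels=labels,
        residue_indices=res_idx,
        dh_pairs=dh_pairs,
    )


#: In-plane ring radius of the drug model (nm); chosen so the gyration radius
#: about the in-plane (minor) axes is about 0.22 nm.
DRUG_RING_RADIUS_NM = 0.31
DRUG_MOLAR_MASS = 381.37


def build_drug_template() -> MoleculeTemplate:
    """Rigid planar 6-site drug model: 1 donor (with hydrogen), 4 acceptors,
    1 neutral site.

    Sites sit on a ring of radius 0.31 nm in the xy plane; the donor hydrogen
    extends along +x, so the donor->hydrogen axis of an unrotated drug is
    x-hat.  Heavy-site masses are chosen so the molar mass matches 381.37 Da.
    """
    r = DRUG_RING_RADIUS_NM
    angles = np.deg2rad(np.arange(6) * 60.0)
    ring = np.column_stack([r * np.cos(angles), r * np.sin(angles), np.zeros(6)])
    heavy_mass = (DRUG_MOLAR_MASS - 1.008) / 6.0
    coords = [ring[0], np.array([r + 0.1, 0.0, 0.0])] + [ring[i] for i in range(1, 6)]
    names = ["OD", "HD", "A1", "A2", "A3", "A4", "C1"]
    elements = ["O", "H", "O", "N", "O", "N", "C"]
    masses = np.array([heavy_mass, 1.008] + [heavy_mass] * 5)
    roles = [
        frozenset({ROLE_DONOR}),
        frozenset({ROLE_POLAR_HYDROGEN}),
        frozenset({ROLE_ACCEPTOR}),
        frozenset({ROLE_ACCEPTOR}),
        frozenset({ROLE_ACCEPTOR}),
        frozenset({ROLE_ACCEPTOR}),
        frozenset(),
    ]
    return MoleculeTemplate(
        kind=KIND_DRUG,
        names=names,
        elements=elements,
        masses=masses,
        coords=np.array(coords),
        roles=roles,
        residue_labels=["IND"] * 7,
        residue_indices=[0] * 7,
        dh_pairs=[(0, 1)],
    )


def build_water_template() -> MoleculeTemplate:
    half = np.deg2rad(104.5 / 2.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.09572 * np.cos(half), 0.09572 * np.sin(half), 0.0],
            [0.09572 * np.cos(half), -0.09572 * np.sin(half), 0.0],
        ]
    )
    return MoleculeTemplate(
        kind=KIND_WATER,
        names=["OW", "HW1", "HW2"],
        elements=["O", "H", "H"],
        masses=np.array([15.999, 1.008, 1.008]),
        coords=coords,
        roles=[
            frozenset({ROLE_DONOR, ROLE_ACCEPTOR}),
            frozenset({ROLE_POLAR_HYDROGEN}),
            frozenset({ROLE_POLAR_HYDROGEN}),
        ],
        residue_labels=["SOL"] * 3,
        residue_indices=[0] * 3,
        dh_pairs=[(0, 1), (0, 2)],
    )


@dataclass(frozen=True)
class HBondSchedule:
    """Plant one bond between two molecules at an exact occupancy.

    The drug side of the pair (the acceptor molecule when the donor is a
    protein, otherwise the donor molecule) is positionally steered; the other
    molecule acts as the anchor and must not itself be steered later in the
    schedule list.
    """

    donor_molecule: int
    acceptor_molecule: int
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise DomainError(f"occupancy must be in [0, 1], got {self.occupancy}")


@dataclass
class GeneratorConfig:
    """Knobs for :func:`simulate`.  Diffusivities are in 1e-9 cm^2/s."""

    seed: int = 0
    box_edges: tuple = (6.0, 6.0, 6.0)
    n_frames: int = 2000
    frame_dt: float = 10.0
    n_protein: int = 1
    n_drug: int = 10
    n_water: int = 0
    protein_sites: int = 24
    protein_radius: float = 0.8
    residue_palette: tuple = DEFAULT_PALETTE
    drug_D: float | dict = 0.1
    water_D: float = 1.0
    tethered_fraction: float = 0.0
    tether_k: float = 1.0e5
    drift_per_frame: tuple = (0.0, 0.0, 0.0)
    comoving_drugs: tuple = ()
    hbond_schedules: tuple = ()
    min_separation: float = 1.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.tethered_fraction <= 1.0:
            raise DomainError(f"tethered_fraction must be in [0,1], got {self.tethered_fraction}")
        if self.frame_dt <= 0:
            raise DomainError(f"frame_dt must be positive, got {self.frame_dt}")
        if self.n_frames < 2:
            raise DomainError(f"need at least 2 frames, got {self.n_frames}")

    @classmethod
    def from_plan(cls, plan: SystemPlan, **kwargs) -> "GeneratorConfig":
        return cls(
            n_protein=plan.n_protein, n_drug=plan.n_drug, n_water=plan.n_water, **kwargs
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by molecule / atom-triple."""

    true_D: dict = field(default_factory=dict)
    tethered: dict = field(default_factory=dict)
    bond_occupancy: dict = field(default_factory=dict)
    planted_shell: dict = field(default_factory=dict)
    drift: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    comoving: tuple = ()
    scheduled: tuple = ()

    def to_json(self, path) -> None:
        payload = {
            "true_D": {str(k): v for k, v in self.true_D.items()},
            "tethered": {str(k): v for k, v in self.tethered.items()},
            "bond_occupancy": {
                ",".join(map(str, k)): v for k, v in self.bond_occupancy.items()
            },
            "planted_shell": {str(k): v for k, v in self.planted_shell.items()},
            "drift": self.drift.tolist(),
            "comoving": list(self.comoving),
            "scheduled": list(self.scheduled),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# assembly helpers
# ---------------------------------------------------------------------------


class _Assembler:
    """Accumulates templates into a global Topology."""

    def __init__(self) -> None:
        self.atoms: list = []
        self.molecules: list = []
        self.dh_pairs: list = []
        self.template_of: list = []  # template per molecule (same order as molecules)

    def add(self, template: MoleculeTemplate) -> int:
        base = len(self.atoms)
        mol_id = len(self.molecules)
        for i in range(template.n_atoms):
            self.atoms.append(
                Atom(
                    atom_id=base + i,
                    name=template.names[i],
                    element=template.elements[i],
                    mass=float(template.masses[i]),
                    roles=template.roles[i],
                    residue_label=template.residue_labels[i],
                    residue_index=template.residue_indices[i],
                )
            )
        self.molecules.append(
            Molecule(
                molecule_id=mol_id,
                kind=template.kind,
                atom_ids=tuple(range(base, base + template.n_atoms)),
            )
        )
        for d, h in template.dh_pairs:
            self.dh_pairs.append((base + d, base + h))
        self.template_of.append(template)
        return mol_id

    def topology(self) -> Topology:
        return Topology(self.atoms, self.molecules, self.dh_pairs)


def _grid_cells(box: np.ndarray, spacing: float) -> np.ndarray:
    counts = np.maximum(np.floor(box / spacing).astype(int), 1)
    axes = [np.arange(c) * (box[i] / counts[i]) + 0.5 * box[i] / counts[i] for i, c in enumerate(counts)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _protein_centers(box: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 3))
    if n == 1:
        return box[None, :] * 0.5
    per_axis = int(np.ceil(n ** (1.0 / 3.0)))
    cells = _grid_cells(box, float(box.min()) / per_axis)
    return cells[:n]


def simulate(config: GeneratorConfig):
    """Generate a trajectory plus its planted ground truth.

    Per-step free displacements are sampled with variance ``2*D*dt`` per
    axis; tethered drugs additionally feel an overdamped harmonic pull toward
    their (drifting) rest point; scheduled drugs are positionally steered to
    realize their bond's exact frame mask.  A single RNG stream seeded from
    ``config.seed`` drives everything; molecule order is fixed, so output is
    reproducible.
    """
    rng = np.random.default_rng(config.seed)
    box = np.asarray(config.box_edges, dtype=float)
    n_frames = config.n_frames
    dt = config.frame_dt

    asm = _Assembler()
    protein_templates = [
        build_pseudo_protein(
            config.protein_sites, config.protein_radius, config.residue_palette,
            seed=int(rng.integers(2**31)),
        )
        for _ in range(config.n_protein)
    ]
    for t in protein_templates:
        asm.add(t)
    drug_template = build_drug_template()
    drug_ids = [asm.add(drug_template) for _ in range(config.n_drug)]
    water_template = build_water_template()
    water_ids = [asm.add(water_template) for _ in range(config.n_water)]
    topology = asm.topology()

    # --- placement ---------------------------------------------------------
    protein_centers = _protein_centers(box, config.n_protein)
    cells = _grid_cells(box, config.min_separation)
    if config.n_protein:
        keep = np.ones(len(cells), dtype=bool)
        for c in protein_centers:
            d = cells - c
            d -= box * np.floor(d / box + 0.5)
            keep &= np.sqrt((d * d).sum(axis=1)) > (config.protein_radius + 0.9)
        cells = cells[keep]
    n_mobile = config.n_drug + config.n_water
    if len(cells) < n_mobile:
        raise DomainError(
            f"packing error: {n_mobile} molecules requested but only "
            f"{len(cells)} home cells available at {config.min_separation} nm separation"
        )
    homes = cells[rng.permutation(len(cells))[:n_mobile]]
    drug_homes = homes[: config.n_drug]
    water_homes = homes[config.n_drug :]

    # --- planted roles ------------------------------------------------------
    drift = np.cumsum(
        np.tile(np.asarray(config.drift_per_frame, float), (n_frames, 1)), axis=0
    ) - np.asarray(config.drift_per_frame, float)

    schedules = list(config.hbond_schedules)
    steered: dict = {}  # drug molecule_id -> schedule
    for s in schedules:
        kinds = (
            topology.molecule(s.donor_molecule).kind,
            topology.molecule(s.acceptor_molecule).kind,
        )
        if KIND_DRUG not in kinds:
            raise DomainError("each schedule needs at least one drug molecule")
        mobile = (
            s.acceptor_molecule
            if topology.molecule(s.donor_molecule).kind == KIND_PROTEIN
            else s.donor_molecule
        )
        if mobile in steered:
            raise DomainError(f"drug molecule {mobile} steered by more than one schedule")
        steered[mobile] = s

    comoving = set(config.comoving_drugs)
    free_pool = [m for m in drug_ids if m not in steered and m not in comoving]
    n_tethered = int(round(config.tethered_fraction * len(free_pool)))
    tether_choice = rng.permutation(len(free_pool))[:n_tethered]
    tethered_ids = {free_pool[i] for i in tether_choice}

    d_assign: dict = {}
    for m in drug_ids:
        if isinstance(config.drug_D, dict):
            d_assign[m] = float(config.drug_D.get(m, 0.1))
        else:
            d_assign[m] = float(config.drug_D)

    # --- paths --------------------------------------------------------------
    com_paths: dict = {}
    rotations: dict = {}
    truth = GroundTruth(drift=drift, comoving=tuple(sorted(comoving)), scheduled=tuple(sorted(steered)))
    protein_site_info: dict = {}  # mol_id -> (heavy atom positions at t0, radial dirs)
    for mol_id in range(config.n_protein):
        center = protein_centers[mol_id]
        tmpl = protein_templates[mol_id]
        com_paths[mol_id] = center + drift
        rotations[mol_id] = np.eye(3)

    tether_info: dict = {}
    if tethered_ids and config.n_protein == 0:
        raise DomainError("tethering requested but no protein in the box")
    for mol_id in sorted(tethered_ids):
        p_idx = int(rng.integers(config.n_protein))
        site = int(rng.integers(config.protein_sites))
        direction = _fibonacci_sphere(config.protein_sites)[site]
        rest0 = protein_centers[p_idx] + direction * (config.protein_radius + 0.6)
        tether_info[mol_id] = {
            "protein": p_idx,
            "site": site,
            "rest_point": rest0.tolist(),
        }

    for mol_id in drug_ids:
        d_nm = d_assign[mol_id] * REPORT_UNITS_IN_NM2_PER_PS
        home = drug_homes[mol_id - config.n_protein]
        if mol_id in comoving:
            com_paths[mol_id] = home + drift
            rotations[mol_id] = np.eye(3)
        elif mol_id in steered:
            com_paths[mol_id] = np.tile(home, (n_frames, 1))  # overwritten below
            rotations[mol_id] = np.eye(3)
        elif mol_id in tethered_ids:
            sigma = np.sqrt(2.0 * d_nm * dt)
            noise = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
            mobility = d_nm / KT_KJ_MOL
            rest0 = np.array(tether_info[mol_id]["rest_point"])
            path = np.empty((n_frames, 3))
            path[0] = rest0
            for f in range(1, n_frames):
                rest = rest0 + drift[f]
                path[f] = (
                    path[f - 1]
                    - mobility * config.tether_k * (path[f - 1] - rest) * dt
                    + noise[f - 1]
                )
            com_paths[mol_id] = path
            rotations[mol_id] = np.eye(3)
        else:
            sigma = np.sqrt(2.0 * d_nm * dt)
            steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
            path = np.empty((n_frames, 3))
            path[0] = home
            path[1:] = home + np.cumsum(steps, axis=0)
            com_paths[mol_id] = path
            rotations[mol_id] = np.eye(3)
        truth.true_D[mol_id] = d_assign[mol_id]
        truth.tethered[mol_id] = tether_info.get(mol_id)

    for mol_id in water_ids:
        d_nm = config.water_D * REPORT_UNITS_IN_NM2_PER_PS
        home = water_homes[mol_id - config.n_protein - config.n_drug]
        sigma = np.sqrt(2.0 * d_nm * dt)
        steps = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
        path = np.empty((n_frames, 3))
        path[0] = home
        path[1:] = home + np.cumsum(steps, axis=0)
        com_paths[mol_id] = path
        rotations[mol_id] = np.eye(3)

    # --- schedules ----------------------------------------------------------
    anchor_site_counter: dict = {}
    for s in schedules:
        _apply_schedule(
            s,
            topology,
            asm,
            com_paths,
            rotations,
            truth,
            rng,
            n_frames,
            anchor_site_counter,
            steered,
        )

    # --- assemble frames ----------------------------------------------------
    n_atoms = topology.n_atoms
    positions = np.empty((n_frames, n_atoms, 3))
    for mol in topology.molecules:
        tmpl = asm.template_of[mol.molecule_id]
        rot = rotations[mol.molecule_id]
        local = (tmpl.coords - tmpl.com()) @ rot.T
        idx = list(mol.atom_ids)
        path = com_paths[mol.molecule_id]
        if path.ndim == 2:
            positions[:, idx, :] = path[:, None, :] + local[None, :, :]
        else:  # (F, n_atoms, 3) fully-specified per-frame coordinates
            positions[:, idx, :] = path
    frames = [
        Frame(time=f * dt, box=box, positions=wrap_positions(positions[f], box))
        for f in range(n_frames)
    ]
    return Trajectory(frames, topology=topology), truth


def _first_atom_with_role(topology: Topology, mol_id: int, role: str, skip: int = 0) -> int:
    hits = [
        a
        for a in topology.molecule(mol_id).atom_ids
        if role in topology.atoms[a].roles
    ]
    if not hits:
        raise DomainError(f"molecule {mol_id} has no atom with role {role}")
    return hits[skip % len(hits)]


def _apply_schedule(
    s: HBondSchedule,
    topology: Topology,
    asm: _Assembler,
    com_paths: dict,
    rotations: dict,
    truth: GroundTruth,
    rng: np.random.Generator,
    n_frames: int,
    anchor_site_counter: dict,
    steered: dict,
) -> None:
    """Realize one planted bond by steering the mobile drug's path."""
    donor_kind = topology.molecule(s.donor_molecule).kind
    mobile = s.acceptor_molecule if donor_kind == KIND_PROTEIN else s.donor_molecule
    anchor = s.donor_molecule if mobile == s.acceptor_molecule else s.acceptor_molecule

    k = int(round(s.occupancy * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    mask[rng.permutation(n_frames)[:k]] = True

    skip = anchor_site_counter.get(anchor, 0)
    anchor_site_counter[anchor] = skip + 1
    anchor_tmpl = asm.template_of[anchor]
    anchor_rot = rotations[anchor]
    anchor_path = com_paths[anchor]
    if anchor_path.ndim != 2:
        raise DomainError("schedule anchors must be rigid-translation molecules")

    mobile_tmpl = asm.template_of[mobile]
    mobile_local = mobile_tmpl.coords - mobile_tmpl.com()
    home_path = com_paths[mobile]

    if mobile == s.donor_molecule:
        # drug donor -> anchor acceptor: orient the drug's D->H axis toward
        # the acceptor and park the donor one bond length outside it
        acc_atom = _first_atom_with_role(topology, anchor, ROLE_ACCEPTOR, skip)
        acc_local = (
            asm.template_of[anchor].coords[_local_index(topology, anchor, acc_atom)]
            - anchor_tmpl.com()
        ) @ anchor_rot.T
        out_dir = _outward(acc_local)
        don_atom = _first_atom_with_role(topology, mobile, ROLE_DONOR)
        hyd_atom = _hydrogen_of(topology, don_atom)
        d_loc = mobile_local[_local_index(topology, mobile, don_atom)]
        h_loc = mobile_local[_local_index(topology, mobile, hyd_atom)]
        u_dh = (h_loc - d_loc) / np.linalg.norm(h_loc - d_loc)
        rot = _rotation_between(u_dh, -out_dir)
        rotations[mobile] = rot
        donor_target = anchor_path + acc_local + BOND_DISTANCE_NM * out_dir
        bonded_com = donor_target - rot @ d_loc
        triple = (don_atom, hyd_atom, acc_atom)
    else:
        # anchor donor -> drug acceptor: park the drug's acceptor one bond
        # length along the anchor's D->H axis
        don_atom = _first_atom_with_role(topology, anchor, ROLE_DONOR, skip)
        hyd_atom = _hydrogen_of(topology, don_atom)
        d_local = (
            asm.template_of[anchor].coords[_local_index(topology, anchor, don_atom)]
            - anchor_tmpl.com()
        ) @ anchor_rot.T
        h_local = (
            asm.template_of[anchor].coords[_local_index(topology, anchor, hyd_atom)]
            - anchor_tmpl.com()
        ) @ anchor_rot.T
        u = (h_local - d_local) / np.linalg.norm(h_local - d_local)
        # use the acceptor diametrically opposite the drug's donor and point
        # it at the anchor, so the rest of the drug (donor included) faces away
        acc_atom = _first_atom_with_role(topology, mobile, ROLE_ACCEPTOR, skip=2)
        a_loc = mobile_local[_local_index(topology, mobile, acc_atom)]
        rot = _rotation_between(_outward(a_loc), -u)
        rotations[mobile] = rot
        acc_target = anchor_path + d_local + BOND_DISTANCE_NM * u
        bonded_com = acc_target - rot @ a_loc
        triple = (don_atom, hyd_atom, acc_atom)

    path = np.where(mask[:, None], bonded_com, home_path)
    com_paths[mobile] = path
    truth.bond_occupancy[triple] = k / n_frames
    truth.true_D[mobile] = truth.true_D.get(mobile)


def _local_index(topology: Topology, mol_id: int, atom_id: int) -> int:
    return list(topology.molecule(mol_id).atom_ids).index(atom_id)


def _hydrogen_of(topology: Topology, donor_atom: int) -> int:
    for d, h in topology.donor_hydrogen_pairs:
        if d == donor_atom:
            return h
    raise DomainError(f"donor atom {donor_atom} has no paired hydrogen")


def _outward(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def make_two_layer_fixture(
    n_first_shell: int,
    n_second_layer: int,
    seed: int = 0,
    n_frames: int = 50,
    frame_dt: float = 10.0,
    box_edges: tuple = (6.0, 6.0, 6.0),
    protein_radius: float = 0.8,
):
    """Static fixture with planted first-shell and second-layer drugs.

    First-shell drugs sit with their innermost atom about 0.28 nm from the
    protein surface (atom-atom contact well inside 0.4 nm); second-layer
    drugs sit at a 0.65-0.85 nm surface gap, jittered per molecule.  Drug
    rings are rotated edge-on to the radial direction so the planted gap is
    the actual nearest-atom distance (up to the 0.1 nm donor hydrogens).
    """
    if n_first_shell < 0 or n_second_layer < 0:
        raise DomainError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    box = np.asarray(box_edges, dtype=float)
    n_total = n_first_shell + n_second_layer
    n_sites = max(32, n_total)

    asm = _Assembler()
    protein_tmpl = build_pseudo_protein(
        n_sites=n_sites, radius=protein_radius, seed=seed
    )
    asm.add(protein_tmpl)
    drug_tmpl = build_drug_template()
    drug_ids = [asm.add(drug_tmpl) for _ in range(n_total)]
    topology = asm.topology()

    center = box * 0.5
    dirs = _fibonacci_sphere(n_sites)
    order = rng.permutation(n_sites)[:n_total]
    labels = ["first_shell"] * n_first_shell + ["second_layer"] * n_second_layer
    rng.shuffle(labels)

    drug_local = drug_tmpl.coords - drug_tmpl.com()
    positions = np.empty((topology.n_atoms, 3))
    positions[list(topology.molecule(0).atom_ids)] = protein_tmpl.coords - protein_tmpl.com() + center

    truth = GroundTruth(drift=np.zeros((n_frames, 3)))
    for mol_id, site, label in zip(drug_ids, order, labels):
        r_hat = dirs[site]
        if label == "first_shell":
            gap = 0.28
        else:
            gap = float(rng.uniform(0.65, 0.85))
        rot = _rotation_between(np.array([1.0, 0.0, 0.0]), r_hat)
        com = center + r_hat * (protein_radius + gap + DRUG_RING_RADIUS_NM)
        positions[list(topology.molecule(mol_id).atom_ids)] = com + drug_local @ rot.T
        truth.planted_shell[mol_id] = label
        truth.true_D[mol_id] = 0.0
        truth.tethered[mol_id] = None

    frames = [
        Frame(time=f * frame_dt, box=box, positions=wrap_positions(positions, box))
        for f in range(n_frames)
    ]
    return Trajectory(frames, topology=topology), truth
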