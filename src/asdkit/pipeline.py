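"""Full-analysis orchestration: shells -> H-bonds -> generations -> mobility.

One declarative :class:`RunConfig` drives every stage with the standard
defaults (0.35 nm / 30 deg detection, strict 0.80/0.50 stability, 0.4 nm
shells, 1/5/10 Angstrom displacement classes, 10-50% lag fit window); every
artifact records the exact parameters in a JSON manifest so any output is
traceable to its thresholds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import hbond as hb
from . import mobility as mb
from . import spatial as sp
from .io import read_topology, read_trajectory
from .model import KIND_DRUG, KIND_PROTEIN, AsdkitError, DomainError, Trajectory

__all__ = [
    "RunConfig",
    "StageError",
    "ReportBundle",
    "resolve_window",
    "analyze_trajectory",
    "run_full_analysis",
    "crosstab_mobility_bonding",
]

logger = logging.getLogger("asdkit.pipeline")

ARTIFACTS = (
    "shell_table.tsv",
    "distance_histogram.tsv",
    "existence_matrix.tsv",
    "hbond_index.json",
    "stable_bonds.tsv",
    "generations.tsv",
    "residue_ranking.tsv",
    "diffusivity_records.tsv",
    "group_summary.json",
    "diffusivity_histogram.tsv",
    "crosstab.tsv",
)


class StageError(AsdkitError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Declarative configuration for one full analysis run."""

    traj_path: str = ""
    top_path: str = ""
    format: str = "extxyz"
    window: str = "all"  # "all", "last:N", or "START:STOP" frame indices
    d_cut: float = hb.D_CUT_NM
    angle_cut: float = hb.ANGLE_CUT_DEG
    vertex: str = "donor"
    threshold_protein_drug: float = hb.THRESHOLD_PROTEIN_DRUG
    threshold_other: float = hb.THRESHOLD_OTHER
    shell_width: float = sp.SHELL_WIDTH_NM
    fds_cut: float = sp.FDS_CUT_NM
    histogram_bin_width: float = 0.05
    displacement_thresholds: tuple = mb.DEFAULT_DISPLACEMENT_THRESHOLDS_A
    fit_window: tuple = mb.DEFAULT_FIT_WINDOW
    max_lag_fraction: float = mb.DEFAULT_MAX_LAG_FRACTION
    max_generation: int | None = None
    seed: int = 0
    out_dir: str = "asd_out"

    def __post_init__(self) -> None:
        for name in ("d_cut", "angle_cut", "shell_width", "fds_cut", "histogram_bin_width"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise DomainError(f"unknown config keys: {sorted(unknown)}")
        for key in ("displacement_thresholds", "fit_window"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def resolve_window(spec: str, n_frames: int) -> list:
    """Resolve a window spec against a trajectory length.

    ``"all"``, ``"last:N"``, or ``"START:STOP"`` (0-based, half-open).
    """
    if spec == "all":
        return list(range(n_frames))
    if spec.startswith("last:"):
        n = int(spec.split(":", 1)[1])
        if n <= 0 or n > n_frames:
            raise DomainError(f"window {spec!r} not resolvable against {n_frames} frames")
        return list(range(n_frames - n, n_frames))
    if ":" in spec:
        a, b = spec.split(":", 1)
        start, stop = int(a), int(b)
        if not (0 <= start < stop <= n_frames):
            raise DomainError(f"window {spec!r} not resolvable against {n_frames} frames")
        return list(range(start, stop))
    raise DomainError(f"bad window spec {spec!r}")


@dataclass
class ReportBundle:
    """In-memory results of a full analysis."""

    window: list
    shell_table: pd.DataFrame
    distance_histogram: tuple
    matrix: hb.HBondExistenceMatrix
    stable_bonds: set
    generations: dict
    residue_ranking: list
    records: list
    drift: np.ndarray
    group_summary: dict
    distribution: dict
    crosstab: pd.DataFrame
    displacement_table: pd.DataFrame


def _bonded_status(mol_id: int, generations: dict, stable_bonds: set) -> str:
    g = generations.get(mol_id)
    if g == 1:
        return "gen1"
    if g == 2:
        return "gen2"
    for b in stable_bonds:
        if mol_id in (b.donor_molecule_id, b.acceptor_molecule_id):
            return "bonded"
    return "nonbonded"


def analyze_trajectory(trajectory: Trajectory, config: RunConfig) -> ReportBundle:
    """Run every stage on an in-memory trajectory."""
    if trajectory.topology is None:
        raise DomainError("trajectory needs an attached topology")
    window = resolve_window(config.window, trajectory.n_frames)
    top = trajectory.topology
    has_protein = bool(top.molecules_of_kind(KIND_PROTEIN))

    def stage(name, fn):
        logger.info("stage %s starting", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc

    if has_protein:
        shell_table = stage(
            "shells",
            lambda: sp.build_shell_table(trajectory, window, config.shell_width, config.fds_cut),
        )
        hist = stage(
            "distance_histogram",
            lambda: sp.distance_histogram(
                trajectory, window, bin_width=config.histogram_bin_width, shell_table=shell_table
            ),
        )
    else:
        shell_table = pd.DataFrame(
            columns=[
                "molecule_id", "frame_index", "frame_time",
                "min_dist_com", "min_dist_atom", "shell_index", "fds_flag",
            ]
        )
        hist = (np.empty(0), np.empty(0))

    matrix = stage(
        "hbond_matrix",
        lambda: hb.build_existence_matrix(
            trajectory, window, config.d_cut, config.angle_cut, config.vertex
        ),
    )
    stable = stage(
        "stability",
        lambda: hb.classify_stable(matrix, config.threshold_protein_drug, config.threshold_other),
    )
    generations = stage(
        "generations",
        lambda: hb.assign_generations(stable, top, config.max_generation),
    )
    ranking = stage("residue_ranking", lambda: hb.rank_residues(matrix, top, stable_only=False))

    def mobility_stage():
        series = mb.com_series(trajectory, window)
        referenced, drift = mb.subtract_protein_motion(series)
        records = mb.diffusivity_records(
            referenced, KIND_DRUG, config.max_lag_fraction, config.fit_window
        )
        first_frame = window[0]
        shell_at_start = (
            shell_table[shell_table.frame_index == first_frame]
            .set_index("molecule_id")["shell_index"]
            .to_dict()
            if not shell_table.empty
            else {}
        )
        for rec in records:
            rec.groups["shell"] = shell_at_start.get(rec.molecule_id)
            rec.groups["bonded_status"] = _bonded_status(rec.molecule_id, generations, stable)
        drug_cols = referenced.indices_of_kind(KIND_DRUG)
        disp = mb.displacement_classes(
            referenced.coms[:, drug_cols],
            [int(i) for i in referenced.molecule_ids[drug_cols]],
            config.displacement_thresholds,
        )
        return series, referenced, drift, records, disp

    _, referenced, drift, records, disp_table = stage("mobility", mobility_stage)

    group_summary = stage(
        "grouping",
        lambda: {
            "by_shell": mb.group_diffusivity(records, "shell"),
            "by_bonded_status": mb.group_diffusivity(records, "bonded_status"),
            "all": mb.group_diffusivity(records, lambda r: "all"),
            "excluding_gen12": mb.group_diffusivity(
                records,
                lambda r: "kept" if r.groups["bonded_status"] not in ("gen1", "gen2") else None,
            ),
            "excluding_bonded": mb.group_diffusivity(
                records,
                lambda r: "kept" if r.groups["bonded_status"] == "nonbonded" else None,
            ),
        },
    )
    distribution = (
        stage("distribution", lambda: mb.diffusivity_distribution(records)) if records else {}
    )
    crosstab = stage("crosstab", lambda: crosstab_mobility_bonding(records))

    return ReportBundle(
        window=window,
        shell_table=shell_table,
        distance_histogram=hist,
        matrix=matrix,
        stable_bonds=stable,
        generations=generations,
        residue_ranking=ranking,
        records=records,
        drift=drift,
        group_summary=group_summary,
        distribution=distribution,
        crosstab=crosstab,
        displacement_table=disp_table,
    )


def crosstab_mobility_bonding(records: Sequence[mb.DiffusivityRecord]) -> pd.DataFrame:
    """Mean diffusivity and count by (shell x bonded_status); empty cells NaN."""
    if not records:
        return pd.DataFrame(columns=["shell", "bonded_status", "mean_D", "count"])
    rows = [
        {
            "shell": r.groups.get("shell"),
            "bonded_status": r.groups.get("bonded_status"),
            "D": r.D,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["shell", "bonded_status"], dropna=False)["D"]
        .agg(mean_D="mean", count="count")
        .reset_index()
    )
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Load inputs, run every stage, write all artifacts; returns the manifest.

    On a stage failure, previously written artifacts are kept, a ``FAILED``
    marker naming the stage is written, and the :class:`StageError`
    propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        topology = read_topology(config.top_path)
        trajectory = read_trajectory(config.traj_path, config.format, topology=topology)
        bundle = analyze_trajectory(trajectory, config)
        _write_bundle(bundle, trajectory, out, config)
    except StageError as exc:
        (out / "FAILED").write_text(f"stage: {exc.stage}\nerror: {exc.cause}\n")
        raise
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: input\nerror: {exc}\n")
        raise StageError("input", exc) from exc

    manifest = {
        "artifacts": list(ARTIFACTS) + ["manifest.json"],
        "parameters": asdict(config),
        "n_frames": trajectory.n_frames,
        "window_frames": [bundle.window[0], bundle.window[-1]],
        "n_molecules": len(trajectory.topology.molecules),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _write_bundle(bundle: ReportBundle, trajectory: Trajectory, out: Path, config: RunConfig) -> None:
    top = trajectory.topology
    bundle.shell_table.to_csv(out / "shell_table.tsv", sep="\t", index=False, float_format="%.6f")

    edges, fractions = bundle.distance_histogram
    with open(out / "distance_histogram.tsv", "w") as fh:
        fh.write("bin_lo\tbin_hi\tfraction\n")
        for lo, hi, f in zip(edges[:-1], edges[1:], fractions):
            fh.write(f"{lo:.6f}\t{hi:.6f}\t{f:.8f}\n")

    hb.write_existence_matrix(bundle.matrix, top, out / "existence_matrix.tsv", out / "hbond_index.json")

    with open(out / "stable_bonds.tsv", "w") as fh:
        fh.write("donor_atom\thydrogen_atom\tacceptor_atom\tdonor_molecule\tacceptor_molecule\tpair_class\toccupancy\n")
        for t in sorted(bundle.stable_bonds):
            occ = bundle.matrix.occupancy_of(t)
            fh.write(
                f"{t.donor_atom_id + 1}\t{t.hydrogen_atom_id + 1}\t{t.acceptor_atom_id + 1}\t"
                f"{t.donor_molecule_id + 1}\t{t.acceptor_molecule_id + 1}\t{t.pair_class}\t{occ:.6f}\n"
            )

    with open(out / "generations.tsv", "w") as fh:
        fh.write("molecule_id\tgeneration\n")
        for mid in sorted(bundle.generations):
            g = bundle.generations[mid]
            fh.write(f"{mid + 1}\t{'none' if g is None else g}\n")

    with open(out / "residue_ranking.tsv", "w") as fh:
        fh.write("residue_label\tcount\tfraction\tmajor\n")
        for label, count, frac, major in bundle.residue_ranking:
            fh.write(f"{label}\t{count:.6f}\t{frac:.6f}\t{int(major)}\n")

    with open(out / "diffusivity_records.tsv", "w") as fh:
        fh.write("molecule_id\tD_1e-9_cm2_s\tfit_r2\tclipped\tshell\tbonded_status\n")
        for r in bundle.records:
            fh.write(
                f"{r.molecule_id + 1}\t{r.D:.8g}\t{r.fit_r2:.6f}\t{int(r.clipped)}\t"
                f"{r.groups.get('shell')}\t{r.groups.get('bonded_status')}\n"
            )

    with open(out / "group_summary.json", "w") as fh:
        json.dump(bundle.group_summary, fh, indent=1, default=str)

    with open(out / "diffusivity_histogram.tsv", "w") as fh:
        fh.write("quantile\tcumulative_fraction\n")
        if bundle.distribution:
            for q, c in zip(
                bundle.distribution["cum_quantiles"], bundle.distribution["cum_fractions"]
            ):
                fh.write(f"{q:.8f}\t{c:.8f}\n")

    bundle.crosstab.to_csv(out / "crosstab.tsv", sep="\t", index=False, float_format="%.8g")
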