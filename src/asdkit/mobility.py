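"""Per-molecule mobility analysis.

The pipeline here is: (1) build continuous (unwrapped) center-of-mass series
from the wrapped trajectory by accumulating minimum-image displacements
between consecutive frames; (2) optionally transform into the protein
reference frame by subtracting the protein-set center-of-mass displacement;
(3) compute time-origin-averaged mean squared displacements and fit the
Einstein relation ``MSD = 6 D tau`` over a lag window; (4) aggregate fitted
diffusivities by group and summarize their distribution.

Diffusivities are reported in units of 1e-9 cm^2/s (1 nm^2/ps = 1e7 of
these units).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    KIND_DRUG,
    KIND_PROTEIN,
    NM2_PER_PS_IN_REPORT_UNITS,
    DomainError,
    Topology,
    Trajectory,
    minimum_image_displacement,
)

__all__ = [
    "ComSeries",
    "com_series",
    "atom_series",
    "subtract_protein_motion",
    "per_molecule_msd",
    "fit_diffusivity",
    "DiffusivityRecord",
    "diffusivity_records",
    "group_diffusivity",
    "diffusivity_distribution",
    "displacement_classes",
]

DEFAULT_FIT_WINDOW = (0.1, 0.5)
DEFAULT_MAX_LAG_FRACTION = 0.5
DEFAULT_DISPLACEMENT_THRESHOLDS_A = (1.0, 5.0, 10.0)


@dataclass
class ComSeries:
    """Continuous center-of-mass paths for every molecule.

    ``coms`` has shape (n_frames, n_molecules, 3) in nm and is *unwrapped*:
    consecutive frames differ by true displacements, not wrapped jumps.
    """

    times: np.ndarray
    molecule_ids: np.ndarray
    kinds: list
    mol_masses: np.ndarray
    coms: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.coms.shape[0]

    def indices_of_kind(self, kind: str) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == kind], dtype=int)

    def column(self, molecule_id: int) -> int:
        hits = np.nonzero(self.molecule_ids == molecule_id)[0]
        if hits.size != 1:
            raise KeyError(f"molecule {molecule_id} not in series")
        return int(hits[0])


def _grouped_molecule_indices(topology: Topology):
    """Group molecules by atom count so unwrapping vectorizes per group."""
    groups: dict = {}
    for mol in topology.molecules:
        groups.setdefault(mol.n_atoms, []).append(mol)
    return groups


def com_series(trajectory: Trajectory, window: Sequence[int] | None = None) -> ComSeries:
    """Build unwrapped COM paths for all molecules over the window."""
    top = trajectory.topology
    if top is None:
        raise DomainError("trajectory has no topology attached")
    frames_idx = list(range(trajectory.n_frames)) if window is None else list(window)
    if not frames_idx:
        raise DomainError("empty analysis window")

    groups = _grouped_molecule_indices(top)
    mol_order = [m for n in sorted(groups) for m in groups[n]]
    mol_ids = np.array([m.molecule_id for m in mol_order], dtype=int)
    kinds = [m.kind for m in mol_order]
    mol_masses = np.array([top.molar_mass(m) for m in mol_order], dtype=float)

    n_frames = len(frames_idx)
    n_mol = len(mol_order)
    coms = np.empty((n_frames, n_mol, 3))
    col0 = 0
    for n_atoms in sorted(groups):
        mols = groups[n_atoms]
        idx = np.array([list(m.atom_ids) for m in mols], dtype=int)  # (M, n)
        masses = top.masses[idx]  # (M, n)
        msum = masses.sum(axis=1)
        raw = np.empty((n_frames, len(mols), 3))
        for fi_out, fi in enumerate(frames_idx):
            frame = trajectory.frames[fi]
            pos = frame.positions[idx]  # (M, n, 3)
            whole = np.empty_like(pos)
            whole[:, 0] = pos[:, 0]
            for a in range(1, n_atoms):
                whole[:, a] = whole[:, a - 1] + minimum_image_displacement(
                    pos[:, a] - whole[:, a - 1], frame.box
                )
            raw[fi_out] = np.einsum("man,ma->mn", whole, masses) / msum[:, None]
        # accumulate minimum-image COM displacements into a continuous path
        cont = np.empty_like(raw)
        cont[0] = raw[0]
        for f in range(1, n_frames):
            box = trajectory.frames[frames_idx[f]].box
            cont[f] = cont[f - 1] + minimum_image_displacement(raw[f] - raw[f - 1], box)
        coms[:, col0 : col0 + len(mols)] = cont
        col0 += len(mols)

    # restore molecule-id ordering of columns
    order = np.argsort(mol_ids, kind="stable")
    return ComSeries(
        times=trajectory.times[frames_idx],
        molecule_ids=mol_ids[order],
        kinds=[kinds[i] for i in order],
        mol_masses=mol_masses[order],
        coms=coms[:, order],
    )


def atom_series(trajectory: Trajectory, window: Sequence[int] | None = None) -> np.ndarray:
    """Continuous per-atom coordinates (n_frames, n_atoms, 3).

    Atoms are re-wholed per molecule and shifted so each molecule's COM
    follows its unwrapped path; valid for rigid or near-rigid molecules.
    """
    top = trajectory.topology
    if top is None:
        raise DomainError("trajectory has no topology attached")
    series = com_series(trajectory, window)
    frames_idx = list(range(trajectory.n_frames)) if window is None else list(window)
    out = np.empty((len(frames_idx), top.n_atoms, 3))
    col_of = {int(mid): i for i, mid in enumerate(series.molecule_ids)}
    for fi_out, fi in enumerate(frames_idx):
        frame = trajectory.frames[fi]
        for mol in top.molecules:
            idx = list(mol.atom_ids)
            pos = frame.positions[idx]
            whole = np.empty_like(pos)
            whole[0] = pos[0]
            for a in range(1, len(idx)):
                whole[a] = whole[a - 1] + minimum_image_displacement(
                    pos[a] - whole[a - 1], frame.box
                )
            masses = top.masses[idx]
            com_local = masses @ whole / masses.sum()
            out[fi_out, idx] = whole - com_local + series.coms[fi_out, col_of[mol.molecule_id]]
    return out


def subtract_protein_motion(series: ComSeries):
    """Transform COM paths into the protein reference frame.

    Subtracts, per frame, the displacement of the mass-weighted COM of all
    protein molecules relative to the first window frame.  Returns
    ``(referenced_series, drift)`` where ``drift`` is the subtracted (F, 3)
    protein displacement.  Without protein molecules the transform is the
    identity and a warning is issued.
    """
    prot_cols = series.indices_of_kind(KIND_PROTEIN)
    if prot_cols.size == 0:
        warnings.warn("no protein molecules; protein-frame transform is the identity")
        drift = np.zeros((series.n_frames, 3))
        return series, drift
    w = series.mol_masses[prot_cols]
    prot_com = np.einsum("fmn,m->fn", series.coms[:, prot_cols], w) / w.sum()
    drift = prot_com - prot_com[0]
    referenced = ComSeries(
        times=series.times.copy(),
        molecule_ids=series.molecule_ids.copy(),
        kinds=list(series.kinds),
        mol_masses=series.mol_masses.copy(),
        coms=series.coms - drift[:, None, :],
    )
    return referenced, drift


# ---------------------------------------------------------------------------
# MSD and diffusivity
# ---------------------------------------------------------------------------


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one path (F, 3) for all lags 0..F-1.

    Uses the FFT decomposition MSD(m) = S1(m) - 2*S2(m) with S2 the summed
    per-axis autocorrelation; O(F log F).
    """
    n = r.shape[0]
    sq = (r * r).sum(axis=1)
    csum = np.concatenate(([0.0], np.cumsum(sq)))
    total = csum[-1]
    m = np.arange(n)
    # sum_{t=0}^{n-m-1} (sq[t] + sq[t+m])
    s1 = (csum[n - m] + (total - csum[m])) / (n - m)
    f = np.fft.rfft(r, 2 * n, axis=0)
    acf = np.fft.irfft(f * f.conj(), axis=0)[:n].sum(axis=1)
    s2 = acf / (n - m)
    msd = s1 - 2.0 * s2
    msd[0] = 0.0
    return np.maximum(msd, 0.0)


def per_molecule_msd(
    coms: np.ndarray,
    times: np.ndarray,
    max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
):
    """MSD curve for one molecule's (F, 3) path; all time origins.

    Returns ``(lags_ps, msd_nm2)`` for lags up to ``max_lag_fraction`` of the
    window.  Requires at least 10 uniformly spaced frames.
    """
    coms = np.asarray(coms, dtype=float)
    times = np.asarray(times, dtype=float)
    if coms.shape[0] < 10:
        raise DomainError(f"need at least 10 frames for an MSD, got {coms.shape[0]}")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise DomainError("MSD requires uniform frame spacing")
    msd = _msd_fft(coms)
    n_lags = max(2, int(np.floor(max_lag_fraction * (coms.shape[0] - 1))) + 1)
    lags = np.arange(n_lags) * dts[0]
    return lags, msd[:n_lags]


def fit_diffusivity(
    lags: np.ndarray,
    msd: np.ndarray,
    window_duration: float,
    fit_window: tuple = DEFAULT_FIT_WINDOW,
):
    """Least-squares Einstein fit over lags in ``fit_window`` (fractions of
    the analysis-window duration).

    Returns ``(D, r2, clipped)`` with D in 1e-9 cm^2/s; negative slopes are
    clipped to zero and flagged.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    lo, hi = fit_window
    mask = (lags >= lo * window_duration) & (lags <= hi * window_duration)
    if mask.sum() < 2:
        raise DomainError(
            f"degenerate fit window: {int(mask.sum())} lag points in "
            f"[{lo * window_duration}, {hi * window_duration}] ps"
        )
    x = lags[mask]
    y = msd[mask]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    d_nm2_ps = slope / 6.0
    clipped = d_nm2_ps < 0
    d_report = max(d_nm2_ps, 0.0) * NM2_PER_PS_IN_REPORT_UNITS
    return float(d_report), float(r2), bool(clipped)


@dataclass
class DiffusivityRecord:
    """Fitted diffusivity for one molecule plus its grouping labels."""

    molecule_id: int
    lags: np.ndarray
    msd: np.ndarray
    D: float
    fit_r2: float
    clipped: bool
    groups: dict = field(default_factory=dict)


def diffusivity_records(
    series: ComSeries,
    kind: str = KIND_DRUG,
    max_lag_fraction: float = DEFAULT_MAX_LAG_FRACTION,
    fit_window: tuple = DEFAULT_FIT_WINDOW,
) -> list:
    """Fit per-molecule diffusivities for all molecules of one kind."""
    cols = series.indices_of_kind(kind)
    window_duration = float(series.times[-1] - series.times[0])
    records = []
    for c in cols:
        lags, msd = per_molecule_msd(series.coms[:, c], series.times, max_lag_fraction)
        d, r2, clipped = fit_diffusivity(lags, msd, window_duration, fit_window)
        records.append(
            DiffusivityRecord(
                molecule_id=int(series.molecule_ids[c]),
                lags=lags,
                msd=msd,
                D=d,
                fit_r2=r2,
                clipped=clipped,
                groups={"kind": kind},
            )
        )
    return records


def group_diffusivity(
    records: Sequence[DiffusivityRecord],
    label_of: str | Callable,
    expected_groups: Sequence | None = None,
) -> dict:
    """Arithmetic-mean D per group.

    ``label_of`` is a group-label name (looked up in ``record.groups``) or a
    callable ``record -> label``.  Records whose label is None are skipped.
    Groups listed in ``expected_groups`` but absent are reported with count 0
    and mean None.
    """
    if callable(label_of):
        get = label_of
    else:
        get = lambda rec: rec.groups.get(label_of)
    buckets: dict = {}
    for rec in records:
        label = get(rec)
        if label is None:
            continue
        buckets.setdefault(label, []).append(rec.D)
    out = {}
    labels = set(buckets) | set(expected_groups or ())
    for label in labels:
        ds = buckets.get(label, [])
        out[label] = {
            "mean_D": float(np.mean(ds)) if ds else None,
            "count": len(ds),
        }
    return out


def diffusivity_distribution(records: Sequence[DiffusivityRecord], bin_width: float | None = None) -> dict:
    """Histogram plus cumulative-contribution summary of per-molecule D.

    The cumulative curve sorts molecules by D ascending and plots the running
    share of the summed diffusivity against the molecule quantile; ``d90`` is
    the D level at which the curve crosses 90% of the total (0 when every
    molecule is immobile, in which case the curve degenerates to the
    diagonal).
    """
    if not records:
        raise DomainError("need at least one diffusivity record")
    ds = np.array([r.D for r in records], dtype=float)
    n = ds.size
    order = np.argsort(ds, kind="stable")
    sorted_d = ds[order]
    total = sorted_d.sum()
    quantiles = np.arange(1, n + 1) / n
    if total > 0:
        cum = np.cumsum(sorted_d) / total
        d90 = float(sorted_d[np.searchsorted(cum, 0.9)])
    else:
        cum = quantiles.copy()
        d90 = 0.0
    if bin_width is None:
        bin_width = max(sorted_d.max() / 20.0, 1e-12)
    n_bins = int(np.floor(sorted_d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.histogram(ds, bins=edges)[0].astype(float)
    return {
        "hist_edges": edges,
        "hist_fractions": counts / n,
        "cum_quantiles": quantiles,
        "cum_fractions": cum,
        "d90": d90,
    }


def displacement_classes(
    positions: np.ndarray,
    entity_ids: Sequence[int],
    thresholds_angstrom: Sequence[float] = DEFAULT_DISPLACEMENT_THRESHOLDS_A,
) -> pd.DataFrame:
    """Classify entities by their maximum displacement from the window start.

    ``positions`` is (n_frames, n_entities, 3) in nm, already in the protein
    reference frame (COM paths for molecule level, atom paths for atom
    level).  The class is the smallest threshold the displacement stays
    strictly below; entities at or above the largest threshold get +inf.
    """
    positions = np.asarray(positions, dtype=float)
    disp = positions - positions[0]
    max_disp_a = np.sqrt((disp * disp).sum(axis=-1)).max(axis=0) * 10.0  # nm -> A
    thresholds = sorted(float(t) for t in thresholds_angstrom)
    classes = np.full(max_disp_a.shape, np.inf)
    for thr in reversed(thresholds):
        classes[max_disp_a < thr] = thr
    return pd.DataFrame(
        {
            "entity_id": list(entity_ids),
            "max_displacement_A": max_disp_a,
            "class_threshold_A": classes,
        }
    )
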