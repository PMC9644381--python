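import numpy as np
import pytest

from _oracles import brute_force_msd
from asdkit.mobility import (
    DiffusivityRecord,
    atom_series,
    com_series,
    diffusivity_distribution,
    diffusivity_records,
    displacement_classes,
    fit_diffusivity,
    group_diffusivity,
    per_molecule_msd,
    subtract_protein_motion,
)
from asdkit.model import (
    KIND_DRUG,
    NM2_PER_PS_IN_REPORT_UNITS,
    DomainError,
    minimum_image_distance,
)
from asdkit.synthetic import GeneratorConfig, simulate


class TestMsd:
    def test_ballistic_closed_form(self):
        times = np.arange(100, dtype=float)
        v = np.array([0.01, -0.02, 0.005])
        path = times[:, None] * v
        lags, msd = per_molecule_msd(path, times)
        expected = (np.linalg.norm(v) * lags) ** 2
        np.testing.assert_allclose(msd, expected, rtol=1e-10, atol=1e-14)

    def test_frozen_molecule(self):
        times = np.arange(50, dtype=float)
        path = np.ones((50, 3)) * 2.5
        _, msd = per_molecule_msd(path, times)
        np.testing.assert_allclose(msd, 0.0, atol=1e-12)

    def test_fft_matches_direct_oracle(self, rng):
        for _ in range(10):
            path = np.cumsum(rng.normal(0, 0.1, (64, 3)), axis=0)
            times = np.arange(64, dtype=float)
            lags, msd = per_molecule_msd(path, times, max_lag_fraction=1.0)
            expected = brute_force_msd(path)
            np.testing.assert_allclose(msd, expected[: len(msd)], rtol=1e-9, atol=1e-12)

    def test_too_few_frames(self):
        with pytest.raises(DomainError):
            per_molecule_msd(np.zeros((5, 3)), np.arange(5.0))

    def test_nonuniform_spacing(self):
        times = np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8, 20])
        with pytest.raises(DomainError):
            per_molecule_msd(np.zeros((10, 3)), times)


class TestFitDiffusivity:
    def test_unit_conversion_constant(self):
        # MSD = 6*D*tau with D = 1e-7 nm^2/ps, i.e. exactly 1.0 in 1e-9 cm^2/s:
        # 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s = 1e7 x (1e-9 cm^2/s)
        assert NM2_PER_PS_IN_REPORT_UNITS == 1e7
        lags = np.linspace(0, 1000, 101)
        msd = 6.0 * 1e-7 * lags
        d, r2, clipped = fit_diffusivity(lags, msd, window_duration=1000.0)
        assert d == pytest.approx(1.0, rel=1e-9)
        assert r2 == pytest.approx(1.0)
        assert not clipped

    def test_slope_six_per_ps(self):
        lags = np.linspace(0, 100, 51)
        msd = 6.0 * lags  # 1 nm^2/ps
        d, _, _ = fit_diffusivity(lags, msd, window_duration=100.0)
        assert d == pytest.approx(1e7, rel=1e-9)

    def test_zero_msd(self):
        lags = np.linspace(0, 100, 51)
        d, r2, clipped = fit_diffusivity(lags, np.zeros(51), window_duration=100.0)
        assert d == 0.0
        assert r2 == 1.0
        assert not clipped

    def test_negative_slope_clipped(self):
        lags = np.linspace(0, 100, 51)
        d, _, clipped = fit_diffusivity(lags, -0.01 * lags, window_duration=100.0)
        assert d == 0.0
        assert clipped

    def test_degenerate_window(self):
        lags = np.linspace(0, 10, 5)
        with pytest.raises(DomainError):
            fit_diffusivity(lags, np.zeros(5), window_duration=1000.0)


class TestProteinFrame:
    def _series(self, **kwargs):
        traj, truth = simulate(GeneratorConfig(**kwargs))
        return traj, truth, com_series(traj)

    def test_stationary_protein_identity(self):
        _, _, series = self._series(seed=1, n_drug=4, n_frames=30, drug_D=0.1)
        referenced, drift = subtract_protein_motion(series)
        np.testing.assert_allclose(drift, 0.0, atol=1e-12)
        np.testing.assert_allclose(referenced.coms, series.coms, atol=1e-12)

    def test_recovers_planted_drift(self):
        traj, truth, series = self._series(
            seed=2, n_drug=4, n_frames=100, drug_D=0.1,
            drift_per_frame=(2e-4, 1e-4, -5e-5),
        )
        _, drift = subtract_protein_motion(series)
        assert np.abs(drift - truth.drift).max() < 1e-9

    def test_comoving_drug_zeroed(self):
        traj, truth, series = self._series(
            seed=3, n_drug=4, n_frames=100, drug_D=0.5,
            drift_per_frame=(3e-4, 0.0, 1e-4), comoving_drugs=(1,),
        )
        referenced, _ = subtract_protein_motion(series)
        col = referenced.column(1)
        disp = referenced.coms[:, col] - referenced.coms[0, col]
        assert np.abs(disp).max() < 1e-9

    def test_rigid_translation_of_everything(self):
        # co-moving drugs + drift on protein = whole-box translation
        traj, truth, series = self._series(
            seed=4, n_drug=3, n_frames=50, drug_D=0.0,
            drift_per_frame=(1e-3, -1e-3, 5e-4), comoving_drugs=(1, 2, 3),
        )
        referenced, _ = subtract_protein_motion(series)
        disp = referenced.coms - referenced.coms[0]
        assert np.abs(disp).max() < 1e-9

    def test_intermolecular_distances_preserved(self):
        _, _, series = self._series(
            seed=5, n_drug=5, n_frames=20, drug_D=1.0, drift_per_frame=(1e-3, 0, 0)
        )
        referenced, _ = subtract_protein_motion(series)
        for f in (0, 10, 19):
            orig = series.coms[f]
            ref = referenced.coms[f]
            d_orig = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
            d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
            np.testing.assert_allclose(d_ref, d_orig, atol=1e-10)


class TestDisplacementClasses:
    def test_frozen_lowest_class(self):
        pos = np.zeros((10, 4, 3))
        table = displacement_classes(pos, list(range(4)))
        assert (table.max_displacement_A == 0).all()
        assert (table.class_threshold_A == 1.0).all()

    def test_seven_angstrom_in_ten_class(self):
        pos = np.zeros((3, 1, 3))
        pos[2, 0, 0] = 0.7  # nm -> 7 A
        table = displacement_classes(pos, [0])
        assert table.class_threshold_A.iloc[0] == 10.0

    def test_above_max(self):
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 1.5  # 15 A
        table = displacement_classes(pos, [0])
        assert np.isinf(table.class_threshold_A.iloc[0])

    def test_planted_fast_subset(self, rng):
        n = 20
        pos = np.zeros((30, n, 3))
        fast = rng.choice(n, 6, replace=False)
        pos[-1, fast, 0] = 0.8  # 8 A displacement for the fast subset
        table = displacement_classes(pos, list(range(n)), thresholds_angstrom=[5.0])
        top = set(table.entity_id[np.isinf(table.class_threshold_A)])
        assert top == set(int(i) for i in fast)

    def test_atom_level_series_shape(self):
        traj, _ = simulate(GeneratorConfig(seed=6, n_drug=3, n_frames=12, drug_D=0.2))
        pos = atom_series(traj)
        assert pos.shape == (12, traj.topology.n_atoms, 3)
        # wrapped trajectory distances match the continuous series per frame
        for f in (0, 11):
            d = minimum_image_distance(
                pos[f] % traj.frames[f].box, traj.frames[f].positions, traj.frames[f].box
            )
            assert np.max(d) < 1e-9


class TestGroupsAndDistribution:
    def _records(self, ds, **groups_per_record):
        records = []
        for i, d in enumerate(ds):
            groups = {k: v[i] for k, v in groups_per_record.items()}
            records.append(
                DiffusivityRecord(
                    molecule_id=i, lags=np.arange(2.0), msd=np.zeros(2),
                    D=float(d), fit_r2=1.0, clipped=False, groups=groups,
                )
            )
        return records

    def test_identical_d_every_group(self):
        recs = self._records([0.4] * 6, shell=[0, 0, 1, 1, 2, 2])
        out = group_diffusivity(recs, "shell")
        for v in out.values():
            assert v["mean_D"] == pytest.approx(0.4)
        assert sum(v["count"] for v in out.values()) == 6

    def test_excluding_bonded_raises_mean(self):
        recs = self._records(
            [0.01, 0.01, 1.0, 1.0],
            status=["bonded", "bonded", "nonbonded", "nonbonded"],
        )
        all_mean = group_diffusivity(recs, lambda r: "all")["all"]["mean_D"]
        free_mean = group_diffusivity(
            recs, lambda r: "kept" if r.groups["status"] == "nonbonded" else None
        )["kept"]["mean_D"]
        assert free_mean > all_mean

    def test_empty_expected_group_flagged(self):
        recs = self._records([0.1], shell=[0])
        out = group_diffusivity(recs, "shell", expected_groups=[0, 1])
        assert out[1] == {"mean_D": None, "count": 0}

    def test_equal_d_diagonal(self):
        recs = self._records([0.3] * 10)
        dist = diffusivity_distribution(recs)
        np.testing.assert_allclose(dist["cum_fractions"], dist["cum_quantiles"], atol=1e-12)

    def test_one_mobile_rest_frozen(self):
        recs = self._records([0.0] * 9 + [2.0])
        dist = diffusivity_distribution(recs)
        assert np.all(dist["cum_fractions"][:-1] < 1e-12)
        assert dist["cum_fractions"][-1] == pytest.approx(1.0)

    def test_monotone_ends_at_one(self, rng):
        recs = self._records(rng.uniform(0, 1, 25))
        dist = diffusivity_distribution(recs)
        assert np.all(np.diff(dist["cum_fractions"]) >= -1e-15)
        assert dist["cum_fractions"][-1] == pytest.approx(1.0)

    def test_d90_shifts_right_with_fast_subpopulation(self, rng):
        slow = list(rng.uniform(0.01, 0.05, 30))
        base = diffusivity_distribution(self._records(slow))["d90"]
        shifted = diffusivity_distribution(self._records(slow + [0.5] * 10))["d90"]
        assert shifted > base

    def test_needs_records(self):
        with pytest.raises(DomainError):
            diffusivity_distribution([])


class TestEndToEndRecovery:
    def test_single_molecule_within_25_percent(self):
        # a lone trajectory's Einstein fit is noisy; average a fixed seed set
        fits = []
        for seed in range(12):
            traj, _ = simulate(
                GeneratorConfig(seed=seed, n_drug=1, n_frames=2000, drug_D=1.0, box_edges=(8.0,) * 3)
            )
            series = com_series(traj)
            referenced, _ = subtract_protein_motion(series)
            (rec,) = diffusivity_records(referenced)
            fits.append(rec.D)
        assert np.mean(fits) == pytest.approx(1.0, rel=0.25)
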