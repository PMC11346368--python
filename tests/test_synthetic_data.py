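import numpy as np
import pytest
from scipy import stats

from coroplaque import (
    GroundTruth,
    MonotoneWarp,
    PhantomSpec,
    emulate_ivus_pullback,
    make_phantom,
    sample_cohort,
)
from coroplaque.synthetic_data import Deposit, Stenosis


class TestGroundTruth:
    def test_annular_tube_plaque_volume(self):
        spec = PhantomSpec(length_mm=20.0, lumen_radius_mm=1.5, outer_radius_mm=2.5)
        truth = GroundTruth(spec=spec, bifurcations_mm=[])
        assert truth.volume("plaque") == pytest.approx(
            np.pi * (2.5**2 - 1.5**2) * 20, rel=1e-6
        )

    def test_zero_plaque_when_wall_absent(self):
        spec = PhantomSpec(length_mm=15.0, lumen_radius_mm=2.0, outer_radius_mm=2.0)
        truth = GroundTruth(spec=spec, bifurcations_mm=[])
        assert truth.volume("plaque") == pytest.approx(0.0, abs=1e-9)

    def test_component_areas_partition_wall(self):
        spec = PhantomSpec(
            deposits=[
                Deposit(5.0, 12.0, 0.0, 80.0, "CP"),
                Deposit(7.0, 15.0, 200.0, 100.0, "LAP"),
            ]
        )
        truth = GroundTruth(spec=spec, bifurcations_mm=[])
        s = np.linspace(0, spec.length_mm, 101)
        total = truth.cp_area(s) + truth.ncp_area(s) + truth.lap_area(s)
        assert np.allclose(total, truth.vessel_area(s) - truth.lumen_area(s))

    def test_truth_independent_of_voxel_grid(self):
        base = dict(length_mm=12.0, stenoses=[Stenosis(6.0, 4.0, 0.3)])
        t1 = GroundTruth(PhantomSpec(voxel_spacing_mm=0.4, **base), [])
        t2 = GroundTruth(PhantomSpec(voxel_spacing_mm=0.2, **base), [])
        assert t1.volume("lumen") == t2.volume("lumen")
        assert t1.volume("plaque") == t2.volume("plaque")

    def test_nonphysical_spec_rejected(self):
        # lumen wider than the outer wall: rejected, naming the station
        with pytest.raises(ValueError, match="outer radius < lumen radius at s"):
            PhantomSpec(lumen_radius_mm=2.0, outer_radius_mm=1.8, length_mm=10.0)

    def test_overlapping_deposits_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(
                deposits=[
                    Deposit(5.0, 10.0, 0.0, 90.0, "CP"),
                    Deposit(8.0, 12.0, 45.0, 90.0, "LAP"),
                ]
            )


class TestMakePhantom:
    def test_seeded_determinism(self):
        spec = PhantomSpec(length_mm=10.0, voxel_spacing_mm=0.5, seed=9)
        img1, lab1, _, _ = make_phantom(spec)
        img2, lab2, _, _ = make_phantom(spec)
        assert np.array_equal(img1.data, img2.data)
        assert np.array_equal(lab1.data, lab2.data)

    def test_voxelized_lumen_volume_convergence(self, tube_phantom):
        spec, _, labels, _, truth = tube_phantom
        vox = np.count_nonzero(labels.data == 1) * spec.voxel_spacing_mm**3
        assert vox == pytest.approx(truth.volume("lumen"), rel=0.02)

    def test_component_hu_distributions(self):
        """Interior voxels of each tissue match its HU distribution (KS)."""
        spec = PhantomSpec(
            length_mm=40.0,
            lumen_radius_mm=2.0,
            outer_radius_mm=3.2,
            psf_sigma_mm=0.0,
            noise_sd_hu=0.0,
            voxel_spacing_mm=0.25,
            seed=123,
        )
        image, labels, _, _ = make_phantom(spec)
        h = spec.voxel_spacing_mm
        x = image.origin[0] + np.arange(image.data.shape[0]) * h
        y = image.origin[1] + np.arange(image.data.shape[1]) * h
        z = image.origin[2] + np.arange(image.data.shape[2]) * h
        R = np.hypot(x[:, None, None], y[None, :, None]) * np.ones_like(z)
        Z = np.broadcast_to(z, image.data.shape)
        margin = h * np.sqrt(3)  # strictly interior: away from any boundary
        axial = (Z > margin) & (Z < 40.0 - margin)
        lumen_core = axial & (R < 2.0 - margin)
        wall_core = axial & (R > 2.0 + margin) & (R < 3.2 - margin)
        for mask, (mean, sd) in (
            (lumen_core, spec.hu_params["lumen"]),
            (wall_core, spec.hu_params["NCP"]),
        ):
            samples = image.data[mask].astype(float)
            assert len(samples) >= 10_000
            p = stats.kstest(samples, "norm", args=(mean, sd)).pvalue
            assert p > 0.01


class TestEmulateIvusPullback:
    def _truth(self, length=20.0, bifs=(8.0,)):
        spec = PhantomSpec(length_mm=length, stenoses=[Stenosis(10.0, 6.0, 0.3)])
        return GroundTruth(spec=spec, bifurcations_mm=list(bifs))

    def test_identity_noise_free_matches_truth(self):
        truth = self._truth()
        pb = emulate_ivus_pullback(truth, area_noise_cv=0.0, warp=None, seed=0)
        assert np.allclose(pb.position, np.arange(21.0))
        assert np.allclose(pb.lumen_area, truth.lumen_area(pb.position))
        assert np.allclose(pb.vessel_area, truth.vessel_area(pb.position))

    def test_linear_stretch_scales_anchors(self):
        truth = self._truth()
        warp = MonotoneWarp(np.array([0.0, 20.0]), np.array([0.0, 22.0]))
        pb = emulate_ivus_pullback(truth, 0.0, warp, 0)
        anchors = dict((k, p) for p, k in pb.anchors)
        assert anchors["end"] == pytest.approx(22.0)
        bif = [p for p, k in pb.anchors if k == "bifurcation"]
        assert bif[0] == pytest.approx(8.0 * 1.1)

    def test_noise_cv_calibration(self):
        # 200 stations, cv = 0.05: sample CV of measured/true in [0.03, 0.07]
        truth = self._truth(length=200.0, bifs=())
        pb = emulate_ivus_pullback(truth, area_noise_cv=0.05, warp=None, seed=11)
        ratio = pb.lumen_area / truth.lumen_area(pb.position)
        assert len(ratio) >= 200
        assert 0.03 < ratio.std(ddof=1) / ratio.mean() < 0.07

    def test_negative_cv_error(self):
        with pytest.raises(ValueError):
            emulate_ivus_pullback(self._truth(), area_noise_cv=-0.1)

    def test_non_monotone_warp_error(self):
        with pytest.raises(ValueError):
            MonotoneWarp(np.array([0.0, 10.0, 20.0]), np.array([0.0, 12.0, 11.0]))

    def test_random_warp_slopes_within_clamp(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            w = MonotoneWarp.random(30.0, rng)
            slopes = np.diff(w.knots_p) / np.diff(w.knots_s)
            assert np.all(slopes >= 0.8 - 1e-12) and np.all(slopes <= 1.25 + 1e-12)
            grid = np.linspace(0, 30, 500)
            assert np.all(np.diff(w(grid)) > 0)


class TestSampleCohort:
    def test_single_case_consistent(self):
        (case,) = sample_cohort(1, seed=4, voxelize=False)
        assert case.truth.length == case.spec.length_mm
        assert case.pullback.anchors[0][1] == "start"

    def test_cohort_determinism(self):
        a = sample_cohort(8, seed=21, voxelize=False)
        b = sample_cohort(8, seed=21, voxelize=False)
        for ca, cb in zip(a, b):
            assert ca.spec == cb.spec
            assert np.array_equal(ca.pullback.lumen_area, cb.pullback.lumen_area)

    def test_lap_prevalence_binomial(self):
        cases = sample_cohort(50, seed=2024, voxelize=False)
        frac = np.mean([c.truth.volume("lap") > 0 for c in cases])
        assert 0.35 <= frac <= 0.65

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            sample_cohort(0)
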