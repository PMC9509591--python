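"""Phantom sampling and the grayscale -> QCT density regression."""

import logging
from dataclasses import replace

import numpy as np
import pytest

import bonemap as bm


def make_samples_on_line(slope, intercept, grayscales):
    return [
        bm.PhantomSample(label=f"s{i}", qct_density=slope * g + intercept,
                         mean_grayscale=g, sd_grayscale=0.0, n=100)
        for i, g in enumerate(grayscales)
    ]


class TestProfileLine:
    def test_constant_field_mean(self, uniform_volume):
        line = bm.ProfileLine(start=(2.0, 2.0, 1.0), end=(12.0, 12.0, 6.0), step=0.5)
        s = bm.sample_profile_line(uniform_volume, line)
        assert s.mean_grayscale == 300.0
        # interpolation weights leave ~1e-14 ripple; the mean is still exact
        assert s.sd_grayscale == pytest.approx(0.0, abs=1e-9)
        assert s.n >= 2

    def test_default_step_is_half_min_spacing(self, uniform_volume):
        line = bm.ProfileLine(start=(2.0, 2.0, 1.0), end=(12.0, 2.0, 1.0))
        s = bm.sample_profile_line(uniform_volume, line)
        # length 10 mm at 0.5 mm steps -> 21 points
        assert s.n == 21

    def test_noisy_insert_mean_within_clt_bound(self, rng):
        """>=100 interpolated points through N(850, 20) noise recover the mean."""
        voxels = np.round(850 + rng.normal(0, 20, size=(8, 40, 40))).astype(np.int16)
        v = bm.CTVolume(voxels=voxels, spacing=np.array([1.0, 1.0, 1.0]))
        line = bm.ProfileLine(start=(1.0, 19.5, 3.5), end=(38.0, 19.5, 3.5), step=0.25)
        s = bm.sample_profile_line(v, line)
        assert s.n >= 100
        assert abs(s.mean_grayscale - 850) <= 3 * 20 / np.sqrt(100)

    def test_line_exiting_volume_rejected(self, uniform_volume):
        line = bm.ProfileLine(start=(2.0, 2.0, 1.0), end=(200.0, 2.0, 1.0), step=1.0)
        with pytest.raises(bm.GeometryError, match="leaves the volume"):
            bm.sample_profile_line(uniform_volume, line)

    def test_degenerate_line_rejected(self):
        with pytest.raises(bm.DataError):
            bm.ProfileLine(start=(0, 0, 0), end=(0, 0, 0))
        with pytest.raises(bm.DataError):
            bm.ProfileLine(start=(0, 0, 0), end=(1, 0, 0), step=0.0)


class TestCylinderROI:
    def test_constant_region_mean(self, uniform_volume):
        roi = bm.CylinderROI(center=(8.0, 8.0, 4.0), radius=3.0, half_height=2.0)
        s = bm.sample_cylinder_roi(uniform_volume, roi)
        assert s.mean_grayscale == 300.0
        assert s.sd_grayscale == 0.0
        assert s.n > 50

    def test_roi_and_line_agree_on_same_insert(self, rng):
        """Two estimators of one simulated mean agree within joint SEs."""
        voxels = np.round(850 + rng.normal(0, 20, size=(16, 32, 32))).astype(np.int16)
        v = bm.CTVolume(voxels=voxels, spacing=np.ones(3))
        roi = bm.CylinderROI(center=(15.5, 15.5, 7.5), radius=6.0, half_height=6.0)
        s_roi = bm.sample_cylinder_roi(v, roi)
        line = bm.ProfileLine(start=(2.0, 15.5, 7.5), end=(29.0, 15.5, 7.5), step=0.5)
        s_line = bm.sample_profile_line(v, line)
        joint_se = np.hypot(s_roi.sd_grayscale / np.sqrt(s_roi.n),
                            s_line.sd_grayscale / np.sqrt(s_line.n))
        assert abs(s_roi.mean_grayscale - s_line.mean_grayscale) <= 4 * joint_se

    def test_empty_intersection_rejected(self, uniform_volume):
        roi = bm.CylinderROI(center=(8.4, 8.4, 4.4), radius=0.05, half_height=0.05)
        with pytest.raises(bm.GeometryError, match="no voxel centers"):
            bm.sample_cylinder_roi(uniform_volume, roi)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(bm.DataError):
            bm.CylinderROI(center=(0, 0, 0), radius=-1.0, half_height=1.0)
        with pytest.raises(bm.DataError):
            bm.CylinderROI(center=(0, 0, 0), radius=1.0, half_height=1.0,
                           axis=(0, 0, 2))


class TestFit:
    def test_exact_line_recovered(self):
        samples = make_samples_on_line(2.0, -100.0, [50, 100, 150, 250, 450])
        m = bm.fit_calibration(samples)
        assert m.slope == pytest.approx(2.0, rel=1e-12)
        assert m.intercept == pytest.approx(-100.0, abs=1e-9)
        assert m.r_squared == pytest.approx(1.0)
        assert m.residual_se == pytest.approx(0.0, abs=1e-9)

    def test_two_points_define_the_line(self):
        m = bm.fit_calibration(make_samples_on_line(1.5, 10.0, [100, 400]))
        assert m.slope == pytest.approx(1.5)
        assert m.n_samples == 2

    def test_single_sample_rejected(self):
        with pytest.raises(bm.DataError):
            bm.fit_calibration(make_samples_on_line(1.0, 0.0, [100]))

    def test_identical_grayscales_rejected(self):
        samples = [
            bm.PhantomSample(label="a", qct_density=0.0, mean_grayscale=100.0),
            bm.PhantomSample(label="b", qct_density=50.0, mean_grayscale=100.0),
        ]
        with pytest.raises(bm.DataError, match="identical"):
            bm.fit_calibration(samples)

    def test_poor_fit_logs_warning(self, caplog):
        samples = [
            bm.PhantomSample(label=l, qct_density=rho, mean_grayscale=g)
            for l, rho, g in [("a", 0, 100), ("b", 500, 120), ("c", 100, 300)]
        ]
        with caplog.at_level(logging.WARNING, logger="bonemap.calibration"):
            bm.fit_calibration(samples)
        assert any("R^2" in r.message for r in caplog.records)

    def test_noisy_recovery_within_3_se(self):
        """Coverage study: >=99/100 seeded phantoms recover the true line."""
        study = bm.calibration_recovery_study(n_runs=100, noise_sd=20.0, base_seed=0)
        assert study["hits"] >= 99


class TestApplyCalibration:
    def test_intercept_readout(self):
        v = bm.CTVolume(voxels=np.zeros((2, 2, 2), dtype=np.int16), spacing=np.ones(3))
        model = bm.CalibrationModel(slope=2.0, intercept=-100.0, r_squared=1.0,
                                    residual_se=0.0, n_samples=2)
        out = bm.apply_calibration(v, model)
        assert np.all(out.values == -100.0)
        assert out.units == "mg/cm3"

    def test_identity_model_reinterprets_stored_values(self, make_random_ct):
        v = make_random_ct()
        out = bm.apply_calibration(v, bm.identity_calibration())
        assert np.array_equal(out.values, v.voxels.astype(float))

    def test_affine_shift_property(self, make_random_ct):
        """Shifting stored values by +k shifts the output by slope*k."""
        v = make_random_ct(shape=(6, 6, 6), lo=0, hi=500)
        model = bm.CalibrationModel(slope=2.0, intercept=-100.0, r_squared=1.0,
                                    residual_se=0.0, n_samples=2)
        shifted = bm.CTVolume(voxels=v.voxels + 7, spacing=v.spacing)
        a = bm.apply_calibration(v, model)
        b = bm.apply_calibration(shifted, model)
        assert np.allclose(b.values - a.values, model.slope * 7)

    def test_training_point_predicted_within_residual_se(self):
        rng = np.random.default_rng(5)
        g = np.array([50.0, 100, 150, 250, 450])
        rho = 2.0 * g - 100.0 + rng.normal(0, 1.0, 5)
        samples = [
            bm.PhantomSample(label=f"s{i}", qct_density=max(r, 0.0), mean_grayscale=x)
            for i, (x, r) in enumerate(zip(g, rho))
        ]
        m = bm.fit_calibration(samples)
        for s in samples:
            assert abs(m.predict(s.mean_grayscale) - s.qct_density) <= 3 * m.residual_se


class TestGrayscaleCalibratorEstimator:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        est = bm.GrayscaleCalibrator()
        clone(est)
        assert "r2_warn_threshold" in est.get_params()

    def test_fit_predict_shapes(self):
        g = np.array([[50.0], [100.0], [150.0]])
        rho = np.array([0.0, 100.0, 200.0])
        est = bm.GrayscaleCalibrator().fit(g, rho)
        assert est.slope_ == pytest.approx(2.0)
        assert est.predict(np.array([[200.0]]))[0] == pytest.approx(300.0)
        model = est.to_model()
        assert model.slope == est.slope_

    def test_score_is_r2(self):
        g = np.array([[50.0], [100.0], [150.0], [250.0]])
        rho = 2.0 * g[:, 0] - 100.0
        est = bm.GrayscaleCalibrator().fit(g, rho)
        assert est.score(g, rho) == pytest.approx(1.0)


def test_propagated_se_scales_with_measurement_noise():
    base = make_samples_on_line(2.0, -100.0, [50, 100, 150, 250, 450])
    noisy = [replace(s, sd_grayscale=20.0, n=400) for s in base]
    quiet = [replace(s, sd_grayscale=2.0, n=400) for s in base]
    m = bm.fit_calibration(base)
    se_noisy = bm.propagated_coefficient_se(noisy, m)
    se_quiet = bm.propagated_coefficient_se(quiet, m)
    assert se_noisy[0] == pytest.approx(10 * se_quiet[0])
    assert se_noisy[1] == pytest.approx(10 * se_quiet[1])
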