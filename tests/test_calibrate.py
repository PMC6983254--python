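"""Gravity alignment, SVD heading recovery and full calibration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.base import clone
from sklearn.pipeline import Pipeline

from postucal import (
    AccelCalibrator,
    AccelTimeSeries,
    apply_calibration,
    auto_calibrate,
    flip_heading,
    generate_recording,
    gravity_alignment_rotation,
    heading_from_svd,
    random_mounting,
    rotation_from_tilt_heading,
    walk_calibration_scenario,
)
from postucal.exceptions import (
    DegenerateGravityError,
    InsufficientMotionError,
    InvalidRotationError,
    IsotropicMotionWarning,
    NoQuasiStaticError,
)
from .conftest import geodesic_deg, heading_ambiguous_error_deg

DOWN = np.array([0.0, 0.0, -1.0])


class TestGravityAlignment:
    def test_already_aligned_gives_identity(self):
        np.testing.assert_allclose(gravity_alignment_rotation(DOWN), np.eye(3),
                                   atol=1e-12)

    def test_horizontal_gravity_matches_rodrigues_oracle(self):
        # Rodrigues rotation about +y by π/2 maps (1,0,0) to (0,0,−1)
        expected = np.array([[0.0, 0.0, 1.0],
                             [0.0, 1.0, 0.0],
                             [-1.0, 0.0, 0.0]])
        R = gravity_alignment_rotation([1.0, 0.0, 0.0])
        np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_antipodal_tie_break_rotates_about_x(self):
        R = gravity_alignment_rotation([0.0, 0.0, 1.0])
        np.testing.assert_allclose(R, np.diag([1.0, -1.0, -1.0]), atol=1e-12)
        np.testing.assert_allclose(R @ [0, 0, 1], DOWN, atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_directions_align_and_stay_proper(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        R = gravity_alignment_rotation(g)
        np.testing.assert_allclose(R @ g, DOWN, atol=1e-9)
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGravityError):
            gravity_alignment_rotation([0.0, 0.0, 0.0])


def _leveled(motion_xy):
    rows = np.column_stack([motion_xy, np.zeros(len(motion_xy))]) + DOWN
    mask = np.zeros(len(motion_xy), dtype=bool)
    return rows, mask


class TestHeadingFromSvd:
    def test_motion_along_x_gives_zero_heading(self):
        rows, mask = _leveled([(0.5, 0.0), (-0.5, 0.0)] * 5)
        heading, _, v1, _ = heading_from_svd(rows, mask)
        assert heading == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(v1, [1.0, 0.0], atol=1e-12)

    def test_motion_along_y_gives_half_pi_after_sign_fix(self):
        rows, mask = _leveled([(0.0, 0.3), (0.0, -0.3)] * 5)
        heading, _, v1, _ = heading_from_svd(rows, mask)
        assert heading == pytest.approx(np.pi / 2, abs=1e-12)
        np.testing.assert_allclose(v1, [0.0, 1.0], atol=1e-12)

    def test_noisy_oblique_motion_matches_covariance_oracle(self, rng):
        direction = np.array([np.cos(np.radians(30)), np.sin(np.radians(30))])
        amp = 0.4 * np.sin(2 * np.pi * 1.8 * np.arange(600) / 60.0)
        xy = np.outer(amp, direction) + rng.normal(0, 0.02, (600, 2))
        rows, mask = _leveled(xy)
        heading, svals, v1, planarity = heading_from_svd(rows, mask)
        assert abs(np.degrees(heading) - 30) < 2
        # independent oracle: eigendecomposition of the 2×2 covariance
        evals, evecs = np.linalg.eigh(xy.T @ xy)
        e1 = evecs[:, np.argmax(evals)]
        if e1[0] < 0:
            e1 = -e1
        assert heading == pytest.approx(np.arctan2(e1[1], e1[0]), abs=1e-6)
        assert svals[0] >= svals[1] >= 0
        assert planarity > 1.2

    def test_too_few_motion_rows_rejected(self):
        rows, mask = _leveled([(0.5, 0.0)] * 5)
        mask[:3] = True  # only two motion rows remain
        with pytest.raises(InsufficientMotionError):
            heading_from_svd(rows, mask)

    def test_isotropic_motion_warns(self, rng):
        xy = rng.normal(0, 0.3, (500, 2))
        rows, mask = _leveled(xy)
        with pytest.warns(IsotropicMotionWarning):
            _, _, _, planarity = heading_from_svd(rows, mask)
        assert planarity < 1.2


class TestAutoCalibrate:
    def test_identity_mounting_recovers_identity(self):
        series, _ = generate_recording(
            walk_calibration_scenario(noise_sigma_g=0.0, seed=0))
        result = auto_calibrate(series)
        np.testing.assert_allclose(result.R, np.eye(3), atol=1e-6)

    def test_recovers_tilted_mounting_within_two_degrees(self):
        Q = rotation_from_tilt_heading(40.0, 25.0)
        series, truth = generate_recording(
            walk_calibration_scenario(true_rotation=Q, seed=11))
        result = auto_calibrate(series)
        assert heading_ambiguous_error_deg(result.R, truth.true_rotation.T) <= 2.0
        np.testing.assert_allclose(result.R @ result.g_hat.g_hat, DOWN,
                                   atol=1e-9)

    def test_record_without_rest_raises(self, rng):
        t = np.arange(0, 60, 1 / 60.0)
        samples = np.tile(DOWN, (len(t), 1))
        samples[:, 0] += 0.5 * np.sin(2 * np.pi * 2.0 * t)
        series = AccelTimeSeries(t0=0.0, fs=60.0, samples=samples)
        with pytest.raises(NoQuasiStaticError):
            auto_calibrate(series)

    @pytest.mark.parametrize("seed", range(5))
    def test_full_pipeline_is_rotation_equivariant(self, seed):
        # calibrating a rotated copy of the same recording recovers the
        # same world-frame signal (modulo the forward/backward ambiguity)
        rng = np.random.default_rng(seed)
        series, _ = generate_recording(
            walk_calibration_scenario(seed=500 + seed))
        Q = random_mounting(rng)
        rotated = series.with_samples(series.samples @ Q.T)
        R0 = auto_calibrate(series).R
        R1 = auto_calibrate(rotated).R
        assert heading_ambiguous_error_deg(R1 @ Q, R0) <= 2.0


class TestApplyCalibration:
    def test_identity_is_a_no_op(self, still_series):
        out = apply_calibration(still_series, np.eye(3))
        np.testing.assert_allclose(out.samples, still_series.samples)
        assert out.fs == still_series.fs and out.t0 == still_series.t0

    def test_rotation_preserves_magnitudes(self, rng):
        samples = rng.normal(size=(200, 3))
        series = AccelTimeSeries(t0=0.0, fs=60.0, samples=samples)
        R = Rotation.from_euler("zyx", [10, 40, -70], degrees=True).as_matrix()
        out = apply_calibration(series, R)
        np.testing.assert_allclose(
            np.linalg.norm(out.samples, axis=1),
            np.linalg.norm(samples, axis=1), atol=1e-12)

    def test_non_rotation_rejected(self, still_series):
        with pytest.raises(InvalidRotationError):
            apply_calibration(still_series, np.eye(3) * 1.1)

    def test_calibrated_still_record_points_down(self, rng):
        Q = rotation_from_tilt_heading(35.0, 200.0)
        series, _ = generate_recording(
            walk_calibration_scenario(true_rotation=Q, seed=21))
        result = auto_calibrate(series)
        calibrated = apply_calibration(series, result.R)
        rest = calibrated.samples[:int(100 * series.fs)].mean(axis=0)
        angle = np.degrees(np.arccos(np.clip(
            rest @ DOWN / np.linalg.norm(rest), -1, 1)))
        assert angle < 0.5


class TestFlipHeading:
    def test_flip_is_an_involution(self):
        series, _ = generate_recording(walk_calibration_scenario(seed=3))
        result = auto_calibrate(series)
        twice = flip_heading(flip_heading(result))
        np.testing.assert_allclose(twice.R, result.R, atol=1e-12)
        assert twice.heading_rad == pytest.approx(result.heading_rad, abs=1e-12)
        assert twice.flipped == result.flipped

    def test_flip_preserves_gravity_alignment_and_shifts_heading(self):
        series, _ = generate_recording(walk_calibration_scenario(seed=3))
        result = auto_calibrate(series)
        flipped = flip_heading(result)
        np.testing.assert_allclose(flipped.R @ result.g_hat.g_hat, DOWN,
                                   atol=1e-9)
        delta = (flipped.heading_rad - result.heading_rad) % (2 * np.pi)
        assert delta == pytest.approx(np.pi, abs=1e-9)
        assert flipped.flipped != result.flipped


class TestSklearnInterface:
    def test_calibrator_composes_in_a_pipeline(self):
        Q = rotation_from_tilt_heading(25.0, 80.0)
        series, _ = generate_recording(
            walk_calibration_scenario(true_rotation=Q, seed=8))
        pipe = Pipeline([("calibrate", AccelCalibrator(fs=series.fs))])
        world = pipe.fit_transform(series.samples)
        rest = world[:int(100 * series.fs)].mean(axis=0)
        assert rest[2] < -0.99

    def test_clone_and_params_round_trip(self):
        cal = AccelCalibrator(fs=30.0, threshold_g=0.01, flip=True)
        other = clone(cal)
        assert other.get_params() == cal.get_params()

    def test_transform_then_inverse_transform_is_identity(self):
        series, _ = generate_recording(walk_calibration_scenario(seed=4))
        cal = AccelCalibrator(fs=series.fs).fit(series.samples)
        back = cal.inverse_transform(cal.transform(series.samples))
        np.testing.assert_allclose(back, series.samples, atol=1e-12)

    def test_flip_parameter_matches_flip_heading(self):
        series, _ = generate_recording(walk_calibration_scenario(seed=4))
        plain = AccelCalibrator(fs=series.fs).fit(series.samples)
        flipped = AccelCalibrator(fs=series.fs, flip=True).fit(series.samples)
        np.testing.assert_allclose(
            flip_heading(plain.result_()).R, flipped.rotation_, atol=1e-12)
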