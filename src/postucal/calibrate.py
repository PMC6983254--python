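"""Automatic 3-DOF orientation calibration of a body-worn accelerometer.

The mounting orientation of an arbitrarily placed triaxial accelerometer is
recovered in two steps.  Gravity, constant in the world frame, constrains
two degrees of freedom: the minimal rotation R′ maps the measured gravity
direction ĝ onto the downward vertical (0, 0, −1).  The remaining degree of
freedom — the heading about the vertical — is constrained by a variance
analysis of the levelled motion: under everyday locomotion most movement
variance lies along the forward axis, so the leading right-singular vector
v₁ of the horizontal motion matrix gives the forward-facing direction.  The
full calibration is R = Rz(−heading)·R′, mapping sensor-frame readings into
the gravity-aligned world frame with +x forward.

Forward and backward cannot be told apart from variance alone; the sign of
v₁ is fixed deterministically and :func:`flip_heading` (or the CLI
``--flip`` flag) applies the manual π correction when needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import (
    DegenerateGravityError,
    InsufficientMotionError,
    InvalidRotationError,
    IsotropicMotionWarning,
    ParameterError,
)
from .ingest import AccelTimeSeries
from .quasistatic import (
    GravityEstimate,
    QuasiStaticDetector,
    QuasiStaticMask,
    estimate_gravity,
)

DOWN = np.array([0.0, 0.0, -1.0])

#: σ1/σ2 below which horizontal motion is considered isotropic and the
#: recovered heading unreliable.
PLANARITY_WARN_RATIO = 1.2


@dataclass
class CalibrationResult:
    """Recovered rotation and its diagnostics.

    ``R`` maps sensor-frame rows to the world frame; ``R_prime`` is the
    gravity-alignment part and ``heading_rad`` the rotation about the world
    vertical composed on top of it.
    """

    R: np.ndarray
    R_prime: np.ndarray
    heading_rad: float
    g_hat: GravityEstimate
    singular_values: tuple
    v1: np.ndarray
    planarity_ratio: float
    flipped: bool = False
    isotropic_motion: bool = False


def _rotz(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3×3, got {R.shape}")
    if np.abs(R.T @ R - np.eye(3)).max() > tol:
        raise InvalidRotationError("matrix is not orthonormal")
    if abs(np.linalg.det(R) - 1.0) > tol:
        raise InvalidRotationError("matrix is not a proper rotation (det ≠ +1)")
    return R


def gravity_alignment_rotation(g_hat: np.ndarray) -> np.ndarray:
    """Minimal rotation R′ taking ``g_hat`` to the downward vertical.

    The rotation axis is ``g_hat × (0,0,−1)`` (Rodrigues construction), so
    R′ tilts the frame without introducing any heading.  For the antipodal
    input (0,0,+1) the axis is undefined; the tie-break is a π rotation
    about +x, and the same axis is used within 1° of the antipode for
    numerical stability.
    """
    g_hat = np.asarray(g_hat, dtype=float)
    norm = np.linalg.norm(g_hat)
    if norm < 1e-12:
        raise DegenerateGravityError("zero gravity direction")
    if abs(norm - 1.0) > 1e-6:
        raise ParameterError(f"g_hat must be unit length, got ‖g_hat‖={norm}")
    g = g_hat / norm
    cosang = float(np.clip(g @ DOWN, -1.0, 1.0))
    angle = np.arccos(cosang)
    if angle < 1e-12:
        return np.eye(3)
    if np.degrees(angle) > 179.0:
        axis = np.array([1.0, 0.0, 0.0])
    else:
        axis = np.cross(g, DOWN)
        axis = axis / np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def heading_from_svd(leveled: np.ndarray, mask: QuasiStaticMask | np.ndarray):
    """Recover the forward heading from levelled motion samples.

    The constant gravity (0,0,−1) g is subtracted from every levelled row so
    only motion remains; rows flagged quasi-static are discarded and the
    horizontal (x, y) columns of the rest form an m′×2 matrix whose SVD
    gives the principal motion direction v₁.  Its sign is fixed so the x
    component is ≥ 0 (ties: y ≥ 0).

    Returns
    -------
    heading_rad : float
        ``atan2(v1_y, v1_x)``.
    singular_values : tuple
        (σ1, σ2), descending.
    v1 : ndarray of shape (2,)
        Principal horizontal motion direction.
    planarity_ratio : float
        σ1/σ2 (∞ if σ2 = 0); below 1.2 an isotropic-motion warning is
        issued and the heading is unreliable.
    """
    leveled = np.asarray(leveled, dtype=float)
    qs = mask.mask if isinstance(mask, QuasiStaticMask) else np.asarray(mask, bool)
    motion = leveled[~qs] - DOWN
    if motion.shape[0] < 3:
        raise InsufficientMotionError(
            f"only {motion.shape[0]} motion samples; need at least 3"
        )
    horizontal = motion[:, :2]
    _, s, vt = np.linalg.svd(horizontal, full_matrices=False)
    v1 = vt[0]
    if v1[0] < 0 or (v1[0] == 0 and v1[1] < 0):
        v1 = -v1
    planarity = float(s[0] / s[1]) if s[1] > 0 else np.inf
    if planarity < PLANARITY_WARN_RATIO:
        warnings.warn(
            f"horizontal motion nearly isotropic (σ1/σ2 = {planarity:.3f}); "
            "heading is unreliable",
            IsotropicMotionWarning,
            stacklevel=2,
        )
    heading = float(np.arctan2(v1[1], v1[0]))
    return heading, (float(s[0]), float(s[1])), v1, planarity


class AccelCalibrator(BaseEstimator, TransformerMixin):
    """Estimate and apply the sensor-to-world rotation of a recording.

    ``fit`` runs the full automatic calibration — quasi-static detection,
    gravity averaging, levelling, SVD heading — on an m×3 array of specific
    force in g; ``transform`` rotates samples into the world frame.  The
    method assumes the wearer rests mostly in the neutral (upright) posture,
    that sustained non-gravitational acceleration is absent, and that
    movement variance concentrates in the vertical plane through the
    forward axis.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    cof_hz : float, default 0.1
        Cutoff of the zero-phase filters separating gravity from motion.
    window_s : float, default 2.0
        Hann smoothing window for the motion-intensity signal, seconds.
    threshold_g : float, default 0.02
        Quasi-static intensity threshold in g.
    min_duration_s : float, default 2.0
        Minimum quasi-static run length in seconds.
    flip : bool, default False
        Apply the manual forward/backward π correction.

    Attributes
    ----------
    rotation_ : ndarray of shape (3, 3)
        Full calibration R (sensor → world).
    gravity_rotation_ : ndarray of shape (3, 3)
        Gravity-alignment part R′.
    heading_rad_ : float
        Heading composed into ``rotation_``.
    g_hat_ : GravityEstimate
        Estimated gravity direction in the sensor frame.
    singular_values_, v1_, planarity_ratio_, isotropic_motion_
        SVD diagnostics of the horizontal motion.
    """

    def __init__(self, fs: float = 60.0, cof_hz: float = 0.1,
                 window_s: float = 2.0, threshold_g: float = 0.02,
                 min_duration_s: float = 2.0, flip: bool = False):
        self.fs = fs
        self.cof_hz = cof_hz
        self.window_s = window_s
        self.threshold_g = threshold_g
        self.min_duration_s = min_duration_s
        self.flip = flip

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=4)
        if X.shape[1] != 3:
            raise ParameterError(f"expected m×3 samples, got {X.shape}")
        self.n_features_in_ = 3

        detector = QuasiStaticDetector(
            fs=self.fs, cof_hz=self.cof_hz, window_s=self.window_s,
            threshold_g=self.threshold_g, min_duration_s=self.min_duration_s,
        )
        mask = detector.fit_predict(X)
        series = AccelTimeSeries(t0=0.0, fs=self.fs, samples=X)
        qsm = QuasiStaticMask(mask=mask, intensity=detector.intensity_,
                              threshold_g=self.threshold_g,
                              min_duration_s=self.min_duration_s)
        gravity = estimate_gravity(series, qsm, self.cof_hz)
        R_prime = gravity_alignment_rotation(gravity.g_hat)
        leveled = X @ R_prime.T
        heading, svals, v1, planarity = heading_from_svd(leveled, qsm)
        R = _rotz(-heading) @ R_prime
        if self.flip:
            R = _rotz(np.pi) @ R
            heading = float(np.arctan2(np.sin(heading + np.pi),
                                       np.cos(heading + np.pi)))

        self.quasistatic_mask_ = qsm
        self.g_hat_ = gravity
        self.gravity_rotation_ = R_prime
        self.heading_rad_ = heading
        self.singular_values_ = svals
        self.v1_ = v1
        self.planarity_ratio_ = planarity
        self.isotropic_motion_ = planarity < PLANARITY_WARN_RATIO
        self.rotation_ = R
        self.flipped_ = bool(self.flip)
        return self

    def transform(self, X) -> np.ndarray:
        """Rotate sensor-frame rows into the world frame."""
        check_is_fitted(self, "rotation_")
        X = check_array(X)
        return X @ self.rotation_.T

    def inverse_transform(self, X) -> np.ndarray:
        check_is_fitted(self, "rotation_")
        X = check_array(X)
        return X @ self.rotation_

    def result_(self) -> CalibrationResult:
        """Package the fitted attributes as a :class:`CalibrationResult`."""
        check_is_fitted(self, "rotation_")
        return CalibrationResult(
            R=self.rotation_, R_prime=self.gravity_rotation_,
            heading_rad=self.heading_rad_, g_hat=self.g_hat_,
            singular_values=self.singular_values_, v1=self.v1_,
            planarity_ratio=self.planarity_ratio_, flipped=self.flipped_,
            isotropic_motion=self.isotropic_motion_,
        )


def auto_calibrate(series: AccelTimeSeries, cof_hz: float = 0.1,
                   window_s: float = 2.0, threshold_g: float = 0.02,
                   min_duration_s: float = 2.0,
                   flip: bool = False) -> CalibrationResult:
    """Run the full automatic calibration on a recording.

    Thin wrapper over :class:`AccelCalibrator`.
    """
    cal = AccelCalibrator(fs=series.fs, cof_hz=cof_hz, window_s=window_s,
                          threshold_g=threshold_g,
                          min_duration_s=min_duration_s, flip=flip)
    cal.fit(series.samples)
    return cal.result_()


def apply_calibration(series: AccelTimeSeries, R: np.ndarray) -> AccelTimeSeries:
    """Rotate every row of a recording by a proper rotation R.

    Sampling rate, start time and metadata are preserved; rotation is an
    isometry so per-row magnitudes are unchanged.
    """
    R = _check_rotation(R)
    return series.with_samples(series.samples @ R.T)


def flip_heading(result: CalibrationResult) -> CalibrationResult:
    """Apply the manual forward/backward π correction.

    An involution: flipping twice restores the original rotation.  The
    gravity alignment is untouched (a rotation about the vertical preserves
    the z axis), only the reported heading shifts by π.
    """
    R = _rotz(np.pi) @ result.R
    h = result.heading_rad + np.pi
    h = float(np.arctan2(np.sin(h), np.cos(h)))
    return replace(result, R=R, heading_rad=h, flipped=not result.flipped)
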