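"""Quasi-static epoch detection and gravity-direction estimation.

An accelerometer at rest reads the gravity vector in its own (sensor)
frame.  Epochs with negligible dynamic acceleration are found from a
smoothed motion-intensity signal — the rectified high-passed magnitude —
and the low-passed axis channels are averaged over those epochs to obtain
the measured gravity direction ĝ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array

from . import filters
from .exceptions import (
    DegenerateGravityError,
    LengthError,
    NoQuasiStaticError,
    ParameterError,
)
from .ingest import AccelTimeSeries


@dataclass
class QuasiStaticMask:
    """Per-sample quasi-static mask with the intensity signal behind it."""

    mask: np.ndarray
    intensity: np.ndarray
    threshold_g: float
    min_duration_s: float

    @property
    def n_quasistatic(self) -> int:
        return int(self.mask.sum())

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class GravityEstimate:
    """Unit gravity direction in the sensor frame, with QC statistics."""

    g_hat: np.ndarray
    n_samples: int
    mean_magnitude_g: float


def _runs(mask: np.ndarray):
    """Yield (start, stop) half-open index pairs of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _drop_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    out = mask.copy()
    for start, stop in _runs(mask):
        if stop - start < min_len:
            out[start:stop] = False
    return out


class QuasiStaticDetector(BaseEstimator):
    """Detect low-movement samples of a triaxial recording.

    The motion intensity is the Hann-smoothed absolute value of the
    high-passed acceleration magnitude; samples where it falls below
    ``threshold_g`` form candidate quasi-static epochs, and runs shorter
    than ``min_duration_s`` are discarded so only substantially long rest
    periods remain.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    cof_hz : float, default 0.1
        Cutoff of the zero-phase high-pass separating motion from gravity.
    window_s : float, default 2.0
        Hann smoothing window in seconds.
    threshold_g : float, default 0.02
        Intensity below which a sample counts as quasi-static.
    min_duration_s : float, default 2.0
        Minimum accepted run length in seconds.
    """

    def __init__(self, fs: float = 60.0, cof_hz: float = 0.1,
                 window_s: float = 2.0, threshold_g: float = 0.02,
                 min_duration_s: float = 2.0):
        self.fs = fs
        self.cof_hz = cof_hz
        self.window_s = window_s
        self.threshold_g = threshold_g
        self.min_duration_s = min_duration_s

    def _validate(self, X):
        X = check_array(X, ensure_min_samples=2)
        if X.shape[1] != 3:
            raise ParameterError(f"expected m×3 samples, got {X.shape}")
        if X.shape[0] / self.fs < 2.0 / self.cof_hz:
            raise LengthError(
                f"record of {X.shape[0] / self.fs:.1f} s is too short to "
                f"separate motion from gravity at {self.cof_hz} Hz "
                f"(need > {2.0 / self.cof_hz:.0f} s)"
            )
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        self.intensity_ = self.score_samples(X)
        self.mask_ = self._threshold(self.intensity_)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Smoothed motion-intensity signal in g (non-negative)."""
        X = self._validate(X)
        mag = filters.magnitude(X)
        hp = filters.highpass(mag, self.fs, self.cof_hz)
        return filters.hann_smooth(np.abs(hp), self.window_s, self.fs)

    def _threshold(self, intensity: np.ndarray) -> np.ndarray:
        mask = intensity < self.threshold_g
        min_len = int(round(self.min_duration_s * self.fs))
        return _drop_short_runs(mask, max(min_len, 1))

    def predict(self, X) -> np.ndarray:
        """Boolean mask, True where the sample is quasi-static."""
        return self._threshold(self.score_samples(X))

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).mask_


def detect_quasi_static(series: AccelTimeSeries, cof_hz: float = 0.1,
                        window_s: float = 2.0, threshold_g: float = 0.02,
                        min_duration_s: float = 2.0) -> QuasiStaticMask:
    """Identify quasi-static samples of a recording.

    Thin wrapper over :class:`QuasiStaticDetector` returning a
    :class:`QuasiStaticMask`.
    """
    det = QuasiStaticDetector(fs=series.fs, cof_hz=cof_hz, window_s=window_s,
                              threshold_g=threshold_g,
                              min_duration_s=min_duration_s)
    det.fit(series.samples)
    return QuasiStaticMask(mask=det.mask_, intensity=det.intensity_,
                           threshold_g=threshold_g,
                           min_duration_s=min_duration_s)


def estimate_gravity(series: AccelTimeSeries, mask: QuasiStaticMask,
                     cof_hz: float = 0.1) -> GravityEstimate:
    """Average the low-passed reading over quasi-static samples.

    The three axis channels are low-pass filtered (removing impacts,
    high-frequency noise and limb movements), the filtered rows where the
    mask is true are averaged, and the mean is normalized to the unit
    vector ĝ — the direction of the measured gravitational acceleration in
    the sensor frame.  No sign flip is applied.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape[0] != series.n_samples:
        raise ParameterError("mask length does not match the record")
    if not m.any():
        raise NoQuasiStaticError(
            "no quasi-static samples; use the assisted/manual mode"
        )
    low = filters.lowpass(series.samples, series.fs, cof_hz)
    mean = low[m].mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < 0.1:
        raise DegenerateGravityError(
            f"mean quasi-static reading has magnitude {norm:.3f} g (< 0.1 g)"
        )
    mean_mag = float(filters.magnitude(low[m]).mean())
    return GravityEstimate(g_hat=mean / norm, n_samples=int(m.sum()),
                           mean_magnitude_g=mean_mag)
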