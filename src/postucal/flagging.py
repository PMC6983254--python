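"""Detection of erroneous-orientation segments in calibrated recordings.

After calibration the low-frequency component of the reading should point
along the downward vertical.  Intervals where the low-passed gravity
direction deviates from vertical beyond a user threshold indicate either a
sensor that shifted on the body since calibration or a sustained
non-upright posture (e.g. lying down); telling the two apart is left to the
user.  Flags are advisory — nothing is recalibrated automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import filters
from .exceptions import ParameterError
from .ingest import AccelTimeSeries

_DOWN = np.array([0.0, 0.0, -1.0])

#: below this low-passed magnitude (g) the direction is meaningless
#: (free-fall-like; sustained non-gravitational acceleration)
MIN_GRAVITY_NORM_G = 0.1


@dataclass
class FlaggedSegments:
    """Disjoint, sorted intervals whose gravity deviation exceeds threshold."""

    segments: list  # of (start_index, end_index half-open, max_deviation_deg)
    threshold_deg: float
    min_duration_s: float

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def to_times(self, fs: float, t0: float = 0.0):
        """Segments as (start_s, end_s, max_deviation_deg)."""
        return [
            (t0 + a / fs, t0 + b / fs, d) for a, b, d in self.segments
        ]


def deviation_angle_signal(calibrated: AccelTimeSeries,
                           cof_hz: float = 0.1) -> np.ndarray:
    """Per-sample angle (degrees) between low-passed gravity and vertical.

    The three channels are low-pass filtered to isolate the gravitational
    measurement; the returned angle is in [0, 180].  Samples whose
    low-passed vector has magnitude below 0.1 g are NaN — there the reading
    is free-fall-like and no direction can be trusted.
    """
    low = filters.lowpass(calibrated.samples, calibrated.fs, cof_hz)
    norm = filters.magnitude(low)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (low @ _DOWN) / norm
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angle[norm < MIN_GRAVITY_NORM_G] = np.nan
    return angle


class OrientationErrorFlagger(BaseEstimator):
    """Flag intervals where the calibrated gravity is off vertical.

    ``fit`` computes the deviation signal of an m×3 calibrated array and the
    flagged segments; ``predict`` returns the per-sample boolean flag.
    Above-threshold runs separated by less than ``min_duration_s`` are
    merged (one physical event should not fragment) and runs shorter than
    ``min_duration_s`` are dropped.  NaN deviation samples count as
    above-threshold.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    threshold_deg : float, default 15.0
        User deviation threshold in degrees, in (0, 180).
    cof_hz : float, default 0.1
        Low-pass cutoff isolating gravity.
    min_duration_s : float, default 10.0
        Minimum flagged duration and merging gap, seconds.
    """

    def __init__(self, fs: float = 60.0, threshold_deg: float = 15.0,
                 cof_hz: float = 0.1, min_duration_s: float = 10.0):
        self.fs = fs
        self.threshold_deg = threshold_deg
        self.cof_hz = cof_hz
        self.min_duration_s = min_duration_s

    def fit(self, X, y=None):
        if not (0.0 < self.threshold_deg < 180.0):
            raise ParameterError("threshold_deg must be in (0, 180)")
        X = check_array(X)
        if X.shape[1] != 3:
            raise ParameterError(f"expected m×3 samples, got {X.shape}")
        self.n_features_in_ = 3
        series = AccelTimeSeries(t0=0.0, fs=self.fs, samples=X)
        dev = deviation_angle_signal(series, self.cof_hz)
        self.deviation_deg_ = dev
        above = np.isnan(dev) | (dev > self.threshold_deg)
        min_len = max(int(round(self.min_duration_s * self.fs)), 1)

        runs = _true_runs(above)
        runs = _merge_gaps(runs, min_len)
        runs = [(a, b) for a, b in runs if b - a >= min_len]
        segments = []
        for a, b in runs:
            chunk = dev[a:b]
            max_dev = float(np.nanmax(chunk)) if not np.isnan(chunk).all() else float("nan")
            segments.append((int(a), int(b), max_dev))
        self.segments_ = segments
        self.flagged_ = np.zeros(X.shape[0], dtype=bool)
        for a, b, _ in segments:
            self.flagged_[a:b] = True
        return self

    def predict(self, X) -> np.ndarray:
        """Per-sample boolean flag for the array given to ``fit``-style input."""
        self.fit(X)
        return self.flagged_

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).flagged_


def _true_runs(mask: np.ndarray):
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _merge_gaps(runs, min_gap: int):
    merged = []
    for a, b in runs:
        if merged and a - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def detect_orientation_errors(calibrated: AccelTimeSeries,
                              threshold_deg: float = 15.0,
                              min_duration_s: float = 10.0,
                              cof_hz: float = 0.1) -> FlaggedSegments:
    """Flag intervals whose gravity deviation exceeds ``threshold_deg``.

    Thin wrapper over :class:`OrientationErrorFlagger`.
    """
    flagger = OrientationErrorFlagger(
        fs=calibrated.fs, threshold_deg=threshold_deg, cof_hz=cof_hz,
        min_duration_s=min_duration_s,
    )
    flagger.fit(calibrated.samples)
    return FlaggedSegments(segments=flagger.segments_,
                           threshold_deg=threshold_deg,
                           min_duration_s=min_duration_s)
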