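"""Threshold-based activity classification: idle, walk, run.

A single motion-intensity signal — the Hann-smoothed absolute deviation of
the acceleration magnitude from its low-passed (gravity) baseline — is
thresholded twice.  The magnitude is rotation-invariant, so activity labels
do not depend on how (or how well) the sensor is mounted or calibrated.
Intensity below the walk threshold is idle, at or above the run threshold
is run, walk in between; bouts shorter than a minimum duration are absorbed
into a neighbour to remove label chatter around transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array

from . import filters
from .exceptions import ParameterError
from .ingest import AccelTimeSeries

IDLE, WALK, RUN = "idle", "walk", "run"
_STATES = (IDLE, WALK, RUN)


@dataclass
class ActivityLabels:
    """Per-sample activity labels with the intensity and thresholds used."""

    labels: np.ndarray
    intensity: np.ndarray
    walk_threshold_g: float
    run_threshold_g: float
    bouts: list  # of (state, start_index, end_index half-open)


def _bouts_of(labels: np.ndarray):
    """Maximal constant runs of a label array as (state, start, stop)."""
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(labels)]))
    return [(str(labels[a]), int(a), int(b)) for a, b in zip(starts, stops)]


def _absorb_short_bouts(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb bouts shorter than ``min_len`` into a neighbouring state.

    The shortest offending bout is relabelled first (earlier on ties), into
    whichever adjacent bout is longer (earlier on ties), until every
    remaining bout is at least ``min_len`` samples or a single bout is left.
    """
    labels = labels.copy()
    while True:
        bouts = _bouts_of(labels)
        if len(bouts) <= 1:
            return labels
        short = [(b - a, i) for i, (_, a, b) in enumerate(bouts)
                 if b - a < min_len]
        if not short:
            return labels
        _, i = min(short)
        state, a, b = bouts[i]
        left = bouts[i - 1] if i > 0 else None
        right = bouts[i + 1] if i < len(bouts) - 1 else None
        if left is None:
            target = right
        elif right is None:
            target = left
        else:
            llen = left[2] - left[1]
            rlen = right[2] - right[1]
            target = left if llen >= rlen else right
        labels[a:b] = target[0]


class ActivityClassifier(BaseEstimator, ClassifierMixin):
    """Classify each sample of a triaxial recording as idle/walk/run.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    cof_hz : float, default 0.1
        Low-pass cutoff for the gravity baseline of the magnitude.
    window_s : float, default 2.0
        Hann smoothing window in seconds.
    walk_threshold_g : float, default 0.05
        Intensity at or above which a sample is at least walking.
    run_threshold_g : float, default 0.4
        Intensity at or above which a sample is running.
    min_bout_s : float, default 2.0
        Bouts shorter than this are absorbed into a neighbour.
    """

    def __init__(self, fs: float = 60.0, cof_hz: float = 0.1,
                 window_s: float = 2.0, walk_threshold_g: float = 0.05,
                 run_threshold_g: float = 0.4, min_bout_s: float = 2.0):
        self.fs = fs
        self.cof_hz = cof_hz
        self.window_s = window_s
        self.walk_threshold_g = walk_threshold_g
        self.run_threshold_g = run_threshold_g
        self.min_bout_s = min_bout_s

    def _check_params(self):
        if not (self.walk_threshold_g < self.run_threshold_g):
            raise ParameterError(
                "walk_threshold_g must be below run_threshold_g"
            )

    def fit(self, X, y=None):
        self._check_params()
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array(sorted(_STATES))
        return self

    def score_samples(self, X) -> np.ndarray:
        """Motion-intensity signal in g (non-negative)."""
        self._check_params()
        X = check_array(X)
        mag = filters.magnitude(X)
        baseline = filters.lowpass(mag, self.fs, self.cof_hz)
        return filters.hann_smooth(np.abs(mag - baseline), self.window_s,
                                   self.fs)

    def predict_from_intensity(self, intensity: np.ndarray) -> np.ndarray:
        """Threshold a precomputed intensity signal into labels."""
        self._check_params()
        intensity = np.asarray(intensity, dtype=float)
        labels = np.full(intensity.shape, WALK, dtype=object)
        labels[intensity < self.walk_threshold_g] = IDLE
        labels[intensity >= self.run_threshold_g] = RUN
        min_len = max(int(round(self.min_bout_s * self.fs)), 1)
        return _absorb_short_bouts(labels, min_len).astype(str)

    def predict(self, X) -> np.ndarray:
        return self.predict_from_intensity(self.score_samples(X))


def activity_intensity(series: AccelTimeSeries, cof_hz: float = 0.1,
                       window_s: float = 2.0) -> np.ndarray:
    """Smoothed motion-band magnitude, the input to the classifier."""
    clf = ActivityClassifier(fs=series.fs, cof_hz=cof_hz, window_s=window_s)
    return clf.score_samples(series.samples)


def classify_activity(intensity: np.ndarray, fs: float,
                      walk_threshold_g: float = 0.05,
                      run_threshold_g: float = 0.4,
                      min_bout_s: float = 2.0) -> ActivityLabels:
    """Threshold an intensity signal into idle/walk/run labels.

    Thin wrapper over :class:`ActivityClassifier`.
    """
    clf = ActivityClassifier(fs=fs, walk_threshold_g=walk_threshold_g,
                             run_threshold_g=run_threshold_g,
                             min_bout_s=min_bout_s)
    labels = clf.predict_from_intensity(intensity)
    return ActivityLabels(labels=labels, intensity=np.asarray(intensity, float),
                          walk_threshold_g=walk_threshold_g,
                          run_threshold_g=run_threshold_g,
                          bouts=_bouts_of(labels))


def label_activity(series: AccelTimeSeries, cof_hz: float = 0.1,
                   window_s: float = 2.0, walk_threshold_g: float = 0.05,
                   run_threshold_g: float = 0.4,
                   min_bout_s: float = 2.0) -> ActivityLabels:
    """Intensity + classification in one call on a recording."""
    intensity = activity_intensity(series, cof_hz, window_s)
    return classify_activity(intensity, series.fs, walk_threshold_g,
                             run_threshold_g, min_bout_s)
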