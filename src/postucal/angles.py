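"""Segment tilt angles and per-window activity/posture summaries.

The tilt of a body segment carrying the sensor is the angle between the
low-passed calibrated reading and the downward vertical — 0° standing
upright, 90° lying.  Hour-scale summaries combine the tilt with activity
labels into the percentages of time walking and running plus a mean tilt,
the quantities typically tabulated against a logbook in long field
recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activity import ActivityLabels, RUN, WALK
from .exceptions import AlignmentError, ParameterError
from .flagging import deviation_angle_signal
from .ingest import AccelTimeSeries


@dataclass
class TiltSeries:
    """Per-sample tilt angle (degrees, [0, 180]; NaN where gravity is lost)."""

    angle_deg: np.ndarray
    fs: float
    t0: float = 0.0


@dataclass
class WindowSummary:
    """Activity percentages and mean tilt over one time window."""

    start_s: float
    end_s: float
    walk_pct: float
    run_pct: float
    mean_tilt_deg: float


def tilt_angle(calibrated: AccelTimeSeries, cof_hz: float = 0.1) -> TiltSeries:
    """Tilt of the calibrated sensor relative to vertical, per sample.

    Identical computation to the orientation-error deviation signal,
    exposed as a kinematic output.
    """
    return TiltSeries(
        angle_deg=deviation_angle_signal(calibrated, cof_hz),
        fs=calibrated.fs,
        t0=calibrated.t0,
    )


def summarize_windows(calibrated: AccelTimeSeries, labels: ActivityLabels,
                      tilt: TiltSeries,
                      window_s: float = 3600.0) -> list[WindowSummary]:
    """Summarize activity and tilt over consecutive non-overlapping windows.

    Per window: percentage of samples labelled walk and run, and the mean
    tilt ignoring NaN samples.  A trailing partial window is included when
    it covers at least 10% of ``window_s``.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    m = calibrated.n_samples
    if len(labels.labels) != m or len(tilt.angle_deg) != m:
        raise AlignmentError(
            f"length mismatch: samples {m}, labels {len(labels.labels)}, "
            f"tilt {len(tilt.angle_deg)}"
        )
    fs = calibrated.fs
    win = int(round(window_s * fs))
    summaries = []
    for start in range(0, m, win):
        stop = min(start + win, m)
        if stop - start < 0.1 * win and start > 0:
            break
        lab = labels.labels[start:stop]
        ang = tilt.angle_deg[start:stop]
        n = stop - start
        mean_tilt = float(np.nanmean(ang)) if not np.isnan(ang).all() else float("nan")
        summaries.append(WindowSummary(
            start_s=start / fs,
            end_s=stop / fs,
            walk_pct=100.0 * float(np.sum(lab == WALK)) / n,
            run_pct=100.0 * float(np.sum(lab == RUN)) / n,
            mean_tilt_deg=mean_tilt,
        ))
    return summaries
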