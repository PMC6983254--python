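"""Zero-phase filtering and Hann-window smoothing.

All downstream stages share the same preprocessing primitives: a
bidirectional (forward–backward) Butterworth filter, which cancels phase
delay at the cost of applying the magnitude response twice, and a
normalized Hann moving average.  The Butterworth filter is designed as
second-order sections; at the very low normalized cutoffs typical here
(0.1 Hz at 60 Hz sampling) a transfer-function realization would be
numerically fragile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import LengthError, ParameterError

DEFAULT_CUTOFF_HZ = 0.1
DEFAULT_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """Specification of a low- or high-pass filter.

    ``cutoff_hz`` is the single-pass −3 dB point; ``order`` is the order of
    one pass (a bidirectional application squares the magnitude response).
    """

    kind: str = "lowpass"
    cutoff_hz: float = DEFAULT_CUTOFF_HZ
    order: int = DEFAULT_ORDER
    bidirectional: bool = True

    def __post_init__(self):
        if self.kind not in ("lowpass", "highpass"):
            raise ParameterError(f"unknown filter kind {self.kind!r}")
        if not (self.cutoff_hz > 0):
            raise ParameterError("cutoff_hz must be > 0")
        if self.order < 1:
            raise ParameterError("order must be >= 1")


def _design(spec: FilterSpec, fs: float):
    if not (spec.cutoff_hz < fs / 2):
        raise ParameterError(
            f"cutoff {spec.cutoff_hz} Hz must be below Nyquist {fs / 2} Hz"
        )
    return signal.butter(
        spec.order, spec.cutoff_hz, btype=spec.kind, fs=fs, output="sos"
    )


def filter_signal(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply ``spec`` to a 1-D signal or m×3 array along the time axis.

    Bidirectional application (the default) runs the filter forward then
    backward, yielding zero phase lag.  Edge transients are suppressed with
    odd-reflection padding of length 3×order.
    """
    x = np.asarray(x, dtype=float)
    m = x.shape[0]
    padlen = 3 * spec.order
    if m <= padlen:
        raise LengthError(
            f"signal of {m} samples is too short for order-{spec.order} "
            f"filtering (need > {padlen})"
        )
    sos = _design(spec, fs)
    if spec.bidirectional:
        return signal.sosfiltfilt(sos, x, axis=0, padtype="odd", padlen=padlen)
    return signal.sosfilt(sos, x, axis=0)


def lowpass(x: np.ndarray, fs: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
            order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase low-pass; isolates the gravity component of a recording."""
    return filter_signal(x, FilterSpec("lowpass", cutoff_hz, order), fs)


def highpass(x: np.ndarray, fs: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ,
             order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase high-pass; isolates the motion component of a recording."""
    return filter_signal(x, FilterSpec("highpass", cutoff_hz, order), fs)


def hann_smooth(x: np.ndarray, window_s: float, fs: float) -> np.ndarray:
    """Moving weighted average with normalized Hann weights.

    The window length is ``round(window_s * fs)`` samples, forced odd so the
    window is centered; the weights sum to one.  At the record edges the
    window is truncated and renormalized, keeping the output the same
    length as the input.  A window that rounds to one sample is the
    identity.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    x = np.asarray(x, dtype=float)
    n = int(round(window_s * fs))
    if n < 1:
        raise ParameterError("window rounds to zero samples")
    if n % 2 == 0:
        n += 1
    if n == 1:
        return x.copy()
    w = signal.windows.hann(n, sym=True)
    w = w / w.sum()
    num = np.convolve(x, w, mode="same")
    den = np.convolve(np.ones_like(x), w, mode="same")
    return num / den


def magnitude(samples: np.ndarray) -> np.ndarray:
    """Per-row Euclidean norm of an m×3 array, in g."""
    samples = np.asarray(samples, dtype=float)
    return np.linalg.norm(samples, axis=-1)
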