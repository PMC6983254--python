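import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def still_series():
    """60 s noiseless upright recording at 60 Hz."""
    from postucal import AccelTimeSeries

    samples = np.tile([0.0, 0.0, -1.0], (3600, 1))
    return AccelTimeSeries(t0=0.0, fs=60.0, samples=samples)


def geodesic_deg(A: np.ndarray, B: np.ndarray) -> float:
    """Angle of the relative rotation between two rotation matrices."""
    cosang = (np.trace(A @ B.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def heading_ambiguous_error_deg(R: np.ndarray, R_true: np.ndarray) -> float:
    """Geodesic error modulo the forward/backward π heading ambiguity."""
    Rz_pi = np.diag([-1.0, -1.0, 1.0])
    return min(geodesic_deg(R, R_true), geodesic_deg(Rz_pi @ R, R_true))
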