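"""Synthetic wearable-accelerometer recordings with ground truth.

The generator emulates the signal structure the calibration method relies
on: gravity measured in an arbitrarily rotated sensor frame, long
quasi-static neutral-posture epochs, locomotion whose variance is dominated
by the forward axis (sinusoidal surrogates for walking and running),
lying-down episodes, instantaneous sensor-shift events, and additive
Gaussian noise.  World-frame specific force is built per scripted event and
mapped through the current mounting rotation; every draw is determined by
the scenario seed.

The waveforms are deliberately simple surrogates — fixed-frequency
sinusoids, not biomechanically realistic gait — chosen to separate the
three activity-intensity classes and to give the heading SVD a dominant
horizontal axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import ConfigError
from .ingest import AccelTimeSeries

DOWN = np.array([0.0, 0.0, -1.0])

# surrogate locomotion parameters (frequency Hz, horizontal / vertical
# amplitude g); plausible magnitudes for waist or thigh mounts
WALK_FREQ_HZ, WALK_AMP_X_G, WALK_AMP_Z_G = 1.8, 0.15, 0.20
RUN_FREQ_HZ, RUN_AMP_X_G, RUN_AMP_Z_G = 2.8, 0.5, 0.7

_EVENT_KINDS = ("still", "walk", "run", "lie", "shift")


@dataclass
class Event:
    """One scripted episode.

    ``shift`` events are instantaneous (only ``start_s`` matters) and carry
    ``params["new_rotation"]``, the world→sensor mounting applied from that
    time onward; all other kinds occupy ``[start_s, end_s)``.
    """

    kind: str
    start_s: float
    end_s: float
    params: dict = field(default_factory=dict)


@dataclass
class ScenarioConfig:
    """Full description of a synthetic recording."""

    duration_s: float
    script: list
    true_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    fs: float = 60.0
    noise_sigma_g: float = 0.02
    seed: int = 0


@dataclass
class GroundTruth:
    """Per-sample truth paired with a generated recording."""

    activity: np.ndarray
    tilt_deg: np.ndarray
    shift_times: list
    shift_rotations: list
    heading_rad: float
    true_rotation: np.ndarray
    events: list


def rotation_from_tilt_heading(tilt_deg: float, heading_deg: float,
                               roll_deg: float = 0.0) -> np.ndarray:
    """Mounting rotation (world→sensor) with a given tilt from vertical.

    Built as intrinsic z–y–z Euler angles: heading about the vertical,
    tilt away from it, then roll about the sensor axis.
    """
    return Rotation.from_euler(
        "ZYZ", [heading_deg, tilt_deg, roll_deg], degrees=True
    ).as_matrix()


def random_mounting(rng: np.random.Generator,
                    max_tilt_deg: float = 60.0) -> np.ndarray:
    """Random mounting rotation with tilt uniform in [0, max_tilt_deg]."""
    return rotation_from_tilt_heading(
        tilt_deg=rng.uniform(0.0, max_tilt_deg),
        heading_deg=rng.uniform(0.0, 360.0),
        roll_deg=rng.uniform(0.0, 360.0),
    )


def _roty(deg: float) -> np.ndarray:
    return Rotation.from_euler("y", deg, degrees=True).as_matrix()


def _validate_script(config: ScenarioConfig):
    for ev in config.script:
        if ev.kind not in _EVENT_KINDS:
            raise ConfigError(f"unknown event kind {ev.kind!r}")
    posture = sorted(
        (ev for ev in config.script if ev.kind != "shift"),
        key=lambda e: e.start_s,
    )
    if not posture:
        raise ConfigError("script must contain at least one non-shift event")
    cursor = 0.0
    for ev in posture:
        if ev.start_s < cursor - 1e-9:
            raise ConfigError(
                f"overlapping events at {ev.start_s} s (previous ends {cursor} s)"
            )
        if abs(ev.start_s - cursor) > 1e-9:
            raise ConfigError(f"script gap at {cursor}–{ev.start_s} s")
        cursor = ev.end_s
    if abs(cursor - config.duration_s) > 1e-9:
        raise ConfigError(
            f"script covers [0, {cursor}] s but duration is {config.duration_s} s"
        )
    return posture


def true_heading(true_rotation: np.ndarray) -> float:
    """Heading a perfect calibration of this mounting would report.

    The world forward axis +x seen in the sensor frame, levelled by the
    minimal gravity-alignment rotation, points at this angle from +x.
    """
    from .calibrate import gravity_alignment_rotation

    Q = np.asarray(true_rotation, dtype=float)
    g_hat = Q @ DOWN
    R_prime = gravity_alignment_rotation(g_hat)
    d = R_prime @ (Q @ np.array([1.0, 0.0, 0.0]))
    return float(np.arctan2(d[1], d[0]))


def generate_recording(config: ScenarioConfig) -> tuple[AccelTimeSeries, GroundTruth]:
    """Generate a recording and its ground truth from a scenario.

    World-frame specific force is (0,0,−1) g plus the event's motion term;
    each row is mapped through the mounting rotation in force at that time
    and perturbed with i.i.d. zero-mean Gaussian noise per axis.
    """
    posture = _validate_script(config)
    fs = float(config.fs)
    m = int(round(config.duration_s * fs))
    t = np.arange(m) / fs

    force_body = np.tile(DOWN, (m, 1))
    activity = np.full(m, "idle", dtype="<U4")
    tilt_deg = np.zeros(m)

    for ev in posture:
        a = int(round(ev.start_s * fs))
        b = min(int(round(ev.end_s * fs)), m)
        if b <= a:
            continue
        tt = t[a:b]
        if ev.kind in ("walk", "run"):
            if ev.kind == "walk":
                freq = ev.params.get("freq_hz", WALK_FREQ_HZ)
                amp_x = ev.params.get("amp_x_g", WALK_AMP_X_G)
                amp_z = ev.params.get("amp_z_g", WALK_AMP_Z_G)
            else:
                freq = ev.params.get("freq_hz", RUN_FREQ_HZ)
                amp_x = ev.params.get("amp_x_g", RUN_AMP_X_G)
                amp_z = ev.params.get("amp_z_g", RUN_AMP_Z_G)
            phase = 2.0 * np.pi * freq * (tt - ev.start_s)
            force_body[a:b, 0] = amp_x * np.sin(phase)
            force_body[a:b, 2] = DOWN[2] + amp_z * np.sin(phase + np.pi / 2)
            activity[a:b] = ev.kind
        elif ev.kind == "lie":
            tilt = ev.params.get("tilt_deg", 90.0)
            # gravity as read by a body tilted about the world y axis
            force_body[a:b] = _roty(tilt).T @ DOWN
            tilt_deg[a:b] = tilt

    # mounting rotation per sample: base rotation until the first shift,
    # then each shift's new rotation from its start time onward
    shifts = sorted((ev for ev in config.script if ev.kind == "shift"),
                    key=lambda e: e.start_s)
    boundaries = [0] + [int(round(ev.start_s * fs)) for ev in shifts] + [m]
    rotations = [np.asarray(config.true_rotation, dtype=float)]
    for ev in shifts:
        if "new_rotation" not in ev.params:
            raise ConfigError("shift event needs params['new_rotation']")
        rotations.append(np.asarray(ev.params["new_rotation"], dtype=float))

    samples = np.empty((m, 3))
    for Q, a, b in zip(rotations, boundaries[:-1], boundaries[1:]):
        samples[a:b] = force_body[a:b] @ Q.T

    rng = np.random.default_rng(config.seed)
    if config.noise_sigma_g > 0:
        samples = samples + rng.normal(0.0, config.noise_sigma_g, (m, 3))

    series = AccelTimeSeries(
        t0=0.0, fs=fs, samples=samples,
        meta={"synthetic": True, "seed": config.seed},
    )
    truth = GroundTruth(
        activity=activity,
        tilt_deg=tilt_deg,
        shift_times=[ev.start_s for ev in shifts],
        shift_rotations=[np.asarray(ev.params["new_rotation"], float)
                         for ev in shifts],
        heading_rad=true_heading(config.true_rotation),
        true_rotation=np.asarray(config.true_rotation, dtype=float),
        events=list(config.script),
    )
    return series, truth


# ---------------------------------------------------------------------------
# scenario presets


def walk_calibration_scenario(true_rotation: np.ndarray | None = None,
                              duration_s: float = 600.0,
                              noise_sigma_g: float = 0.02,
                              seed: int = 0,
                              fs: float = 60.0) -> ScenarioConfig:
    """Rest-dominated scenario with two walking bouts along world +x.

    The default timing keeps roughly 60% of the record quasi-static, which
    satisfies the neutral-posture assumption while leaving enough forward
    locomotion for the heading SVD.
    """
    if true_rotation is None:
        true_rotation = np.eye(3)
    f = duration_s / 600.0
    script = [
        Event("still", 0.0, 150.0 * f),
        Event("walk", 150.0 * f, 270.0 * f),
        Event("still", 270.0 * f, 330.0 * f),
        Event("walk", 330.0 * f, 450.0 * f),
        Event("still", 450.0 * f, 600.0 * f),
    ]
    return ScenarioConfig(duration_s=duration_s, script=script,
                          true_rotation=true_rotation, fs=fs,
                          noise_sigma_g=noise_sigma_g, seed=seed)


def activity_script_scenario(true_rotation: np.ndarray | None = None,
                             noise_sigma_g: float = 0.02, seed: int = 0,
                             fs: float = 60.0) -> ScenarioConfig:
    """Five-minute idle–walk–run–walk–idle script (60 s each)."""
    if true_rotation is None:
        true_rotation = np.eye(3)
    script = [
        Event("still", 0.0, 60.0),
        Event("walk", 60.0, 120.0),
        Event("run", 120.0, 180.0),
        Event("walk", 180.0, 240.0),
        Event("still", 240.0, 300.0),
    ]
    return ScenarioConfig(duration_s=300.0, script=script,
                          true_rotation=true_rotation, fs=fs,
                          noise_sigma_g=noise_sigma_g, seed=seed)


def lab_routine_scenario(true_rotation: np.ndarray | None = None,
                         include_shifts: bool = True,
                         include_lying: bool = True,
                         shift_tilt_deg: float = 30.0,
                         noise_sigma_g: float = 0.02, seed: int = 0,
                         fs: float = 60.0) -> ScenarioConfig:
    """15-minute mixed routine: 6 walks, 2 runs, 2 lying episodes, 3 shifts.

    Each deliberate sensor shift tilts the mounting by ``shift_tilt_deg``
    for 35 s and is then restored, so every perturbation produces one
    bounded flagged interval.  With ``include_shifts=False`` and
    ``include_lying=False`` the scenario is an upright control that should
    produce no orientation-error flags.
    """
    if true_rotation is None:
        true_rotation = np.eye(3)
    Q0 = np.asarray(true_rotation, dtype=float)
    lie = "lie" if include_lying else "still"
    script = [
        Event("still", 0.0, 60.0),
        Event("walk", 60.0, 90.0),
        Event("still", 90.0, 120.0),
        Event("walk", 120.0, 150.0),
        Event("still", 150.0, 180.0),
        Event("run", 180.0, 210.0),
        Event("still", 210.0, 255.0),
        Event("walk", 255.0, 285.0),
        Event(lie, 285.0, 345.0),
        Event("still", 345.0, 375.0),
        Event("walk", 375.0, 405.0),
        Event("still", 405.0, 450.0),
        Event("walk", 450.0, 480.0),
        Event("still", 480.0, 510.0),
        Event("run", 510.0, 540.0),
        Event(lie, 540.0, 600.0),
        Event("still", 600.0, 660.0),
        Event("walk", 660.0, 690.0),
        Event("still", 690.0, 900.0),
    ]
    if include_shifts:
        shifted = Q0 @ _roty(shift_tilt_deg)
        for start, stop in ((215.0, 250.0), (410.0, 445.0), (695.0, 730.0)):
            script.append(Event("shift", start, start,
                                {"new_rotation": shifted}))
            script.append(Event("shift", stop, stop,
                                {"new_rotation": Q0}))
    return ScenarioConfig(duration_s=900.0, script=script,
                          true_rotation=Q0, fs=fs,
                          noise_sigma_g=noise_sigma_g, seed=seed)


PRESETS = {
    "lab-routine": lab_routine_scenario,
    "upright-control": lambda **kw: lab_routine_scenario(
        include_shifts=False, include_lying=False, **kw),
    "walk-calibration": walk_calibration_scenario,
    "activity-script": activity_script_scenario,
}


def flag_onsets(config: ScenarioConfig) -> list[float]:
    """Ground-truth onset times (s) of orientation-error intervals.

    Outward shifts (mounting leaving the base rotation) and lying episodes
    both move the measured gravity off vertical.
    """
    onsets = []
    Q0 = np.asarray(config.true_rotation, dtype=float)
    for ev in config.script:
        if ev.kind == "lie":
            onsets.append(ev.start_s)
        elif ev.kind == "shift":
            if not np.allclose(ev.params["new_rotation"], Q0):
                onsets.append(ev.start_s)
    return sorted(onsets)
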