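"""The synthetic-recording generator and its scenario presets."""

import numpy as np
import pytest

from postucal import (
    Event,
    ScenarioConfig,
    detect_quasi_static,
    generate_recording,
    rotation_from_tilt_heading,
)
from postucal.exceptions import ConfigError
from postucal.simulate import (
    WALK_AMP_X_G,
    WALK_FREQ_HZ,
    activity_script_scenario,
    flag_onsets,
    lab_routine_scenario,
    walk_calibration_scenario,
)


def _still_config(**kw):
    defaults = dict(duration_s=30.0,
                    script=[Event("still", 0.0, 30.0)],
                    noise_sigma_g=0.0, seed=0)
    defaults.update(kw)
    return ScenarioConfig(**defaults)


def test_noiseless_still_scenario_is_rotated_gravity():
    Q = rotation_from_tilt_heading(40.0, 120.0, 30.0)
    series, truth = generate_recording(_still_config(true_rotation=Q))
    expected = Q @ np.array([0.0, 0.0, -1.0])
    np.testing.assert_allclose(series.samples, np.tile(expected, (1800, 1)),
                               atol=1e-12)
    np.testing.assert_allclose(np.linalg.norm(series.samples, axis=1), 1.0,
                               atol=1e-12)
    assert (truth.activity == "idle").all()


def test_same_seed_is_bit_identical():
    config = lab_routine_scenario(seed=77)
    a, _ = generate_recording(config)
    b, _ = generate_recording(lab_routine_scenario(seed=77))
    assert np.array_equal(a.samples, b.samples)


def test_different_seed_differs():
    a, _ = generate_recording(_still_config(noise_sigma_g=0.02, seed=1))
    b, _ = generate_recording(_still_config(noise_sigma_g=0.02, seed=2))
    assert not np.array_equal(a.samples, b.samples)


def test_walk_event_is_closed_form_sinusoid():
    config = ScenarioConfig(
        duration_s=60.0,
        script=[Event("still", 0.0, 10.0), Event("walk", 10.0, 50.0),
                Event("still", 50.0, 60.0)],
        noise_sigma_g=0.0, seed=0)
    series, truth = generate_recording(config)
    fs = series.fs
    i = slice(int(10 * fs), int(50 * fs))
    t_rel = np.arange(int(40 * fs)) / fs
    expected_x = WALK_AMP_X_G * np.sin(2 * np.pi * WALK_FREQ_HZ * t_rel)
    np.testing.assert_allclose(series.samples[i, 0], expected_x, atol=1e-12)
    assert (truth.activity[i] == "walk").all()


def test_mean_magnitude_of_noisy_still_epoch_is_one_g():
    config = _still_config(duration_s=120.0,
                           script=[Event("still", 0.0, 120.0)],
                           noise_sigma_g=0.02, seed=5)
    series, _ = generate_recording(config)
    n = series.n_samples
    mean_mag = np.linalg.norm(series.samples, axis=1).mean()
    assert abs(mean_mag - 1.0) < 3 * 0.02 / np.sqrt(n) + 0.02**2


def test_overlapping_events_rejected():
    config = ScenarioConfig(
        duration_s=20.0,
        script=[Event("still", 0.0, 15.0), Event("walk", 10.0, 20.0)],
        seed=0)
    with pytest.raises(ConfigError):
        generate_recording(config)


def test_script_gap_rejected():
    config = ScenarioConfig(
        duration_s=20.0,
        script=[Event("still", 0.0, 5.0), Event("walk", 10.0, 20.0)],
        seed=0)
    with pytest.raises(ConfigError):
        generate_recording(config)


def test_shift_changes_mounting_from_its_time_onward():
    Q1 = rotation_from_tilt_heading(25.0, 0.0)
    config = ScenarioConfig(
        duration_s=20.0,
        script=[Event("still", 0.0, 20.0),
                Event("shift", 10.0, 10.0, {"new_rotation": Q1})],
        noise_sigma_g=0.0, seed=0)
    series, truth = generate_recording(config)
    down = np.array([0.0, 0.0, -1.0])
    np.testing.assert_allclose(series.samples[:600], np.tile(down, (600, 1)),
                               atol=1e-12)
    np.testing.assert_allclose(series.samples[600:],
                               np.tile(Q1 @ down, (600, 1)), atol=1e-12)
    assert truth.shift_times == [10.0]


class TestPresets:
    def test_lab_routine_structure(self):
        config = lab_routine_scenario()
        kinds = [ev.kind for ev in config.script]
        assert kinds.count("walk") == 6
        assert kinds.count("run") == 2
        assert kinds.count("lie") == 2
        assert kinds.count("shift") == 6  # three out-and-back pairs
        assert flag_onsets(config) == [215.0, 285.0, 410.0, 540.0, 695.0]

    def test_upright_control_has_no_flag_sources(self):
        config = lab_routine_scenario(include_shifts=False,
                                      include_lying=False)
        assert flag_onsets(config) == []
        assert all(ev.kind != "lie" and ev.kind != "shift"
                   for ev in config.script)

    def test_default_scenario_is_mostly_quasi_static(self):
        series, _ = generate_recording(walk_calibration_scenario(seed=6))
        mask = detect_quasi_static(series)
        assert mask.fraction > 0.5

    def test_walk_epochs_have_anisotropic_horizontal_motion(self):
        series, truth = generate_recording(walk_calibration_scenario(seed=6))
        walk = series.samples[truth.activity == "walk"]
        xy = walk[:, :2] - walk[:, :2].mean(axis=0)
        evals = np.linalg.eigvalsh(xy.T @ xy / len(xy))
        assert evals[-1] / evals[0] > 3.0

    def test_activity_script_covers_five_events(self):
        config = activity_script_scenario()
        assert [ev.kind for ev in config.script] == \
            ["still", "walk", "run", "walk", "still"]
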