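"""Time synchronization and functional sensor-to-segment alignment."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kneekin.calibration import (
    build_anatomical_frame,
    calibrate_pair,
    detect_still_intervals,
    estimate_hinge_axis,
    estimate_vertical_axis,
    synchronize,
)
from kneekin.errors import (
    DegenerateGeometryError,
    InsufficientSignalError,
    NotStillError,
    PoorCalibrationError,
)
from kneekin.simulator import TrialSpec, generate_trial
from kneekin.streams import GRAVITY, ImuStream


def _still_stream(accel_vec, n=256, fs=128.0, noise=0.0, rng=None):
    t = np.arange(n) / fs
    accel = np.tile(accel_vec, (n, 1)).astype(float)
    if noise and rng is not None:
        accel = accel + noise * rng.standard_normal((n, 3))
    return ImuStream(t, np.zeros((n, 3)), accel)


class TestSynchronize:
    def test_identical_streams_zero_lag(self, clean_fe_trial):
        assert synchronize(clean_fe_trial.shank, clean_fe_trial.shank) == pytest.approx(0.0)

    def test_known_shift_recovered(self, clean_fe_trial):
        s = clean_fe_trial.shank
        n = int(round(0.150 * 128))
        delayed = ImuStream(s.t, np.roll(s.gyro, n, axis=0), np.roll(s.accel, n, axis=0))
        lag = synchronize(s, delayed)
        assert lag == pytest.approx(0.150, abs=0.5 / 128)

    def test_pure_noise_raises(self, rng):
        t = np.arange(512) / 128.0
        mk = lambda: ImuStream(
            t, np.deg2rad(0.5) * rng.standard_normal((512, 3)),
            np.tile([0, 0, GRAVITY], (512, 1)),
        )
        with pytest.raises(InsufficientSignalError):
            synchronize(mk(), mk())


class TestVerticalAxis:
    def test_upright_sensor(self):
        s = _still_stream([0, 0, GRAVITY])
        z, a0 = estimate_vertical_axis(s, (0.0, 2.0))
        assert np.allclose(z, [0, 0, 1], atol=1e-12)
        assert np.allclose(a0, [0, 0, GRAVITY])

    def test_tilted_sensor_closed_form(self):
        # sensor rolled 30 deg about x: gravity reads (0, -sin30, cos30) * g
        vec = GRAVITY * np.array([0.0, -np.sin(np.pi / 6), np.cos(np.pi / 6)])
        z, _ = estimate_vertical_axis(_still_stream(vec), (0.0, 2.0))
        assert np.allclose(z, vec / GRAVITY, atol=1e-12)

    def test_noise_robustness_monte_carlo(self):
        # sigma = 0.1 m/s^2 noise keeps the axis within 0.5 deg of truth
        worst = 0.0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            s = _still_stream([0, 0, GRAVITY], n=256, noise=0.1, rng=rng)
            z, _ = estimate_vertical_axis(s, (0.0, 2.0))
            worst = max(worst, np.degrees(np.arccos(np.clip(z[2], -1, 1))))
        assert worst < 0.5

    def test_not_still_raises(self):
        s = _still_stream([0, 0, 1.1 * GRAVITY])
        with pytest.raises(NotStillError):
            estimate_vertical_axis(s, (0.0, 2.0))


class TestHingeAxis:
    def test_noiseless_axis_recovered_exactly(self):
        # pure hinge about sensor-frame x in both sensors (identity mounting)
        eye = tuple(map(tuple, np.eye(3)))
        trial = generate_trial(
            TrialSpec(movement="alignment", seed=0, mount_shank=eye, mount_thigh=eye,
                      trial_duration=2.5, still_post=0.5)
        )
        n_s, n_t = estimate_hinge_axis(
            trial.shank, trial.thigh, trial.phases["calibration"],
            medial_hint_s=[1, 0, 0], medial_hint_t=[1, 0, 0],
        )
        assert np.allclose(n_s, [1, 0, 0], atol=1e-6)
        assert np.allclose(n_t, [1, 0, 0], atol=1e-6)

    def test_skewed_mounting_with_noise_within_one_degree(self):
        for seed in (11, 12, 13):
            trial = generate_trial(
                TrialSpec(movement="alignment", seed=seed, gyro_noise_deg_s=0.5,
                          trial_duration=2.5, still_post=0.5)
            )
            n_s, n_t = estimate_hinge_axis(
                trial.shank, trial.thigh, trial.phases["calibration"],
                medial_hint_s=trial.calib_shank.n_hat, medial_hint_t=trial.calib_thigh.n_hat,
            )
            for est, tru in ((n_s, trial.calib_shank.n_hat), (n_t, trial.calib_thigh.n_hat)):
                err = np.degrees(np.arccos(np.clip(np.dot(est, tru), -1, 1)))
                assert err < 1.0

    def test_low_excitation_raises(self, rng):
        t = np.arange(512) / 128.0
        slow = np.deg2rad(4.0) * np.column_stack([np.sin(t), 0 * t, 0 * t])
        grav = np.tile([0, 0, GRAVITY], (512, 1))
        a = ImuStream(t, slow, grav)
        b = ImuStream(t, slow, grav)
        with pytest.raises(PoorCalibrationError):
            estimate_hinge_axis(a, b, (0.0, 4.0))

    def test_error_shrinks_with_excitation(self):
        # Monte-Carlo: larger hinge amplitude at fixed noise -> smaller axis error
        def mean_err(rom):
            errs = []
            for seed in range(8):
                trial = generate_trial(
                    TrialSpec(movement="alignment", seed=seed, gyro_noise_deg_s=1.0,
                              calib_rom_deg=rom, trial_duration=2.5, still_post=0.5)
                )
                n_s, _ = estimate_hinge_axis(
                    trial.shank, trial.thigh, trial.phases["calibration"],
                    medial_hint_s=trial.calib_shank.n_hat,
                    medial_hint_t=trial.calib_thigh.n_hat,
                )
                errs.append(
                    np.degrees(np.arccos(np.clip(np.dot(n_s, trial.calib_shank.n_hat), -1, 1)))
                )
            return np.mean(errs)

        assert mean_err(160.0) < mean_err(60.0)


class TestAnatomicalFrame:
    def test_canonical_axes_give_identity(self):
        cal = build_anatomical_frame([0, 0, 1], [1, 0, 0])
        assert np.allclose(cal.R, np.eye(3), atol=1e-12)

    def test_vertical_estimate_reorthogonalized(self):
        z_est = np.array([np.sin(np.deg2rad(5)), 0, np.cos(np.deg2rad(5))])  # tilted toward n
        cal = build_anatomical_frame(z_est, [1, 0, 0])
        assert np.allclose(cal.R @ cal.R.T, np.eye(3), atol=1e-12)
        # re-orthogonalization removes the tilt component along the hinge axis
        assert np.linalg.norm(cal.z_axis - [0, 0, 1]) < np.linalg.norm(z_est - [0, 0, 1])
        assert np.allclose(cal.x_axis, cal.n_hat)

    def test_parallel_axes_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            build_anatomical_frame([1, 0, 0], [1, 0, 0])

    def test_matches_ground_truth_mounting(self, clean_fe_trial):
        cal_s, cal_t = calibrate_pair(
            clean_fe_trial.shank, clean_fe_trial.thigh,
            still=clean_fe_trial.phases["still_pre"],
            hinge_motion=clean_fe_trial.phases["calibration"],
            medial_hint_s=clean_fe_trial.calib_shank.n_hat,
            medial_hint_t=clean_fe_trial.calib_thigh.n_hat,
        )
        for est, tru in ((cal_s, clean_fe_trial.calib_shank), (cal_t, clean_fe_trial.calib_thigh)):
            rel = Rotation.from_matrix(est.R @ tru.R.T)
            assert np.linalg.norm(rel.as_rotvec()) < 1e-6  # rad equivalent angle

    def test_json_round_trip(self, tmp_path, clean_fe_trial):
        cal = clean_fe_trial.calib_shank
        path = tmp_path / "cal.json"
        cal.to_json(path)
        from kneekin.calibration import AnatomicalCalibration

        back = AnatomicalCalibration.from_json(path)
        assert np.allclose(back.R, cal.R)
        assert np.allclose(back.a0, cal.a0)


class TestStillDetector:
    def test_finds_scripted_stills(self, noisy_drifting_trial):
        trial = noisy_drifting_trial
        ivs = detect_still_intervals(trial.shank)
        a, b = trial.phases["still_pre"]
        # at least one detected interval substantially covers the scripted still
        assert any(s <= a + 1.0 and e >= b - 1.0 for s, e in ivs)
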