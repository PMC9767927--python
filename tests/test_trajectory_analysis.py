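"""Velocity, pitch, correlation and yaw-direction quantification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gnrtrack import kinematics as K
from gnrtrack import synthetic_data as sd
from gnrtrack import trajectory_analysis as ta


def _track(duration=3.0, v=0.5, pitch=0.7, yaw_sign=-1, phi=0.0,
           noise=None, seed=0):
    mm = sd.default_motion_model(v=v, pitch_um=pitch, yaw_sign=yaw_sign, phi=phi)
    gt = sd.GroundTruth(model=mm, duration=duration, seed=seed)
    true, noisy = sd.gen_track(gt, noise or sd.NoiseSpec.none())
    return true if noise is None else noisy


class TestVelocity:
    def test_exact_linear_trace(self):
        t = np.arange(100) / 100.0
        track = pd.DataFrame({"t": t, "x_um": 0.5 * t})
        v, se = ta.fit_velocity(track)
        assert np.isclose(v, 0.5)
        assert se < 1e-12

    def test_too_short_rejected(self):
        track = pd.DataFrame({"t": np.arange(5) / 100, "x_um": np.arange(5.0)})
        with pytest.raises(ValueError):
            ta.fit_velocity(track)

    def test_noisy_slope_within_confidence(self, rng):
        t = np.arange(300) / 100.0
        hits = 0
        for _ in range(50):
            track = pd.DataFrame({"t": t, "x_um": 0.4 * t + rng.normal(0, 0.02, 300)})
            v, se = ta.fit_velocity(track)
            hits += abs(v - 0.4) < 1.96 * se
        assert hits >= 40  # ~95% coverage

    def test_kif1a_like_track(self):
        track = _track(v=0.51, noise=sd.NoiseSpec(), seed=3)
        v, _ = ta.fit_velocity(track)
        assert np.isclose(v, 0.51, rtol=0.02)


class TestDetectCycles:
    def test_pure_sine_interior_periods(self):
        # 3.2 periods: upward crossings at 0.05, 1.05, 2.05, 3.05
        t = np.linspace(0, 3.2, 3200)
        cycles = ta.detect_cycles(np.sin(2 * np.pi * (t - 0.05)), t, smooth_window=1)
        assert len(cycles) == 3
        for (t0, t1) in cycles:
            assert np.isclose(t1 - t0, 1.0, atol=2e-3)

    def test_monotone_ramp_is_empty(self):
        t = np.linspace(0, 1, 100)
        assert ta.detect_cycles(t * 2.0, t) == []

    def test_noisy_sine_period_within_5pct(self, rng):
        t = np.linspace(0, 5, 500)
        periods = []
        for _ in range(100):
            y = np.sin(2 * np.pi * t) + rng.normal(0, 0.2, len(t))
            cycles = ta.detect_cycles(y, t, smooth_window=15)
            periods.extend(t1 - t0 for t0, t1 in cycles)
        assert np.isclose(np.mean(periods), 1.0, rtol=0.05)


class TestPitches:
    def test_zero_noise_pitch_is_exact(self):
        track = _track(duration=6.0)
        hp = ta.helix_pitch(track)
        pp = ta.polarization_pitch(track)
        assert hp.n >= 3
        assert np.isclose(hp.mean, 0.7, rtol=0.02)
        assert pp.n >= 3
        assert np.isclose(pp.mean, 0.7, rtol=0.02)

    def test_helix_pitch_matches_angular_velocity(self):
        """P = 2 pi v / omega on a synthetic track."""
        track = _track(duration=4.0, v=0.4, pitch=0.56)
        hp = ta.helix_pitch(track)
        assert np.isclose(hp.mean, 0.56, rtol=0.02)

    def test_pitch_ratio_unity_for_coupled_yaw(self):
        """|omega_yaw| = |omega_helix|/2 makes the polarization pitch
        equal the helix pitch (ratio 1)."""
        for phi in (0.0, 0.9):
            track = _track(duration=6.0, phi=phi)
            ratio = ta.polarization_pitch(track).mean / ta.helix_pitch(track).mean
            assert np.isclose(ratio, 1.0, atol=0.02)

    def test_full_rate_yaw_halves_polarization_pitch(self):
        """Hypothetical full-rate yaw (omega_yaw = omega_helix, no roll
        modulation): the angle advances 360 deg per orbit, so the
        polarization pitch is half the helix pitch.  (With the roll also
        locked to the orbit the projection would instead oscillate with
        no net advance.)"""
        omega = 2 * np.pi / 1.4
        mm = sd.MotionModel(
            helix=K.HelixParams(v=0.5, omega_helix=omega, h=35.0),
            yawroll=K.YawRollParams(omega_roll=0.0, omega_yaw=omega, phi=0.3),
        )
        true, _ = sd.gen_track(sd.GroundTruth(model=mm, duration=5.6), sd.NoiseSpec.none())
        ratio = ta.polarization_pitch(true).mean / ta.helix_pitch(true).mean
        assert np.isclose(ratio, 0.5, atol=0.03)


class TestCorrectPitch:
    def test_straight_lattice_is_identity(self):
        assert ta.correct_pitch(0.7, None) == 0.7
        assert ta.correct_pitch(0.7, np.inf) == 0.7

    def test_closed_form_value(self):
        assert np.isclose(ta.correct_pitch(0.7, -24.8), 0.68078, atol=1e-4)

    def test_forward_inverse_round_trip(self):
        p_motor, p_mt = 0.66, 6.8
        p_meas = 1.0 / (1.0 / p_motor + 1.0 / p_mt)
        assert np.isclose(ta.correct_pitch(p_meas, p_mt), p_motor)

    def test_supertwist_influence_bounded_for_short_pitches(self):
        """For |P_measured| <= 1 um the correction changes the pitch by
        < 42% for every protofilament number (smallest |P_MT| = 3.4 um),
        i.e. the supertwist has limited influence on short pitches."""
        for p_mt in ta.SUPERTWIST_PITCH_UM.values():
            for p in (0.2, 0.5, 0.7, 1.0, -0.7):
                rel = abs(ta.correct_pitch(p, p_mt) - p) / abs(p)
                assert rel < 0.42

    def test_guards(self):
        with pytest.raises(ValueError):
            ta.correct_pitch(0.0, 5.0)
        with pytest.raises(ValueError):
            ta.correct_pitch(0.7, 0.7)


class TestCrossCorrelation:
    def test_identical_sinusoids(self):
        t = np.linspace(0, 4, 400, endpoint=False)
        y = np.sin(2 * np.pi * t)
        lags, ccf = ta.cross_correlation(y, y, max_lag=150)
        assert np.isclose(ccf[150], 1.0)
        peaks = lags[np.isclose(ccf, ccf.max(), atol=1e-3)]
        # CCF itself oscillates with the signal period (100 samples)
        assert np.isclose(ccf[150 + 100], 1.0, atol=0.01)

    def test_quarter_period_shift(self):
        t = np.linspace(0, 4, 400, endpoint=False)
        a = np.sin(2 * np.pi * t)
        b = np.sin(2 * np.pi * (t - 0.25))
        lags, ccf = ta.cross_correlation(a, b, max_lag=50)
        assert abs(ccf[50]) < 0.02
        assert np.argmax(ccf) == 50 + 25

    def test_constant_input_undefined(self):
        _, ccf = ta.cross_correlation(np.ones(50), np.arange(50.0), max_lag=5)
        assert np.all(np.isnan(ccf))

    def test_track_ccf_periodic_with_helix(self):
        """CCF between Y and DOP of a synthetic track oscillates with
        the helix period."""
        track = _track(duration=4.0)
        y = track.y_um.to_numpy()
        d = track.dop.to_numpy()
        lags, ccf = ta.cross_correlation(y, d, max_lag=160)
        period = 0.7 / 0.5 * 100  # frames per helix period = 140
        mid = len(lags) // 2
        assert np.isclose(ccf[mid + int(period)], ccf[mid], atol=0.15)


class TestYawDirection:
    @pytest.mark.parametrize("phi", [0.0, 0.8, 1.5, 2.4])
    def test_sign_recovers_yaw_sense(self, phi):
        for sign, expect in ((-1, "cw"), (1, "ccw")):
            track = _track(duration=3.0, yaw_sign=sign, phi=phi)
            r, direction = ta.yaw_direction(track)
            assert direction == expect

    def test_no_yaw_is_undetermined(self):
        omega = 2 * np.pi / 1.4
        mm = sd.MotionModel(
            helix=K.HelixParams(v=0.5, omega_helix=omega, h=35.0),
            yawroll=K.YawRollParams(omega_roll=omega, omega_yaw=0.0, phi=0.4),
        )
        undet = 0
        for seed in range(10):
            _, noisy = sd.gen_track(
                sd.GroundTruth(model=mm, duration=3.0, seed=seed), sd.NoiseSpec()
            )
            _, direction = ta.yaw_direction(noisy)
            undet += direction == "undetermined"
        assert undet >= 8

    def test_noisy_recovery_rate(self, rng):
        """The yaw sign is recovered from >= 95% of noisy tracks with
        random phase angles."""
        hits = total = 0
        for seed in range(40):
            sign = -1 if seed % 2 else 1
            phi = float(rng.uniform(0, np.pi))
            track = _track(duration=3.0, yaw_sign=sign, phi=phi,
                           noise=sd.NoiseSpec(), seed=seed)
            _, direction = ta.yaw_direction(track)
            total += 1
            hits += direction == ("cw" if sign == -1 else "ccw")
        assert hits / total >= 0.95


class TestSignificanceTests:
    def test_binomial_exact_tail_values(self):
        """8 cw of 13 gives p ~ 0.58 (not significant); 13 of 13 gives
        p = 2/2^13."""
        assert np.isclose(ta.binomial_direction_test(8, 13), 0.5811, atol=1e-4)
        assert np.isclose(ta.binomial_direction_test(13, 13), 2.0 / 8192)
        assert ta.binomial_direction_test(7, 14) == 1.0

    def test_binomial_matches_scipy(self):
        for n_cw, n in ((3, 10), (8, 13), (0, 5), (12, 20)):
            ours = ta.binomial_direction_test(n_cw, n)
            ref = stats.binomtest(n_cw, n, 0.5).pvalue
            assert np.isclose(ours, ref, atol=1e-12)

    def test_welch_basics(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = ta.welch_test(x, x)
        assert np.isclose(p, 1.0)
        _, p2 = ta.welch_test(x, x + 100.0)
        assert p2 < 1e-6
        with pytest.raises(ValueError):
            ta.welch_test([1.0, 1.0], [2.0, 2.0])

    def test_welch_type_i_error_calibrated(self, rng):
        """Under the null (equal means) the Welch test rejects at ~5%
        over 10^4 replicates."""
        a = rng.normal(0, 1, (10000, 8))
        b = rng.normal(0, 2, (10000, 12))
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rate = np.mean(res.pvalue < 0.05)
        assert abs(rate - 0.05) < 0.01


class TestTrackModel:
    def test_fit_summarises_coupled_motion(self):
        res = ta.TrackModel(_track(duration=6.0)).fit()
        assert np.isclose(res.velocity, 0.5, rtol=0.02)
        assert np.isclose(res.pitch_ratio, 1.0, atol=0.03)
        assert res.direction == "cw"
        text = res.summary()
        assert "helix pitch" in text and "polarization pitch" in text
        d = res.to_dict()
        assert d["yaw_direction"] == "cw"
        assert d["helix_pitch_n"] == len(d["helix_cycles"])
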