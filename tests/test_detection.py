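"""Detection layer: stop rules, windowed majority rule, calibration, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemoinfer import (
    ConfigurationError,
    DetectionConfig,
    PatientParams,
    PopulationModel,
    RunResult,
    Trajectory,
    calibrate_thresholds,
    classify_run,
    find_stop_time,
    naive_hct_detector,
    windowed_detector,
)
from hemoinfer.detection import calibrate_all
from hemoinfer.evaluation import build_scenario_grid

P = PatientParams(vb0=5.0, alpha_u=0.5, alpha_h=2.0, k=0.1, sigma0=0.40)
CFG = DetectionConfig()


def _traj(x1, sigma):
    x1 = np.asarray(x1, dtype=float)
    n = len(x1)
    return Trajectory(
        times=np.arange(n, dtype=float), x1=x1, x2=np.zeros(n),
        vr=np.asarray(sigma) * (P.vb0 + x1), sigma=np.asarray(sigma, dtype=float),
        u=np.zeros(n), h=np.zeros(n), sigma0=0.40,
    )


class TestStopTime:
    def test_cap_when_no_rule_fires(self):
        traj = _traj(np.zeros(100), np.full(100, 0.4))
        assert find_stop_time(traj, P) == (99.0, "cap")

    def test_bv25(self):
        x1 = np.linspace(0.0, -1.30, 100)  # crosses -1.25 L near the end
        traj = _traj(x1, np.full(100, 0.4))
        t, reason = find_stop_time(traj, P)
        assert reason == "bv25"
        assert P.vb0 + np.interp(t, traj.times, traj.x1) < 0.75 * P.vb0

    def test_hct10_before_volume_rule(self):
        sigma = np.linspace(0.4, 0.05, 41)  # crosses 0.10 at t = 35
        traj = _traj(np.zeros(41), sigma)
        t, reason = find_stop_time(traj, P)
        assert (t, reason) == (35.0, "hct10")


class TestWindowedDetector:
    def test_hand_enumerated_majority(self):
        # condition true from t=20 at 1/min sampling: the trailing 10-min
        # window [t-10, t) first holds 6 true samples at t=26
        sig = np.zeros(60)
        sig[20:] = -1.0
        out = windowed_detector(sig, -0.5, "below", CFG)
        assert out.detect_idx == 26
        assert out.sustained_idx == 26
        assert out.sustained

    def test_never_true(self):
        out = windowed_detector(np.zeros(60), -0.5, "below", CFG)
        assert out.detect_idx is None and out.sustained_idx is None

    def test_always_true_declares_at_window(self):
        out = windowed_detector(-np.ones(60), -0.5, "below", CFG)
        assert out.detect_idx == 10

    def test_short_series_returns_none(self):
        assert windowed_detector(-np.ones(10), -0.5, "below", CFG).detect_idx is None

    def test_min_index_excludes_settling(self):
        out = windowed_detector(-np.ones(60), -0.5, "below", CFG, min_index=20)
        assert out.detect_idx == 20

    def test_transient_not_sustained(self):
        sig = np.zeros(80)
        sig[15:40] = -1.0  # long transient, recovers before the end
        out = windowed_detector(sig, -0.5, "below", CFG)
        assert out.detect_idx == 21
        assert out.sustained_idx is None
        assert not out.sustained

    def test_later_sustained_declaration(self):
        sig = np.zeros(100)
        sig[15:40] = -1.0
        sig[60:] = -1.0  # second episode holds to the end
        out = windowed_detector(sig, -0.5, "below", CFG)
        assert out.detect_idx == 21
        assert out.sustained_idx == 66
        assert not out.sustained

    def test_above_direction(self):
        sig = np.zeros(40)
        sig[12:] = 0.1
        out = windowed_detector(sig, 0.05, "above", CFG)
        assert out.detect_idx == 18

    def test_threshold_curve(self):
        sig = -0.1 * np.ones(60)
        curve = np.full(60, -0.5)
        curve[30:] = -0.05  # threshold loosens mid-series
        out = windowed_detector(sig, curve, "below", CFG)
        assert out.detect_idx == 36

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        shift=st.floats(0.0, 0.3),
        seed=st.integers(0, 2**16),
    )
    def test_raising_threshold_magnitude_only_delays(self, shift, seed):
        rng = np.random.default_rng(seed)
        sig = rng.normal(-0.1, 0.15, size=120)
        base = windowed_detector(sig, -0.1, "below", CFG).detect_idx
        stricter = windowed_detector(sig, -0.1 - shift, "below", CFG).detect_idx
        if base is None:
            assert stricter is None
        elif stricter is not None:
            assert stricter >= base


class TestNaiveDetector:
    def test_crossing(self):
        sm = np.full(60, 0.40)
        sm[30:] = 0.355
        out = naive_hct_detector(sm, 0.40, CFG)
        assert out.detect_idx == 30 and out.sustained_idx == 30

    def test_constant_baseline_never_triggers(self):
        assert naive_hct_detector(np.full(60, 0.40), 0.40, CFG).detect_idx is None

    def test_false_positive_by_construction(self, nominal):
        # noise-free resuscitation-only run that dilutes past the 10% drop:
        # the naive rule fires although there is no hemorrhage
        from hemoinfer import InputSignal, simulate

        traj = simulate(nominal, InputSignal.step(u=0.15, h=0.0), t_max=180.0)
        out = naive_hct_detector(traj.sigma, nominal.sigma0, CFG, min_index=11)
        assert out.detect_idx is not None


def _rr(detect, sustained_detect, stop=40.0):
    return RunResult(
        vp_id=0, scenario_id="s", detector="lo",
        detect_time=detect, detect_time_sustained=sustained_detect,
        sustained=detect is not None and detect == sustained_detect,
        stop_time=stop, stop_reason="bv25", t_limit=stop, nae=None,
    )


class TestClassifyRun:
    def test_detected_hemorrhage_is_tp(self):
        assert classify_run(_rr(12.0, 12.0), True, corrected=False) == "TP"

    def test_missed_hemorrhage_is_fn(self):
        assert classify_run(_rr(None, None), True, corrected=False) == "FN"

    def test_transient_detection_fails_corrected(self):
        r = _rr(12.0, None)
        assert classify_run(r, True, corrected=False) == "TP"
        assert classify_run(r, True, corrected=True) == "FN"

    def test_hemorrhage_free_classes(self):
        assert classify_run(_rr(12.0, None), False, corrected=False) == "FP"
        assert classify_run(_rr(12.0, None), False, corrected=True) == "TN"
        assert classify_run(_rr(None, None), False, corrected=False) == "TN"


class TestCalibration:
    def test_empty_grid_rejected(self, pop, lo_cfg, ekf_cfg):
        with pytest.raises(ConfigurationError):
            calibrate_all(pop, [], 2, 1, lo_cfg, ekf_cfg)

    def test_scalar_thresholds_are_curve_extremes(self, pop, lo_cfg, ekf_cfg,
                                                  short_settings):
        grid = build_scenario_grid(hem_rates=(0.03, 0.08), u_fracs=(0.5, 1.5),
                                   noise_levels=(0.01,))
        cal = calibrate_all(pop, grid, 2, 7, lo_cfg, ekf_cfg, short_settings)
        start = short_settings.settle_idx
        assert cal.x3_lo_threshold == pytest.approx(
            cal.per_noise[0.01]["lo"][start:].min()
        )
        assert cal.x3_ekf_threshold == pytest.approx(
            cal.per_noise[0.01]["ekf"][start:].max()
        )
        assert cal.x3_lo_threshold < 0 < cal.x3_ekf_threshold

    def test_estimator_selector(self, pop, lo_cfg, ekf_cfg, short_settings):
        grid = build_scenario_grid(hem_rates=(0.05,), u_fracs=(0.9,),
                                   noise_levels=(0.01,))
        lo_thr = calibrate_thresholds(pop, grid, "lo", 1, 3, lo_cfg, ekf_cfg,
                                      short_settings)
        ekf_thr = calibrate_thresholds(pop, grid, "ekf", 1, 3, lo_cfg, ekf_cfg,
                                       short_settings)
        assert lo_thr < 0 < ekf_thr
        with pytest.raises(ConfigurationError):
            calibrate_thresholds(pop, grid, "bogus", 1, 3, lo_cfg, ekf_cfg)

    def test_matched_noise_free_thresholds_are_tiny(self, nominal, lo_cfg,
                                                    short_settings):
        # zero spread, zero noise: the only signature left is the sampling bias
        from hemoinfer import EKFConfig

        pop0 = PopulationModel.from_cv(cv=0.0, sigma0_range=(0.40, 0.40))
        ekf0 = EKFConfig(params_nominal=nominal, q_theta=pop0.q_theta, q_v=0.0)
        grid = build_scenario_grid(hem_rates=(0.03, 0.1), u_fracs=(0.5, 1.9),
                                   noise_levels=(0.0,))
        cal = calibrate_all(pop0, grid, 1, 5, lo_cfg, ekf0, short_settings)
        assert abs(cal.x3_lo_threshold) < 2e-3
        assert abs(cal.x3_ekf_threshold) < 2e-3

    def test_roundtrip_json(self, pop, lo_cfg, ekf_cfg, short_settings):
        from hemoinfer.detection import CalibrationResult

        grid = build_scenario_grid(hem_rates=(0.05,), u_fracs=(0.9,),
                                   noise_levels=(0.01,))
        cal = calibrate_all(pop, grid, 1, 3, lo_cfg, ekf_cfg, short_settings)
        back = CalibrationResult.from_json(cal.to_json())
        assert back.x3_lo_threshold == cal.x3_lo_threshold
        np.testing.assert_allclose(back.per_noise[0.01]["lo"],
                                   cal.per_noise[0.01]["lo"])
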