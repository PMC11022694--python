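"""Calibration, the PI law, gain updates, and the closed loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromostat.controller import (
    CalibrationModel,
    ControllerConfig,
    ControllerState,
    SetpointSchedule,
    calibrate_from_buffers,
    fit_calibration,
    pi_update,
    read_gain_updates,
    run_closed_loop,
    voltage_to_pH,
)
from chromostat.errors import CalibrationError, ConfigError, ParameterError
from chromostat.io import write_log
from chromostat.plant import ElectrodeModel, wash_to_pH


class TestCalibration:
    def test_two_point_closed_form(self):
        """Line through (6, 2.157 V) and (7, 2.100 V): slope -0.057, icpt 2.499."""
        cal = fit_calibration([(2.157, 6.0), (2.100, 7.0)])
        assert cal.slope == pytest.approx(-0.057, abs=1e-12)
        assert cal.intercept == pytest.approx(2.499, abs=1e-12)

    def test_least_squares_matches_normal_equations(self, rng):
        ph = np.array([4.0, 5.5, 6.8, 7.9, 9.6])
        volts = -0.055 * ph + 2.48 + rng.normal(0, 0.003, ph.size)
        cal = fit_calibration(list(zip(volts, ph)))
        X = np.column_stack([ph, np.ones_like(ph)])
        beta = np.linalg.solve(X.T @ X, X.T @ volts)
        assert cal.slope == pytest.approx(beta[0], abs=1e-10)
        assert cal.intercept == pytest.approx(beta[1], abs=1e-10)

    def test_noise_free_electrode_recovered_exactly(self):
        e = ElectrodeModel(slope=-0.0603, intercept=2.41, noise_sd=0.0)
        cal = calibrate_from_buffers(e, buffer_phs=(4.0, 7.0, 10.0))
        assert cal.slope == pytest.approx(-0.0603, abs=1e-12)
        assert cal.intercept == pytest.approx(2.41, abs=1e-12)

    def test_too_few_or_degenerate_points(self):
        with pytest.raises(CalibrationError):
            fit_calibration([(2.1, 7.0)])
        with pytest.raises(CalibrationError):
            fit_calibration([(2.1, 7.0), (2.2, 7.0)])

    def test_voltage_to_ph_inverse(self):
        cal = CalibrationModel(slope=-0.057, intercept=2.5)
        assert voltage_to_pH(cal, 2.5) == 0.0
        e = ElectrodeModel(slope=-0.057, intercept=2.5, noise_sd=0.0)
        assert voltage_to_pH(cal, e.measure(6.43)) == pytest.approx(6.43, abs=1e-12)

    @given(
        slope=st.floats(-0.08, -0.03),
        intercept=st.floats(2.0, 3.0),
        ph=st.floats(3.0, 11.0),
    )
    def test_round_trip_property(self, slope, intercept, ph):
        cal = CalibrationModel(slope=slope, intercept=intercept)
        v = slope * ph + intercept
        assert voltage_to_pH(cal, v) == pytest.approx(ph, abs=1e-9)


class TestPIUpdate:
    CFG = ControllerConfig(kp=5.0, ki=0.1)

    def test_null_error_no_actuation(self):
        s = pi_update(self.CFG, ControllerState(), 7.0, 7.0)
        assert s.power_blue == 0.0 and s.power_red == 0.0

    def test_printed_gains_small_positive_error(self):
        """kp=5, e=+0.1, empty integral -> red at exactly 0.5."""
        s = pi_update(self.CFG, ControllerState(), 7.1, 7.0)
        assert s.power_red == pytest.approx(0.5, abs=1e-12)
        assert s.power_blue == 0.0

    def test_large_negative_error_clips_blue(self):
        s = pi_update(self.CFG, ControllerState(), 6.0, 7.0)
        assert s.power_blue == 1.0 and s.power_red == 0.0

    def test_antiwindup_freezes_integral_at_saturation(self):
        """Persistent e=+1 saturates red; the accumulator must not grow."""
        s = ControllerState()
        for _ in range(5):
            s = pi_update(self.CFG, s, 8.0, 7.0)
            assert s.power_red == 1.0
        assert s.integral == 0.0

    def test_without_antiwindup_integral_winds_up(self):
        cfg = ControllerConfig(kp=5.0, ki=0.1, antiwindup="off")
        s = ControllerState()
        for _ in range(5):
            s = pi_update(cfg, s, 8.0, 7.0)
        assert s.integral == pytest.approx(5.0)

    @given(st.lists(st.floats(-2.0, 2.0), min_size=1, max_size=50))
    def test_exclusivity_and_limits_property(self, errors):
        """At most one LED color is powered, and powers stay in [0, 1]."""
        s = ControllerState()
        for e in errors:
            s = pi_update(self.CFG, s, 7.0 + e, 7.0)
            assert 0.0 <= s.power_blue <= 1.0
            assert 0.0 <= s.power_red <= 1.0
            assert s.power_blue == 0.0 or s.power_red == 0.0


class TestGainUpdates:
    def test_parse_and_idempotence(self, tmp_path):
        f = tmp_path / "PIDparams.txt"
        f.write_text("kp=5\nki=0.1\n")
        assert read_gain_updates(f) == (5.0, 0.1)
        assert read_gain_updates(f, previous=(5.0, 0.1)) == (5.0, 0.1)

    def test_corrupted_file_keeps_previous_with_warning(self, tmp_path):
        f = tmp_path / "PIDparams.txt"
        f.write_text("kp=5\nki=oops\n")
        with pytest.warns(UserWarning):
            gains = read_gain_updates(f, previous=(4.0, 0.2))
        assert gains == (4.0, 0.2)

    def test_missing_file_at_startup_is_config_error(self, tmp_path):
        with pytest.raises(ConfigError):
            read_gain_updates(tmp_path / "nope.txt")


class TestSetpointSchedule:
    def test_lookup(self):
        sched = SetpointSchedule(((0.0, 6.0), (600.0, 6.5), (1200.0, 7.0)))
        assert sched.setpoint_at(0.0) == 6.0
        assert sched.setpoint_at(599.9) == 6.0
        assert sched.setpoint_at(600.0) == 6.5
        assert sched.setpoint_at(5000.0) == 7.0

    def test_invariants(self):
        with pytest.raises(ParameterError):
            SetpointSchedule(())
        with pytest.raises(ParameterError):
            SetpointSchedule(((0.0, 6.0), (0.0, 6.5)))
        with pytest.raises(ParameterError):
            SetpointSchedule(((0.0, 2.0),))

    def test_file_round_trip(self, tmp_path):
        sched = SetpointSchedule(((0.0, 5.9), (1800.0, 7.2)))
        back = SetpointSchedule.from_file(sched.to_file(tmp_path / "sched.txt"))
        assert back == sched


class TestClosedLoop:
    def _rig(self, default_cfg):
        model = default_cfg.build_plant()
        electrode = default_cfg.build_electrode(seed=11)
        cal = calibrate_from_buffers(default_cfg.build_electrode(seed=12))
        return model, electrode, cal, default_cfg.build_controller()

    def test_zero_gains_keep_leds_dark(self, default_cfg):
        model, electrode, cal, _ = self._rig(default_cfg)
        cfg = ControllerConfig(kp=0.0, ki=0.0)
        res = run_closed_loop(
            model, wash_to_pH(6.5), electrode, cal, cfg,
            SetpointSchedule(((0.0, 7.0),)), duration=60.0, seed=1,
        )
        assert all(r.intensity == 0.0 and r.color == "none" for r in res.log)
        assert res.final_state.ph_out == pytest.approx(6.5, abs=1e-9)

    def test_steady_state_error_with_integral_action(self, default_cfg):
        """A reachable setpoint is held within 0.02 pH over the dwell tail."""
        model, electrode, cal, cfg = self._rig(default_cfg)
        res = run_closed_loop(
            model, wash_to_pH(6.0), electrode, cal, cfg,
            SetpointSchedule(((0.0, 6.5),)), duration=600.0, seed=5,
        )
        tail = res.log[-120:]
        mae = np.mean([abs(r.ph - r.setpoint) for r in tail])
        assert mae < 0.02

    def test_saturation_during_large_step(self, default_cfg):
        """A big upward setpoint change drives red to the 1.0 ceiling."""
        model, electrode, cal, cfg = self._rig(default_cfg)
        res = run_closed_loop(
            model, wash_to_pH(6.0), electrode, cal, cfg,
            SetpointSchedule(((0.0, 6.0), (60.0, 7.0))), duration=300.0, seed=5,
        )
        reds = [r for r in res.log if r.time_s >= 60.0 and r.color == "red"]
        assert any(r.intensity == 1.0 for r in reds)

    def test_actuation_exclusivity_in_log(self, default_cfg):
        model, electrode, cal, cfg = self._rig(default_cfg)
        res = run_closed_loop(
            model, wash_to_pH(6.0), electrode, cal, cfg,
            SetpointSchedule(((0.0, 6.3),)), duration=120.0, seed=5,
        )
        tr = res.trajectory
        assert ((tr.power_blue > 0) & (tr.power_red > 0)).sum() == 0

    def test_byte_identical_logs_under_fixed_seed(self, default_cfg, tmp_path):
        model, _, cal, cfg = self._rig(default_cfg)
        paths = []
        for i in (1, 2):
            electrode = default_cfg.build_electrode(seed=11)
            res = run_closed_loop(
                model, wash_to_pH(6.0), electrode, cal, cfg,
                SetpointSchedule(((0.0, 6.4),)), duration=90.0, seed=77,
            )
            paths.append(write_log(res.log, tmp_path / f"log{i}.txt"))
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_live_gain_updates_reflected_in_log(self, default_cfg, tmp_path):
        model, electrode, cal, cfg = self._rig(default_cfg)
        gains = tmp_path / "PIDparams.txt"
        gains.write_text("kp=3\nki=0.05\n")
        res = run_closed_loop(
            model, wash_to_pH(6.0), electrode, cal, cfg,
            SetpointSchedule(((0.0, 6.2),)), duration=30.0, seed=5,
            gains_file=gains,
        )
        assert all(r.kp == 3.0 and r.ki == 0.05 for r in res.log)
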