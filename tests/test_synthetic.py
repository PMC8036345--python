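"""Synthetic stream generators: determinism and guaranteed structure."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import brute_force_window_counts
from quarmon.alerts import IndoorBounds, indoor_check
from quarmon.rsc import RscConfig, classify_stream
from quarmon.synthetic import (
    ActivitySchedule,
    Segment,
    TempModelParams,
    generate_accel,
    generate_indoor,
    generate_temperature,
)
from quarmon.temperature import lowpass_series


def simple_schedule(mode: str, duration: float = 60.0) -> ActivitySchedule:
    return ActivitySchedule.from_tuples([(0.0, duration, mode)])


class TestSchedule:
    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ActivitySchedule.from_tuples([(0, 30, "none"), (40, 60, "none")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ActivitySchedule(())

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            Segment(0, 10, "jogging")

    def test_mode_lookup_and_intervals(self):
        sch = ActivitySchedule.from_tuples(
            [(0, 60, "none"), (60, 120, "exercise"), (120, 180, "normal")]
        )
        assert sch.mode_at(59.9) == "none"
        assert sch.mode_at(60.0) == "exercise"
        assert sch.exercise_intervals() == [(60.0, 120.0)]


class TestAccel:
    def test_no_motion_deltas_below_threshold(self, rsc_cfg):
        samples = generate_accel(simple_schedule("none"), rsc_cfg, seed=0)
        az = np.array([s.az for s in samples])
        assert (np.abs(np.diff(az)) * 1000.0 < rsc_cfg.dz_th_mg).all()

    def test_normal_activity_never_classifies_as_exercise(self, rsc_cfg):
        samples = generate_accel(simple_schedule("normal", 600.0), rsc_cfg, seed=1)
        decisions = classify_stream(samples, rsc_cfg)
        assert decisions and all(not d.exercise for d in decisions)

    def test_exercise_windows_reach_count_threshold(self, rsc_cfg):
        """Every complete exercise window counts >= 24 spikes (direct oracle)."""
        samples = generate_accel(simple_schedule("exercise", 120.0), rsc_cfg, seed=2)
        filtered = [
            type(s)(s.t, y)
            for s, y in zip(samples, lowpass_series([s.az for s in samples]))
        ]
        oracle = brute_force_window_counts(filtered, rsc_cfg)
        assert oracle and all(count >= rsc_cfg.count_th for count, _ in oracle)
        decisions = classify_stream(samples, rsc_cfg)
        assert all(d.exercise for d in decisions)

    def test_seed_determinism(self, rsc_cfg):
        a = generate_accel(simple_schedule("normal", 120.0), rsc_cfg, seed=9)
        b = generate_accel(simple_schedule("normal", 120.0), rsc_cfg, seed=9)
        assert a == b

    def test_within_device_range(self, rsc_cfg):
        samples = generate_accel(simple_schedule("exercise", 60.0), rsc_cfg, seed=3)
        assert all(abs(s.az) <= 2.0 for s in samples)


class TestTemperature:
    def test_noiseless_rest_is_constant_baseline(self):
        params = TempModelParams(noise_sd_c=0.0)
        samples = generate_temperature(simple_schedule("none", 600.0), params)
        assert all(s.value == pytest.approx(36.5, abs=1e-9) for s in samples)

    def test_exercise_plateau_stays_below_elevated_threshold(self):
        """A long noiseless bout saturates at 37.0 and never reaches 37.5."""
        params = TempModelParams(noise_sd_c=0.0, exercise_rise_c=0.5)
        sch = ActivitySchedule.from_tuples([(0, 4 * 3600.0, "exercise")])
        values = [s.value for s in generate_temperature(sch, params)]
        assert max(values) < 37.5
        assert values[-1] == pytest.approx(37.0, abs=0.01)

    def test_fever_ramp_crosses_once_and_holds(self):
        params = TempModelParams(noise_sd_c=0.0, fever_target_c=38.0)
        values = [
            s.value
            for s in generate_temperature(simple_schedule("none", 3600.0), params)
        ]
        above = [v >= 37.0 for v in values]
        first = above.index(True)
        assert all(above[first:])

    def test_post_exercise_relaxation_toward_baseline(self):
        params = TempModelParams(noise_sd_c=0.0, relax_tau_s=1200.0)
        sch = ActivitySchedule.from_tuples(
            [(0, 2100.0, "exercise"), (2100.0, 2100.0 + 4 * 3600.0, "none")]
        )
        samples = generate_temperature(sch, params)
        peak = max(s.value for s in samples if s.t <= 2100.0)
        assert peak > 36.6
        assert samples[-1].value == pytest.approx(36.5, abs=0.01)

    def test_noise_std_calibrated(self):
        """Baseline sample std within +-25 % of the configured noise level."""
        params = TempModelParams(noise_sd_c=0.2)
        samples = generate_temperature(
            simple_schedule("none", 3000.0), params, seed=4
        )
        assert len(samples) >= 500
        sd = float(np.std([s.value for s in samples]))
        assert 0.15 <= sd <= 0.25

    def test_seed_determinism(self):
        sch = simple_schedule("none", 600.0)
        assert generate_temperature(sch, seed=5) == generate_temperature(sch, seed=5)


class TestIndoor:
    def test_steady_room_flags(self):
        """A 23.5 C / 18 % room reads temp-ok but humidity-low throughout."""
        samples = generate_indoor(600.0, temp_c=23.5, rh_pct=18.0, seed=0)
        statuses = [indoor_check(s) for s in samples]
        assert all(st.temp == "ok" and st.rh == "low" for st in statuses)

    def test_in_range_room(self):
        samples = generate_indoor(600.0, temp_c=22.0, rh_pct=40.0, seed=1)
        assert all(indoor_check(s).in_range for s in samples)

    def test_rh_drift_transitions_low_ok_high(self):
        samples = generate_indoor(
            3600.0, temp_c=22.0, rh_pct=15.0, rh_drift_pct=50.0,
            noise_sd_rh_pct=0.0, seed=2,
        )
        states = [indoor_check(s).rh for s in samples]
        # pointwise oracle: strip repeats, expect the ordered progression
        collapsed = [states[0]] + [
            b for a, b in zip(states, states[1:]) if b != a
        ]
        assert collapsed == ["low", "ok", "high"]

    def test_seed_determinism(self):
        assert generate_indoor(300.0, seed=7) == generate_indoor(300.0, seed=7)
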