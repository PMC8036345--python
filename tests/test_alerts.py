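"""Adaptive threshold, dwell alert state machine, indoor checker."""

from __future__ import annotations

import pytest

from quarmon.alerts import (
    AlertConfig,
    AlertState,
    IndoorBounds,
    IndoorSample,
    MonitorEvent,
    ThresholdConfig,
    ThresholdState,
    alert_step,
    indoor_check,
    threshold_step,
)
from quarmon.rsc import WindowDecision


def run_threshold(decisions, eval_times, cfg=None):
    """Drive the threshold manager; returns {eval time: applied T_TH}."""
    cfg = cfg or ThresholdConfig()
    state = ThresholdState()
    merged = sorted(
        [(d.window_end, "d", d) for d in decisions]
        + [(t, "e", None) for t in eval_times]
    )
    out = {}
    for t, tag, d in merged:
        state, t_th = threshold_step(state, d, t, cfg)
        if tag == "e":
            out[t] = t_th
    return out


def run_alert(samples, t_th=37.0, cfg=None):
    """Drive the alert machine over (t, t_body) pairs; returns all events."""
    cfg = cfg or AlertConfig()
    state = AlertState()
    events = []
    for t, body in samples:
        th = t_th(t) if callable(t_th) else t_th
        state, ev = alert_step(state, body, th, t, cfg)
        events.extend(ev)
    return events


class TestThreshold:
    def test_elevated_while_exercising(self):
        state = ThresholdState()
        state, t_th = threshold_step(
            state, WindowDecision(60.0, 50, True), 60.0, ThresholdConfig()
        )
        assert t_th == 37.5

    def test_normal_after_hold_expires(self):
        """25 min after the bout the threshold is back to 37.0."""
        out = run_threshold(
            [WindowDecision(600.0, 50, True), WindowDecision(630.0, 0, False)],
            [600.0 + 25 * 60.0],
        )
        assert out[600.0 + 25 * 60.0] == 37.0

    def test_elevated_inside_hold(self):
        out = run_threshold(
            [WindowDecision(600.0, 50, True), WindowDecision(630.0, 0, False)],
            [600.0 + 10 * 60.0],
        )
        assert out[600.0 + 10 * 60.0] == 37.5

    def test_reversion_at_exact_hold_boundary(self):
        """Reversion happens at the first evaluation >= 20 min after the bout."""
        te = 600.0
        out = run_threshold(
            [WindowDecision(te, 50, True), WindowDecision(te + 30, 0, False)],
            [te + 1200.0 - 5.0, te + 1200.0, te + 1200.0 + 5.0],
        )
        assert out[te + 1195.0] == 37.5
        assert out[te + 1200.0] == 37.0
        assert out[te + 1205.0] == 37.0

    def test_new_bout_restarts_hold(self):
        decisions = [
            WindowDecision(600.0, 50, True),
            WindowDecision(630.0, 0, False),
            WindowDecision(1500.0, 50, True),  # second bout inside first hold
            WindowDecision(1530.0, 0, False),
        ]
        out = run_threshold(decisions, [600.0 + 1200.0, 1500.0 + 1199.0, 1500.0 + 1200.0])
        assert out[1800.0] == 37.5  # still held by the second bout
        assert out[2699.0] == 37.5
        assert out[2700.0] == 37.0

    def test_threshold_never_intermediate(self):
        cfg = ThresholdConfig()
        decisions = [
            WindowDecision(30.0 * k, 30 if k % 3 == 0 else 0, k % 3 == 0)
            for k in range(1, 40)
        ]
        out = run_threshold(decisions, [7.0 * k for k in range(170)], cfg)
        assert set(out.values()) <= {cfg.t_normal, cfg.t_exercise}


class TestAlert:
    def test_alert_fires_after_12_min_continuous(self):
        events = run_alert([(5.0 * k, 37.2) for k in range(300)])
        raised = [e for e in events if e.kind == "alert_raised"]
        assert len(raised) == 1
        assert raised[0].t == 12 * 60.0  # first sample at t=0 starts the dwell
        kinds = [e.kind for e in events]
        assert "request_infrared_confirmation" in kinds

    def test_sub_threshold_sample_restarts_timer(self):
        """6 min over, one dip, then over again: nothing before +18 min."""
        samples = [(5.0 * k, 37.2) for k in range(72)]  # 0..355 s
        samples.append((360.0, 36.8))
        samples += [(365.0 + 5.0 * k, 37.2) for k in range(400)]
        events = run_alert(samples)
        raised = [e for e in events if e.kind == "alert_raised"]
        assert len(raised) == 1
        assert raised[0].t >= 18 * 60.0
        assert raised[0].t == 365.0 + 720.0

    def test_no_exceedance_no_events(self):
        events = run_alert([(5.0 * k, 36.6) for k in range(300)])
        assert events == []

    def test_alert_cleared_on_drop(self):
        samples = [(5.0 * k, 37.2) for k in range(200)] + [(1000.0, 36.5)]
        events = run_alert(samples)
        kinds = [e.kind for e in events]
        assert kinds == ["alert_raised", "request_infrared_confirmation", "alert_cleared"]

    def test_raised_once_per_episode(self):
        samples = [(5.0 * k, 37.2) for k in range(400)]
        events = run_alert(samples)
        assert sum(e.kind == "alert_raised" for e in events) == 1

    @pytest.mark.parametrize("offset", [0.0, 1.7, 4.9])
    def test_dwell_exactness(self, offset):
        """Alert latency after a step lies in [dwell, dwell + sampling interval]."""
        dt, dwell = 5.0, 720.0
        step_t = 100.0 + offset

        def body(t):
            return 37.2 if t >= step_t else 36.5

        samples = [(dt * k, body(dt * k)) for k in range(400)]
        events = run_alert(samples)
        raised = [e for e in events if e.kind == "alert_raised"][0]
        assert dwell <= raised.t - step_t <= dwell + dt

    def test_threshold_rise_mid_dwell_clears_timer(self):
        """An exercise-elevated threshold above T_body excuses the exceedance."""

        def t_th(t):
            return 37.5 if 300.0 <= t < 600.0 else 37.0

        samples = [(5.0 * k, 37.2) for k in range(400)]
        events = run_alert(samples, t_th=t_th)
        raised = [e for e in events if e.kind == "alert_raised"]
        # timer restarts at 600 s when the threshold drops back
        assert raised[0].t == 600.0 + 720.0

    def test_monotone_under_threshold_lowering(self):
        """Lowering T_TH or the dwell can only make the alert fire earlier."""
        samples = [(5.0 * k, 36.9 + 0.0005 * 5.0 * k) for k in range(600)]

        def first_alert(t_th, dwell_min):
            events = run_alert(samples, t_th=t_th, cfg=AlertConfig(dwell_min=dwell_min))
            raised = [e for e in events if e.kind == "alert_raised"]
            return raised[0].t if raised else float("inf")

        assert first_alert(36.95, 12.0) <= first_alert(37.0, 12.0)
        assert first_alert(37.0, 6.0) <= first_alert(37.0, 12.0)


class TestIndoor:
    @pytest.mark.parametrize(
        "temp, rh, expected",
        [
            (23.5, 18.0, ("ok", "low")),   # observed morning room reading
            (22.0, 40.0, ("ok", "ok")),
            (25.0, 40.0, ("high", "ok")),  # observed afternoon reading
            (19.9, 40.0, ("low", "ok")),
            (22.0, 61.0, ("ok", "high")),
        ],
    )
    def test_classification(self, temp, rh, expected):
        status = indoor_check(IndoorSample(0.0, temp, rh))
        assert (status.temp, status.rh) == expected

    @pytest.mark.parametrize(
        "temp, rh",
        [(20.0, 20.0), (24.0, 60.0), (20.0, 60.0), (24.0, 20.0)],
    )
    def test_bounds_inclusive(self, temp, rh):
        status = indoor_check(IndoorSample(0.0, temp, rh))
        assert status.in_range

    def test_rh_out_of_physical_range_rejected(self):
        with pytest.raises(ValueError, match="humidity"):
            indoor_check(IndoorSample(0.0, 22.0, 120.0))
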