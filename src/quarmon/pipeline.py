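"""Streaming orchestrator: merge the three sensor streams and run the monitor.

Processing chain per session::

    accel (20 Hz) --low-pass--> spike counter --window verdicts--+
                                                                 v
    contact temp --low-pass--> +bias calibration --> adaptive threshold
    infrared temp -------------(bypasses both)----> + dwell alert machine
    indoor (0.2 Hz) --> range check --> out-of-range events

Streams run at independent rates; they are fused sample-and-hold (last
observation carried forward) onto a telemetry tick every
``telemetry_period_s`` seconds, mirroring a device that displays and
uploads the latest value of each sensor. Time is relative seconds
within one session; sessions are processed independently with no
cross-session state. The whole pipeline is deterministic given its
inputs and configuration.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .alerts import (
    AlertConfig,
    AlertState,
    IndoorBounds,
    IndoorSample,
    IndoorStatus,
    MonitorEvent,
    ThresholdConfig,
    ThresholdState,
    alert_step,
    indoor_check,
    threshold_step,
)
from .rsc import AccelSample, RscConfig, RscState, WindowDecision, rsc_flush, rsc_step
from .temperature import CalibrationModel, LowPassFilter, TempSample, calibrate_apply

__all__ = [
    "MonitorConfig",
    "TelemetryRecord",
    "SessionSummary",
    "MonitorResult",
    "make_telemetry",
    "summarize_session",
    "run_monitor",
]


@dataclass(frozen=True)
class MonitorConfig:
    """Complete configuration of one monitoring session."""

    rsc: RscConfig = field(default_factory=RscConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    alert: AlertConfig = field(default_factory=AlertConfig)
    indoor: IndoorBounds = field(default_factory=IndoorBounds)
    accel_beta: float = 0.5
    temp_beta: float = 0.5
    calibration: CalibrationModel | None = None
    telemetry_period_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accel_beta", "temp_beta"):
            b = getattr(self, name)
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {b!r}")
        if self.telemetry_period_s <= 0:
            raise ValueError("telemetry_period_s must be > 0")


@dataclass(frozen=True)
class TelemetryRecord:
    """One cloud-payload snapshot; booleans are encoded as 0/1 integers."""

    t: float
    alert: int
    t_body: float
    t_indoor: float
    rh: float
    exercise: int

    def to_payload(self) -> dict[str, float | int]:
        """Flat key-value mapping, suitable for an MQTT-style JSON payload."""
        return {
            "t_s": self.t,
            "alert": self.alert,
            "t_body_c": self.t_body,
            "t_indoor_c": self.t_indoor,
            "rh_pct": self.rh,
            "exercise": self.exercise,
        }


@dataclass(frozen=True)
class SessionSummary:
    """Session statistics of the body temperature (population std)."""

    n: int
    t_body_min: float
    t_body_max: float
    t_body_mean: float
    t_body_std: float


@dataclass(frozen=True)
class MonitorResult:
    """Everything one session produces.

    ``events`` and ``telemetry`` are time-ordered; ``summary`` is
    recomputable from the telemetry. ``decisions`` (per-window exercise
    verdicts) and ``threshold_trace`` (the T_TH applied at each
    body-temperature evaluation) are retained for reporting and
    analysis.
    """

    events: tuple[MonitorEvent, ...]
    telemetry: tuple[TelemetryRecord, ...]
    summary: SessionSummary
    decisions: tuple[WindowDecision, ...] = ()
    threshold_trace: tuple[tuple[float, float], ...] = ()


def make_telemetry(
    t: float,
    *,
    alert_active: bool,
    t_body: float,
    t_indoor: float,
    rh: float,
    exercising: bool,
) -> TelemetryRecord:
    """Snapshot the current monitor state into one telemetry record."""
    return TelemetryRecord(
        t=float(t),
        alert=int(bool(alert_active)),
        t_body=float(t_body),
        t_indoor=float(t_indoor),
        rh=float(rh),
        exercise=int(bool(exercising)),
    )


def summarize_session(telemetry: Sequence[TelemetryRecord]) -> SessionSummary:
    """Min/max/mean/population-std of T_body over a session's telemetry."""
    if not telemetry:
        raise ValueError("cannot summarize an empty session")
    values = np.array([rec.t_body for rec in telemetry], dtype=float)
    return SessionSummary(
        n=len(telemetry),
        t_body_min=float(values.min()),
        t_body_max=float(values.max()),
        t_body_mean=float(values.mean()),
        t_body_std=float(values.std()),  # population (ddof=0)
    )


# merge priorities: sensor samples first, telemetry tick last at equal times
_P_ACCEL, _P_TEMP, _P_INDOOR, _P_TICK = 0, 1, 2, 3


def run_monitor(
    accel_stream: Sequence[AccelSample],
    temp_stream: Sequence[TempSample],
    indoor_stream: Sequence[IndoorSample],
    cfg: MonitorConfig | None = None,
) -> MonitorResult:
    """Run one full monitoring session over three time-ordered streams.

    The temperature stream must be non-empty. An empty acceleration
    stream is allowed: the session then runs with exercise permanently
    0 and the normal threshold throughout. Telemetry is emitted at every
    multiple of ``telemetry_period_s`` from the first tick at or after
    the first temperature sample, using the latest value of each stream.
    """
    cfg = cfg or MonitorConfig()
    if not temp_stream:
        raise ValueError("temperature stream is empty: nothing to monitor")

    end_t = max(
        s[-1].t for s in (accel_stream, temp_stream, indoor_stream) if s
    )
    period = cfg.telemetry_period_s
    n_ticks = int(math.floor(end_t / period + 1e-9)) + 1
    ticks = [k * period for k in range(n_ticks)]

    queue = heapq.merge(
        ((s.t, _P_ACCEL, i, s) for i, s in enumerate(accel_stream)),
        ((s.t, _P_TEMP, i, s) for i, s in enumerate(temp_stream)),
        ((s.t, _P_INDOOR, i, s) for i, s in enumerate(indoor_stream)),
        ((t, _P_TICK, i, None) for i, t in enumerate(ticks)),
    )

    accel_filter = LowPassFilter(cfg.accel_beta)
    temp_filter = LowPassFilter(cfg.temp_beta)
    rsc_state = RscState()
    thr_state = ThresholdState()
    alert_state = AlertState()

    events: list[MonitorEvent] = []
    telemetry: list[TelemetryRecord] = []
    decisions: list[WindowDecision] = []
    threshold_trace: list[tuple[float, float]] = []

    t_body: float | None = None
    t_indoor = math.nan
    rh = math.nan
    exercising = False
    last_indoor_status: IndoorStatus | None = None
    prev_temp_t: float | None = None
    prev_indoor_t: float | None = None

    def apply_decision(decision: WindowDecision) -> None:
        nonlocal thr_state, exercising
        thr_state, _ = threshold_step(
            thr_state, decision, decision.window_end, cfg.thresholds
        )
        decisions.append(decision)
        if decision.exercise and not exercising:
            events.append(
                MonitorEvent(
                    t=decision.window_end,
                    kind="exercise_start",
                    detail={"count": decision.count},
                )
            )
        elif not decision.exercise and exercising:
            events.append(
                MonitorEvent(
                    t=decision.window_end,
                    kind="exercise_end",
                    detail={"count": decision.count},
                )
            )
        exercising = decision.exercise

    for t, prio, _i, sample in queue:
        if prio == _P_ACCEL:
            filtered = accel_filter.step(sample.az)
            rsc_state, decision = rsc_step(
                rsc_state, AccelSample(sample.t, filtered), cfg.rsc
            )
            if decision is not None:
                apply_decision(decision)
        elif prio == _P_TEMP:
            if prev_temp_t is not None and sample.t <= prev_temp_t:
                raise ValueError(
                    f"out-of-order temperature sample at t={sample.t}"
                )
            prev_temp_t = sample.t
            if sample.source == "infrared":
                # single-shot confirmation: no filtering, no calibration
                t_body = float(sample.value)
            else:
                y = temp_filter.step(sample.value)
                if cfg.calibration is not None:
                    y = calibrate_apply(cfg.calibration, y)
                t_body = y
            thr_state, t_th = threshold_step(thr_state, None, t, cfg.thresholds)
            threshold_trace.append((t, t_th))
            alert_state, new_events = alert_step(
                alert_state, t_body, t_th, t, cfg.alert
            )
            events.extend(new_events)
        elif prio == _P_INDOOR:
            if prev_indoor_t is not None and sample.t <= prev_indoor_t:
                raise ValueError(f"out-of-order indoor sample at t={sample.t}")
            prev_indoor_t = sample.t
            t_indoor, rh = sample.temp, sample.rh
            status = indoor_check(sample, cfg.indoor)
            if status != last_indoor_status and not status.in_range:
                events.append(
                    MonitorEvent(
                        t=t,
                        kind="indoor_out_of_range",
                        detail={
                            "temp_c": sample.temp,
                            "rh_pct": sample.rh,
                            "temp_status": status.temp,
                            "rh_status": status.rh,
                        },
                    )
                )
            last_indoor_status = status
        else:  # telemetry tick
            if t_body is None:
                continue  # no temperature seen yet
            telemetry.append(
                make_telemetry(
                    t,
                    alert_active=alert_state.active,
                    t_body=t_body,
                    t_indoor=t_indoor,
                    rh=rh,
                    exercising=exercising,
                )
            )

    tail = rsc_flush(rsc_state, cfg.rsc)
    if tail is not None:
        apply_decision(tail)
    # the tail window's events carry the window-end timestamp, which can
    # precede later temperature events; stable sort restores time order
    events.sort(key=lambda e: e.t)

    summary = summarize_session(telemetry) if telemetry else SessionSummary(
        0, math.nan, math.nan, math.nan, math.nan
    )
    return MonitorResult(
        events=tuple(events),
        telemetry=tuple(telemetry),
        summary=summary,
        decisions=tuple(decisions),
        threshold_trace=tuple(threshold_trace),
    )
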