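"""Adaptive fever threshold, dwell-time alerting, and indoor-condition checks.

Three coupled pieces of decision logic sit downstream of the sensor
processing:

* **Threshold manager** — the body-temperature alert threshold T_TH
  switches between a normal-activity value (37.0 °C) and an elevated
  exercise value (37.5 °C). It is elevated while the spike counter
  reports exercise and for a *hold* period (20 min) after the last
  exercise window, because body temperature typically needs that long
  to return to baseline after training.
* **Alert state machine** — an alert fires only when T_body >= T_TH
  *continuously* for a *dwell* period (12 min). Any sample below the
  current threshold resets the timer. Raising an alert also requests an
  infrared spot-measurement to confirm the contact reading.
* **Indoor checker** — classifies room temperature against 20-24 °C and
  relative humidity against 20-60 % (bounds inclusive), the ranges
  recommended for limiting airborne virus spread indoors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "ThresholdConfig",
    "ThresholdState",
    "threshold_step",
    "AlertConfig",
    "AlertState",
    "alert_step",
    "IndoorBounds",
    "IndoorSample",
    "IndoorStatus",
    "indoor_check",
    "MonitorEvent",
    "EVENT_KINDS",
]

#: Event vocabulary of the monitor's JSONL log.
EVENT_KINDS = (
    "exercise_start",
    "exercise_end",
    "alert_raised",
    "alert_cleared",
    "request_infrared_confirmation",
    "indoor_out_of_range",
)


@dataclass(frozen=True)
class MonitorEvent:
    """One structured event: time (s), kind, free-form detail mapping."""

    t: float
    kind: str
    detail: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")


# --------------------------------------------------------------------------
# Activity-adaptive threshold
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold values (°C) and the post-exercise hold time (minutes)."""

    t_normal: float = 37.0
    t_exercise: float = 37.5
    hold_min: float = 20.0

    def __post_init__(self) -> None:
        if self.t_exercise < self.t_normal:
            raise ValueError("t_exercise must be >= t_normal")
        if self.hold_min < 0:
            raise ValueError("hold_min must be >= 0")


@dataclass
class ThresholdState:
    """Whether exercise is ongoing, and when the last exercise window ended."""

    exercising: bool = False
    last_exercise_end: float | None = None


def threshold_step(
    state: ThresholdState,
    decision: "Any | None",
    now: float,
    cfg: ThresholdConfig,
) -> tuple[ThresholdState, float]:
    """Update activity state from a window verdict and return the current T_TH.

    ``decision`` is a window verdict from the spike counter (or ``None``
    when no window closed at this evaluation). The elevated threshold
    applies while exercising and until ``hold_min`` minutes have elapsed
    since the end of the last exercise window; every new exercise window
    restarts the hold. Reversion happens at the first evaluation at or
    past the hold boundary. The threshold is always exactly ``t_normal``
    or ``t_exercise``.
    """
    if decision is not None:
        if decision.exercise:
            state.exercising = True
            state.last_exercise_end = decision.window_end
        else:
            state.exercising = False
    elevated = state.exercising or (
        state.last_exercise_end is not None
        and now - state.last_exercise_end < cfg.hold_min * 60.0
    )
    return state, cfg.t_exercise if elevated else cfg.t_normal


# --------------------------------------------------------------------------
# Dwell-time alert state machine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AlertConfig:
    """Continuous-exceedance dwell required before an alert fires, minutes."""

    dwell_min: float = 12.0

    def __post_init__(self) -> None:
        if self.dwell_min <= 0:
            raise ValueError("dwell_min must be > 0")


@dataclass
class AlertState:
    """Dwell-timer start (``None`` when below threshold) and active flag."""

    exceed_since: float | None = None
    active: bool = False


def alert_step(
    state: AlertState,
    t_body: float,
    t_th: float,
    now: float,
    cfg: AlertConfig,
) -> tuple[AlertState, list[MonitorEvent]]:
    """Feed one body-temperature evaluation; emit alert events on edges.

    Exceedance is judged against the *current* threshold at every
    sample, so an exercise-elevated threshold that moves above T_body
    clears the dwell timer — an exercise-induced rise is excused.
    ``alert_raised`` is edge-triggered (once per episode) and is
    accompanied by ``request_infrared_confirmation``; a below-threshold
    sample while active emits ``alert_cleared``.
    """
    if not math.isfinite(t_body):
        raise ValueError(f"non-finite body temperature at t={now}: {t_body!r}")
    events: list[MonitorEvent] = []
    if t_body >= t_th:
        if state.exceed_since is None:
            state.exceed_since = now
        if not state.active and now - state.exceed_since >= cfg.dwell_min * 60.0:
            state.active = True
            events.append(
                MonitorEvent(
                    t=now,
                    kind="alert_raised",
                    detail={
                        "t_body_c": t_body,
                        "t_th_c": t_th,
                        "exceed_since_s": state.exceed_since,
                    },
                )
            )
            events.append(
                MonitorEvent(
                    t=now,
                    kind="request_infrared_confirmation",
                    detail={"t_body_c": t_body},
                )
            )
    else:
        if state.active:
            events.append(
                MonitorEvent(
                    t=now,
                    kind="alert_cleared",
                    detail={"t_body_c": t_body, "t_th_c": t_th},
                )
            )
        state.active = False
        state.exceed_since = None
    return state, events


# --------------------------------------------------------------------------
# Indoor condition
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IndoorSample:
    """Room reading: time (s), temperature (°C), relative humidity (%)."""

    t: float
    temp: float
    rh: float


@dataclass(frozen=True)
class IndoorBounds:
    """Recommended indoor ranges; both bounds inclusive on each dimension."""

    temp_lo: float = 20.0
    temp_hi: float = 24.0
    rh_lo: float = 20.0
    rh_hi: float = 60.0

    def __post_init__(self) -> None:
        if self.temp_lo > self.temp_hi or self.rh_lo > self.rh_hi:
            raise ValueError("lower bounds must not exceed upper bounds")


@dataclass(frozen=True)
class IndoorStatus:
    """Per-dimension classification: 'low', 'ok' or 'high'."""

    temp: str
    rh: str

    @property
    def in_range(self) -> bool:
        return self.temp == "ok" and self.rh == "ok"


def _classify(value: float, lo: float, hi: float) -> str:
    if value < lo:
        return "low"
    if value > hi:
        return "high"
    return "ok"


def indoor_check(sample: IndoorSample, bounds: IndoorBounds | None = None) -> IndoorStatus:
    """Classify one room reading against the recommended ranges."""
    bounds = bounds or IndoorBounds()
    if not (0.0 <= sample.rh <= 100.0):
        raise ValueError(
            f"relative humidity out of physical range [0, 100]: {sample.rh!r}"
        )
    if not (math.isfinite(sample.temp) and math.isfinite(sample.rh)):
        raise ValueError(f"non-finite indoor sample at t={sample.t}")
    return IndoorStatus(
        temp=_classify(sample.temp, bounds.temp_lo, bounds.temp_hi),
        rh=_classify(sample.rh, bounds.rh_lo, bounds.rh_hi),
    )
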