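"""Published reference measurements from the 14-day quarantine case study.

These are the printed values from the monitoring study the package
re-implements; they serve as replay inputs and expected outcomes for
end-to-end checks. All temperatures are degrees Celsius.
"""

from __future__ import annotations

__all__ = [
    "DAILY_AVG_TBODY_C",
    "DAILY_ALERTS",
    "INFRARED_SPOT_CHECKS_C",
    "ROOM_AVERAGES",
]

#: Average body temperature of the last wearable session of each of the
#: 14 quarantine days (day 1 .. day 14), contact thermometer.
DAILY_AVG_TBODY_C: tuple[float, ...] = (
    36.82, 36.70, 36.70, 36.45, 36.70, 36.58, 36.33,
    36.70, 36.78, 36.33, 36.69, 36.45, 36.58, 36.33,
)

#: Alert flag reported for each of those days (all zero: no fever).
DAILY_ALERTS: tuple[int, ...] = (0,) * 14

#: Infrared spot measurements taken on the last quarantine day.
INFRARED_SPOT_CHECKS_C: tuple[float, ...] = (36.51, 36.49, 36.70, 36.68)

#: Session-averaged room condition on the last quarantine day:
#: {period: (indoor temperature C, relative humidity %)}.
ROOM_AVERAGES: dict[str, tuple[float, float]] = {
    "morning": (23.5, 18.0),
    "afternoon": (25.0, 15.0),
    "night": (24.0, 16.5),
}
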