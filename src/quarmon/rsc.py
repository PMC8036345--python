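"""Repetition Spikes Counter (RSC): exercise recognition from Z-axis acceleration.

The idea: physical exercise produces large, repetitive jumps in the
vertical (Z) acceleration of a wrist-worn accelerometer, while ordinary
indoor activity produces only sparse, small jumps and rest produces
essentially none. The detector therefore

1. low-pass filters the 20 Hz Z-axis stream,
2. takes the absolute difference of consecutive samples (|dZ|, in
   milli-g),
3. flags a *spike* whenever |dZ| >= dz_th_mg (default 90 mg),
4. counts spikes over tumbling (non-overlapping) windows of
   ``window_s`` seconds (default 30 s), and
5. declares *exercise* for a window when the count reaches
   ``count_th`` (default 24).

Both comparisons use >= so the published constants themselves are the
decision boundaries. The first ``warmup_s`` seconds of a stream are
discarded as sensor start-up; windows are anchored at the end of the
warm-up. A delta whose two samples straddle a window boundary is
credited to the window containing the later sample. A gap longer than
two sampling intervals resets the previous-sample memory so that a data
dropout cannot fabricate a spike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .temperature import LowPassFilter

__all__ = [
    "AccelSample",
    "RscConfig",
    "RscState",
    "WindowDecision",
    "abs_delta_mg",
    "is_spike",
    "rsc_step",
    "rsc_flush",
    "classify_stream",
]

#: Default smoothing coefficient for the acceleration pre-filter.
DEFAULT_ACCEL_BETA = 0.5

#: Stated accelerometer full-scale range, g.
ACCEL_RANGE_G = 2.0


@dataclass(frozen=True)
class AccelSample:
    """One Z-axis acceleration reading: time in seconds, value in g."""

    t: float
    az: float


@dataclass(frozen=True)
class RscConfig:
    """Tunable thresholds of the spike counter.

    window_s
        Tumbling analysis window length, seconds.
    dz_th_mg
        Minimum |consecutive-sample difference|, in milli-g, counted as
        a spike. 90 mg separates deliberate training motion from
        ordinary activity on a wrist-worn device.
    count_th
        Spikes per window at or above which the window is classified as
        exercise.
    warmup_s
        Start-up interval discarded before counting begins.
    fs_hz
        Nominal sampling rate of the acceleration stream.
    """

    window_s: float = 30.0
    dz_th_mg: float = 90.0
    count_th: int = 24
    warmup_s: float = 30.0
    fs_hz: float = 20.0

    def __post_init__(self) -> None:
        for name in ("window_s", "dz_th_mg", "count_th", "fs_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.warmup_s < 0:
            raise ValueError("warmup_s must be non-negative")
        n = self.window_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window_s * fs_hz must be a whole number of samples, got {n}"
            )


@dataclass(frozen=True)
class WindowDecision:
    """Verdict for one completed window: spike count and exercise flag."""

    window_end: float
    count: int
    exercise: bool


@dataclass
class RscState:
    """Mutable per-stream state of the counter."""

    prev_az: float | None = None
    prev_t: float | None = None
    start_t: float | None = None
    window_start: float | None = None
    count: int = 0
    warmed_up: bool = False


def abs_delta_mg(z_prev: float, z_curr: float) -> float:
    """|difference of two consecutive Z samples|, converted g -> milli-g."""
    if not (math.isfinite(z_prev) and math.isfinite(z_curr)):
        raise ValueError(f"non-finite acceleration pair: {z_prev!r}, {z_curr!r}")
    return abs(float(z_curr) - float(z_prev)) * 1000.0


def is_spike(dz_mg: float, cfg: RscConfig) -> bool:
    """True when a delta reaches the spike amplitude threshold (>=)."""
    return dz_mg >= cfg.dz_th_mg


def rsc_step(
    state: RscState, sample: AccelSample, cfg: RscConfig
) -> tuple[RscState, WindowDecision | None]:
    """Feed one (already filtered) sample; maybe emit a window verdict.

    During warm-up only the previous-sample memory is updated. After
    warm-up, each consecutive pair of samples contributes at most one
    spike, and crossing a tumbling-window boundary emits a
    :class:`WindowDecision` for the completed window and resets the
    count. Samples must arrive in strictly increasing time order.
    """
    t, az = sample.t, sample.az
    if not math.isfinite(az):
        raise ValueError(f"non-finite acceleration at t={t}: {az!r}")
    if state.prev_t is not None and t <= state.prev_t:
        raise ValueError(
            f"out-of-order acceleration sample: t={t} after t={state.prev_t}"
        )

    if state.start_t is None:
        state.start_t = t

    # A dropout longer than two sampling intervals must not produce a
    # spurious delta when the stream resumes.
    if state.prev_t is not None and (t - state.prev_t) > 2.0 / cfg.fs_hz:
        state.prev_az = None

    decision: WindowDecision | None = None

    if not state.warmed_up and t - state.start_t >= cfg.warmup_s:
        state.warmed_up = True
        state.window_start = state.start_t + cfg.warmup_s
        state.count = 0

    if state.warmed_up:
        assert state.window_start is not None
        # Close any window(s) that ended at or before this sample; the
        # delta ending at this sample belongs to the window that
        # contains the sample itself.
        while t >= state.window_start + cfg.window_s:
            decision = WindowDecision(
                window_end=state.window_start + cfg.window_s,
                count=state.count,
                exercise=state.count >= cfg.count_th,
            )
            state.window_start += cfg.window_s
            state.count = 0
        if state.prev_az is not None and is_spike(
            abs_delta_mg(state.prev_az, az), cfg
        ):
            state.count += 1

    state.prev_az = az
    state.prev_t = t
    return state, decision


def rsc_flush(state: RscState, cfg: RscConfig) -> WindowDecision | None:
    """Close the final window at end of stream, if it is complete.

    The streaming step only closes a window when a later sample arrives.
    A stream that ends exactly on a window's final sample slot has still
    filled that window, so it is emitted here; a genuinely partial
    trailing window is not.
    """
    if not state.warmed_up or state.window_start is None or state.prev_t is None:
        return None
    if state.prev_t >= state.window_start + cfg.window_s - 1.0 / cfg.fs_hz - 1e-9:
        decision = WindowDecision(
            window_end=state.window_start + cfg.window_s,
            count=state.count,
            exercise=state.count >= cfg.count_th,
        )
        state.window_start += cfg.window_s
        state.count = 0
        return decision
    return None


def classify_stream(
    samples: Iterable[AccelSample],
    cfg: RscConfig | None = None,
    beta: float = DEFAULT_ACCEL_BETA,
) -> list[WindowDecision]:
    """Run the full RSC chain (low-pass filter -> spike count) over a stream.

    Returns one decision per complete post-warm-up window; a trailing
    partial window produces no decision. ``beta = 1`` disables the
    pre-filter. An empty stream yields an empty result.
    """
    cfg = cfg or RscConfig()
    filt = LowPassFilter(beta)
    state = RscState()
    decisions: list[WindowDecision] = []
    for s in samples:
        state, d = rsc_step(state, AccelSample(s.t, filt.step(s.az)), cfg)
        if d is not None:
            decisions.append(d)
    tail = rsc_flush(state, cfg)
    if tail is not None:
        decisions.append(tail)
    return decisions
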