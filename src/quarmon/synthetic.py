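"""Synthetic sensor streams with the statistical structure the monitor assumes.

These generators stand in for a wrist-worn device: a 20 Hz Z-axis
accelerometer riding at 1 g, a contact thermometer sampled every 5 s
around 36.5 °C with ~0.2 °C measurement noise, and a slow 0.2 Hz
room-condition stream. An :class:`ActivitySchedule` drives both the
acceleration texture and the exercise-induced temperature dynamics, so
tests can compare detector output against known ground truth.

The exercise carrier is a deterministic square wave (±100 mg about 1 g
at 1.5 Hz) with small additive noise: every level transition produces a
consecutive-sample jump of ~200 mg raw (~100 mg after the default
half-weight low-pass filter), comfortably at/above the 90 mg spike
threshold, and 1.5 Hz alternation yields ~90 transitions per 30 s
window — far above the 24-spike exercise threshold. Window counts are
therefore provable, not merely probable. "Normal activity" jumps are
capped below the spike threshold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .alerts import IndoorSample
from .rsc import AccelSample, RscConfig
from .temperature import TempSample

__all__ = [
    "Segment",
    "ActivitySchedule",
    "TempModelParams",
    "generate_accel",
    "generate_temperature",
    "generate_indoor",
]

MODES = ("none", "normal", "exercise")


@dataclass(frozen=True)
class Segment:
    """One contiguous activity segment: [start_s, end_s) with a mode."""

    start_s: float
    end_s: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown activity mode: {self.mode!r}")
        if self.end_s <= self.start_s:
            raise ValueError("segment must have positive duration")


@dataclass(frozen=True)
class ActivitySchedule:
    """Ordered, contiguous, non-overlapping activity segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s != a.end_s:
                raise ValueError(
                    f"segments must be contiguous: {a.end_s} != {b.start_s}"
                )

    @classmethod
    def from_tuples(cls, items: Iterable[tuple[float, float, str]]) -> "ActivitySchedule":
        return cls(tuple(Segment(*it) for it in items))

    @property
    def start_s(self) -> float:
        return self.segments[0].start_s

    @property
    def end_s(self) -> float:
        return self.segments[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def mode_at(self, t: float) -> str:
        """Mode of the segment containing ``t`` (end-exclusive except the last)."""
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg.mode
        if t == self.end_s:
            return self.segments[-1].mode
        raise ValueError(f"t={t} outside schedule [{self.start_s}, {self.end_s}]")

    def exercise_intervals(self) -> list[tuple[float, float]]:
        return [
            (s.start_s, s.end_s) for s in self.segments if s.mode == "exercise"
        ]


@dataclass(frozen=True)
class TempModelParams:
    """Body-temperature model parameters.

    baseline_c
        Resting body temperature (36.5 °C is a typical healthy value).
    noise_sd_c
        Per-sample measurement noise of the contact thermometer
        (~0.2 °C observed in practice on a wrist-worn probe).
    exercise_rise_c
        Asymptotic temperature rise sustained by continuous exercise.
    relax_tau_s
        First-order time constant for both the exercise-driven rise and
        the post-exercise recovery; 1200 s makes recovery essentially
        complete within the 20 minutes that the elevated alert threshold
        is held.
    fever_target_c
        When set, the deterministic component ramps toward this value
        and holds, overriding activity-driven dynamics (simulated fever).
    seed
        Generator seed (overridden by an explicit seed argument).
    """

    baseline_c: float = 36.5
    noise_sd_c: float = 0.2
    exercise_rise_c: float = 0.5
    relax_tau_s: float = 1200.0
    fever_target_c: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_c < 0:
            raise ValueError("noise_sd_c must be >= 0")
        if self.relax_tau_s <= 0:
            raise ValueError("relax_tau_s must be > 0")


def generate_accel(
    schedule: ActivitySchedule,
    cfg: RscConfig | None = None,
    seed: int = 0,
    *,
    noise_sd_g: float = 0.002,
    normal_jump_rate_hz: float = 0.2,
    normal_jump_mg: tuple[float, float] = (20.0, 60.0),
    exercise_amp_g: float = 0.1,
    exercise_freq_hz: float = 1.5,
) -> list[AccelSample]:
    """Synthesize the Z-axis acceleration stream for a schedule.

    Per mode: ``none`` is 1 g plus 2 mg gaussian noise; ``normal`` adds
    sparse single-sample jumps of 20-60 mg (mean rate 0.2/s, below the
    spike threshold, never adjacent so jump deltas cannot stack);
    ``exercise`` adds the ±100 mg, 1.5 Hz square-wave carrier.
    """
    cfg = cfg or RscConfig()
    fs = cfg.fs_hz
    rng = np.random.default_rng(seed)
    n = int(round(schedule.duration_s * fs))
    if n == 0:
        raise ValueError("schedule too short for one sample")
    t = schedule.start_s + np.arange(n) / fs
    az = 1.0 + rng.normal(0.0, noise_sd_g, size=n)

    for seg in schedule.segments:
        mask = (t >= seg.start_s) & (t < seg.end_s)
        if seg.mode == "exercise":
            phase = (t[mask] - seg.start_s) * exercise_freq_hz
            az[mask] += np.where(phase % 1.0 < 0.5, exercise_amp_g, -exercise_amp_g)
        elif seg.mode == "normal":
            idx = np.flatnonzero(mask)
            p = normal_jump_rate_hz / fs
            hits = idx[rng.random(idx.size) < p]
            # keep jumps isolated (>= 2 samples apart) so two adjacent
            # jump edges can never combine into a super-threshold delta
            keep: list[int] = []
            last = -10
            for i in hits:
                if i - last >= 2:
                    keep.append(i)
                    last = i
            if keep:
                amp = rng.uniform(*normal_jump_mg, size=len(keep)) / 1000.0
                sign = rng.choice([-1.0, 1.0], size=len(keep))
                az[np.asarray(keep)] += sign * amp

    np.clip(az, -2.0, 2.0, out=az)
    return [AccelSample(float(ti), float(zi)) for ti, zi in zip(t, az)]


def generate_temperature(
    schedule: ActivitySchedule,
    params: TempModelParams | None = None,
    fs_hz: float = 0.2,
    seed: int | None = None,
) -> list[TempSample]:
    """Synthesize the contact body-temperature stream for a schedule.

    The deterministic component follows first-order dynamics
    ``dT/dt = (target - T) / tau`` with target = baseline during rest,
    baseline + exercise_rise during exercise, or the fever target when
    one is set; gaussian measurement noise is added on output.
    """
    params = params or TempModelParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt = 1.0 / fs_hz
    n = int(round(schedule.duration_s * fs_hz))
    if n == 0:
        raise ValueError("schedule too short for one sample")
    t = schedule.start_s + np.arange(n) * dt

    temp = np.empty(n)
    state = params.baseline_c
    for i, ti in enumerate(t):
        if params.fever_target_c is not None:
            target = params.fever_target_c
        elif schedule.mode_at(min(ti, schedule.end_s)) == "exercise":
            target = params.baseline_c + params.exercise_rise_c
        else:
            target = params.baseline_c
        state += (target - state) * (1.0 - np.exp(-dt / params.relax_tau_s))
        temp[i] = state
    if params.noise_sd_c > 0:
        temp = temp + rng.normal(0.0, params.noise_sd_c, size=n)

    return [
        TempSample(float(ti), float(vi), "contact") for ti, vi in zip(t, temp)
    ]


def generate_indoor(
    duration_s: float,
    temp_c: float = 22.0,
    rh_pct: float = 40.0,
    *,
    temp_drift_c: float = 0.0,
    rh_drift_pct: float = 0.0,
    noise_sd_temp_c: float = 0.05,
    noise_sd_rh_pct: float = 0.2,
    fs_hz: float = 0.2,
    seed: int = 0,
) -> list[IndoorSample]:
    """Synthesize the room-condition stream (one sample every 5 s).

    ``temp_drift_c`` / ``rh_drift_pct`` are the total linear change over
    the whole stream (e.g. ``rh_pct=15, rh_drift_pct=50`` drifts RH from
    15 % to 65 %). Humidity is clamped to [0, 100].
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    if n == 0:
        raise ValueError("duration too short for one sample")
    t = np.arange(n) / fs_hz
    frac = t / duration_s
    temp = temp_c + frac * temp_drift_c + rng.normal(0.0, noise_sd_temp_c, size=n)
    rh = rh_pct + frac * rh_drift_pct + rng.normal(0.0, noise_sd_rh_pct, size=n)
    rh = np.clip(rh, 0.0, 100.0)
    return [
        IndoorSample(float(ti), float(tc), float(h))
        for ti, tc, h in zip(t, temp, rh)
    ]
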