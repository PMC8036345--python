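"""CSV/JSONL readers and writers, the flat config file, and session reports.

Fixed CSV dialect throughout: comma-separated, dot decimal, UTF-8,
mandatory header, timestamps as relative seconds. Validation errors are
addressed to the offending data line (header = line 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .alerts import (
    AlertConfig,
    IndoorBounds,
    IndoorSample,
    MonitorEvent,
    ThresholdConfig,
)
from .pipeline import MonitorConfig, MonitorResult, TelemetryRecord
from .rsc import AccelSample, RscConfig, WindowDecision
from .temperature import CalibrationModel, TempSample

__all__ = [
    "StreamFormatError",
    "ConfigError",
    "read_stream",
    "write_accel_csv",
    "write_temp_csv",
    "write_indoor_csv",
    "write_events_jsonl",
    "read_events_jsonl",
    "write_telemetry_csv",
    "read_telemetry_csv",
    "write_decisions_jsonl",
    "load_config",
    "save_config",
    "config_to_flat",
    "config_from_flat",
    "report",
]


class StreamFormatError(ValueError):
    """A stream CSV failed validation; the message names the line."""


class ConfigError(ValueError):
    """A config file failed validation."""


_COLUMNS = {
    "accel": ["t_s", "az_g"],
    "temp": ["t_s", "value_c", "source"],
    "indoor": ["t_s", "temp_c", "rh_pct"],
}


def _check_monotone(path: Path, t: pd.Series) -> None:
    bad = t.diff().le(0)
    if bad.any():
        i = int(bad.idxmax())
        raise StreamFormatError(
            f"{path}: line {i + 2}: non-monotone timestamp t_s={t.iloc[i]}"
        )


def _check_finite(path: Path, col: pd.Series, name: str) -> None:
    finite = pd.to_numeric(col, errors="coerce")
    bad = ~finite.notna() | ~finite.apply(math.isfinite)
    if bad.any():
        i = int(bad.idxmax())
        raise StreamFormatError(
            f"{path}: line {i + 2}: non-finite {name}={col.iloc[i]!r}"
        )


def read_stream(
    path: str | Path, kind: str
) -> list[AccelSample] | list[TempSample] | list[IndoorSample]:
    """Read and validate one sensor stream CSV.

    ``kind`` is ``"accel"`` (columns ``t_s,az_g``; extra ``ax_g``/``ay_g``
    columns are ignored), ``"temp"`` (``t_s,value_c,source``) or
    ``"indoor"`` (``t_s,temp_c,rh_pct``). Returns typed, time-ordered
    samples; any violation raises :class:`StreamFormatError` naming the
    offending line.
    """
    path = Path(path)
    if kind not in _COLUMNS:
        raise ValueError(f"unknown stream kind: {kind!r}")
    if not path.exists():
        raise StreamFormatError(f"{path}: file not found")
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise StreamFormatError(
            f"{path}: missing required column(s) {missing} for kind '{kind}'"
        )
    if df.empty:
        return []
    _check_finite(path, df["t_s"], "t_s")
    _check_monotone(path, df["t_s"].astype(float))

    if kind == "accel":
        _check_finite(path, df["az_g"], "az_g")
        return [
            AccelSample(float(r.t_s), float(r.az_g)) for r in df.itertuples()
        ]
    if kind == "temp":
        _check_finite(path, df["value_c"], "value_c")
        bad = ~df["source"].isin(["contact", "infrared"])
        if bad.any():
            i = int(bad.idxmax())
            raise StreamFormatError(
                f"{path}: line {i + 2}: source must be 'contact' or "
                f"'infrared', got {df['source'].iloc[i]!r}"
            )
        return [
            TempSample(float(r.t_s), float(r.value_c), str(r.source))
            for r in df.itertuples()
        ]
    # indoor
    _check_finite(path, df["temp_c"], "temp_c")
    _check_finite(path, df["rh_pct"], "rh_pct")
    rh = df["rh_pct"].astype(float)
    bad = (rh < 0) | (rh > 100)
    if bad.any():
        i = int(bad.idxmax())
        raise StreamFormatError(
            f"{path}: line {i + 2}: rh_pct out of range [0, 100]: {rh.iloc[i]}"
        )
    return [
        IndoorSample(float(r.t_s), float(r.temp_c), float(r.rh_pct))
        for r in df.itertuples()
    ]


def _write_csv(path: str | Path, header: str, rows: Iterable[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write(row + "\n")


def _num(x: float) -> str:
    # repr() is the shortest decimal that round-trips the float exactly
    return repr(float(x))


def write_accel_csv(path: str | Path, samples: Sequence[AccelSample]) -> None:
    _write_csv(path, "t_s,az_g", (f"{_num(s.t)},{_num(s.az)}" for s in samples))


def write_temp_csv(path: str | Path, samples: Sequence[TempSample]) -> None:
    _write_csv(
        path,
        "t_s,value_c,source",
        (f"{_num(s.t)},{_num(s.value)},{s.source}" for s in samples),
    )


def write_indoor_csv(path: str | Path, samples: Sequence[IndoorSample]) -> None:
    _write_csv(
        path,
        "t_s,temp_c,rh_pct",
        (f"{_num(s.t)},{_num(s.temp)},{_num(s.rh)}" for s in samples),
    )


def write_events_jsonl(path: str | Path, events: Sequence[MonitorEvent]) -> None:
    """One JSON object per line: ``{"t_s", "kind", "detail"}``."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for e in events:
            fh.write(
                json.dumps(
                    {"t_s": e.t, "kind": e.kind, "detail": e.detail},
                    sort_keys=True,
                )
                + "\n"
            )


def read_events_jsonl(path: str | Path) -> list[MonitorEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            events.append(
                MonitorEvent(t=obj["t_s"], kind=obj["kind"], detail=obj["detail"])
            )
    return events


TELEMETRY_HEADER = "t_s,alert,t_body_c,t_indoor_c,rh_pct,exercise"


def write_telemetry_csv(path: str | Path, records: Sequence[TelemetryRecord]) -> None:
    _write_csv(
        path,
        TELEMETRY_HEADER,
        (
            f"{_num(r.t)},{r.alert},{_num(r.t_body)},{_num(r.t_indoor)},"
            f"{_num(r.rh)},{r.exercise}"
            for r in records
        ),
    )


def read_telemetry_csv(path: str | Path) -> list[TelemetryRecord]:
    df = pd.read_csv(path, encoding="utf-8")
    expected = TELEMETRY_HEADER.split(",")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: missing telemetry column(s) {missing}")
    return [
        TelemetryRecord(
            t=float(r.t_s),
            alert=int(r.alert),
            t_body=float(r.t_body_c),
            t_indoor=float(r.t_indoor_c),
            rh=float(r.rh_pct),
            exercise=int(r.exercise),
        )
        for r in df.itertuples()
    ]


def write_decisions_jsonl(path: str | Path, decisions: Sequence[WindowDecision]) -> None:
    """Per-window exercise verdicts as JSONL."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in decisions:
            fh.write(
                json.dumps(
                    {
                        "window_end_s": d.window_end,
                        "count": d.count,
                        "exercise": bool(d.exercise),
                    },
                    sort_keys=True,
                )
                + "\n"
            )


# --------------------------------------------------------------------------
# Flat config file
# --------------------------------------------------------------------------

def config_to_flat(cfg: MonitorConfig) -> dict:
    """Flatten a MonitorConfig to the human-editable key-value document."""
    flat = {
        "window_s": cfg.rsc.window_s,
        "dz_th_mg": cfg.rsc.dz_th_mg,
        "count_th": cfg.rsc.count_th,
        "warmup_s": cfg.rsc.warmup_s,
        "fs_hz": cfg.rsc.fs_hz,
        "t_normal_c": cfg.thresholds.t_normal,
        "t_exercise_c": cfg.thresholds.t_exercise,
        "hold_min": cfg.thresholds.hold_min,
        "dwell_min": cfg.alert.dwell_min,
        "indoor_temp_lo_c": cfg.indoor.temp_lo,
        "indoor_temp_hi_c": cfg.indoor.temp_hi,
        "indoor_rh_lo_pct": cfg.indoor.rh_lo,
        "indoor_rh_hi_pct": cfg.indoor.rh_hi,
        "accel_beta": cfg.accel_beta,
        "temp_beta": cfg.temp_beta,
        "cal_t_ref_c": cfg.calibration.t_ref if cfg.calibration else None,
        "cal_t_avg_c": cfg.calibration.t_avg if cfg.calibration else None,
        "cal_n": cfg.calibration.n if cfg.calibration else None,
        "telemetry_period_s": cfg.telemetry_period_s,
        "seed": cfg.seed,
    }
    return flat


_CONFIG_KEYS = frozenset(config_to_flat(MonitorConfig()))


def config_from_flat(flat: dict) -> MonitorConfig:
    """Build a MonitorConfig from the flat document; unknown keys rejected."""
    unknown = set(flat) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    defaults = config_to_flat(MonitorConfig())
    merged = {**defaults, **flat}
    cal_fields = [merged["cal_t_ref_c"], merged["cal_t_avg_c"], merged["cal_n"]]
    if any(v is not None for v in cal_fields):
        if any(v is None for v in cal_fields):
            raise ConfigError(
                "calibration requires all of cal_t_ref_c, cal_t_avg_c, cal_n"
            )
        calibration = CalibrationModel(
            t_ref=float(merged["cal_t_ref_c"]),
            t_avg=float(merged["cal_t_avg_c"]),
            bias=float(merged["cal_t_ref_c"]) - float(merged["cal_t_avg_c"]),
            n=int(merged["cal_n"]),
        )
    else:
        calibration = None
    try:
        return MonitorConfig(
            rsc=RscConfig(
                window_s=float(merged["window_s"]),
                dz_th_mg=float(merged["dz_th_mg"]),
                count_th=int(merged["count_th"]),
                warmup_s=float(merged["warmup_s"]),
                fs_hz=float(merged["fs_hz"]),
            ),
            thresholds=ThresholdConfig(
                t_normal=float(merged["t_normal_c"]),
                t_exercise=float(merged["t_exercise_c"]),
                hold_min=float(merged["hold_min"]),
            ),
            alert=AlertConfig(dwell_min=float(merged["dwell_min"])),
            indoor=IndoorBounds(
                temp_lo=float(merged["indoor_temp_lo_c"]),
                temp_hi=float(merged["indoor_temp_hi_c"]),
                rh_lo=float(merged["indoor_rh_lo_pct"]),
                rh_hi=float(merged["indoor_rh_hi_pct"]),
            ),
            accel_beta=float(merged["accel_beta"]),
            temp_beta=float(merged["temp_beta"]),
            calibration=calibration,
            telemetry_period_s=float(merged["telemetry_period_s"]),
            seed=int(merged["seed"]),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(cfg: MonitorConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_flat(cfg), fh, sort_keys=True)


def load_config(path: str | Path) -> MonitorConfig:
    with open(path, encoding="utf-8") as fh:
        flat = yaml.safe_load(fh)
    if flat is None:
        flat = {}
    if not isinstance(flat, dict):
        raise ConfigError(f"{path}: config must be a flat key-value mapping")
    return config_from_flat(flat)


# --------------------------------------------------------------------------
# Session report
# --------------------------------------------------------------------------

def report(result: MonitorResult, cfg: MonitorConfig | None = None) -> str:
    """Human-readable per-session report.

    Shows min/max/average/std of the body temperature, the alert
    thresholds that were actually applied, total detected exercise time,
    and the alert outcome (with the first alert time when one fired).
    """
    cfg = cfg or MonitorConfig()
    if not result.telemetry:
        return "Session report\n==============\nEmpty session: no telemetry records.\n"
    s = result.summary
    period = cfg.telemetry_period_s
    exercise_min = sum(r.exercise for r in result.telemetry) * period / 60.0
    applied = sorted({t_th for _, t_th in result.threshold_trace}) or [
        cfg.thresholds.t_normal
    ]
    raised = [e for e in result.events if e.kind == "alert_raised"]
    lines = [
        "Session report",
        "==============",
        f"Telemetry records : {s.n} (every {period:g} s, "
        f"{(result.telemetry[-1].t - result.telemetry[0].t) / 60.0:.1f} min)",
        f"T_body minimum (C): {s.t_body_min:.2f}",
        f"T_body maximum (C): {s.t_body_max:.2f}",
        f"T_body average (C): {s.t_body_mean:.2f}",
        f"T_body std     (C): {s.t_body_std:.2f}",
        "Applied T_TH   (C): " + ", ".join(f"{v:g}" for v in applied),
        f"Exercise detected : {exercise_min:.1f} min",
    ]
    if raised:
        lines.append(
            f"Alert             : Yes (first raised at t={raised[0].t:g} s)"
        )
    else:
        lines.append("Alert             : No")
    return "\n".join(lines) + "\n"
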