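"""Temperature stream conditioning.

Two small primitives shared by the rest of the monitor:

* a first-order IIR (exponentially weighted) low-pass filter,
  ``y_i = beta * x_i + (1 - beta) * y_{i-1}``, used to suppress
  vibration noise on the contact-thermometer stream (and reused to
  pre-filter the accelerometer stream before spike detection);
* an additive bias calibration that transfers a wrist-mounted contact
  reading onto a core-equivalent reference: the bias is the difference
  between a reference thermometer value and the mean of N stabilized
  raw samples, and is simply added to every subsequent raw reading.

Infrared readings are treated as an independent spot check and pass
through uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "TempSample",
    "FilterState",
    "LowPassFilter",
    "lowpass_step",
    "lowpass_series",
    "CalibrationModel",
    "InsufficientCalibrationError",
    "calibrate_fit",
    "calibrate_apply",
]

#: Default smoothing coefficient: balances noise suppression against
#: dynamic response on a 0.2 Hz body-temperature stream.
DEFAULT_BETA = 0.5

#: Default number of stabilized samples averaged when fitting the bias.
DEFAULT_CALIBRATION_N = 50

#: Default wait, in seconds, before calibration samples are trusted
#: (time for the reference glass thermometer and the skin-contact probe
#: to reach a stable reading).
DEFAULT_STABILIZATION_S = 600.0

#: Plausible range for human body temperature streams, degrees Celsius.
BODY_TEMP_RANGE_C = (30.0, 45.0)


@dataclass(frozen=True)
class TempSample:
    """One time-stamped temperature reading.

    Parameters
    ----------
    t : float
        Seconds since the start of the stream (non-negative).
    value : float
        Temperature in degrees Celsius.
    source : {"contact", "infrared"}
        Which thermometer produced the reading. Contact readings are
        filtered and calibrated downstream; infrared readings bypass
        both and serve as single-shot confirmations.
    """

    t: float
    value: float
    source: Literal["contact", "infrared"] = "contact"


@dataclass
class FilterState:
    """State of the first-order IIR low-pass filter.

    ``prev`` is ``None`` until the first sample has been seen; the first
    sample passes through unchanged and initializes the recursion, which
    avoids imposing an arbitrary prior output.
    """

    beta: float = DEFAULT_BETA
    prev: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta!r}")


def lowpass_step(state: FilterState, x: float) -> tuple[FilterState, float]:
    """Advance the low-pass filter by one sample.

    Returns the updated state and the filtered output
    ``y = beta * x + (1 - beta) * y_prev``. With ``beta = 1`` the output
    equals the input (no filtering); smaller ``beta`` filters harder at
    the cost of a slower response.

    Raises
    ------
    ValueError
        If ``x`` is not finite.
    """
    if not math.isfinite(x):
        raise ValueError(f"non-finite temperature sample: {x!r}")
    if state.prev is None:
        y = float(x)
    else:
        y = state.beta * float(x) + (1.0 - state.beta) * state.prev
    state.prev = y
    return state, y


class LowPassFilter:
    """Convenience stateful wrapper around :func:`lowpass_step`."""

    def __init__(self, beta: float = DEFAULT_BETA):
        self._state = FilterState(beta=beta)

    @property
    def beta(self) -> float:
        return self._state.beta

    def step(self, x: float) -> float:
        self._state, y = lowpass_step(self._state, x)
        return y

    def reset(self) -> None:
        self._state.prev = None


def lowpass_series(values: Iterable[float], beta: float = DEFAULT_BETA) -> list[float]:
    """Filter a whole sequence, returning one output per input."""
    filt = LowPassFilter(beta)
    return [filt.step(v) for v in values]


class InsufficientCalibrationError(ValueError):
    """Raised when fewer raw samples are supplied than the average needs."""


@dataclass(frozen=True)
class CalibrationModel:
    """Additive bias correction fitted against a reference thermometer.

    Attributes
    ----------
    t_ref : float
        Reference (e.g. glass-thermometer) temperature, degrees Celsius.
    t_avg : float
        Mean of the ``n`` stabilized raw samples, degrees Celsius.
    bias : float
        Additive correction ``t_ref - t_avg`` applied to raw readings.
    n : int
        Number of samples averaged (>= 1).
    """

    t_ref: float
    t_avg: float
    bias: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"calibration needs n >= 1 samples, got {self.n}")
        if not math.isclose(self.bias, self.t_ref - self.t_avg, abs_tol=1e-9):
            raise ValueError(
                "inconsistent calibration model: bias must equal t_ref - t_avg"
            )


def calibrate_fit(
    raw: Sequence[float], t_ref: float, n: int = DEFAULT_CALIBRATION_N
) -> CalibrationModel:
    """Fit the additive bias from the first ``n`` stabilized raw samples.

    The caller is responsible for dropping the pre-stabilization portion
    of the stream (by default the first 10 minutes of skin contact)
    before passing ``raw``; the first ``n`` of the remaining samples are
    averaged, and the bias is ``t_ref - mean``.

    Raises
    ------
    InsufficientCalibrationError
        If fewer than ``n`` samples are available.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if len(raw) < n:
        raise InsufficientCalibrationError(
            f"insufficient calibration data: need {n} samples, got {len(raw)}"
        )
    window = [float(v) for v in raw[:n]]
    for v in window:
        if not math.isfinite(v):
            raise ValueError(f"non-finite calibration sample: {v!r}")
    t_avg = sum(window) / n
    return CalibrationModel(t_ref=float(t_ref), t_avg=t_avg, bias=float(t_ref) - t_avg, n=n)


def calibrate_apply(model: CalibrationModel, t_raw: float) -> float:
    """Apply the fitted bias: ``t_cal = t_raw + bias``."""
    if not math.isfinite(t_raw):
        raise ValueError(f"non-finite temperature sample: {t_raw!r}")
    return float(t_raw) + model.bias
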