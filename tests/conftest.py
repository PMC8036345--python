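"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from quarmon.rsc import AccelSample, RscConfig


def toggle_stream(
    n_toggles: int,
    amp_mg: float = 150.0,
    cfg: RscConfig | None = None,
    n_windows: int = 1,
    spacing: int = 4,
) -> list[AccelSample]:
    """A controlled stream: quiet warm-up, then level toggles in the windows.

    Each toggle switches the signal between 1 g and 1 g + amp, producing
    exactly one consecutive-sample delta of ``amp_mg``. Toggles are
    spread over the post-warm-up windows, ``spacing`` samples apart, all
    inside the first window unless more are requested than fit.
    """
    cfg = cfg or RscConfig()
    fs = int(cfg.fs_hz)
    warm = int(cfg.warmup_s * fs)
    win = int(cfg.window_s * fs)
    n = warm + n_windows * win
    az = np.ones(n)
    level = 0.0
    toggle_at = warm + np.arange(n_toggles) * spacing
    assert toggle_at[-1] < n if n_toggles else True
    ti = 0
    for i in range(warm, n):
        if ti < n_toggles and i == toggle_at[ti]:
            level = amp_mg / 1000.0 - level if level == 0.0 else 0.0
            ti += 1
        az[i] = 1.0 + level
    return [AccelSample(i / fs, float(a)) for i, a in enumerate(az)]


def brute_force_window_counts(
    samples: list[AccelSample], cfg: RscConfig
) -> list[tuple[int, bool]]:
    """Independent per-window spike count on an (already filtered) stream.

    Direct pass: for every consecutive-sample delta, assign it to the
    tumbling window (anchored at warm-up end) containing the *later*
    sample and count it when |delta| >= threshold. Only windows whose
    final sample slot is covered by the stream are reported.
    """
    t = np.array([s.t for s in samples])
    az = np.array([s.az for s in samples])
    start = t[0]
    warm_end = start + cfg.warmup_s
    last = t[-1]
    n_windows = int(np.floor((last - warm_end) / cfg.window_s + 1.0 / (cfg.window_s * cfg.fs_hz) + 1e-9))
    counts = [0] * n_windows
    for i in range(1, len(samples)):
        if t[i] - t[i - 1] > 2.0 / cfg.fs_hz:
            continue  # dropout: no valid delta
        if t[i] < warm_end:
            continue
        w = int(np.floor((t[i] - warm_end) / cfg.window_s + 1e-9))
        if w >= n_windows:
            continue
        if abs(az[i] - az[i - 1]) * 1000.0 >= cfg.dz_th_mg:
            counts[w] += 1
    return [(c, c >= cfg.count_th) for c in counts]


@pytest.fixture
def rsc_cfg() -> RscConfig:
    return RscConfig()
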