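"""Fixational gaze preprocessing and the towardness statistic.

The preprocessing chain mirrors common eye-tracking practice for covert
spatial-attention studies: blink interpolation (±100 ms padding), binocular
averaging, anti-aliased downsampling to 250 Hz, a ±2.75° fixation filter,
15-sample (60 ms) moving-average smoothing, and per-trial baselining to the
−200–0 ms pre-cue window. Towardness at each time point is half the
difference between the mean horizontal position on right-cued and
left-cued trials (leftward positions negative), so positive values mean
gaze is biased toward the cued item.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import GazeRaw

__all__ = [
    "GazeEpochs",
    "interpolate_blinks",
    "detect_blinks",
    "preprocess_gaze",
    "towardness",
    "moving_average",
]


@dataclass
class GazeEpochs:
    """Preprocessed gaze epochs (degrees visual angle)."""

    x: np.ndarray  # trials × samples
    y: np.ndarray
    times_ms: np.ndarray
    rate_hz: float
    table_index: np.ndarray  # surviving trial-table row labels
    n_input_trials: int = 0

    @property
    def retention(self) -> float:
        return self.x.shape[0] / max(self.n_input_trials, 1)


def interpolate_blinks(trace: np.ndarray, blink_intervals, times_ms: np.ndarray,
                       pad_ms: float = 100.0) -> np.ndarray:
    """Linearly interpolate across blink intervals padded by ``pad_ms``.

    Endpoints outside the padded interval are preserved exactly; a blink
    touching a trace boundary is filled with the nearest valid value.
    """
    out = np.array(trace, dtype=float, copy=True)
    if not blink_intervals:
        return out
    bad = np.zeros(out.shape[-1], dtype=bool)
    for b0, b1 in blink_intervals:
        if b0 > times_ms[-1] or b1 < times_ms[0]:
            raise ValueError("blink interval outside trace")
        bad |= (times_ms >= b0 - pad_ms) & (times_ms <= b1 + pad_ms)
    good = ~bad
    if not good.any():
        raise ValueError("blink padding covers the whole trace")
    out[..., bad] = np.interp(times_ms[bad], times_ms[good], out[..., good])
    return out


def detect_blinks(trace: np.ndarray, times_ms: np.ndarray,
                  threshold: float = 20.0) -> list:
    """Saturation-based blink detector for external data: contiguous runs
    with |value| ≥ threshold become (start_ms, end_ms) intervals."""
    bad = np.abs(np.asarray(trace, float)) >= threshold
    edges = np.diff(np.concatenate([[0], bad.view(np.int8), [0]]))
    starts, stops = np.flatnonzero(edges == 1), np.flatnonzero(edges == -1) - 1
    return [(float(times_ms[a]), float(times_ms[b])) for a, b in zip(starts, stops)]


def moving_average(x: np.ndarray, n_samples: int) -> np.ndarray:
    """Centered moving average along the last axis, edges truncated to the
    available window (shorter effective windows near the boundaries)."""
    kernel = np.ones(n_samples)
    num = np.apply_along_axis(np.convolve, -1, x, kernel, "same")
    norm = np.convolve(np.ones(x.shape[-1]), kernel, "same")
    return num / norm


def _downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Anti-alias by a ``factor``-sample moving average, then decimate."""
    if factor == 1:
        return x
    return moving_average(x, factor)[..., ::factor]


def preprocess_gaze(raw: GazeRaw, target_rate_hz: float = 250.0,
                    fixation_limit_deg: float = 2.75,
                    smooth_samples: int = 15,
                    baseline_ms: tuple = (-200.0, 0.0),
                    blink_pad_ms: float = 100.0,
                    blink_threshold: float = 20.0) -> GazeEpochs:
    """Full preprocessing chain: blinks → binocular average → downsample →
    fixation filter → smooth → baseline.

    Blink intervals come from the generator's ground truth when present,
    otherwise from :func:`detect_blinks`. Trials whose |x| or |y| exceeds
    ``fixation_limit_deg`` after downsampling are dropped; if every trial
    is dropped the (empty) result still reports ``n_input_trials`` so the
    caller can see the participant was fully excluded.
    """
    if raw.rate_hz < target_rate_hz:
        raise ValueError("raw sampling rate must be at least the target rate")
    factor = raw.rate_hz / target_rate_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("raw rate must be an integer multiple of the target rate")
    factor = int(round(factor))

    n = raw.x_left.shape[0]
    x = np.empty_like(raw.x_left, dtype=float)
    y = np.empty_like(raw.y_left, dtype=float)
    for i in range(n):
        ivals = raw.blink_intervals[i] if raw.blink_intervals is not None else None
        if ivals is None:
            ivals = detect_blinks(raw.x_left[i], raw.times_ms, blink_threshold)
        eyes = [interpolate_blinks(e[i], ivals, raw.times_ms, blink_pad_ms)
                for e in (raw.x_left, raw.x_right, raw.y_left, raw.y_right)]
        x[i] = 0.5 * (eyes[0] + eyes[1])
        y[i] = 0.5 * (eyes[2] + eyes[3])

    x, y = _downsample(x, factor), _downsample(y, factor)
    times = raw.times_ms[::factor]

    keep = (np.abs(x).max(axis=1) <= fixation_limit_deg) \
        & (np.abs(y).max(axis=1) <= fixation_limit_deg)
    x, y = x[keep], y[keep]
    if x.shape[0] == 0:  # fully excluded participant: report, don't crash
        return GazeEpochs(x=x, y=y, times_ms=times, rate_hz=target_rate_hz,
                          table_index=raw.table_index[keep], n_input_trials=n)

    x = moving_average(x, smooth_samples)
    y = moving_average(y, smooth_samples)
    base = (times >= baseline_ms[0]) & (times < baseline_ms[1])
    if base.any():
        x = x - x[:, base].mean(axis=1, keepdims=True)
        y = y - y[:, base].mean(axis=1, keepdims=True)
    return GazeEpochs(x=x, y=y, times_ms=times, rate_hz=target_rate_hz,
                      table_index=raw.table_index[keep], n_input_trials=n)


def towardness(x_right_cued: np.ndarray, x_left_cued: np.ndarray) -> np.ndarray:
    """Towardness time course in degrees (positive = toward the cued item).

    Per time point: (mean over right-cued trials − mean over left-cued
    trials) / 2, with positions left of fixation negative. Antisymmetric
    under swapping the two condition labels.
    """
    xr, xl = np.asarray(x_right_cued, float), np.asarray(x_left_cued, float)
    if xr.size == 0 or xl.size == 0:
        raise ValueError("both cue-side conditions must be non-empty")
    return (xr.mean(axis=0) - xl.mean(axis=0)) / 2.0
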