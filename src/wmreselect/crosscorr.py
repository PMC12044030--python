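"""Normalized cross-correlation and peak-lag analysis.

The raw cross-correlation at lag k is z[k] = Σ_i x[i]·y[i−k], evaluated
over the full lag range −(n−1) … (n−1) including partial overlap at the
edges. Normalization divides by √(Σx² · Σy²) (global energy), bounding the
coefficients in [−1, 1] by Cauchy–Schwarz and making them invariant to
positive rescaling of either input.

Sign convention: if y is a delayed copy of x, y[i] = x[i−d], then
z[k] = Σ x[i]·x[i−k−d] peaks at k = −d — a *positive* delay of y shows up
as a *negative* peak lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import TTestResult, one_sample_t

__all__ = [
    "XCorrResult",
    "normalized_xcorr",
    "peak_lag",
    "zero_lag_test",
    "normalize_to_peak",
]


@dataclass
class XCorrResult:
    """Cross-correlation over the full symmetric lag axis."""

    lags: np.ndarray  # integer sample offsets, −(n−1) … (n−1)
    coefficients: np.ndarray  # in [−1, 1]; masked lags are NaN
    dt_ms: float = 1.0

    @property
    def lags_ms(self) -> np.ndarray:
        return self.lags * self.dt_ms


def normalized_xcorr(x, y, dt_ms: float = 1.0, mean_center: bool = True,
                     min_overlap_frac: float = 0.5,
                     per_lag: bool = False) -> XCorrResult:
    """Normalized cross-correlation of two equal-length time courses.

    ``mean_center`` (default) removes each signal's mean over the analysis
    window first, preventing shared offsets from dominating the peak.
    Partial-overlap lags are computed, but lags where the overlap drops
    below ``min_overlap_frac`` of the signal length are masked to NaN
    (set 0 to keep everything). ``per_lag=True`` switches the denominator
    from global energy to the energy of the overlapping segments at each
    lag (a Pearson-like variant, still bounded by 1 in magnitude).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be equal-length 1-D time courses")
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant signal: normalization undefined")
    if mean_center:
        x, y = x - x.mean(), y - y.mean()
    ex, ey = float(np.sum(x**2)), float(np.sum(y**2))

    # np.correlate(x, y, 'full')[k + n - 1] = Σ_i x[i]·y[i−k] = z[k]
    z = np.correlate(x, y, mode="full")
    lags = np.arange(-(n - 1), n)
    if per_lag:
        cx = np.concatenate([[0.0], np.cumsum(x**2)])
        cy = np.concatenate([[0.0], np.cumsum(y**2)])
        exk = np.where(lags >= 0, cx[n] - cx[lags.clip(0)], cx[n + lags.clip(None, 0)])
        eyk = np.where(lags >= 0, cy[n - lags.clip(0)], cy[n] - cy[-lags.clip(None, 0)])
        with np.errstate(invalid="ignore", divide="ignore"):
            coeff = np.where((exk > 0) & (eyk > 0), z / np.sqrt(exk * eyk), np.nan)
    else:
        coeff = z / np.sqrt(ex * ey)
    overlap = n - np.abs(lags)
    coeff = np.where(overlap >= min_overlap_frac * n, coeff, np.nan)
    return XCorrResult(lags=lags, coefficients=coeff, dt_ms=dt_ms)


def peak_lag(result: XCorrResult) -> float:
    """Lag (ms) of the maximum coefficient.

    Ties are broken toward the smallest |lag|, then toward the negative
    lag, making the readout deterministic.
    """
    c = result.coefficients
    finite = np.isfinite(c)
    if not finite.any():
        raise ValueError("no finite coefficients")
    best = np.nanmax(c)
    at = np.flatnonzero(finite & (c == best))
    lags = result.lags[at]
    order = np.lexsort((lags, np.abs(lags)))  # |lag| first, negative before positive
    return float(lags[order[0]] * result.dt_ms)


def zero_lag_test(peak_lags_ms) -> TTestResult:
    """One-sample t-test of per-participant peak lags against zero."""
    return one_sample_t(np.asarray(peak_lags_ms, float), 0.0)


def normalize_to_peak(course) -> np.ndarray:
    """Scale a time course to percent of its extreme magnitude (±100)."""
    c = np.asarray(course, dtype=float)
    peak = np.nanmax(np.abs(c))
    if not peak > 0:
        raise ValueError("course has no nonzero peak")
    return 100.0 * c / peak
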