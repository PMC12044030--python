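"""Time–frequency decomposition and hemispheric lateralization indices.

Power is obtained from complex Morlet wavelets spanning 3–40 Hz with a
fixed 300-ms analysis window, i.e. the number of cycles grows with
frequency (n_cycles = f × 0.3 s, so 3 cycles at 10 Hz, 6 at 20 Hz). The
lateralization index for an electrode pair is

    100 × (contra − ipsi) / (contra + ipsi)

on trial-averaged power, computed per electrode and then averaged over the
left/right pair. For visual selection the contra/ipsi split follows the
cued item's side at posterior electrodes (PO7/PO8, alpha 8–12 Hz); for
motor selection it follows the prospective response hand at central
electrodes (C3/C4, beta 13–30 Hz). The index is self-normalizing, so no
power baseline is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from mne.time_frequency import tfr_array_morlet

from .containers import EpochArray, hemisphere

__all__ = [
    "TFR",
    "TFRLateralization",
    "BandCourse",
    "morlet_tfr",
    "lateralization_index",
    "cohort_lateralization",
    "band_course",
    "topography_contrast",
    "epoch_around_event",
]

EDGE_PAD_MS = 150.0  # half the 300-ms analysis window


@dataclass
class TFR:
    """Time–frequency power for one participant's trials."""

    power: np.ndarray  # (n_trials, n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times_ms: np.ndarray
    channels: list
    sfreq: float
    edge_valid: np.ndarray = None  # bool per time point

    def __post_init__(self):
        if self.edge_valid is None:
            t = self.times_ms
            self.edge_valid = (t >= t[0] + EDGE_PAD_MS) & (t <= t[-1] - EDGE_PAD_MS)


@dataclass
class TFRLateralization:
    """Participant × frequency × time lateralization index (in %)."""

    index: np.ndarray  # (n_participants, n_freqs, n_times)
    freqs: np.ndarray
    times_ms: np.ndarray
    channel_pair: tuple
    basis: str
    edge_valid: np.ndarray = None


@dataclass
class BandCourse:
    """Participant × time band-averaged lateralization index (in %)."""

    course: np.ndarray
    times_ms: np.ndarray
    band: tuple
    label: str = ""
    edge_valid: np.ndarray = None


def morlet_tfr(data: np.ndarray, sfreq: float, freqs=None,
               window_ms: float = 300.0, decim: int = 1,
               times_ms: np.ndarray | None = None,
               channels: list | None = None) -> TFR:
    """Morlet wavelet power of epoched data (trials × channels × samples).

    ``n_cycles = f × window`` keeps the analysis window fixed at
    ``window_ms`` across frequencies. Output time points within half a
    window of either epoch edge are flagged invalid in ``edge_valid``.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("expected (n_trials, n_channels, n_samples)")
    freqs = np.arange(3.0, 41.0) if freqs is None else np.asarray(freqs, float)
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency axis must be strictly increasing")
    if freqs.max() >= sfreq / 2:
        raise ValueError(f"max frequency {freqs.max()} Hz at or above Nyquist "
                         f"({sfreq / 2} Hz)")
    n_cycles = freqs * (window_ms / 1000.0)
    if data.shape[-1] / sfreq * 1000.0 <= window_ms:
        raise ValueError("epoch must be longer than the analysis window")
    power = tfr_array_morlet(data, sfreq=sfreq, freqs=freqs,
                             n_cycles=n_cycles, output="power",
                             zero_mean=True, decim=decim)
    if times_ms is None:
        times_ms = np.arange(data.shape[-1]) / sfreq * 1000.0
    times_ms = np.asarray(times_ms, float)[::decim]
    return TFR(power=power, freqs=freqs, times_ms=times_ms,
               channels=channels or [], sfreq=sfreq / decim)


def lateralization_index(tfr: TFR, trial_feature: np.ndarray,
                         pair: tuple = ("PO7", "PO8")) -> np.ndarray:
    """Pair-averaged lateralization index for one participant.

    ``trial_feature`` gives each trial's relevant side ('left'/'right'):
    the cued item's location for the visual (item-side) basis or the
    response hand for the motor (response-hand) basis. For each electrode,
    power is averaged over its contralateral and ipsilateral trials,
    normalized as 100 × (contra − ipsi)/(contra + ipsi), then averaged
    over the two electrodes. Cells where contra + ipsi = 0 propagate NaN.
    Returns (n_freqs, n_times).
    """
    feature = np.asarray(trial_feature)
    per_electrode = []
    for ch in pair:
        try:
            ci = tfr.channels.index(ch)
        except ValueError:
            raise KeyError(f"channel {ch!r} not present in TFR") from None
        hemi = hemisphere(ch)
        contra_mask = feature != hemi
        if not contra_mask.any() or contra_mask.all():
            raise ValueError("both contra and ipsi trial sets must be non-empty")
        contra = tfr.power[contra_mask, ci].mean(axis=0)
        ipsi = tfr.power[~contra_mask, ci].mean(axis=0)
        denom = contra + ipsi
        with np.errstate(invalid="ignore", divide="ignore"):
            idx = np.where(denom > 0, 100.0 * (contra - ipsi) / denom, np.nan)
        per_electrode.append(idx)
    return np.mean(per_electrode, axis=0)


def cohort_lateralization(epochs: EpochArray, table: pd.DataFrame,
                          pair: tuple = ("PO7", "PO8"),
                          basis: str = "item-side",
                          freqs=None, window_ms: float = 300.0,
                          decim: int = 1,
                          trial_mask: pd.Series | None = None) -> TFRLateralization:
    """Per-participant lateralization indices for a whole cohort.

    ``basis='item-side'`` splits trials by ``cued_side`` (visual marker);
    ``basis='response-hand'`` splits by ``response_hand`` (motor marker).
    ``trial_mask`` (aligned with ``table``) restricts the trials used,
    e.g. to one interrupter-onset condition.
    """
    col = {"item-side": "cued_side", "response-hand": "response_hand"}[basis]
    out, times = [], None
    for pi, pid in enumerate(epochs.participants):
        sub = table[table["participant"] == pid]
        mask = np.ones(len(sub), bool)
        if trial_mask is not None:
            mask = trial_mask.loc[sub.index].to_numpy()
        tfr = morlet_tfr(epochs.data[pi][mask], epochs.sfreq, freqs=freqs,
                         window_ms=window_ms, decim=decim,
                         times_ms=epochs.times_ms, channels=epochs.channels)
        out.append(lateralization_index(tfr, sub[col].to_numpy()[mask], pair))
        times, fx, edge = tfr.times_ms, tfr.freqs, tfr.edge_valid
    return TFRLateralization(index=np.stack(out), freqs=fx, times_ms=times,
                             channel_pair=tuple(pair), basis=basis,
                             edge_valid=edge)


def band_course(lat: TFRLateralization, band: tuple,
                label: str = "") -> BandCourse:
    """Unweighted mean of the lateralization index over a frequency band."""
    lo, hi = band
    sel = (lat.freqs >= lo) & (lat.freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {band} outside frequency axis "
                         f"[{lat.freqs[0]}, {lat.freqs[-1]}]")
    return BandCourse(course=lat.index[:, sel, :].mean(axis=1),
                      times_ms=lat.times_ms, band=(float(lo), float(hi)),
                      label=label, edge_valid=lat.edge_valid)


def topography_contrast(tfr: TFR, trial_feature: np.ndarray, band: tuple,
                        windows_ms: list) -> pd.DataFrame:
    """Per-channel normalized right-vs-left contrast maps.

    For every channel: band-average power on right-feature and
    left-feature trials, 100 × (right − left)/(right + left), averaged
    within each requested time window. Returns channels × windows.
    """
    if len(tfr.channels) < 2:
        raise ValueError("need at least 2 channels for a topography")
    feature = np.asarray(trial_feature)
    lo, hi = band
    fsel = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    bp = tfr.power[:, :, fsel, :].mean(axis=2)  # trials × ch × time
    right = bp[feature == "right"].mean(axis=0)
    left = bp[feature == "left"].mean(axis=0)
    denom = right + left
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.where(denom > 0, 100.0 * (right - left) / denom, np.nan)
    cols = {}
    for w0, w1 in windows_ms:
        tsel = (tfr.times_ms >= w0) & (tfr.times_ms < w1)
        cols[f"{int(w0)}-{int(w1)}ms"] = contrast[:, tsel].mean(axis=1)
    return pd.DataFrame(cols, index=tfr.channels)


def epoch_around_event(data: np.ndarray, times_ms: np.ndarray,
                       event_times_ms: np.ndarray, sfreq: float,
                       window_ms: tuple = (-400.0, 400.0)):
    """Re-epoch trialwise data around per-trial event times.

    ``data`` has trials first and samples last (any axes in between). The
    new time axis is re-zeroed at the event, sample-exactly (event mapped
    to the nearest sample). Trials whose window would leave the source
    epoch, or whose event time is missing, are dropped and reported.

    Returns ``(new_data, new_times_ms, kept)`` with ``kept`` a boolean
    trial mask.
    """
    data = np.asarray(data)
    times_ms = np.asarray(times_ms, float)
    ev = np.asarray(event_times_ms, float)
    if ev.shape[0] != data.shape[0]:
        raise ValueError("one event time per trial required")
    dt = 1000.0 / sfreq
    pre = int(round(-window_ms[0] / dt))
    post = int(round(window_ms[1] / dt))
    new_times = dt * np.arange(-pre, post + 1)

    ev_idx = np.round((ev - times_ms[0]) / dt).astype(float)
    kept = (np.isfinite(ev)
            & (ev_idx - pre >= 0) & (ev_idx + post <= len(times_ms) - 1))
    pieces = []
    for i in np.flatnonzero(kept):
        c = int(ev_idx[i])
        pieces.append(data[i, ..., c - pre:c + post + 1])
    new = (np.stack(pieces) if pieces
           else np.empty((0, *data.shape[1:-1], len(new_times)), data.dtype))
    return new, new_times, kept
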