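"""In-memory containers shared across analysis stages.

The trial table is a plain :class:`pandas.DataFrame` (column dictionary in
:data:`TRIAL_COLUMNS`); epoched multichannel data travel in
:class:`EpochArray`, a thin 4-D array container with channel labels, a
millisecond time axis and HDF5 round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: Column dictionary for the per-trial behavioral/design table.
TRIAL_COLUMNS = {
    "participant": "integer participant id",
    "trial": "within-participant trial index (0-based)",
    "block": "block index (0-based)",
    "block_type": "'no-interruption' or 'interruption'",
    "predictability": "'fixed', 'variable' or 'none' (no-interruption blocks)",
    "onset_condition": "'early', 'medium', 'late' or 'none'",
    "onset_ms": "interrupter onset in ms post-cue (NaN if none)",
    "cued_side": "'left' or 'right' — location of the cued memory item",
    "response_hand": "'left' or 'right' — hand required for the memory report",
    "target_orientation": "cued bar tilt, degrees in (−90, +90]",
    "interrupter_orientation": "interrupter bar tilt, degrees (NaN if none)",
    "interrupter_rt_ms": "reaction time to the interrupter (NaN if none)",
    "interrupter_correct": "interrupter discrimination correct (bool/NaN)",
    "reported_orientation": "reproduced tilt, degrees (NaN until sampled)",
    "rt_probe_ms": "reaction time from probe onset to first key press",
}


def validate_trial_table(table: pd.DataFrame, require: tuple[str, ...] = ()) -> None:
    """Raise ``ValueError`` naming any required column that is missing."""
    needed = set(require) or set(TRIAL_COLUMNS) - {"reported_orientation"}
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")


@dataclass
class EpochArray:
    """Epoched multichannel time series for a cohort.

    data : float array, (n_participants, n_trials, n_channels, n_samples)
        Trials are aligned with the row order of the cohort's trial table
        within each participant.
    """

    data: np.ndarray
    participants: np.ndarray
    channels: list[str]
    sfreq: float
    times_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.participants = np.asarray(self.participants)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("EpochArray.data must be 4-D "
                             "(participants, trials, channels, samples)")
        n_p, _, n_c, n_s = self.data.shape
        if n_p != len(self.participants):
            raise ValueError("participant axis does not match participant ids")
        if n_c != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if n_s != len(self.times_ms):
            raise ValueError("sample axis does not match time axis")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}; "
                           f"available: {self.channels}") from None

    def get_participant(self, pid) -> np.ndarray:
        """(n_trials, n_channels, n_samples) view for one participant."""
        idx = np.flatnonzero(self.participants == pid)
        if idx.size != 1:
            raise KeyError(f"participant {pid!r} not found")
        return self.data[idx[0]]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("times_ms", data=self.times_ms)
            f.create_dataset("participants", data=self.participants)
            f.attrs["sfreq"] = self.sfreq
            f.attrs["channels"] = [str(c) for c in self.channels]

    @classmethod
    def load(cls, path) -> "EpochArray":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                participants=f["participants"][()],
                channels=[str(c) for c in f.attrs["channels"]],
                sfreq=float(f.attrs["sfreq"]),
                times_ms=f["times_ms"][()],
            )


def hemisphere(label: str) -> str:
    """Hemisphere of a 10-20 channel label: odd digit → left, even → right.

    Raises for midline or digit-free labels, which carry no laterality.
    """
    digits = "".join(ch for ch in label if ch.isdigit())
    if not digits:
        raise ValueError(f"channel {label!r} has no laterality (midline?)")
    return "left" if int(digits) % 2 == 1 else "right"
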