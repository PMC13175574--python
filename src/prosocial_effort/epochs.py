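"""Epoched-EEG container and its on-disk format.

An :class:`EpochSet` holds feedback-locked epochs as a dense
``channels x times x trials`` float array in microvolts, together with
channel labels, the sampling rate, the epoch time axis in milliseconds,
and the trial table the third axis is aligned to. The default geometry is
the study's: 512 Hz, -200 to 1000 ms around feedback onset.

On disk an epoch set is a pair of files: ``<prefix>.bin`` (little-endian
float32, channel-major C order) and ``<prefix>.json`` (channel labels,
rate, time axis, trial count), so that everything stays plain text or
raw numbers with a self-describing header.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "default_time_axis", "DEFAULT_SFREQ"]

DEFAULT_SFREQ = 512.0
_EPOCH_TMIN_S = -0.2
_EPOCH_TMAX_S = 1.0


def default_time_axis(sfreq: float = DEFAULT_SFREQ) -> np.ndarray:
    """Epoch time axis in ms: samples on the sampling grid covering
    -200..1000 ms, inclusive of 0."""
    first = int(np.round(_EPOCH_TMIN_S * sfreq))
    last = int(np.round(_EPOCH_TMAX_S * sfreq))
    return np.arange(first, last + 1) / sfreq * 1000.0


@dataclass
class EpochSet:
    """Feedback-locked epochs for one participant.

    data : ndarray, shape (n_channels, n_times, n_trials), microvolts
    trial_table : DataFrame with one row per trial, aligned to axis 2.
    """

    data: np.ndarray
    channel_labels: list[str]
    trial_table: pd.DataFrame
    sfreq: float = DEFAULT_SFREQ
    times_ms: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.times_ms is None:
            self.times_ms = default_time_axis(self.sfreq)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be channels x times x trials")
        n_ch, n_t, n_trials = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        if n_t != len(self.times_ms):
            raise ValueError("time axis does not match times_ms")
        if n_trials != len(self.trial_table):
            raise ValueError("trials axis does not match trial_table")
        dt = np.diff(self.times_ms)
        if dt.size and not np.allclose(dt, 1000.0 / self.sfreq):
            raise ValueError("times_ms spacing inconsistent with sfreq")

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def channel_index(self, labels) -> np.ndarray:
        """Indices of ``labels`` in the channel axis (KeyError if absent)."""
        lookup = {c: i for i, c in enumerate(self.channel_labels)}
        missing = [c for c in labels if c not in lookup]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([lookup[c] for c in labels], dtype=int)

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            channel_labels=list(self.channel_labels),
            trial_table=self.trial_table.copy(),
            sfreq=self.sfreq,
            times_ms=self.times_ms.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def save(self, prefix) -> None:
        """Write ``<prefix>.bin`` + ``<prefix>.json`` (trial table separate)."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        self.data.astype("<f4").tofile(prefix.with_suffix(".bin"))
        header = {
            "channel_labels": list(self.channel_labels),
            "sfreq": self.sfreq,
            "times_ms": [float(t) for t in self.times_ms],
            "n_trials": int(self.n_trials),
            "dtype": "<f4",
            "order": "channel_major",
        }
        prefix.with_suffix(".json").write_text(json.dumps(header, indent=1))

    @classmethod
    def load(cls, prefix, trial_table: pd.DataFrame) -> "EpochSet":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        times = np.asarray(header["times_ms"], dtype=float)
        shape = (len(header["channel_labels"]), len(times), header["n_trials"])
        data = np.fromfile(prefix.with_suffix(".bin"), dtype=header["dtype"])
        return cls(
            data=data.reshape(shape).astype(float),
            channel_labels=list(header["channel_labels"]),
            trial_table=trial_table,
            sfreq=float(header["sfreq"]),
            times_ms=times,
        )
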