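"""Epoched EEG container.

Epochs are stored as a dense ``(n_trials, n_channels, n_samples)`` array in
microvolt, time-locked to stimulus onset, with per-trial condition labels
(HRIS = high restricted-interest stimuli, LRIS = low), per-trial rejection
flags and per-channel bad flags.  Every preprocessing stage returns a new
EpochSet; data arrays are never mutated in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EpochSet", "CONDITIONS", "save_epochs", "load_epochs"]

CONDITIONS = ("HRIS", "LRIS")


class InsufficientDataError(RuntimeError):
    """Raised when a QC stage leaves too little data to continue."""


@dataclass
class EpochSet:
    subject_id: str
    data: np.ndarray  # (n_trials, n_channels, n_samples), μV
    sample_rate: float  # Hz
    tmin_ms: float  # time of the first sample relative to stimulus onset
    channels: tuple[str, ...]
    conditions: np.ndarray  # str label per trial
    bad_channels: tuple[str, ...] = ()
    rejected: np.ndarray = field(default=None)  # bool per trial

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (trials, channels, samples)")
        self.channels = tuple(self.channels)
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.conditions.shape[0] != self.n_trials:
            raise ValueError("one condition label per trial required")
        if self.rejected is None:
            self.rejected = np.zeros(self.n_trials, dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)

    # ---- basic geometry ------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.tmin_ms + 1000.0 * np.arange(self.n_samples) / self.sample_rate

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [start_ms, stop_ms)."""
        t = self.times_ms
        mask = (t >= start_ms) & (t < stop_ms)
        if not mask.any():
            raise ValueError(f"window [{start_ms}, {stop_ms}) ms is empty for this epoch grid")
        return mask

    def with_data(self, data: np.ndarray) -> "EpochSet":
        return replace(self, data=np.asarray(data, dtype=float))

    def retained(self, condition: str | None = None) -> "EpochSet":
        """Subset of non-rejected trials, optionally of a single condition."""
        keep = ~self.rejected
        if condition is not None:
            keep &= self.conditions == condition
        return replace(
            self,
            data=self.data[keep],
            conditions=self.conditions[keep],
            rejected=np.zeros(int(keep.sum()), dtype=bool),
        )


def save_epochs(epochs: EpochSet, path) -> None:
    """Write one subject's epochs as a compressed .npz container.

    Layout: trial-major float64 ``data`` plus metadata arrays.  This is the
    documented interchange format between pipeline stages; all statistical
    outputs are plain text.
    """
    np.savez_compressed(
        Path(path),
        data=epochs.data,
        sample_rate=np.array([epochs.sample_rate]),
        tmin_ms=np.array([epochs.tmin_ms]),
        channels=np.array(epochs.channels, dtype=str),
        conditions=np.array(list(epochs.conditions), dtype=str),
        bad_channels=np.array(list(epochs.bad_channels), dtype=str),
        rejected=epochs.rejected,
        subject_id=np.array([epochs.subject_id], dtype=str),
    )


def load_epochs(path) -> EpochSet:
    with np.load(Path(path), allow_pickle=False) as z:
        return EpochSet(
            subject_id=str(z["subject_id"][0]),
            data=z["data"],
            sample_rate=float(z["sample_rate"][0]),
            tmin_ms=float(z["tmin_ms"][0]),
            channels=tuple(z["channels"]),
            conditions=np.array([str(c) for c in z["conditions"]], dtype=object),
            bad_channels=tuple(z["bad_channels"]),
            rejected=z["rejected"],
        )
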