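"""Core data containers.

The unit of file I/O is a continuous multichannel recording plus a marker
stream (:class:`ContinuousEEG`) and its per-trial labels
(:class:`LabelBlock`).  Trials are always stored continuous + markers;
epoching is an explicit operation (:func:`tribci.preprocess.segment`)
that produces an :class:`EpochSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SchemaError", "ContinuousEEG", "LabelBlock", "EpochSet"]


class SchemaError(ValueError):
    """A container violates the dataset schema or one of its invariants."""


def _as_marker_array(markers) -> np.ndarray:
    arr = np.asarray(markers, dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SchemaError("markers must be an (n, 2) array of (sample_index, event_code)")
    return arr


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG/EMG signal with event markers.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_channels)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    markers : ndarray, shape (n_markers, 2)
        Rows of ``(sample_index, event_code)``; sample indices are 0-based
        positions into ``signal``.
    channel_names : list of str
        Ordered 10-20-system labels, unique.
    channel_kinds : list of str
        ``"EEG"`` or ``"EMG"`` per channel; EMG channels are never silently
        mixed into EEG computations.
    meta : dict
        Free-form metadata (subject/session id, paradigm, phase, simulator
        ground truth, ...).
    """

    signal: np.ndarray
    fs: float
    markers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    channel_names: list[str] = field(default_factory=list)
    channel_kinds: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise SchemaError("signal must be 2-D (samples x channels)")
        if not self.fs > 0:
            raise SchemaError("fs must be positive")
        self.markers = _as_marker_array(self.markers)
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[1])]
        if not self.channel_kinds:
            self.channel_kinds = ["EEG"] * self.signal.shape[1]
        if len(self.channel_names) != self.signal.shape[1]:
            raise SchemaError("channel_names length must equal n_channels")
        if len(self.channel_kinds) != self.signal.shape[1]:
            raise SchemaError("channel_kinds length must equal n_channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise SchemaError("channel_names must be unique")
        if self.markers.size and (
            self.markers[:, 0].min() < 0 or self.markers[:, 0].max() >= self.n_samples
        ):
            raise SchemaError("marker sample indices must lie in [0, n_samples)")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def marker_samples(self) -> np.ndarray:
        return self.markers[:, 0]

    @property
    def marker_codes(self) -> np.ndarray:
        return self.markers[:, 1]

    def eeg_channel_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.channel_kinds) if k == "EEG"], dtype=int)


@dataclass
class LabelBlock:
    """Per-trial class labels in integer, one-hot-logical and name form."""

    y_dec: np.ndarray
    y_logic: np.ndarray
    y_class: list[str]

    def __post_init__(self):
        self.y_dec = np.asarray(self.y_dec, dtype=np.int64).ravel()
        self.y_logic = np.asarray(self.y_logic, dtype=bool)
        self.y_class = [str(c) for c in self.y_class]
        if self.y_logic.ndim != 2:
            raise SchemaError("y_logic must be 2-D (classes x trials)")
        n_classes, n_trials = self.y_logic.shape
        if n_classes != len(self.y_class):
            raise SchemaError("y_logic row count must equal number of class names")
        if n_trials != self.y_dec.size:
            raise SchemaError("y_logic column count must equal number of trials")
        if n_trials and not np.all(self.y_logic.sum(axis=0) == 1):
            raise SchemaError("every y_logic column must sum to exactly 1")
        # y_dec codes are 1-based class indices, consistent with argmax of y_logic
        if n_trials and not np.array_equal(self.y_dec, self.y_logic.argmax(axis=0) + 1):
            raise SchemaError("y_dec inconsistent with argmax of y_logic")

    @classmethod
    def from_y_dec(cls, y_dec: Sequence[int], y_class: Sequence[str]) -> "LabelBlock":
        y_dec = np.asarray(y_dec, dtype=np.int64).ravel()
        n_classes = len(y_class)
        logic = np.zeros((n_classes, y_dec.size), dtype=bool)
        if y_dec.size:
            if y_dec.min() < 1 or y_dec.max() > n_classes:
                raise SchemaError("y_dec codes must be 1-based class indices")
            logic[y_dec - 1, np.arange(y_dec.size)] = True
        return cls(y_dec=y_dec, y_logic=logic, y_class=list(y_class))

    def __len__(self) -> int:
        return self.y_dec.size

    @property
    def n_classes(self) -> int:
        return len(self.y_class)

    def class_names(self) -> list[str]:
        return [self.y_class[c - 1] for c in self.y_dec]

    def subset(self, idx) -> "LabelBlock":
        return LabelBlock.from_y_dec(self.y_dec[idx], self.y_class)


@dataclass
class EpochSet:
    """Stimulus-locked trials as a trials x channels x samples tensor."""

    data: np.ndarray
    time_ms: np.ndarray
    labels: LabelBlock
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64).ravel()
        if self.data.ndim != 3:
            raise SchemaError("epoch data must be 3-D (trials x channels x samples)")
        if self.time_ms.size != self.data.shape[2]:
            raise SchemaError("time axis length must equal samples per epoch")
        if self.time_ms.size > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise SchemaError("time axis must be strictly increasing")
        if len(self.labels) != self.data.shape[0]:
            raise SchemaError("label count must equal trial count")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise SchemaError("channel_names length must equal n_channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            time_ms=self.time_ms,
            labels=self.labels.subset(idx),
            fs=self.fs,
            channel_names=list(self.channel_names),
        )

    def sample_index(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(np.searchsorted(self.time_ms, t_ms - 1e-9))
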