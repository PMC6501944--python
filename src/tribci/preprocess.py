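"""Shared preprocessing: band-pass filtering, downsampling, channel
selection, epoching and baseline correction.

All three decoding pipelines run the same chain: select a paradigm-specific
channel subset, Butterworth band-pass, decimate to 100 Hz, cut
stimulus-locked epochs, and (for ERP) subtract a pre-stimulus baseline.
Offline filtering is zero-phase (forward-backward); the online sliding
window uses a causal single pass, matching how a real-time buffer is
processed as it arrives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import ContinuousEEG, EpochSet, LabelBlock, SchemaError
from .montage import MontagePreset

__all__ = [
    "FilterSpec",
    "bandpass",
    "bandpass_epochs",
    "downsample",
    "segment",
    "baseline_correct",
    "select_channels",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass specification.

    ``mode="offline"`` applies the filter forward-backward (zero phase,
    squared magnitude response); ``mode="online"`` applies a single causal
    pass, as in the real-time loop.
    """

    low_hz: float
    high_hz: float
    order: int = 5
    mode: str = "offline"

    def __post_init__(self):
        if not (self.low_hz > 0 and self.high_hz > self.low_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.mode not in ("offline", "online"):
            raise ValueError("mode must be 'offline' or 'online'")

    def design(self, fs: float):
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high band edge {self.high_hz} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        return sps.butter(self.order, [self.low_hz, self.high_hz], btype="bandpass",
                          fs=fs, output="sos")


def _apply_sos(sos, data: np.ndarray, mode: str, axis: int) -> np.ndarray:
    if mode == "offline":
        return sps.sosfiltfilt(sos, data, axis=axis)
    return sps.sosfilt(sos, data, axis=axis)


def bandpass(rec: ContinuousEEG, spec: FilterSpec) -> ContinuousEEG:
    """Band-pass filter a continuous recording (all channels, same shape)."""
    sos = spec.design(rec.fs)
    out = _apply_sos(sos, rec.signal, spec.mode, axis=0)
    return ContinuousEEG(
        signal=out, fs=rec.fs, markers=rec.markers.copy(),
        channel_names=list(rec.channel_names), channel_kinds=list(rec.channel_kinds),
        meta=dict(rec.meta),
    )


def bandpass_epochs(ep: EpochSet, spec: FilterSpec) -> EpochSet:
    """Band-pass filter already-cut epochs along the time axis."""
    sos = spec.design(ep.fs)
    out = _apply_sos(sos, ep.data, spec.mode, axis=2)
    return EpochSet(out, ep.time_ms, ep.labels, ep.fs, list(ep.channel_names))


def downsample(rec: ContinuousEEG, target_fs: float) -> ContinuousEEG:
    """Decimate to ``target_fs`` after anti-alias low-pass filtering.

    The decimation ratio must be an integer; markers are remapped by the
    same ratio with floor.  The anti-alias filter is an order-8 zero-phase
    Butterworth low-pass at 0.8x the new Nyquist frequency.
    """
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"fs {rec.fs} not an integer multiple of target {target_fs}")
    k = int(round(ratio))
    if k == 1:
        return rec
    sos = sps.butter(8, 0.8 * (target_fs / 2), btype="lowpass", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=0)
    out = filtered[::k]
    markers = rec.markers.copy()
    if markers.size:
        markers[:, 0] = markers[:, 0] // k
    return ContinuousEEG(
        signal=out, fs=target_fs, markers=markers,
        channel_names=list(rec.channel_names), channel_kinds=list(rec.channel_kinds),
        meta=dict(rec.meta),
    )


def segment(rec: ContinuousEEG, labels: LabelBlock | None, ival_ms) -> EpochSet:
    """Cut stimulus-locked epochs over the half-open interval [start, end) ms.

    The epoch length in samples is ``round((end - start) / 1000 * fs)``, so
    at 100 Hz the canonical windows give exactly 100 ([-200, 800) ms, ERP),
    250 ([1000, 3500) ms, MI) and 400 ([0, 4000) ms, SSVEP) samples.
    """
    start_ms, end_ms = float(ival_ms[0]), float(ival_ms[1])
    if end_ms <= start_ms:
        raise ValueError("epoch interval must have end > start")
    n_samp = int(round((end_ms - start_ms) / 1000.0 * rec.fs))
    offset = int(round(start_ms / 1000.0 * rec.fs))
    onsets = rec.marker_samples
    starts = onsets + offset
    bad = np.flatnonzero((starts < 0) | (starts + n_samp > rec.n_samples))
    if bad.size:
        raise ValueError(
            f"epoch interval [{start_ms}, {end_ms}) ms exceeds recording bounds for "
            f"{bad.size} trial(s) at marker indices {bad.tolist()[:10]}"
        )
    data = np.empty((onsets.size, rec.n_channels, n_samp))
    for i, s in enumerate(starts):
        data[i] = rec.signal[s:s + n_samp].T
    time_ms = start_ms + np.arange(n_samp) / rec.fs * 1000.0
    if labels is None or len(labels) == 0:
        labels = LabelBlock.from_y_dec(
            np.ones(onsets.size, dtype=int), ["unlabeled"]
        ) if onsets.size else LabelBlock.from_y_dec([], [])
    if len(labels) != onsets.size:
        raise SchemaError("label count must equal marker count")
    return EpochSet(data, time_ms, labels, rec.fs, list(rec.channel_names))


def baseline_correct(ep: EpochSet, ref_ms) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the reference window."""
    lo, hi = float(ref_ms[0]), float(ref_ms[1])
    mask = (ep.time_ms >= lo) & (ep.time_ms < hi)
    if not mask.any():
        raise ValueError(
            f"reference window [{lo}, {hi}) ms lies outside the epoch time axis "
            f"[{ep.time_ms[0]}, {ep.time_ms[-1]}] ms"
        )
    base = ep.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(ep.data - base, ep.time_ms, ep.labels, ep.fs, list(ep.channel_names))


def select_channels(obj, preset):
    """Reorder/restrict channels of a recording or epoch set to a preset.

    ``preset`` may be a :class:`MontagePreset` or a plain sequence of
    labels; output channel order follows the preset order.
    """
    wanted = list(preset.channels) if isinstance(preset, MontagePreset) else list(preset)
    have = {c: i for i, c in enumerate(obj.channel_names)}
    missing = [c for c in wanted if c not in have]
    if missing:
        raise KeyError(f"channel(s) not present in recording: {missing}")
    idx = [have[c] for c in wanted]
    if isinstance(obj, ContinuousEEG):
        return ContinuousEEG(
            signal=obj.signal[:, idx], fs=obj.fs, markers=obj.markers.copy(),
            channel_names=wanted, channel_kinds=[obj.channel_kinds[i] for i in idx],
            meta=dict(obj.meta),
        )
    if isinstance(obj, EpochSet):
        return EpochSet(obj.data[:, idx, :], obj.time_ms, obj.labels, obj.fs, wanted)
    raise TypeError(f"cannot select channels on {type(obj).__name__}")
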