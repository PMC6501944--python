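"""Neurophysiological summaries: ERD/ERS band-power time courses,
signed r^2 discriminability maps, Welch power spectral density, and
resting-state alpha band power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import ContinuousEEG, EpochSet
from .preprocess import FilterSpec, bandpass_epochs

__all__ = ["BandPowerSeries", "erd_ers", "signed_r2", "psd", "alpha_power"]


@dataclass
class BandPowerSeries:
    """Relative band-power change over time, per channel.

    ``values`` has shape (channels, samples) in percent change relative to
    the reference window (event-related desynchronization is negative,
    synchronization positive, floor -100%).
    """

    values: np.ndarray
    time_ms: np.ndarray
    band_hz: tuple[float, float]
    ref_ival_ms: tuple[float, float]
    channel_names: list[str]
    class_name: str
    kind: str = "ERDERS"


def _moving_average(x: np.ndarray, n: int, axis: int = -1) -> np.ndarray:
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), axis, x)


def erd_ers(
    ep: EpochSet,
    band_hz: tuple[float, float] = (8.0, 12.0),
    ref_ms: tuple[float, float] = (-500.0, 0.0),
    smooth_ms: float = 100.0,
    method: str = "power",
) -> dict[str, BandPowerSeries]:
    """Event-related (de)synchronization per class, in percent.

    Chain: band-pass (zero-phase) -> squared amplitude -> trial average ->
    moving-average smoothing -> ``100 * (P(t) - P_ref) / P_ref`` where
    ``P_ref`` is the mean smoothed power over the reference window.  With
    ``method="envelope"`` the squared analytic (Hilbert) envelope replaces
    the squared band-passed amplitude.
    """
    filt = bandpass_epochs(ep, FilterSpec(band_hz[0], band_hz[1], order=5, mode="offline"))
    if method == "power":
        power = filt.data ** 2
    elif method == "envelope":
        power = np.abs(sps.hilbert(filt.data, axis=2)) ** 2
    else:
        raise ValueError("method must be 'power' or 'envelope'")
    ref_mask = (ep.time_ms >= ref_ms[0]) & (ep.time_ms < ref_ms[1])
    if not ref_mask.any():
        raise ValueError("reference window outside epoch time axis")
    n_smooth = max(1, int(round(smooth_ms / 1000.0 * ep.fs)))
    out = {}
    for code, name in enumerate(ep.labels.y_class, start=1):
        idx = np.flatnonzero(ep.labels.y_dec == code)
        avg = power[idx].mean(axis=0)  # channels x samples
        smoothed = _moving_average(avg, n_smooth, axis=1)
        p_ref = smoothed[:, ref_mask].mean(axis=1, keepdims=True)
        if np.any(p_ref <= 0):
            raise ValueError("zero reference power; cannot normalize ERD/ERS")
        values = 100.0 * (smoothed - p_ref) / p_ref
        out[name] = BandPowerSeries(
            values=values, time_ms=ep.time_ms.copy(), band_hz=tuple(band_hz),
            ref_ival_ms=tuple(ref_ms), channel_names=list(ep.channel_names),
            class_name=name,
        )
    return out


def signed_r2(ep: EpochSet) -> np.ndarray:
    """Signed r^2 (point-biserial) discriminability, channels x samples.

    For each channel and time point, the squared Pearson correlation
    between amplitude and the binary class label, carrying the sign of the
    correlation.  Antisymmetric under label swap.
    """
    if ep.labels.n_classes != 2:
        raise ValueError("signed r^2 requires exactly two classes")
    y = (ep.labels.y_dec == 2).astype(float)  # 0 / 1
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    x = ep.data  # trials x channels x samples
    n = x.shape[0]
    yc = y - y.mean()
    xc = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("t,tcs->cs", yc, xc) / n
    sx = xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / (sx * sy)
    r = np.nan_to_num(r)
    return np.sign(r) * r ** 2


def psd(
    obj: EpochSet | ContinuousEEG,
    range_hz: tuple[float, float] = (1.0, 25.0),
    window_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density per channel, restricted to a range.

    Uses Hann windows of ``window_s`` seconds with 50% overlap; epochs are
    averaged over trials.  Returns ``(freqs, power)`` with power of shape
    (channels, n_freqs).  A segment shorter than one window falls back to a
    single full-length window with a warning.
    """
    if isinstance(obj, EpochSet):
        fs = obj.fs
        nper = int(round(window_s * fs))
        if obj.n_samples < nper:
            warnings.warn("epoch shorter than the Welch window; using a single window")
            nper = obj.n_samples
        f, p = sps.welch(obj.data, fs=fs, window="hann", nperseg=nper, axis=2)
        power = p.mean(axis=0)  # average trials -> channels x freqs
    elif isinstance(obj, ContinuousEEG):
        fs = obj.fs
        nper = int(round(window_s * fs))
        if obj.n_samples < nper:
            warnings.warn("segment shorter than the Welch window; using a single window")
            nper = obj.n_samples
        f, p = sps.welch(obj.signal, fs=fs, window="hann", nperseg=nper, axis=0)
        power = p.T  # channels x freqs
    else:
        raise TypeError("psd expects an EpochSet or ContinuousEEG")
    mask = (f >= range_hz[0]) & (f <= range_hz[1])
    return f[mask], power[:, mask]


def alpha_power(rec: ContinuousEEG, band_hz: tuple[float, float] = (8.0, 12.0)) -> np.ndarray:
    """Resting-state alpha band power in dB per channel.

    ``10 * log10`` of the mean Welch PSD inside the band.  Doubling the
    signal amplitude raises the value by ~6.02 dB.
    """
    if rec.duration_s < 1.0:
        raise ValueError("resting segment must be at least 1 s")
    f, p = psd(rec, range_hz=band_hz)
    return 10.0 * np.log10(p.mean(axis=1))
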