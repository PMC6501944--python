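"""SSVEP frequency recognition by canonical correlation analysis.

For each stimulation frequency ``f_i`` (12, 8.57, 6.67 and 5.45 Hz) a
reference matrix of sine/cosine rows at the fundamental and second
harmonic is built:

    Y_i = [sin(2 pi f_i t); cos(2 pi f_i t);
           sin(2 pi 2 f_i t); cos(2 pi 2 f_i t)],   t = 1/S ... T/S.

A trial is assigned the frequency whose reference attains the largest
canonical correlation with the multichannel epoch.  CCA needs no
calibration data, so the whole recording is used for validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .containers import EpochSet

__all__ = [
    "SSVEP_FREQS",
    "CCAReference",
    "build_reference",
    "cca_max_correlation",
    "classify_ssvep",
]

logger = logging.getLogger(__name__)

#: Stimulation frequencies in the paradigm's index order (f1..f4).
SSVEP_FREQS = (12.0, 8.57, 6.67, 5.45)


@dataclass(frozen=True)
class CCAReference:
    """Per-frequency 4 x T sin/cos reference matrices (second harmonics)."""

    freqs: tuple[float, ...]
    T: int
    S: float
    matrices: tuple[np.ndarray, ...]

    @property
    def n_classes(self) -> int:
        return len(self.freqs)


def build_reference(freqs=SSVEP_FREQS, T: int = 400, S: float = 100.0) -> CCAReference:
    """Build harmonic reference signals; time starts at 1/S."""
    freqs = tuple(float(f) for f in freqs)
    for f in freqs:
        if 2 * f >= S / 2:
            raise ValueError(f"second harmonic of {f} Hz exceeds Nyquist at fs={S}")
    t = np.arange(1, T + 1) / S
    mats = []
    for f in freqs:
        mats.append(np.vstack([
            np.sin(2 * np.pi * f * t),
            np.cos(2 * np.pi * f * t),
            np.sin(2 * np.pi * 2 * f * t),
            np.cos(2 * np.pi * 2 * f * t),
        ]))
    return CCAReference(freqs=freqs, T=T, S=float(S), matrices=tuple(mats))


def _orthonormal_rowspace(A: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Orthonormal basis (columns) of the row space of the centered matrix A."""
    Ac = A - A.mean(axis=1, keepdims=True)
    U, s, _ = scipy.linalg.svd(Ac.T, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((A.shape[1], 0))
    rank = int(np.sum(s > rcond * s[0]))
    return U[:, :rank]


def cca_max_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Largest canonical correlation between rows of X and rows of Y.

    Both blocks are mean-centered along time.  The computation is the
    SVD of the product of orthonormal bases of the two row spaces (a
    QR/SVD formulation; no explicit covariance inversion), numerically
    stable for rank-deficient blocks.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must have the same number of samples")
    Qx = _orthonormal_rowspace(X)
    Qy = _orthonormal_rowspace(Y)
    if Qx.shape[1] == 0 or Qy.shape[1] == 0:
        warnings.warn("zero-variance block in CCA; returning 0")
        return 0.0
    s = scipy.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return float(np.clip(s[0], 0.0, 1.0))


def classify_ssvep(ep: EpochSet, ref: CCAReference) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial frequency classification.

    Returns ``(y_pred, rho)`` where ``y_pred`` holds 1-based class codes in
    the reference's frequency order and ``rho`` is the trials x classes
    canonical-correlation matrix.  Ties break toward the lower frequency
    index (earlier in the reference order).
    """
    if ep.n_samples != ref.T:
        raise ValueError(f"epoch length {ep.n_samples} != reference length {ref.T}")
    n = ep.n_trials
    rho = np.zeros((n, ref.n_classes))
    for i in range(n):
        for j, Y in enumerate(ref.matrices):
            rho[i, j] = cca_max_correlation(ep.data[i], Y)
    # argmax returns the first maximum, i.e. the lower frequency index on ties
    best = rho.argmax(axis=1)
    ties = np.sum(np.isclose(rho, rho.max(axis=1, keepdims=True), rtol=0, atol=1e-12), axis=1)
    if np.any(ties > 1):
        logger.info("%d trial(s) had tied correlations; lower index chosen", int(np.sum(ties > 1)))
    return best + 1, rho
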