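"""ERP speller decoding: discriminant-interval mean-amplitude features,
target/non-target LDA, sequence accumulation to characters, and the
information transfer rate.

A 6x6 symbol grid is spelled by flashing rows and columns; one *sequence*
is a full pass of 12 flashes, and up to five sequences are accumulated per
character.  Target flashes elicit a P300 deflection; features are mean
amplitudes over ten subject-dependent discriminant time intervals within
[-200, 800) ms epochs on 32 channels (320 features).  A shrinkage-LDA
score per flash is accumulated per cell; the cell with the highest mean
score is the predicted symbol.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet
from .metrics import signed_r2

__all__ = [
    "SpellerLayout",
    "IntervalFeatureSpec",
    "ITRParams",
    "select_discriminant_intervals",
    "ma_features",
    "decode_speller",
    "accuracy_by_sequence",
    "compute_itr",
    "itr_bits_per_min",
    "selections_per_minute",
]

logger = logging.getLogger(__name__)

SYMBOLS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ123456789_"

TARGET_CODE, NONTARGET_CODE = 1, 2
ERP_CLASS_NAMES = ["target", "nontarget"]


@dataclass(frozen=True)
class SpellerLayout:
    """6x6 row/column speller layout.

    Cells are indexed row-major 0..35.  Flash group ids 0-5 are rows,
    6-11 are columns; each sequence of 12 flashes covers every cell exactly
    twice (once via its row, once via its column).
    """

    symbols: str = SYMBOLS
    n_rows: int = 6
    n_cols: int = 6
    sequence_len: int = 12

    def __post_init__(self):
        if len(self.symbols) != self.n_rows * self.n_cols:
            raise ValueError("symbol count must fill the grid")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("symbols must be unique")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def group_cells(self, group: int) -> np.ndarray:
        """Cell indices highlighted by flash group ``group`` (0-11)."""
        if group < self.n_rows:
            return np.arange(group * self.n_cols, (group + 1) * self.n_cols)
        col = group - self.n_rows
        if col >= self.n_cols:
            raise ValueError(f"flash group {group} out of range")
        return np.arange(col, self.n_cells, self.n_cols)

    def cell_of(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def groups_of(self, symbol: str) -> tuple[int, int]:
        """(row group, column group) containing a symbol."""
        cell = self.cell_of(symbol)
        return cell // self.n_cols, self.n_rows + cell % self.n_cols


@dataclass(frozen=True)
class IntervalFeatureSpec:
    """Ten disjoint discriminant time windows and the channel set."""

    intervals_ms: tuple[tuple[float, float], ...]
    channels: tuple[str, ...]

    def __post_init__(self):
        ivals = sorted(self.intervals_ms)
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if b0 < a1:
                raise ValueError("discriminant intervals must be disjoint")
        for a0, a1 in ivals:
            if a1 <= a0:
                raise ValueError("interval end must exceed start")

    @property
    def n_features(self) -> int:
        return len(self.intervals_ms) * len(self.channels)


@dataclass(frozen=True)
class ITRParams:
    """Inputs of the information-transfer-rate formula."""

    N: int = 36
    P: float = 1.0
    M: float = 1.0  # selections (commands) per minute

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must be in [0, 1]")
        if not self.M > 0:
            raise ValueError("M must be positive")


def select_discriminant_intervals(
    ep: EpochSet,
    n: int = 10,
    window_ms: float = 50.0,
    step_ms: float = 10.0,
    search_ms: tuple[float, float] = (0.0, 800.0),
) -> IntervalFeatureSpec:
    """Choose ``n`` disjoint windows with maximal class discriminability.

    A ``window_ms`` window slides in ``step_ms`` steps over ``search_ms``;
    each position is scored by the maximum |signed r^2| over channels and
    samples inside it; the top ``n`` non-overlapping positions are kept
    greedily.  Deterministic given the data.
    """
    r2 = signed_r2(ep)  # channels x samples
    score_map = np.abs(r2).max(axis=0)
    t = ep.time_ms
    starts = np.arange(search_ms[0], search_ms[1] - window_ms + 1e-9, step_ms)
    cand = []
    for s in starts:
        mask = (t >= s) & (t < s + window_ms)
        if mask.any():
            cand.append((float(score_map[mask].max()), float(s), float(s + window_ms)))
    cand.sort(key=lambda c: (-c[0], c[1]))
    chosen: list[tuple[float, float]] = []
    for _, s, e in cand:
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} feasible disjoint windows, need {n}")
    return IntervalFeatureSpec(
        intervals_ms=tuple(sorted(chosen)), channels=tuple(ep.channel_names)
    )


def ma_features(ep: EpochSet, spec: IntervalFeatureSpec) -> np.ndarray:
    """Mean amplitude per (channel, interval): trials x (n_ch * n_intervals)."""
    missing = set(spec.channels) - set(ep.channel_names)
    if missing:
        raise KeyError(f"epoch set lacks channels {sorted(missing)}")
    idx = [ep.channel_names.index(c) for c in spec.channels]
    feats = []
    for lo, hi in spec.intervals_ms:
        mask = (ep.time_ms >= lo) & (ep.time_ms < hi)
        if not mask.any():
            raise ValueError(f"interval [{lo}, {hi}) ms outside the epoch time axis")
        feats.append(ep.data[:, idx][:, :, mask].mean(axis=2))
    # trials x channels x intervals, flattened channel-major
    return np.stack(feats, axis=2).reshape(ep.n_trials, -1)


def decode_speller(
    flash_scores: np.ndarray,
    flash_groups: np.ndarray,
    layout: SpellerLayout,
    n_seq: int = 5,
) -> int:
    """Predict the target cell from per-flash classifier scores.

    Uses only the first ``n_seq`` sequences (``n_seq * 12`` flashes); for
    each cell, the mean score of all flashes whose group contains the cell
    is accumulated, and the argmax cell wins.  Ties break toward the lowest
    (row, column) index.
    """
    flash_scores = np.asarray(flash_scores, dtype=float).ravel()
    flash_groups = np.asarray(flash_groups).ravel()
    need = n_seq * layout.sequence_len
    if flash_scores.size < need or flash_groups.size < need:
        raise ValueError(
            f"need {need} flash scores/groups for {n_seq} sequences, "
            f"got {flash_scores.size}/{flash_groups.size}"
        )
    scores = flash_scores[:need]
    groups = flash_groups[:need]
    total = np.zeros(layout.n_cells)
    count = np.zeros(layout.n_cells)
    for s, g in zip(scores, groups):
        cells = layout.group_cells(int(g))
        total[cells] += s
        count[cells] += 1
    if np.any(count == 0):
        raise ValueError(
            f"flash record incomplete: cells {np.flatnonzero(count == 0).tolist()} never flashed"
        )
    mean = total / count
    best = int(np.argmax(mean))
    ties = np.flatnonzero(np.isclose(mean, mean[best], rtol=0, atol=1e-12))
    if ties.size > 1:
        logger.info("speller tie between cells %s; choosing lowest index", ties.tolist())
        best = int(ties.min())
    return best


def accuracy_by_sequence(
    truth: str,
    flash_scores: np.ndarray,
    flash_groups: np.ndarray,
    layout: SpellerLayout,
    max_seq: int = 5,
) -> np.ndarray:
    """Speller accuracy accumulating one to ``max_seq`` sequences.

    ``flash_scores``/``flash_groups`` have shape (n_chars, max_seq * 12).
    Returns a length-``max_seq`` accuracy vector.
    """
    flash_scores = np.asarray(flash_scores, dtype=float)
    flash_groups = np.asarray(flash_groups)
    n_chars = len(truth)
    if flash_scores.shape[0] != n_chars:
        raise ValueError("score rows must equal number of characters")
    acc = np.zeros(max_seq)
    target_cells = np.array([layout.cell_of(c) for c in truth])
    for n_seq in range(1, max_seq + 1):
        pred = np.array([
            decode_speller(flash_scores[i], flash_groups[i], layout, n_seq)
            for i in range(n_chars)
        ])
        acc[n_seq - 1] = np.mean(pred == target_cells)
    return acc


def _xlog2x(x: float) -> float:
    return 0.0 if x <= 0.0 else x * math.log2(x)


def compute_itr(params: ITRParams) -> float:
    """Information transfer rate in bits/min.

    ``ITR = M * (log2 N + P log2 P + (1 - P) log2((1 - P)/(N - 1)))``
    with the ``x log2 x -> 0`` limit at P in {0, 1}.
    """
    N, P, M = params.N, params.P, params.M
    bits = math.log2(N) + _xlog2x(P) + _xlog2x(1 - P) - (1 - P) * math.log2(N - 1)
    return M * bits


def selections_per_minute(
    n_seq: int = 5,
    soa_s: float = 0.215,
    epoch_tail_s: float = 0.8,
    layout: SpellerLayout = SpellerLayout(),
) -> float:
    """Selections (spelled characters) per minute from stimulation timing.

    One selection takes ``n_seq * 12`` flashes at the stimulus-onset
    asynchrony plus the post-stimulus epoch of the final flash; with five
    sequences that is 60 x 0.215 s + 0.8 s = 13.7 s.  Gaze-shifting pauses
    between characters are excluded.
    """
    t = n_seq * layout.sequence_len * soa_s + epoch_tail_s
    return 60.0 / t


def itr_bits_per_min(p: float, n_seq: int = 5, n_symbols: int = 36) -> float:
    """Convenience: ITR for the 6x6 speller at accuracy ``p``."""
    return compute_itr(ITRParams(N=n_symbols, P=p, M=selections_per_minute(n_seq)))
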