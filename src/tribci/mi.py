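"""Binary motor-imagery decoding.

The canonical pipeline band-passes sensorimotor channels at 8-30 Hz, cuts
[1000, 3500) ms epochs, learns common spatial patterns (CSP) maximizing the
variance ratio between left- and right-hand imagery, takes log-variance
features of the top/bottom spatially filtered components, and classifies
with linear discriminant analysis (LDA).  Three variants search for
class-discriminative spectral structure: CSSP (temporal delay embedding),
FBCSP (filter bank + mutual-information feature selection) and BSSFO (a
particle-based stochastic search over band edges).

The CSP eigenproblem solved here is

    Sigma_1 w = lambda (Sigma_1 + Sigma_2) w

with per-class covariances averaged over trace-normalized trial
covariances.  Eigenvalues lie in [0, 1]; filters with the largest and
smallest eigenvalues concentrate variance in one class each.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy import signal as sps
from sklearn.covariance import ledoit_wolf
from sklearn.model_selection import StratifiedKFold

from .containers import ContinuousEEG, EpochSet
from .preprocess import FilterSpec, bandpass_epochs

__all__ = [
    "SpatialFilterBank",
    "LinearClassifier",
    "MIMethodConfig",
    "fit_csp",
    "logvar_features",
    "fit_lda",
    "fit_cssp",
    "delay_embed",
    "fit_fbcsp",
    "fit_bssfo",
    "crossvalidate_mi",
    "online_decode_mi",
    "CSPModel",
    "CSSPModel",
    "FBCSPModel",
    "BSSFOModel",
    "make_model",
    "mutual_information_binned",
]

logger = logging.getLogger(__name__)


@dataclass
class SpatialFilterBank:
    """CSP projection matrix with eigenvalues and retained filter indices.

    ``W`` holds one spatial filter per column, sorted by descending
    eigenvalue; ``selected`` indexes the top-``m`` and bottom-``m`` columns.
    Filters are scaled so that ``w^T (Sigma_1 + Sigma_2) w == 1``.
    """

    W: np.ndarray
    eigvals: np.ndarray
    selected: np.ndarray

    @property
    def n_selected(self) -> int:
        return self.selected.size

    def project(self, data: np.ndarray) -> np.ndarray:
        """Apply the selected filters: (trials, ch, samp) -> (trials, 2m, samp)."""
        return np.einsum("tcs,cf->tfs", data, self.W[:, self.selected])


@dataclass
class LinearClassifier:
    """LDA weight vector and bias with optional covariance shrinkage.

    The decision value is ``x @ w + b``; negative values vote for
    ``class_map[0]``, positive for ``class_map[1]``.  The bias places the
    midpoint of the two class means on the decision boundary.
    """

    w: np.ndarray
    b: float
    shrinkage: float
    class_map: tuple[int, int]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        v = self.decision_values(X)
        return np.where(v > 0, self.class_map[1], self.class_map[0])


@dataclass
class MIMethodConfig:
    """Hyperparameters for one MI decoding method."""

    method: str = "csp"  # csp | cssp | fbcsp | bssfo
    n_pairs: int = 2
    band_hz: tuple[float, float] = (8.0, 30.0)
    ival_ms: tuple[float, float] = (1000.0, 3500.0)
    shrinkage: float | str = 0.0
    cssp_delays: tuple[int, ...] = tuple(range(1, 11))
    fbcsp_bands: tuple[tuple[float, float], ...] = tuple(
        (lo, lo + 4.0) for lo in np.arange(4.0, 40.0, 4.0)
    )
    fbcsp_k: int = 4
    bssfo_particles: int = 30
    bssfo_iterations: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


# ---------------------------------------------------------------------------
# CSP core


def _class_covariances(ep: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    if ep.labels.n_classes != 2:
        raise ValueError(f"CSP requires exactly 2 classes, got {ep.labels.n_classes}")
    covs = []
    for code in (1, 2):
        idx = np.flatnonzero(ep.labels.y_dec == code)
        if idx.size < 2:
            raise ValueError(f"need >= 2 trials per class, class {code} has {idx.size}")
        acc = np.zeros((ep.n_channels, ep.n_channels))
        for i in idx:
            X = ep.data[i] - ep.data[i].mean(axis=1, keepdims=True)
            C = X @ X.T
            tr = np.trace(C)
            if tr > 0:
                acc += C / tr
        covs.append(acc / idx.size)
    return covs[0], covs[1]


def fit_csp(ep: EpochSet, m: int = 2) -> SpatialFilterBank:
    """Fit common spatial patterns from a two-class epoch set.

    Solves the generalized eigenproblem of the class-1 covariance against
    the composite covariance and retains the ``m`` largest plus ``m``
    smallest eigenvalue filters.
    """
    if ep.n_channels < 2 * m:
        raise ValueError(f"need at least {2 * m} channels for m={m}")
    S1, S2 = _class_covariances(ep)
    Sc = S1 + S2
    cond = np.linalg.cond(Sc)
    if not np.isfinite(cond) or cond > 1e10:
        ridge = 1e-8 * np.trace(Sc) / Sc.shape[0]
        Sc = Sc + ridge * np.eye(Sc.shape[0])
        warnings.warn("composite covariance ill-conditioned; ridge regularization applied")
    evals, evecs = scipy.linalg.eigh(S1, Sc)  # ascending, v^T Sc v = I
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, 1.0)
    W = evecs[:, order]
    n = W.shape[1]
    selected = np.r_[np.arange(m), np.arange(n - m, n)]
    return SpatialFilterBank(W=W, eigvals=evals, selected=selected)


def logvar_features(ep: EpochSet, bank: SpatialFilterBank) -> np.ndarray:
    """Log-variance of each selected CSP component, trials x 2m."""
    Z = bank.project(ep.data)
    v = Z.var(axis=2)
    tiny = np.finfo(float).tiny
    if np.any(v <= tiny):
        warnings.warn("zero-variance CSP projection; flooring at machine epsilon")
        v = np.maximum(v, np.finfo(float).eps)
    return np.log(v)


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float | str = 0.0) -> LinearClassifier:
    """Fisher LDA: ``w ∝ Sigma_pooled^-1 (mu_2 - mu_1)``, midpoint bias.

    ``shrinkage`` is either a fixed lambda in [0, 1] blending the pooled
    covariance toward a scaled identity, or ``"auto"`` for the
    Ledoit-Wolf analytic estimate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"LDA requires exactly 2 classes, got {classes.size}")
    X1, X2 = X[y == classes[0]], X[y == classes[1]]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    Xc = np.vstack([X1 - mu1, X2 - mu2])
    n, d = Xc.shape
    S = Xc.T @ Xc / max(n - 2, 1)
    if shrinkage == "auto":
        lam = float(ledoit_wolf(Xc, assume_centered=True)[1])
    else:
        lam = float(shrinkage)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("shrinkage must be in [0, 1] or 'auto'")
    if lam > 0:
        S = (1 - lam) * S + lam * (np.trace(S) / d) * np.eye(d)
    try:
        w = scipy.linalg.solve(S, mu2 - mu1, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError, ValueError) as e:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; use shrinkage > 0 or 'auto'"
        ) from e
    b = float(-w @ (mu1 + mu2) / 2)
    return LinearClassifier(w=w, b=b, shrinkage=lam, class_map=(int(classes[0]), int(classes[1])))


# ---------------------------------------------------------------------------
# Models (fit on an EpochSet already band-passed and segmented)


@dataclass
class CSPModel:
    """CSP + log-variance + LDA, the conventional MI decoder."""

    n_pairs: int = 2
    shrinkage: float | str = 0.0
    bank: SpatialFilterBank | None = None
    lda: LinearClassifier | None = None
    sigma_train: float = 1.0

    def fit(self, ep: EpochSet) -> "CSPModel":
        self.bank = fit_csp(ep, self.n_pairs)
        F = logvar_features(ep, self.bank)
        self.lda = fit_lda(F, ep.labels.y_dec, self.shrinkage)
        v = self.lda.decision_values(F)
        self.sigma_train = float(v.std()) or 1.0
        return self

    def features(self, ep: EpochSet) -> np.ndarray:
        return logvar_features(ep, self.bank)

    def decision_values(self, ep: EpochSet) -> np.ndarray:
        return self.lda.decision_values(self.features(ep))

    def predict(self, ep: EpochSet) -> np.ndarray:
        return self.lda.predict(self.features(ep))


def delay_embed(ep: EpochSet, tau: int) -> EpochSet:
    """Concatenate a tau-delayed copy of every channel (doubling channels).

    Epochs lose ``tau`` samples at the boundary so both copies align.
    """
    if tau < 1 or tau >= ep.n_samples:
        raise ValueError(f"delay must be in [1, {ep.n_samples - 1}] samples")
    a = ep.data[:, :, tau:]
    b = ep.data[:, :, :-tau]
    data = np.concatenate([a, b], axis=1)
    names = list(ep.channel_names) + [f"{c}-d{tau}" for c in ep.channel_names]
    return EpochSet(data, ep.time_ms[tau:], ep.labels, ep.fs, names)


def _cv_accuracy(ep: EpochSet, make, folds: int, seed: int) -> float:
    """Mean stratified k-fold accuracy of a freshly constructed model."""
    y = ep.labels.y_dec
    counts = np.bincount(y)[1:]
    folds = max(2, min(folds, int(counts[counts > 0].min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    accs = []
    for tr, te in skf.split(np.zeros(len(y)), y):
        model = make().fit(ep.subset(tr))
        accs.append(float(np.mean(model.predict(ep.subset(te)) == y[te])))
    return float(np.mean(accs))


def fit_cssp(
    ep: EpochSet,
    m: int = 2,
    delay_grid: tuple[int, ...] = tuple(range(1, 11)),
    shrinkage: float | str = 0.0,
    seed: int = 0,
) -> tuple[SpatialFilterBank, int]:
    """Common spatio-spectral patterns: CSP on delay-embedded channels.

    The delay tau is chosen from ``delay_grid`` by cross-validated training
    accuracy of the embedded CSP+LDA pipeline; ties break toward the
    smallest tau.
    """
    best_tau, best_acc = None, -np.inf
    for tau in sorted(delay_grid):
        if tau >= ep.n_samples:
            raise ValueError(f"delay {tau} >= epoch length {ep.n_samples}")
        acc = _cv_accuracy(
            delay_embed(ep, tau),
            lambda: CSPModel(n_pairs=m, shrinkage=shrinkage),
            folds=3,
            seed=seed,
        )
        if acc > best_acc + 1e-12:
            best_tau, best_acc = tau, acc
    bank = fit_csp(delay_embed(ep, best_tau), m)
    return bank, best_tau


@dataclass
class CSSPModel:
    n_pairs: int = 2
    delay_grid: tuple[int, ...] = tuple(range(1, 11))
    shrinkage: float | str = 0.0
    seed: int = 0
    bank: SpatialFilterBank | None = None
    tau: int | None = None
    lda: LinearClassifier | None = None

    def fit(self, ep: EpochSet) -> "CSSPModel":
        self.bank, self.tau = fit_cssp(ep, self.n_pairs, self.delay_grid, self.shrinkage, self.seed)
        F = logvar_features(delay_embed(ep, self.tau), self.bank)
        self.lda = fit_lda(F, ep.labels.y_dec, self.shrinkage)
        return self

    def features(self, ep: EpochSet) -> np.ndarray:
        return logvar_features(delay_embed(ep, self.tau), self.bank)

    def predict(self, ep: EpochSet) -> np.ndarray:
        return self.lda.predict(self.features(ep))


def mutual_information_binned(f: np.ndarray, y: np.ndarray, bins: int = 4) -> float:
    """Mutual information (bits) between a feature and the label after
    equal-frequency discretization of the feature into ``bins`` bins."""
    f = np.asarray(f, dtype=float).ravel()
    y = np.asarray(y).ravel()
    edges = np.quantile(f, np.linspace(0, 1, bins + 1))
    d = np.clip(np.searchsorted(edges, f, side="right") - 1, 0, bins - 1)
    classes = np.unique(y)
    n = f.size
    mi = 0.0
    for bi in range(bins):
        pb = np.mean(d == bi)
        if pb == 0:
            continue
        for c in classes:
            pbc = np.mean((d == bi) & (y == c))
            pc = np.mean(y == c)
            if pbc > 0:
                mi += pbc * np.log2(pbc / (pb * pc))
    return float(mi)


@dataclass
class FBCSPModel:
    """Filter-bank CSP: per-band CSP features ranked by mutual information."""

    bands: tuple[tuple[float, float], ...] = tuple(
        (lo, lo + 4.0) for lo in np.arange(4.0, 40.0, 4.0)
    )
    n_pairs: int = 2
    k: int = 4
    shrinkage: float | str = 0.0
    banks: list = field(default_factory=list)
    selected_features: np.ndarray | None = None
    feature_mi: np.ndarray | None = None
    lda: LinearClassifier | None = None

    def _band_features(self, ep: EpochSet, fit: bool) -> np.ndarray:
        feats = []
        for i, (lo, hi) in enumerate(self.bands):
            hi = min(hi, 0.99 * ep.fs / 2)
            band_ep = bandpass_epochs(ep, FilterSpec(lo, hi, order=4, mode="offline"))
            if fit:
                self.banks.append(fit_csp(band_ep, self.n_pairs))
            feats.append(logvar_features(band_ep, self.banks[i]))
        return np.hstack(feats)

    def fit(self, ep: EpochSet) -> "FBCSPModel":
        if len(self.bands) < 2:
            raise ValueError("FBCSP needs at least 2 bands")
        if self.k > 2 * self.n_pairs * len(self.bands):
            raise ValueError("k exceeds the number of available features")
        self.banks = []
        F = self._band_features(ep, fit=True)
        y = ep.labels.y_dec
        self.feature_mi = np.array(
            [mutual_information_binned(F[:, j], y) for j in range(F.shape[1])]
        )
        self.selected_features = np.sort(np.argsort(self.feature_mi)[::-1][: self.k])
        self.lda = fit_lda(F[:, self.selected_features], y, self.shrinkage)
        return self

    def features(self, ep: EpochSet) -> np.ndarray:
        return self._band_features(ep, fit=False)[:, self.selected_features]

    def predict(self, ep: EpochSet) -> np.ndarray:
        return self.lda.predict(self.features(ep))

    def band_of_feature(self, j: int) -> tuple[float, float]:
        return self.bands[j // (2 * self.n_pairs)]


@dataclass
class BSSFOModel:
    """Stochastic spectral-band optimization via importance sampling.

    Candidate (low, high) band edges are particles, initialized uniformly
    over [4, 40] Hz, scored by cross-validated CSP+LDA accuracy, resampled
    in proportion to their score and jittered with Gaussian noise each
    iteration.  This is a deliberately simplified particle scheme that
    keeps the spirit of the Bayesian band search without its full MCMC
    machinery.
    """

    n_particles: int = 30
    n_iter: int = 10
    n_pairs: int = 2
    shrinkage: float | str = 0.0
    seed: int = 0
    jitter_hz: float = 1.0
    band: tuple[float, float] | None = None
    inner: CSPModel | None = None
    history: list = field(default_factory=list)

    def _draw_prior(self, rng, n):
        lo = rng.uniform(4.0, 36.0, n)
        width = rng.uniform(2.0, 36.0 - (lo - 4.0).clip(0), n).clip(2.0)
        hi = np.minimum(lo + width, 40.0)
        return np.column_stack([lo, hi])

    def _score(self, ep: EpochSet, band, rng) -> float:
        lo, hi = band
        hi = min(hi, 0.99 * ep.fs / 2)
        band_ep = bandpass_epochs(ep, FilterSpec(lo, hi, order=4))
        return _cv_accuracy(
            band_ep,
            lambda: CSPModel(n_pairs=self.n_pairs, shrinkage=self.shrinkage),
            folds=3,
            seed=int(rng.integers(2**31)),
        )

    def fit(self, ep: EpochSet) -> "BSSFOModel":
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        rng = np.random.default_rng(self.seed)
        particles = self._draw_prior(rng, self.n_particles)
        best_band, best_score = None, -np.inf
        for _ in range(self.n_iter):
            scores = np.array([self._score(ep, p, rng) for p in particles])
            i_best = int(np.argmax(scores))
            if scores[i_best] > best_score:
                best_score, best_band = float(scores[i_best]), tuple(particles[i_best])
            self.history.append((particles.copy(), scores))
            w = np.clip(scores - 0.45, 1e-6, None)
            w = w / w.sum()
            idx = rng.choice(self.n_particles, size=self.n_particles, p=w)
            particles = particles[idx] + rng.normal(0, self.jitter_hz, (self.n_particles, 2))
            particles[:, 0] = particles[:, 0].clip(2.0, 38.0)
            particles[:, 1] = particles[:, 1].clip(4.0, min(40.0, 0.99 * ep.fs / 2))
            bad = particles[:, 0] >= particles[:, 1] - 1.0
            if bad.any():
                logger.debug("resampling %d degenerate particles", int(bad.sum()))
                particles[bad] = self._draw_prior(rng, int(bad.sum()))
        self.band = best_band
        lo, hi = best_band
        band_ep = bandpass_epochs(ep, FilterSpec(lo, min(hi, 0.99 * ep.fs / 2), order=4))
        self.inner = CSPModel(n_pairs=self.n_pairs, shrinkage=self.shrinkage).fit(band_ep)
        return self

    def predict(self, ep: EpochSet) -> np.ndarray:
        lo, hi = self.band
        band_ep = bandpass_epochs(ep, FilterSpec(lo, min(hi, 0.99 * ep.fs / 2), order=4))
        return self.inner.predict(band_ep)


def fit_fbcsp(ep: EpochSet, bands=None, m: int = 2, k: int = 4,
              shrinkage: float | str = 0.0) -> FBCSPModel:
    kwargs = {"n_pairs": m, "k": k, "shrinkage": shrinkage}
    if bands is not None:
        kwargs["bands"] = tuple(tuple(b) for b in bands)
    return FBCSPModel(**kwargs).fit(ep)


def fit_bssfo(ep: EpochSet, n_particles: int = 30, n_iter: int = 10,
              seed: int = 0, m: int = 2, shrinkage: float | str = 0.0) -> BSSFOModel:
    return BSSFOModel(
        n_particles=n_particles, n_iter=n_iter, n_pairs=m,
        shrinkage=shrinkage, seed=seed,
    ).fit(ep)


def make_model(cfg: MIMethodConfig):
    """Construct an unfitted model for a method configuration."""
    method = cfg.method.lower()
    if method == "csp":
        return CSPModel(n_pairs=cfg.n_pairs, shrinkage=cfg.shrinkage)
    if method == "cssp":
        return CSSPModel(n_pairs=cfg.n_pairs, delay_grid=cfg.cssp_delays,
                         shrinkage=cfg.shrinkage, seed=cfg.seed)
    if method == "fbcsp":
        return FBCSPModel(bands=cfg.fbcsp_bands, n_pairs=cfg.n_pairs,
                          k=cfg.fbcsp_k, shrinkage=cfg.shrinkage)
    if method == "bssfo":
        return BSSFOModel(n_particles=cfg.bssfo_particles, n_iter=cfg.bssfo_iterations,
                          n_pairs=cfg.n_pairs, shrinkage=cfg.shrinkage, seed=cfg.seed)
    raise ValueError(f"unknown MI method {cfg.method!r}")


def crossvalidate_mi(
    ep: EpochSet,
    cfg: MIMethodConfig,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """Repeated stratified k-fold cross-validation of an MI decoder.

    All fitting (spatial filters and LDA) happens inside the training
    folds.  Returns (mean, sd, per-fold accuracies) over
    ``folds * repeats`` estimates.
    """
    y = ep.labels.y_dec
    if len(y) < folds:
        raise ValueError("fewer trials than folds")
    ss = np.random.SeedSequence(seed)
    fold_accs = []
    for rep_seed in ss.generate_state(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rep_seed % (2**31)))
        for tr, te in skf.split(np.zeros(len(y)), y):
            model = make_model(cfg).fit(ep.subset(tr))
            pred = model.predict(ep.subset(te))
            fold_accs.append(float(np.mean(pred == y[te])))
    fold_accs = np.array(fold_accs)
    return float(fold_accs.mean()), float(fold_accs.std(ddof=1)), fold_accs


def online_decode_mi(
    stream: ContinuousEEG,
    model: CSPModel,
    band_hz: tuple[float, float] = (8.0, 30.0),
    window_s: float = 1.5,
    step_s: float = 0.5,
) -> dict:
    """Simulated online decoding with a causal sliding window.

    The stream is causally band-pass filtered once, then a window of
    ``window_s`` seconds advances in ``step_s`` steps; each position yields
    one LDA decision value and a horizontal feedback coordinate in [-1, 1]
    via ``tanh(v / sigma_train)``.

    Returns a dict with ``times_s`` (window end times), ``values`` and
    ``coords`` arrays, one entry per window.
    """
    fs = stream.fs
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if stream.n_samples < wlen:
        raise ValueError("stream shorter than the decoding window")
    spec = FilterSpec(band_hz[0], band_hz[1], order=5, mode="online")
    sos = spec.design(fs)
    filtered = sps.sosfilt(sos, stream.signal, axis=0)
    n_win = (stream.n_samples - wlen) // step + 1
    values = np.empty(n_win)
    for i in range(n_win):
        seg = filtered[i * step: i * step + wlen].T[None, :, :]
        Z = model.bank.project(seg)
        v = Z.var(axis=2)
        F = np.log(np.maximum(v, np.finfo(float).eps))
        values[i] = model.lda.decision_values(F)[0]
    times = (np.arange(n_win) * step + wlen) / fs
    coords = np.tanh(values / model.sigma_train)
    return {"times_s": times, "values": values, "coords": coords}
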