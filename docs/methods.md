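# Methods

This note records the models, conventions, parameter values and numerical
choices implemented in `tribci`, and their limitations. Quantities quoted
here are either mathematical identities or behaviors verified by the test
suite on the package's own synthetic data; no empirical claims about
recorded human EEG are made.

## Data model and file format

A recording is a continuous `samples × channels` float64 array in
microvolts with a sampling rate, a marker stream of `(sample_index,
event_code)` rows, per-channel names and kinds (EEG/EMG), and free-form
metadata. Labels live in a separate block: `y_dec` (1-based integer
codes), `y_logic` (one-hot `classes × trials` boolean) and `y_class`
(names). Invariants — one-hot columns summing to 1, `y_dec` equal to the
argmax of `y_logic` plus one, markers inside the recording, unique channel
names — are enforced at construction and raise `SchemaError`.

Files are HDF5; each named struct (e.g. `EEG_MI_train`) holds the seven
canonical fields `x, t, fs, y_dec, y_logic, y_class, chan` plus auxiliary
`event_code` and `chan_kind` datasets and a `meta` attribute group.
MAT v7.3 files are HDF5 underneath, so MATLAB-written structs with this
layout are readable through the same path. Trials are always stored
continuous-plus-markers; epoching is an explicit operation.

The montage is a 62-channel 10-20/10-10 EEG layout with paradigm presets:
32 channels (ERP), 20 motor-area channels (MI), 10 occipito-parietal
channels (SSVEP). Channel coordinates used by the simulator are schematic
2-D positions parsed from the labels, not digitized electrode locations.

## Preprocessing

* Band-pass: Butterworth of order 5 (order 4 inside the filter banks),
  designed as second-order sections. Offline mode is zero-phase
  forward–backward filtering (effective magnitude response |H|²); online
  mode is a single causal pass, as in a real-time buffer.
* Downsampling: integer-ratio decimation after a zero-phase order-8
  Butterworth low-pass at 0.8× the target Nyquist; markers are remapped by
  floor division. Non-integer ratios are rejected rather than resampled.
* Epochs are half-open `[start, end)` windows with
  `n = round((end-start)/1000 · fs)` samples. At the common 100 Hz
  analysis rate the canonical windows are: ERP `[-200, 800)` ms → 100
  samples, MI `[1000, 3500)` ms → 250 samples, SSVEP `[0, 4000)` ms → 400
  samples. ERP epochs are baseline-corrected by subtracting the per-trial,
  per-channel mean over `[-200, 0)` ms.

## Motor imagery

Per-trial covariances are computed from mean-centered epochs and
normalized by their trace before averaging within class; this equalizes
trial power but makes the decomposition invariant only under *orthogonal*
channel transformations (trace is not preserved by general invertible
mixing). CSP solves the generalized symmetric eigenproblem
Σ₁w = λ(Σ₁+Σ₂)w via `scipy.linalg.eigh(S1, Sc)`, which returns filters
normalized to wᵀ(Σ₁+Σ₂)w = 1; eigenvalues lie in [0, 1] (clipped against
rounding) and the top-m and bottom-m filters (default m = 2) are retained.
If the composite covariance is ill-conditioned (condition number > 1e10) a
ridge of 1e-8 · tr(Σc)/C is added with a warning. Features are
log-variances of the projected epochs; classification is Fisher LDA
(w ∝ Σ⁻¹(μ₂−μ₁), midpoint bias), with optional shrinkage of the pooled
covariance toward a scaled identity — a fixed λ ∈ [0, 1] or the
Ledoit–Wolf analytic estimate ("auto").

Variants:

* **CSSP** — each channel is paired with a τ-sample delayed copy
  (channel count doubles, epochs lose τ samples); τ ∈ {1..10} is chosen by
  3-fold cross-validated accuracy of the embedded CSP+LDA pipeline, ties
  resolved toward the smallest τ (deterministic).
* **FBCSP** — nine 4 Hz bands covering 4–40 Hz, CSP per band, features
  ranked by mutual information between the feature (discretized into four
  equal-frequency bins) and the label; the top-4 features feed the LDA.
* **Band-search ("BSSFO-style")** — a deliberately simplified
  importance-sampling particle scheme over (low, high) band edges: uniform
  prior on [4, 40] Hz with ≥2 Hz width, fitness = 3-fold cross-validated
  CSP+LDA accuracy, weights ∝ clip(acc − 0.45), multinomial resampling
  with 1 Hz Gaussian jitter, degenerate particles redrawn from the prior;
  the best band seen is kept. Deterministic given its seed. This keeps
  the spirit of a Bayesian spectral search without full MCMC machinery.

Evaluation: train on one phase and validate on the other, or repeated
stratified k-fold cross-validation (default 10×10) with all fitting inside
the training folds. A simulated online mode band-passes the stream
causally, slides a 1.5 s window in 0.5 s steps and maps each LDA decision
value to a feedback coordinate in [-1, 1] via tanh(v/σ_train).

## ERP speller

6×6 grid of `A..Z 1..9 _`; flash groups 0–5 are rows, 6–11 columns; each
12-flash sequence covers every cell exactly twice. Protocol timing:
80 ms stimulus + 135 ms ISI (SOA 215 ms), five sequences per character,
4.5 s pause between characters. The bundled 33-character training
sentence and 36-character test sentence yield 1980 and 2160 flashes.

Features: signed-r² maps (point-biserial correlation squared, carrying the
sign) over the training epochs; ten disjoint 50 ms windows chosen greedily
on a 10 ms grid within [0, 800) ms by the maximum |signed r²| inside the
window; features are per-channel means over each window (32 × 10 = 320),
classified by Ledoit–Wolf shrinkage LDA. Per-flash scores (oriented so
larger = more target-like) are averaged over all flashes whose group
contains a cell; the argmax cell is the prediction, ties breaking to the
lowest index. Accumulating 1…5 sequences gives an accuracy curve.

ITR (bits/min) is Wolpaw's formula
`M · (log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)))` with the x log₂ x → 0
limit; M = 60 / (n_seq · 12 · 0.215 + 0.8) selections/min — 13.7 s per
selection at five sequences, hence the 22.6 bits/min ceiling at P = 1,
N = 36. Gaze-shift pauses between characters are excluded from M.

## SSVEP

Stimulus frequencies 12, 8.57, 6.67 and 5.45 Hz (classes 1–4 in this
order). The reference for frequency f is the 4 × T matrix of sin/cos at f
and 2f on the time grid t = 1/S … T/S. The first canonical correlation
between a trial (10 channels × 400 samples) and each reference is computed
by the orthonormal-basis method: center each block along time, take the
SVD-based orthonormal basis of each row space, and the largest singular
value of Qxᵀ Qy is ρ — numerically stable for rank-deficient blocks, no
covariance inversion. The trial is assigned to the frequency with the
largest ρ (ties to the lower class index, logged). No training data is
used.

## Neurophysiological metrics

* **ERD/ERS**: zero-phase band-pass (default 8–12 Hz) → squared amplitude
  (or squared Hilbert envelope) → trial average per class → 100 ms moving
  average → `100 · (P(t) − P_ref)/P_ref`, with P_ref the mean smoothed
  power over the reference window. By construction the *mean* of the
  curve over the reference window is 0; individual reference samples
  fluctuate around 0 (the standard Pfurtscheller definition — a pointwise
  zero would require a different, non-standard normalization).
* **Signed r²**: per channel and sample, the squared point-biserial
  correlation between amplitude and the binary label, signed by the
  correlation direction; antisymmetric under label swap.
* **PSD**: Welch with 1 s Hann windows and 50% overlap (trial-averaged for
  epochs), restricted to a frequency range; falls back to a single
  full-length window with a warning for short segments.
* **Alpha power**: 10·log₁₀ of the mean PSD in 8–12 Hz; doubling the
  signal amplitude raises it by ≈ 6.02 dB.

## Illiteracy report

Input: a tidy table (subject, session, paradigm, method, accuracy).
A subject is literate in a paradigm iff accuracy ≥ threshold in *every*
session — accuracy exactly equal to the threshold counts as literate.
Thresholds default to 0.70 (MI, judged on the CSP rows only) and 0.90
(ERP, SSVEP). Categories: universally literate (all three), partially
literate (one or two), universally illiterate (none). Per-session
illiteracy rates use the strict inequality (accuracy < threshold).
Between-paradigm Pearson correlations are computed on session-averaged
per-subject accuracies (≥3 subjects required; NaN when either side has
no variance).

## Synthetic EEG

The simulator produces continuous recordings with the same protocols the
decoders expect, deterministic given a seed (independent sub-streams per
paradigm via `SeedSequence`).

* Background: white noise shaped to a 1/f amplitude spectrum by Kellet's
  economy IIR pinking filter (accurate to ~0.5 dB over three decades),
  scaled to 10 µV per channel, spatially mixed by a unit-row-norm Gaussian
  kernel over the schematic channel positions (σ = 0.35), plus a 2 µV
  white sensor floor. The noise path runs in float32, channels-first.
* MI: continuous 10 Hz mu sources over C3/C4 (5 µV, pink amplitude
  fluctuation, Gaussian spatial spread σ = 0.3). During each task window
  the source contralateral to the cued hand drops its amplitude by
  √(1−d) — a band-power drop of d (the configurable ERD depth) — with a
  200 ms ramp starting 0.5 s after the cue.
* ERP: each target flash adds a Gaussian P300-like bump (default 4 µV,
  latency 350 ± 20 ms, width 60 ms) over Cz/Pz; overlapping responses sum
  linearly. The true sentence and per-flash groups are stored in the
  metadata.
* SSVEP: during each 4 s stimulation the channels around Oz receive
  sinusoids at f, 2f, 3f (ratios 1 : 0.5 : 0.25) with 50 ms on/off ramps,
  amplitude = snr × background sd.
* Resting state (posterior alpha) and five artifact signatures (blink,
  horizontal/vertical eye movement, teeth clenching, arm tension) with
  their characteristic topographies and spectra.

Verified recovery behavior (fixed seeds, see the test suite): zero ERD
depth → cross-validated MI accuracy statistically at chance; depth 0.8 →
phase-to-phase accuracy ≥ 90%. Zero P300 amplitude → speller at chance
(~1/36); 15 µV → 100% at five sequences. SSVEP accuracy rises
monotonically with SNR and reaches 100% at snr = 1.

## Numerical choices

* Generalized eigenproblems use `scipy.linalg.eigh(A, B)` (LAPACK);
  LDA solves use `assume_a="pos"` with an explicit error advising
  shrinkage when the pooled covariance is singular.
* CCA avoids explicit covariance inversion (SVD of orthonormal bases).
* Log-variance features floor the variance at machine epsilon with a
  warning instead of producing −inf.
* Cross-validation seeding derives per-repeat seeds from a single
  `SeedSequence`, making every reported accuracy reproducible.

## Limitations

* The simulator is a phenomenological signal-plus-noise model: no
  volume-conduction head model, no non-stationarities beyond the scripted
  amplitude changes, no realistic artifact mixture during task data. It
  validates decoding machinery, not physiological realism.
* The spectral band search is a simplified particle scheme, not a full
  Bayesian posterior; it is meant as a deterministic, testable stand-in.
* The montage coordinates are schematic; do not use them for source
  localization or topographic interpolation beyond qualitative spreads.
* The ERP channel subset and discriminant windows are re-selected per
  training set; transfer across subjects/sessions is out of scope.
* ITR uses Wolpaw's formula with its usual assumptions (uniform symbol
  priors, symmetric confusions, error-free feedback); reported bits/min
  exclude inter-character gaze shifts.
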