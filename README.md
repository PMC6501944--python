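# tribci

A three-paradigm EEG brain–computer interface (BCI) decoding toolbox:
**motor imagery** (CSP-family spatial filtering + LDA), **ERP speller**
(discriminant mean-amplitude features + shrinkage LDA + sequence
accumulation), and **SSVEP** (calibration-free canonical correlation
analysis against harmonic references) — together with the
neurophysiological summaries (ERD/ERS, signed r², PSD, alpha power),
BCI-illiteracy reporting, and a deterministic synthetic-EEG simulator that
lets every pipeline be exercised end to end without recorded data.

## The science in one page

A non-invasive BCI turns scalp EEG into commands. Three signal types
dominate the field, and each needs its own decoding chain:

**Motor imagery (MI).** Imagining left- vs right-hand movement suppresses
the contralateral sensorimotor mu rhythm (8–30 Hz) — event-related
desynchronization (ERD). Decoding: band-pass 8–30 Hz, epoch 1.0–3.5 s
after the cue on 20 motor-area channels, learn spatial filters by *common
spatial patterns* (CSP): solve Σ₁w = λ(Σ₁+Σ₂)w, keep the filters with the
most extreme eigenvalues (λ near 1 discriminates class 1, near 0 class 2),
take log-variance features, classify with Fisher LDA. Variants: CSSP
(delay-embedded channels add a spectral degree of freedom), FBCSP (CSP per
filter-bank band, features ranked by mutual information) and a stochastic
spectral-band search (a simplified particle scheme).

**ERP speller.** A 6×6 letter board flashes rows and columns; the flash
containing the attended symbol evokes a P300. One *sequence* = 12 flashes
(every row and column once) at a 215 ms stimulus-onset asynchrony; up to
five sequences are accumulated per character. Decoding: 32 channels,
[-200, 800) ms epochs, baseline-corrected; ten discriminant 50 ms windows
selected by signed r²; per-window mean amplitudes (320 features) →
shrinkage LDA; per-flash scores are averaged per cell and the best cell
wins. Throughput is summarized by Wolpaw's information transfer rate
(ITR); at perfect accuracy a selection takes 60×0.215 s + 0.8 s = 13.7 s,
giving the 22.6 bits/min ceiling for 36 symbols.

**SSVEP.** Flickering targets at 12 / 8.57 / 6.67 / 5.45 Hz entrain
occipital EEG at the stimulus frequency and its harmonics. Decoding is
calibration-free: for each 4 s trial, the canonical correlation between
the 10 occipital channels and a sin/cos reference at f and 2f is computed
per frequency and the argmax wins.

**BCI illiteracy.** A sizeable minority of users cannot reach useful
control. Subjects are categorized from their decoding accuracies:
literate in a paradigm if accuracy reaches the threshold (70% MI on the
CSP decoder, 90% ERP/SSVEP) in *every* session; universally literate /
partially literate / universally illiterate overall.

All of this is implemented on a common data model (continuous recording +
marker stream + label block, stored as HDF5 structs) with a shared
preprocessing chain (channel subset → Butterworth band-pass → decimation
to 100 Hz → stimulus-locked epochs).

## Worked example

Simulate a motor-imagery session (deep 70% ERD, 40 trials per phase) and
decode it with CSP+LDA, training on one phase and validating on the other:

```console
$ cat sim.yaml
mi:
  n_trials: 40
  erd_depth: 0.7
$ tribci simulate --paradigm mi --seed 1 --config sim.yaml \
    --struct-name EEG_MI_train --out mi.h5
wrote EEG_MI_train (526286 samples x 62 ch) to mi.h5
$ tribci simulate --paradigm mi --seed 2 --config sim.yaml \
    --struct-name EEG_MI_test --out mi.h5
wrote EEG_MI_test (522876 samples x 62 ch) to mi.h5
$ tribci mi --train mi.h5 --test mi.h5 --method csp --out-dir run --seed 0
{
  "paradigm": "MI",
  "method": "csp",
  "accuracy": 0.875,
  "n_train": 40,
  "n_test": 40
}
```

(Exact output of this command sequence; everything is seeded.) `run/`
now contains `report.json` (with a provenance block: seed, config hash,
package version) and `predictions.csv` with per-trial predictions.

The ITR arithmetic is available directly:

```pycon
>>> from tribci.erp import itr_bits_per_min, selections_per_minute
>>> selections_per_minute(n_seq=5)
4.37956204379562
>>> itr_bits_per_min(1.0, n_seq=5)
22.64200730558677
>>> itr_bits_per_min(0.9, n_seq=3)
29.423895359427636
```

Other commands: `tribci erp` (train/test speller run with per-sequence
accuracy and ITR), `tribci ssvep` (calibration-free CCA run with a
confusion matrix), `tribci illiteracy --table acc.csv` (literacy
categories, per-session illiteracy rates, paradigm correlations),
`tribci viz` (ERD/ERS, signed r², PSD or alpha-power tables as tidy CSV),
and `tribci simulate --paradigm rest|artifact` for resting-state and
artifact signatures.

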