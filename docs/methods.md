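# Methods

This note documents the models, numerical choices and limitations behind
`transfercsp`: the synthetic EEG generator, the CSP/transfer/classification
pipeline, and the evaluation protocol.

## Synthetic session model

The generator produces epoched multichannel sessions under the linear
instantaneous mixing model that CSP itself assumes, so filter/pattern
recovery against the planted mixing matrix is a meaningful test:

    X(t) = g · A s(t) + G r(t) + L n(t) [+ EOG]

* **Task sources** `s`: three band-limited (8–30 Hz, 4th-order Butterworth)
  Gaussian processes anchored under C3 (controlled by right-hand imagery),
  C4 (left hand) and Cz (feet).  Each mixing column of `A` is a Gaussian
  scalp footprint (spatial σ = 0.20 in unit-disc coordinates) peaking at its
  anchor electrode.
* **ERD/ERS**: after the cue (t ≥ 0) a class multiplies the band variance of
  its sources by (1 − d) on the contralateral side and (1 + d)
  ipsilaterally, where d = `erd_depth`; feet imagery suppresses the Cz
  source.  So LH&F lowers band power at C4 and Cz and raises it at C3, and
  RH&F mirrors this.  Combined classes apply the elementwise *product* of
  their components' modulations — the invariance that makes single-task
  filters transferable.  The 0.5 s pre-cue segment carries baseline
  variance.
* **Ongoing rhythms** `r`: seven class-independent band-limited sources at
  fixed canonical locations (occipital, bilateral parietal,
  central-parietal, bilateral premotor, frontal midline) with broad
  footprints (σ = 0.45, emulating far-field volume conduction) and
  lognormal trial-to-trial amplitudes (log-σ = 0.4).  Their typical in-band
  power at their peak channel is 12× the unstructured background.  They are
  the feature of real EEG that makes *absolute* single-channel band power
  unreliable while leaving the task contrast recoverable by spatial
  filtering: with 64 channels a filter can null a handful of point-like
  interferers, a single electrode cannot.  Because the simulated "subject's"
  anatomy is fixed, the same rhythm geometry appears in source and target
  sessions, so source-derived filters null them in the target session too.
  `background_rhythms=0` disables them for algebraic/identity tests.
* **Background** `n`: per-channel 1/f ("pink") noise mixed through the
  Cholesky factor of a smooth spatial covariance (correlation length 0.35).
* **SNR definition**: `snr_db` is the in-band (8–30 Hz) power ratio of a
  task source to the background *at the source's peak channel*, at baseline
  modulation.  This local definition was chosen over a channel-averaged one
  because averaging over a 64-channel montage concentrates implausibly high
  local SNR at the anchors and saturates every classifier; with the local
  definition the default conditions (snr_db = 0, erd_depth = 0.5) reproduce
  the regime reported for weaker subjects in this paradigm — single-channel
  band power near chance, target-only CSP weak at 5 training trials/class,
  transferred filters far ahead — while snr_db = 10, erd_depth = 0.6 gives a
  strong subject where all methods do well.  These constants were calibrated
  once against that qualitative regime and then frozen.
* **Determinism**: every trial draws from a substream keyed by
  `(seed, class index, trial index)`, so trial content is independent of
  trial order and of which other classes a session requests.
* **EOG toggle**: an optional < 4 Hz high-amplitude frontal component
  (`eog_amplitude`, off by default) exercises the preprocessing chain; the
  ICA-based ocular rejection of a real pipeline is a user-supplied step
  outside this package.
* **Units**: output is scaled so the unstructured background has ≈ 10 µV
  RMS; all downstream processing is invariant to global amplitude.

What the generator does **not** model: realistic volume-conduction head
geometry, non-stationarity across runs, 50 Hz line noise, muscle artifacts,
or inter-subject variability.  Passing tests therefore demonstrate
correctness of the algorithms under the generative assumptions of CSP, not
performance on real recordings.

## Preprocessing

Fixed chain (enforced by `preprocess`): linked-mastoid re-reference
(x ← x − RM/2, valid only when the recording reference is LM) →
bad-channel interpolation (samplewise mean of ≥ 2 good neighbors; default
neighbor map = 4 nearest electrodes by montage geometry) → zero-phase
8–30 Hz band-pass (4th-order Butterworth, forward–backward; zero phase
avoids latency distortion of the baseline window) → epoching on half-open
windows [cue−0.5 s, cue+2 s) so sample counts are exactly (tmax−tmin)·fs →
per-trial, per-channel baseline subtraction over [−0.5, 0) s.

## CSP bank

Class covariances are averages of per-trial trace-normalized scatters, so
every trial enters with unit weight and the result has trace 1; covariance
estimation uses the [0, 2) s post-cue window only (the pre-cue baseline
carries no task information), configurable via `window_s`.  Whitening uses
P = Λ^(−1/2)Uᵀ — the exponent that actually makes PRPᵀ = I and hence
Λ₁+Λ₂ = I hold.  Shrinkage Rc ← (1−γ)Rc + γ(tr/N)I is applied only when the
composite covariance is too ill-conditioned to whiten (γ escalates
0 → 1e−6 → 1e−4 → 1e−2); with γ = 0 in the well-conditioned case the
whitening identities hold to ~1e−12 on the raw inputs.  Eigenvalues are
sorted descending with a stable sort (ties keep eigendecomposition order);
each filter row is scaled so its largest-magnitude coefficient is positive,
fixing the arbitrary eigenvector sign.  The bank keeps all N rows — tagged
`high` (first half) / `low` (last half; the middle row of an odd bank is
`mid` and never transferable) — and defers any reduction to the selection
steps.  Patterns (the physiologically interpretable forward model) are rows
of (Wᵀ)⁻¹ᵀ, via the pseudo-inverse for reduced banks.

## Transfer selection

Each source filter is scored by the Fisher ratio of its normalized
log-variance feature computed over the *whole* bank on the target training
trials — the same transform the classifier sees, keeping selection and
inference consistent.  Exactly `k_per_group` filters are kept from each
group (default 2, the top-4 operating point), preserving CSP's symmetric
structure; ties in J go to the filter with the more extreme source
eigenvalue, then the lower index.  An `overall` selection mode (top 2k
regardless of group) exists as a documented alternative reading but is not
the default.  Degenerate scores: zero within-class scatter with positive
between-class scatter maps to +∞ (always selected before finite scores);
all-constant features map to 0.

When the Fisher ranking within each group agrees with eigenvalue extremity
— as on clean sessions where every retained filter is informative —
transfer with source = target and k = m reproduces plain CSP exactly, making
the scheme a strict generalization.

## Features and classifier

f_p = log(var_p / Σ_q var_q) with population (1/G) variances about the row
mean; exp(f) sums to 1 per trial, making features invariant to global
amplitude.  The SVM uses an RBF kernel on z-scored features (standardization
constants from the training set; unstated in the original regime but
necessary for RBF stability on log features), with C ∈ {10⁻¹…10³} and
γ ∈ {10⁻²…10²}/d (5 log steps each) chosen by stratified 5-fold CV —
degrading to leave-one-out with a warning at 2–4 samples/class — and refit
on all training data.  Fold assignment and tie-breaks (first grid point
wins) are deterministic given the seed.

## Evaluation protocol

Inverted cross-validation: per repetition, each class's trials are shuffled
(seeded) and split into 12 stratified folds; each fold (5 trials/class at
60/class) is used once for training with the other 11 as test, giving
12 × 5 = 60 accuracies per method.  Class counts that do not divide into the
requested folds adjust to the nearest stratifiable fold count with a
warning.  Baselines: `csp` (m first + m last filters of a bank built from
the target fold alone) and `psd` (Welch, 1 s windows, 50% overlap; features
= 8–30 Hz log band power at C3, Cz, C4 plus their average — band powers
rather than full spectra, one open reading of "PSD values").  Default
source-task pairings follow the most-similar-limb rule (LH&F vs RH&F ←
LH vs RH; LH&RH vs RH&F ← F vs RH; LH&RH vs LH&F ← F vs LH); any explicit
`TaskSpec` is accepted, enabling arbitrary old/new command sweeps.

Inside `inverted_cv` the per-trial filter-bank variances and PSD features
are computed once per session and reused across folds; the per-fold math
(Fisher selection on variance tables, SVM fits on ≤ 10 samples) is identical
to the public per-call operations, which the self-transfer and protocol
tests verify.

## Problem sizes used in tests

Unit tests run on reduced sessions (8–16 channels, 160–250 Hz) chosen to
exercise the same code paths quickly; the acceptance tests and
`scripts/acceptance.py` use the full study geometry (64 channels, 500 Hz,
60 trials/class) with 2 cross-validation repetitions for the multi-seed
sweeps and the full 5 repetitions for the single high-SNR recovery run.

## Known limitations

* The transfer advantage is demonstrated on the generator's linear,
  stationary world; real EEG breaks session stationarity, which this
  package does not model or correct.
* `ClassifierModel` persistence stores hyperparameters, standardization
  constants and training data, and refits on load rather than serializing
  the fitted SVM.
* EDF export is 16-bit and zero-pads to whole seconds; it is an
  interoperability path, not the lossless container (use the HDF5 layout
  for exact round-trips).  EDF files carry no electrode coordinates, so
  reading without an explicit montage rebuilds a default ring layout.
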