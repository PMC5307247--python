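# Methods

`entrofatigue` benchmarks four entropy features and ten classifiers for
detecting driver fatigue from a **single EEG channel**.  Because
driving-fatigue EEG corpora are generally not shareable, the package ships a
synthetic two-state EEG generator that stands in for the recordings; every
pipeline stage — filtering, epoching, feature extraction, per-subject
normalization, leave-one-out evaluation, ranking — is exercised end to end on
simulated data.  This note documents the models, the numerical choices, and
what the synthetic benchmark does and does not establish.

## Pipeline

1. **Simulate** two labelled recordings (normal / fatigue) per subject.
2. **Preprocess**: 50 Hz notch + 0.15–45 Hz band-pass (zero-phase IIR), then
   segmentation into contiguous 1-s epochs; each epoch inherits its
   recording's state label.
3. **Features**: per epoch and channel, sample entropy (SE), fuzzy entropy
   (FE), approximate entropy (AE) and spectral entropy (PE), with `m = 2`
   and `r = 0.2 × SD` of the epoch.
4. **Normalize** each feature column to [−1, 1] within each subject.
5. **Evaluate** every (subject, channel, feature, classifier) cell by
   leave-one-epoch-out cross-validation: accuracy, sensitivity, specificity
   (fatigue = positive class) and ROC AUC.
6. **Report**: per-subject best combination, feature × classifier mean ± SD
   tables, channel rankings, global best cell.

## Entropy estimators

All template entropies use the Chebyshev (max-norm) distance and the
population SD of the analysed epoch, the canonical choices for these
statistics.

* **Approximate entropy** (Pincus): `Φ^m(r) − Φ^{m+1}(r)` with self-matches
  included; always finite, biased toward regularity.
* **Sample entropy** (Richman & Moorman): `−ln(A/B)` over template pairs with
  self-matches excluded; both template lengths use the same `N − m` starting
  indices so `A ≤ B`.  When no length-`m+1` pair matches (`A = 0`, possible
  on short or very regular epochs) the estimator returns an `inf` sentinel;
  during batch extraction sentinels are replaced by the feature column's
  largest finite value and counted in a warning.  This keeps every epoch
  usable rather than discarding folds; if an entire column is sentinel the
  extraction aborts.
* **Fuzzy entropy** (Chen et al.): templates are baseline-removed and matched
  with the smooth membership `exp(−(d/r)^n)`, `n = 2`; strictly positive
  match degrees make the estimator finite and noise-robust, and invariant to
  constant offsets.
* **Spectral entropy**: Shannon entropy (natural log) of the normalized
  power in 0.5–45 Hz, divided by `ln K` so PE ∈ [0, 1].  The spectrum is a
  Welch average over rectangular-window segments of one fifth of the epoch
  (50 % overlap) — ~9 averaged segments and a 5 Hz bin width for a 1-s epoch.
  A single full-length periodogram is very noisy (each bin is a 2-dof
  chi-square), and its sampling fluctuations depress the entropy of
  broadband signals well below the flat-spectrum limit (by `1 − γ ≈ 0.42`
  nats); segment averaging restores the white-noise value to ≥ 0.9 while the
  rectangular window keeps a bin-frequency tone concentrated in a single bin
  (PE ≈ 0).  The trade-off is coarse frequency resolution and dependence of
  the tone bound on bin alignment; both are acceptable for a bandwidth-style
  summary feature.

Degenerate inputs (zero-variance epochs) raise an error at the single-series
level and become missing values during batch extraction, aborting if they
exceed 0.1 % of the epochs.

Deliberately naive O(N²) double-loop transcriptions of the three template
entropies (and a concordant-pair AUC counter) live in
`entrofatigue.reference` and serve as independent oracles in the tests; the
vectorized implementations agree with them to 1e−12.

## Synthetic EEG generator

Each channel is a sum of four band-limited oscillators (delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30 Hz; conventional edges), `1/f` background noise,
a high-frequency EMG-like component (band-limited 45–150 Hz, capped below
Nyquist) and a small white sensor floor.  Oscillator frequencies are
subject × channel *traits* shared by both states; phases, envelopes and noise
are redrawn per state.  Per-subject log-normal offsets on band amplitudes
(σ = 0.1) and on the per-channel effect size (σ = 0.15) make the best
channel/combination subject-specific, as observed in real cohorts.

The normal-vs-fatigue contrast is one dimensionless effect size δ
(`regularity_boost`), mapped to three physiologically motivated mechanisms:

* **EMG suppression** — fatigue removes the fraction `1 − exp(−1.5 δ)` of the
  EMG power (reduced muscle tone in drowsiness).  The residual of this
  component that survives the 0.15–45 Hz band-pass roll-off is fast,
  sample-scale jitter: the dominant driver of the template entropies.
* **Alpha power transfer** — the fraction `1 − exp(−δ/2)` of the background
  noise power moves into a slowly frequency-wandering tone at the subject's
  alpha trait frequency (drowsy-alpha).
* **Band-profile blending** — band amplitudes blend with weight
  `1 − exp(−δ)` toward a fatigue profile (delta 1.05, theta 0.85, alpha
  0.95, beta 0.42 versus normal 1.0 / 0.7 / 0.8 / 0.5).

At δ = 0 all three mechanisms vanish and the two states are draws from the
same process.  Because δ only scales deterministic mixing coefficients (the
random draws consumed are identical), the entropy contrast is monotone in δ
under a fixed seed.

A design constraint worth making explicit: on an oversampled, band-limited
signal, all four entropies largely measure *bandwidth*, so a purely
narrow-band power transfer gives spectral entropy the strongest contrast —
the opposite of the regime reported for real fatigue EEG, where fuzzy
entropy discriminates best and spectral entropy worst.  The generator
reproduces that regime through the EMG mechanism: the suppressed component
lies **above** the 45 Hz edge of the PE band, so spectral entropy is blind to
it, while the time-domain template entropies see the jitter directly; the
alpha change that PE does see is partially masked by the per-band amplitude
envelopes (log-normal, σ = 0.2 per second).  Default magnitudes (noise
3 µV, EMG 25 µV, sensor 0.5 µV against ~10 µV-amplitude oscillators) were
fixed from component-level effect-size measurements at δ = 2.

What the generator does **not** emulate: eye-blink/movement artifacts,
electrode drift, volume-conduction correlations between channels,
non-stationary fatigue onset within a recording, or any quantitative match
to a particular cohort.  Passing the benchmark therefore shows the pipeline
is correct and well calibrated — not that any accuracy level transfers to
real recordings.

## Classifiers

The ten configurations are scikit-learn estimators behind one
build/score interface: KNN (k = 5), linear-kernel SVM (C = 1), RBF-kernel
SVM (γ = 2, C = 1), Gaussian process, decision tree (depth ≤ 10), random
forest (10 trees, depth ≤ 10), MLP (one hidden layer of 100 units, ≤ 500
iterations, no early stopping — an explicit choice where the architecture is
conventionally unstated), AdaBoost, Gaussian naive Bayes and QDA; everything
else is the library default, recorded in the run manifest.  Continuous
fatigue scores for the ROC come from the class-1 probability where available,
otherwise the decision-function margin.  Stochastic learners are re-seeded
identically per fold.

## Evaluation protocol

The cross-validation unit is the **epoch within one subject**: per-subject
accuracies on single-subject data are only defined with within-subject
folds.  Each of the pooled normal+fatigue epochs is predicted by a model
trained on the remaining epochs; counts accumulate over folds and the AUC is
computed from held-out scores (midrank/Mann–Whitney tie convention).

Two documented caveats:

* **Normalization leakage** — the default per-subject min-max scaling is fit
  on all of a subject's epochs before cross-validation, which leaks the
  test epochs' *range* (not labels) into training.  `fold_normalize=True`
  refits the map on each training fold and clips the held-out value.
* **Null behaviour of LOO** — with balanced classes, each training fold has
  a one-epoch class imbalance opposing the held-out label, and removing the
  held-out epoch also shifts its own class's sample statistics away from it.
  On label-free data these two arbitrarily small biases matter: for
  unstable learners (decision tree, AdaBoost) fold coupling inflates the
  variance of single-cell null accuracies far beyond binomial, and for
  likelihood/margin classifiers (naive Bayes, QDA, SVMs, Gaussian process,
  MLP) a cell whose chance class-mean gap is ≲ 0.02 σ collapses to
  accuracy ≈ 0 — every fold's two likelihoods are near-identical, so the
  anti-held-out biases decide every prediction.  Null leave-one-out accuracy
  is therefore *bimodal* (an atom near 0 plus mass around 0.5), not
  binomial; for the linear SVM, whose high-bias hinge solution degenerates
  toward majority voting, it sits below 0.5 even off the atom.  This is a
  property of the protocol itself on ideally exchangeable data — real
  recordings, with their session-to-session nonstationarity, never reach
  this microscopically null regime.  Calibration checks consequently assess
  accuracies averaged over several independent cells, and the direction of
  the pathology means a *high* null accuracy (spurious signal) is still a
  reliable alarm even where the lower band edge is not attainable.

A stratified k-fold mode exists purely as a smoke-test shortcut and is
labelled non-protocol in the manifest.

## Aggregation conventions

Summary tables report mean ± sample SD (`n − 1`) over all
(subject, channel) cells; accuracies are printed as percentages with one
decimal.  Per-subject best combinations break ties by higher AUC, then
lexicographically (channel, feature, classifier).  A subject whose best
accuracy stays below 0.6 is flagged `no_signal` (the level indistinguishable
from label-free data at these cell sizes).  Channel rankings carry SD columns
so that exchangeable channels are visibly unstable across seeds.

## Problem sizes

The generator defaults mirror a full study — 12 subjects × 2 states ×
30 channels at 1000 Hz, 300 one-second epochs per state (3600 epochs per
state in total).  The test-suite and the acceptance script run the
evaluation-level checks at a smoke scale chosen for one-CPU runs: 250 Hz,
2–4 subjects, 2–4 channels, 60–100 epochs per state.  250 Hz is also where
the template entropies resolve the regularity contrast best (at 1000 Hz a
45 Hz-limited signal is ~11× oversampled and `m = 2` templates span only
2 ms); the full-rate default remains available.

## I/O formats

Recordings travel as plain TSV (channel-labelled columns, `#` key/value
header for fs/subject/state; lossless to printed precision) or EDF (16-bit,
physical range ±200 µV — a standard clinical dialect; subject/state ride in
the EDF identification fields).  EDF files are written by a minimal encoder
in `entrofatigue.io` and read back through `mne`; the ±200 µV/16-bit choice
keeps the quantization step (~6 nV per digit × 10³) three orders of
magnitude below signal amplitude.  EDF export requires integer sampling
rates and whole-second recordings (1-s data records).
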