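# Methods

## Problem and model

`nirsweep` classifies two-group, multichannel fNIRS hemodynamic data at
the level of single trials. Each trial contributes one feature vector
x ∈ ℝ^D: per channel, the mean baseline-standardized oxy-Hb response
(Z-score) over a post-onset analysis window. Labels t ∈ {+1, −1} encode
the two participant groups. The core procedure evaluates **every**
nonempty channel subset A ⊆ {1..D} by the K-fold cross-validation error
(CVE) of a linear soft-margin SVM restricted to A, then ranks subsets
by CVE. This is wrapper feature selection without approximation: for
the array sizes typical of NIRS (D = 12 per hemisphere, D = 24
bilaterally) the 2^D − 1 subsets are enumerable, so the search is exact
where greedy or embedded selectors are heuristic.

The readout is not only the optimal subset's accuracy but the structure
of the top of the ranking: which channels recur in the best K subsets
(occurrence counts) and whether each channel's refit weight keeps one
sign across them (sign consistency). A consistently positive weight
means larger responses at that channel push the classifier toward the
+1 group; a consistently negative weight, toward the −1 group.

## Preprocessing

1. **Band-pass filter**, 0.02–1.0 Hz, 3rd-order Butterworth applied
   forward–backward (`scipy.signal.sosfiltfilt`). Zero phase preserves
   response timing; the band removes slow drift and cardiac pulsation
   (sampling is 10 Hz, so heartbeat ≈ 1–1.5 Hz falls in the transition
   region/stopband of the doubled-order response). The filter family
   and order are configurable; filtering is applied to the continuous
   per-trial record before segmentation, and all later statistics use
   filtered values. Records are extended by mirror (even) reflection
   over ~3 time constants of the slow corner before filtering: point
   reflection would inject a DC jump wherever a record ends away from
   its local mean, and the 0.02 Hz corner rings on such a jump for
   ~15 s. Steady-state stopband gain is <1%; the first/last few
   seconds of a finite record still carry a bounded startup transient
   (worst case ~25% of a stopband component's amplitude), which is
   inherent to zero-phase IIR filtering of short records.
2. **Baseline Z-score** (per trial, per channel): every sample from 3 s
   before test onset through test offset is mapped to
   d = (x − m)/s, with m, s the mean and SD of the 3 s immediately
   preceding onset. The SD convention is population SD (ddof = 0) by
   default and configurable; the transform is invariant under positive
   affine rescaling of the raw signal, which is what makes relative
   NIRS units comparable across trials and channels.
3. **Feature** = mean Z over the closed window [3, 10] s after onset
   (the response peak lags onset by a few seconds; samples landing
   exactly on an endpoint are included).
4. **QC**: a trial is kept only if every expected channel is present
   and gap-free (NaN is the missing-sample sentinel). The rejection
   log records one reason per dropped trial.

Trials — not participants — are the classification unit; one
participant's trials may land in different CV folds. A
participant-averaged mode exists for the univariate screen.

## Classifier and cross-validation

The SVM is the standard soft-margin linear machine (libsvm via
scikit-learn), default C = 1.0, configurable. The formulation being
approximated at large C is the hard-margin classifier (every training
point on its correct side). A decision value of exactly zero is
classed −1 (the loss is defined only for t·y(x) ≠ 0, so a tie rule is
required). Features enter the SVM without re-standardization — they
are already Z-scores on a common scale.

Folds are label-stratified, seeded, and **fixed once per search run**:
every subset is scored against the same partition, so subset accuracies
are directly comparable and the accuracy distribution over subsets is
well defined. A training split that loses a class raises an error
naming the fold. CVE = (held-out misclassifications)/N; accuracy =
(1 − CVE)·100, so accuracy is quantized in steps of 100/N.

Because the exhaustive run refits the SVM 5·(2^D − 1) times on tiny
matrices, the inner loop calls the libsvm training routine directly,
bypassing per-call estimator validation; a dedicated test pins this
fast path to `sklearn.svm.SVC` exactly (coefficients and intercept),
and the code falls back to the public API if the binding is absent.
A D = 12 search (4095 subsets × 5 folds, N = 50) takes seconds on one
CPU; D = 24 (16.7M subsets) is supported through mask-range sharding
and checkpointing (output is independent of the sharding) but is
opt-in in the pipeline driver.

**Ranking.** Ties in CVE are common (quantized accuracy), so the total
order is CVE ascending, then subset size ascending (parsimony), then
mask ascending (reproducibility). "Optimal" collects all subsets at
the minimal CVE. Reported weights come from a refit on the full
dataset per subset. The percentile rank of an external accuracy within
the exhaustive distribution counts strictly greater entries:
rank = 1 + #{a : a > accuracy}.

## Embedded baselines

- **LASSO**: L1-penalized least squares onto the ±1 labels
  (classical regression LASSO), prediction by the sign of the linear
  predictor. Penalty chosen per outer fold by inner 5-fold CV over a
  log grid; ties prefer the sparser (larger) penalty.
- **Sparse logistic regression**: L1-penalized logistic regression
  (liblinear) with inner-CV penalty choice, ties toward the sparser
  (smaller) C, and a penalty floor so perfect separation keeps weights
  finite. This is a deliberate functional stand-in for
  automatic-relevance-determination sparse logistic classifiers: it
  preserves the embedded-selection role (exact zeros during a single
  fit) without the variational posterior machinery.

Both run on the same outer folds as the exhaustive search, so their
accuracies can be percentile-ranked within its distribution.

## Channel-wise screen

Per channel: a two-tailed two-sample t-test on the group difference of
features (pooled variance by default, Welch optional) and, per group, a
one-sample t-test against zero. Each family is corrected across the D
channels with Benjamini–Hochberg at q = 0.05 (statsmodels). Summary
-statistic input is supported for published tables (pooled t from
means/SDs/ns).

## Synthetic studies

The generator's defaults are the emulated study conditions: 25 + 25
trials, 24 channels, 10 Hz sampling, ≥ 20 s baseline + 10 s test per
trial. The raw signal per trial/channel is drift sinusoid (amplitude
1, ~0.008 Hz) + cardiac sinusoid (amplitude 0.4, 1.1 Hz) + white noise
(SD 1), each with random phase. Informative channels add a
gamma-shaped hemodynamic response (zero at onset, peak normalized at
5.5 s, shape 4) to the +1 group's test period. The default planted set
is channels {15:+, 16:+, 18:−} and {14:+} on the right array and
{3:+, 5:+, 6:−} on the left, at ±1.5 feature-SD — right-hemisphere
positive effects with one negative channel, mirroring the spatial
pattern such studies report.

Effect sizes are stated in units of the across-trial SD of the
*feature*, which depends on the noise settings through the Z-divide by
the baseline SD. The generator therefore calibrates empirically per
(spec, seed): a pilot batch of null trials measures the null feature
SD and the realized feature shift per unit HRF amplitude, and
amplitudes are scaled accordingly (realized group differences land
within ~20% of target across replicates). A `dropout_rate` marks one
random channel NaN in that fraction of trials to exercise QC; the QC
reject count equals the planted dropout count exactly.

A second, feature-level generator draws the features directly from
group-shifted equicorrelated multivariate normals — fast, and
appropriate when only classification/screening behavior is under test.

**What the synthetic data do not contain:** motion artifacts,
optode-coupling changes, physiologically coupled noise across channels
(time-series channels are independent), participant-level random
effects, or variable trial counts per child. Passing recovery tests
therefore shows the machinery is correct under the stated noise model,
not that real recordings will separate this cleanly.

## Numerical and degenerate-input choices

- Zero baseline SD, single-class training splits, dimension
  mismatches, non-finite features, empty windows: explicit errors.
- Degenerate two-sample test (both groups constant, equal means):
  t = 0, p = 1; unequal means: error.
- Decision ties → class −1. Percentile rank counts strict exceedance.
- Checkpoint resume and shard concatenation reproduce the
  uninterrupted run exactly; all randomness flows from one root seed.

## Known limitations

- With several strongly informative, mutually redundant channels the
  top of the ranking is a large tie class; the parsimony-first
  tie-break then fills the top-K with small subsets, so per-channel
  occurrence among the top-K understates how informative a redundant
  channel is. Interpret occurrence counts together with the optimal
  tie-class size.
- The sparse-logistic baseline is not the cited ARD estimator; its
  accuracies are representative of L1-embedded selection, not of any
  specific published implementation.
- The bilateral D = 24 exhaustive run is hours-scale on one CPU; the
  pipeline defaults to the two D = 12 hemispheric searches and leaves
  D = 24 behind an explicit flag (sharding recommended).
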