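# Methods

## Decoding model

The package decodes two-class (left vs right hand) motor imagery from
epoched EEG.  The physical signal is event-related desynchronization (ERD):
imagery of one hand attenuates the band power of the contralateral
sensorimotor mu rhythm (~10 Hz).  The decoding chain assumes EEG channels
are an instantaneous linear mixture of latent sources, so a class-dependent
*variance* change in a source appears as a class-dependent spatial
covariance structure — exactly what CSP diagonalizes.

### r² band discriminability

For each frequency bin, per-trial band power is estimated with a Welch
periodogram (one-second segments, giving ~1 Hz resolution, capped at the
trial length) and aggregated over channels by the mean (a single channel
index can be selected instead; whether pooling or per-channel statistics
were used originally is not recorded, so both are exposed).  The statistic

r² = [ √(N₁N₂)/(N₁+N₂) · (mean P₁ − mean P₂) / std(P₁∪P₂) ]²

uses the population (divide-by-n) standard deviation of the pooled sample.
Under that convention r² is algebraically the squared point-biserial
(Pearson) correlation between power and class label, which is how the tests
verify it.  It is invariant to shifting or positively rescaling all powers
and to swapping class labels.  A zero-variance pooled sample yields r² = 0
with a warning.  Band selection enumerates every contiguous window on the
bin grid with width between `min_width` (default 4 Hz) and `max_width`
(default 12 Hz) inside the search range (default 4–40 Hz) and keeps the
window of maximal mean r².  Mathematically tied scores differ by rounding
noise in floating point, so scores within 1e-12 relative are treated as
tied and broken toward lower frequency, then narrower width.

### Filtering

Order-4 Butterworth band-pass applied forward–backward (`sosfiltfilt`):
zero phase, so no group delay is introduced between channels, at the cost
of squaring the magnitude response.  Trials shorter than the filter warm-up
length are rejected rather than silently padded.

### CSP

Per-trial covariance is the raw outer product normalized by its trace,
R = XXᵀ/tr(XXᵀ) — trials enter with equal weight regardless of amplitude,
and band-passed EEG is zero-mean so no centering is applied.  The whitening
path: eigendecompose R̄₁+R̄₂ = UλUᵀ (λ descending), whiten with
P = λ^(−1/2)Uᵀ, eigendecompose P R̄₁ Pᵀ = B D Bᵀ, and set W = BᵀP ordered by
descending D.  Invariants checked on every fit: W(R̄₁+R̄₂)Wᵀ = I, both
whitened class covariances diagonal, and per-component eigenvalue
complementarity d₁ + d₂ = 1.  The same filters solve the generalized
eigenproblem R̄₁v = μ(R̄₁+R̄₂)v, which an independent generic solver verifies
in the tests.

Numerical choices: eigenvector signs are fixed by making each filter's
largest-magnitude entry positive; components with equal eigenvalues keep
the eigendecomposition's output order (arbitrary, documented as such); a
rank-deficient composite covariance raises an error naming the `shrinkage`
remedy — convex shrinkage of each class covariance toward a trace-matched
identity, default 0 — rather than silently regularizing.

Features use the top-m and bottom-m filters (default `n_pairs` m = 3, or
⌊channels/2⌋ below six channels; how many components the original analysis
kept is not recorded).  The feature is the plain variance share
fᵢ = var(Zᵢ)/Σⱼ var(Zⱼ), normalized over the *selected* components
(the denominator's scope is ambiguous in the source description; selected
components is the declared choice), so features are nonnegative, sum to 1,
and are scale-invariant.  The common log-variance variant exists behind a
flag, off by default, to stay faithful to the plain-variance formulation.

### LDA

Class scatters Σⱼ are un-normalized sums of outer products of deviations;
w solves (Σ₀+Σ₁+ridge·I)w = μ₀−μ₁ and is returned unit-norm (using
covariances instead would change only the scale, which normalization
removes).  The Fisher criterion derivation produces no intercept; the
threshold is the equal-prior midpoint wᵀ(μ₀+μ₁)/2, appropriate for the
balanced designs generated here.  Points projecting exactly onto the
threshold go to class 0.  Default ridge is 1e-10·tr(Σ₀+Σ₁)/d for numerical
safety; ridge = 0 gives the exact solve used in the oracle tests (which
check w against a generic generalized-eigenvalue solver and that no random
direction scores a higher Fisher ratio).

### Cross-validation

Stratified k-fold (default 5) repeated (default 5) with per-repeat shuffle
seeds drawn from one seed sequence.  Band selection, CSP and LDA are all
fitted inside each fold on training trials only; filtering is per-trial and
unsupervised, so applying the train-selected band to test trials leaks
nothing.  How the original per-subject accuracies were computed (split,
folds, online vs offline) is not recorded; this protocol is a declared
reconstruction.  Accuracy is reported in percent; the confusion matrix
pools all repeats.

## Synthetic generator

`generate_mi_dataset` realizes X = AS + E per trial:

- **Mixing A** (channels × sources): random orthogonal columns scaled by
  per-source gains drawn from U(0.5, 1.5), drawn once per dataset.
  Orthogonality guarantees full column rank and identifiable patterns; the
  heterogeneous gains reflect that real sources reach the scalp with
  unequal strengths — with exactly equal class-source norms the
  channel-averaged mu power would be identical across classes and the ERD
  invisible to pooled-power statistics (an exact-symmetry artifact no real
  montage exhibits).
- **Class sources** (one per class): amplitude-modulated sinusoids at
  `mu_freq` (default 10 Hz) with random phase per trial, envelope spreading
  the line over ±`mu_bandwidth`/2 (default 2 Hz), unit RMS.  In class-k
  trials the class-k source is scaled by √(1−`erd_depth`), so its band
  power drops by the factor 1−`erd_depth`: ERD as a pure variance change,
  which is all CSP sees.  Both class sources are present in every trial;
  only the active one is attenuated.
- **Common sources** (default 2): 4–30 Hz band-limited Gaussian noise,
  unit RMS, identically distributed across classes.
- **Sensor noise**: white Gaussian per channel, sd `noise_sd`
  (default 0.5).

Defaults describe a small sensorimotor montage: 8 channels (a commonly
used montage size), 2 s epochs at 250 Hz (500 samples; channel count must
stay below sample count for the covariances to be estimable), 100 trials
per class, erd_depth 0.5.  The original recordings' channel count, epoch
length and sampling rate are not documented, so these are declared, not
inferred.  One `numpy` generator seeded by `seed` drives all randomness;
identical configs give bit-identical data.

What the generator does *not* emulate: volume conduction and realistic
10–20 geometry, non-stationarity across a session, ocular/muscular
artifacts, 1/f background spectra, or inter-subject variability.  Passing
recovery and accuracy tests on this model therefore shows the pipeline
correctly exploits class-dependent source variance under linear mixing and
noise — not that it would reach any particular accuracy on real recordings.

## Study statistics

The published 9 × 4 accuracy table (subjects × pre-stimulation /
pseudo-stimulation / tACS / tDCS) is embedded verbatim.  Column summaries
use the sample (n−1) SD, which reproduces the printed SDs exactly.  The
repeated-measures ANOVA is the additive two-way decomposition without
replication, F = MS_condition/MS_error with the subject×condition
interaction as error; p is uncorrected for sphericity (the published
integer degrees of freedom imply none), with Greenhouse–Geisser available
behind a flag.  One printed value is internally inconsistent: the tDCS
column mean is 88.7156, which rounds to 88.72, while the published row
prints 88.71 — a two-decimal truncation.  `reproduce_report` therefore
accepts a printed value that matches to tolerance *or* equals the exact
two-decimal truncation of the recomputed value.  The published pairwise
comparisons name no test and their pairing narrative is ambiguous, so
`pairwise_comparisons` runs two-sided paired t-tests labeled an exploratory
reconstruction; the published p-to-pair mapping is not decidable and no
exact match is claimed.

## Problem sizes

Tests and the acceptance script use 100 trials per class, 8 channels and
500-sample epochs for pipeline-level checks, and 3–8-channel random
instances for the algebraic oracle sweeps; these sizes give stable Monte
Carlo behavior (binomial sd of an accuracy estimate at n = 200 is ~3.5
percentage points at chance) while keeping any single check to seconds.

## Known limitations

- Two classes only throughout (CSP and the Fisher derivation are
  inherently binary here); no multi-class extensions.
- No artifact rejection or EOG removal; no filter banks or Riemannian
  alternatives.
- EDF export is 16-bit quantized by format design; round trips are exact
  only to the quantization step recorded in the header (the CSV bundle is
  lossless).
- The per-subject accuracies of the original experiment depend on
  unreleased recordings and cannot be recomputed; only the table-level
  statistics are reproduced, and the decoding pipeline is validated by
  parameter recovery on synthetic data instead.
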