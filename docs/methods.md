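# Methods

## Problem and model

`enhwalk` classifies DNA sequences as enhancer vs non-enhancer from
sequence alone. Its premise is that regulatory sequence differs from
background both in short-word composition and in the long-range
correlation structure of its purine/pyrimidine arrangement, and that
both signals can be read off two representations:

1. **k-mer counts.** All 4^k words for k = 1..6, i.e. 5460 features,
   counted as raw overlapping occurrences (not length-normalized
   frequencies: with sequences capped at 1500 bp the count scale is
   directly comparable across samples, and group means of individual
   words such as `GGCAG` stay interpretable). Order is canonical:
   ascending k, alphabetical within k. Counting is strand-specific.

2. **DNA-walk statistics.** Each base contributes a step — pyrimidine
   (C, T) +1, purine (A, G) −1 — and the cumulative sum is the walk, a
   1-D non-stationary series. The canonical feature set is exactly 8
   values, in fixed order: `sd` (sample SD of the walk), `dfa`
   (DFA-1 scaling exponent of the walk), `ac`/`ac_200`/`ac_300`
   (sample autocorrelations of the walk at lags 100/200/300), `sampen`
   (sample entropy of the walk), `hurst` (R/S exponent of the *steps*),
   and `rvntsl` (distinct walk values / length).

The full feature vector is the concatenation: 5460 + 8 = 5468 columns.

### Why walk vs steps differs by estimator

DFA is applied to the walk: DFA internally integrates its input once
more, so an uncorrelated base sequence yields α ≈ 1.5 — the regime in
which enhancer/background differences in long-range correlation are
expressed on this feature. R/S analysis is applied to the ±1 increments,
the classic input for which uncorrelated steps give the Brownian value
K = 0.5. Mixing these up shifts both features by ±1 and destroys their
calibration.

## Estimators

**Autocorrelation.** ρ(ℓ) = Σ_{t≤N−ℓ}(x_t−x̄)(x_{t+ℓ}−x̄) / Σ_{t≤N}(x_t−x̄)²
— the conventional biased sample estimator, bounded in [−1, 1].
Sequences shorter than 302 bases are rejected upstream because ρ(300)
needs lag + 2 points; below 400 bases a warning flags edge-effect noise.

**Sample entropy.** −ln(A/B) with Chebyshev template matching, template
length m = 2 and tolerance r = 0.2 × series SD (field-standard defaults;
both exposed via `SampEnParams`). Counts follow the Richman–Moorman
convention: both A (length m+1) and B (length m) range over the first
N − m templates, self-matches excluded. A = 0 or B = 0 yields NaN
(missing), never 0.

**Hurst (R/S).** Chunk sizes are powers of 2 from 8 to L/2; per chunk
the range of the mean-adjusted cumulative sum is divided by the chunk's
sample SD; zero-SD chunks are skipped. The naive log–log OLS slope
overestimates K on series of this length (we measure ≈ 0.56 on
length-1500 Brownian walks), so the default estimator subtracts the
Anis–Lloyd expected R/S of an i.i.d. series (with the Peters
(n − ½)/n small-sample factor) and reports K = 0.5 + slope of the
residual — the same correction nolds applies by default. The uncorrected
slope is available with `corrected=False`.

**DFA.** Order-1 detrending over ~12 geometrically spaced window sizes
in [4, L/4]; the profile is the cumulative sum of the mean-centered
input; fluctuation is the RMS residual over all non-overlapping windows;
α is the log–log OLS slope. Zero-fluctuation scales are dropped with a
warning; fewer than 4 usable scales is an error. Calibration (seeded
simulation, 100 replicates): white noise α = 0.51, i.i.d.-base walks
α = 1.48.

**Lyapunov (Rosenstein).** Delay embedding with default dimension 10 and
delay at the first autocorrelation minimum; Euclidean nearest neighbors
with temporal (Theiler) exclusion = delay; λ is the OLS slope of the
mean log-divergence ⟨ln d(k)⟩ over the initial linear region. With no
explicit fit range, that region is detected as the curve prefix whose
per-step increment stays above half the first increment — divergence
saturates at the attractor diameter, and fitting into the plateau biases
λ toward 0 (on the fully chaotic logistic map the full-range default
fit underestimates ln 2 badly; the knee rule or an explicit (1, 4) range
recovers it). The Lyapunov exponent is a standalone diagnostic, not one
of the canonical 8 features; likewise the extended descriptive
statistics (max, min, skewness, excess kurtosis, IQR, zero/mean crossing
rates, spectral entropy) and the pairwise feature-correlation report —
they are computed on demand but excluded from the 5468-vector, whose
arithmetic (5460 + 8) fixes the canonical set.

**Crossing rates and spectral entropy.** A crossing is a strict sign
change of the level-shifted series between consecutive points (touching
the level exactly does not count); rates are normalized by L − 1.
Spectral entropy is the Shannon entropy of the normalized
positive-frequency periodogram of the mean-centered series, divided by
log(#bins) into [0, 1].

## Data preparation

Sequences are uppercased and truncated to 1500 bp. Truncation keeps the
5' prefix: the choice is arbitrary in principle, but a fixed anchor is
deterministic and orientation-stable. Ambiguous (non-ACGT) bases are
stripped when they make up ≤ 5% of the sequence, otherwise the sequence
is rejected; stripping preserves walk continuity better than arbitrary
placeholder steps, and curated enhancer elements are nearly N-free in
practice. Sequences shorter than 302 bases after cleaning are rejected
(lag-300 statistics undefined).

**Null (negative) sequences** are drawn by rejection sampling from a
reference genome: for each positive interval, a uniformly placed window
of identical length, accepted when its GC content is within ±0.02 of the
positive's and it overlaps neither any positive interval nor a
previously accepted null. Repeat-content matching is deliberately out of
scope: it requires an external repeat annotation, and GC + length
matching with non-overlap captures the dominant compositional
confounder. Sampling is reproducible under a seed; unmatched positives
are skipped with a logged count.

## Synthetic data

`simulate_labeled_set` generates the two-class regime the classifier is
meant to separate: positives are i.i.d. bases at GC 0.55 with a
Poisson(5) number of planted `GGCAG` copies at uniform positions;
negatives are i.i.d. bases at GC 0.40 with no planting; default length
1500 bp; the CLI default of 100 positives / 770 negatives preserves the
~1:7.7 enhancer:background imbalance of realistic training sets. What
this emulates: a compositional (GC) shift plus a motif-content shift
between classes at realistic length and imbalance. What it does not:
real enhancers' long-range correlation structure, repeat content,
motif grammar and positional clustering — i.i.d. backgrounds are
uncorrelated by construction. Passing the pipeline-recovery test
therefore demonstrates that feature extraction, PCA and the ensembles
correctly exploit separable composition signals; it does not certify
performance on genomic data.

## Classifiers

PCA is fitted on the raw (centered, unstandardized) training matrix —
count features dominate the leading components by design, which is what
produces a heavily top-loaded spectrum on real count data — and
truncated at the smallest component count reaching 95% cumulative
explained variance (a `standardize` flag enables scaling). PCA is fitted
inside the training partition only, and refitted per fold in
cross-validation, to avoid test-set leakage.

**Bagged trees** (default): 30 full-depth Gini trees, each on an n-sized
bootstrap resample (a resample missing a class is redrawn); the ensemble
score is the fraction of trees voting positive; hard calls threshold at
0.5.

**RUSBoost**: AdaBoost.M1 rounds in which the majority class is randomly
undersampled (without replacement) to exactly the minority count before
fitting each tree under the current sample weights; weighted error is
computed on the full training set; learner weights α_t =
learning_rate × ln((1 − err)/err) with learning rate 0.1; boosting halts
early if a round's weighted error reaches 0.5. Scores are α-weighted
vote shares. Per-round class counts are recorded on the model for
auditability.

Both trainers are deterministic under their seed. Models persist as a
joblib bundle plus a JSON sidecar (kind, learner count, seed, PCA
components kept, feature-name hash, package version).

**Evaluation.** ROC by sweeping all distinct score thresholds, AUC by
the trapezoidal rule (equal to the Mann–Whitney concordance probability
with ties counted ½ — asserted against an exhaustive pairwise oracle),
accuracy at threshold 0.5. Stratified 75/25 splitting is the default
protocol; stratified 10-fold cross-validation is available.

## Numerical and degenerate-input policy

Statistics that are undefined on an input raise a typed error
(`DegenerateSeriesError` and friends) rather than returning a
placeholder: zero-variance series for autocorrelation and SD-relative
entropy, homopyrimidine/homopurine step series for R/S, exactly
detrendable inputs for DFA. During batch extraction a strictness flag
chooses between propagating the first failure (`raise`) and dropping the
sequence with a logged count (`drop`); prediction emits a `no-call`
instead of a score. Sample-entropy counts of zero yield NaN, reported as
missing.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to give stable means under
fixed seeds: 200 replicates of length 1500 for the Brownian Hurst
calibration; 100 replicates each for DFA (length 2000 noise / 1500-step
walks) and fGn Hurst recovery (length 4096 at H ∈ {0.3, 0.5, 0.8});
the pipeline-recovery run uses 200 positives / 1540 negatives of
1500 bp. Brute-force oracle comparisons use length ≤ 500 inputs, where
exhaustive O(N²) scans are exact and fast.

## Known limitations

- The synthetic generator does not reproduce long-range correlated
  backgrounds; `dfa`, `hurst` and the autocorrelations carry little
  class signal under it (the k-mer block dominates), so the pipeline
  test exercises their computation, not their discriminative power.
- R/S and DFA exponents on 428–1500-point series have replicate-level
  spread of ~±0.1; only their means are calibrated.
- GC matching tolerates ±0.02 absolute; on small or GC-skewed genomes
  rejection sampling may skip positives (reported, never silently).
- The distinct-value ratio (`rvntsl`) depends strongly on sequence
  length; comparisons are only meaningful within a matched-length
  design, which the length-matched null construction guarantees.
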