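# enhwalk

Sequence-only enhancer prediction from DNA random-walk and k-mer
features.

Enhancers — distal regulatory elements that boost transcription of their
target genes — are hard to find computationally because they are poorly
conserved, position-flexible, and cell-type specific when defined
through chromatin data. `enhwalk` takes the opposite route and uses the
DNA sequence alone: it asks whether a candidate sequence *looks like* an
enhancer in terms of short-word composition and the correlation
structure of its purine/pyrimidine arrangement, with no histone marks,
TFBS or accessibility data involved.

## The model

Each sequence (cleaned to ACGT, capped at 1500 bp) is represented by a
5468-dimensional feature vector:

- **5460 k-mer counts** — overlapping occurrences of every word of
  length k = 1..6, in canonical order (ascending k, alphabetical
  within k).
- **8 walk statistics** of the DNA random walk x(i) = +1 for a
  pyrimidine (C/T) and −1 for a purine (A/G), cumulatively summed:
  the walk's standard deviation `sd`; the detrended-fluctuation scaling
  exponent `dfa` (α ≈ 1.5 for uncorrelated bases, higher under
  persistent long-range correlation); autocorrelations `ac`, `ac_200`,
  `ac_300` at lags 100/200/300; sample entropy `sampen` (m = 2,
  r = 0.2·SD); the rescaled-range Hurst exponent `hurst` of the step
  series (K = 0.5 for uncorrelated steps, bias-corrected via the
  Anis–Lloyd expectation); and `rvntsl`, the fraction of distinct
  values the walk attains.

Classification uses PCA on the raw feature matrix (components kept up to
95% cumulative explained variance, fitted on training data only)
followed by an ensemble of 30 full-depth decision trees — either
**bagged** (bootstrap resamples, score = fraction of trees voting
positive) or **RUSBoost** (AdaBoost rounds with the majority class
randomly undersampled to exact 1:1 balance per round, learning rate
0.1), the latter built for the heavy class imbalance (~1:7.7
enhancer:background) typical of this problem. Negative training
sequences are sampled from a reference genome as length-identical,
GC-matched (±0.02), non-overlapping null windows.

See `docs/methods.md` for estimator definitions, defaults and
limitations.

## Worked example

```python
from enhwalk import (simulate_labeled_set, build_dataset, split, train_bagged,
                     predict_proba, evaluate, compare_groups)

# two synthetic classes: GC 0.55 + planted GGCAG motifs vs GC 0.40 background
recs = simulate_labeled_set(n_pos=60, n_neg=200, length=1000, seed=7)
ds = build_dataset(recs)
print(f"dataset: {len(ds)} sequences x {ds.X.shape[1]} features "
      f"({ds.class_counts[0]} positive / {ds.class_counts[1]} negative)")

for row in compare_groups(ds, ["GGCAG", "dfa", "rvntsl"]):
    print(f"{row.feature_name:>6}: mean+ {row.mean_pos:.3f}  mean- {row.mean_neg:.3f}  "
          f"t = {row.t_statistic:+.2f}  p = {row.p_value:.2e}")

train, test = split(ds, test_fraction=0.25, seed=7)
model = train_bagged(train, seed=7)
rep = evaluate(predict_proba(model, test), test.labels)
print(f"PCA kept {model.pca.n_kept} components; "
      f"held-out AUC = {rep.auc:.3f}, accuracy = {rep.accuracy:.3f}")
```

Output:

```
dataset: 260 sequences x 5468 features (60 positive / 200 negative)
 GGCAG: mean+ 6.750  mean- 0.450  t = +21.14  p = 3.50e-30
   dfa: mean+ 1.497  mean- 1.476  t = +2.46  p = 1.55e-02
rvntsl: mean+ 0.053  mean- 0.050  t = +1.15  p = 2.52e-01
PCA kept 111 components; held-out AUC = 1.000, accuracy = 1.000
```

Reading it: the planted motif's count separates the classes sharply
(Welch t = 21, p ≈ 10⁻³⁰); the walk features barely move between i.i.d.
backgrounds (as expected — they respond to correlation structure, not
motif content); and the tree ensemble separates the held-out samples
perfectly on this easy setting. On real data the walk features carry the
long-range-correlation signal that i.i.d. simulations cannot produce.

## Command-line tool

```sh
enhwalk simulate --n-pos 100 --n-neg 770 --seed 1 sim.fa
enhwalk extract sim.fa features.csv --labels sim.labels.tsv
enhwalk train features.csv model.joblib --kind bagged --seed 1
enhwalk predict model.joblib candidates.fa calls.tsv
enhwalk evaluate features.csv model.joblib report.json --roc-out roc.csv
enhwalk compare features.csv comparison.csv
enhwalk make-null genome.fa positives.bed --fasta-out nulls.fa --seed 1
```

`predict` writes one `id / score / call` row per sequence (`enhancer`
at score ≥ 0.5, `no-call` for sequences whose features are undefined).

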