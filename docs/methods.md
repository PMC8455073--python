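# Methods

This note documents the statistical model, the algorithmic choices, the
synthetic data generator, and the known limits of what the test suite
demonstrates.

## Target-decoy confidence estimation

Given scores for a mixed set of target and decoy PSMs, the estimated
false discovery rate at score threshold `s` is `(D(s)+1)/max(T(s),1)`,
where `T` and `D` count targets and decoys scoring at least `s`.
q-values are the running minimum of this estimate over thresholds at or
below each score, clipped at 1. Choices worth stating:

- **+1 pseudocount.** The numerator counts one more decoy than observed.
  This is the standard conservative estimator; it guarantees control in
  expectation under the decoy-modeling assumption at the cost of a small
  downward bias in yield, noticeable only for very small accepted sets.
  It is the package's only estimator (no mix-max, no posterior error
  probabilities).
- **Ties.** At tied scores decoys are counted before targets, so a
  target never benefits from a decoy it ties with. Deterministic and
  conservative.
- **Levels.** PSM-level q-values are computed over rank-1 PSMs only
  (lower-ranked candidates of a spectrum still participate in training).
  Peptide-level rollup keys on the modification-aware peptide string
  with flanking residues stripped, keeps the best-scoring PSM per
  peptide separately within targets and within decoys, and reruns the
  competition on that reduced list.

## Dynamic (semi-supervised) training

Each iteration: score all training PSMs with the current direction
(iteration 0: the single best feature, chosen by maximizing accepted
targets at the training FDR over every signed feature); select targets
with `q ≤ train_fdr` as positives and all decoys as negatives; fit a
linear SVM; rescore. The loop runs a fixed `max_iter = 10` iterations
with no convergence test, so runtime and results are data-independent
given the fold split.

- **SVM.** liblinear's primal L2-regularized L2-loss (squared hinge)
  formulation, `C = 1`, asymmetric class costs as instance weights
  (defaults 1.0/1.0), tolerance 1e-5. The primal Newton solver has no
  random state, which makes model optimization fully deterministic —
  the only randomness in the pipeline is the seeded assignment of
  spectra to cross-validation folds. Features are z-scored on the
  training split (population SD; constant columns get scale 1), and the
  learned weights are mapped back to the original feature space, so a
  saved model needs no normalization statistics at application time. A
  direct consequence is exact scale-invariance: multiplying a feature
  column by a positive constant changes nothing downstream.
- **Degenerate paths.** If no signed single feature accepts any target,
  the initial direction falls back to the feature with the largest
  standardized target-decoy mean difference (flagged). If iteration 0
  selects fewer than `min_positives = 10` positives, the model degrades
  to that single best feature with a `degraded` flag — the small-data
  failure mode. If a later iteration selects zero positives, the loop
  stops and keeps the previous model.
- **Cross-validation.** PSMs are partitioned into 3 folds uniformly at
  random by seed, grouping all PSMs of one scan so candidate ranks never
  straddle folds. Each fold is scored by the model trained on the other
  folds; a fold missing either label class on either side of the split
  is an error suggesting fewer folds.
- **Fold-score merging.** Per-fold SVM scores live on arbitrary scales,
  so each fold's held-out scores receive the affine map sending the
  score at the training-FDR acceptance threshold to 0 and the median
  decoy score to −1 (maximum score to 0 if nothing is accepted; unit
  scale if the anchors coincide). The per-fold models exported in
  `BrewResult` are rescaled the same way, which is what makes averaging
  them into a single static-form weight vector meaningful.
- **Small-experiment warning.** `brew` warns on datasets below 5,000
  total PSMs — the recommended minimum under the rule of thumb that
  roughly one third of PSMs should be confidently assignable — and
  suggests a static model instead.

## Static models

A static model is produced by running the same semi-supervised loop once
on the full external training table, with no cross-validation: folds
exist only to avoid scoring one's own training PSMs, and a static model
never does. Models serialize to JSON (schema_version "1") with
full-precision floats; loading is an exact round-trip and unknown
versions are refused. Application is a single deterministic pass
(`w · x + b`) followed by fresh q-value estimation on the new dataset's
own targets and decoys — a fixed model never carries a threshold with
it. Feature compatibility is checked by name before scoring; extra
table columns are ignored.

The downsampling study needs one exportable model per analyzed
subsample; it uses the mean of the three score-normalized fold models,
recorded as such in provenance.

## Synthetic data generator

The generator produces the statistical structure the method assumes,
plus the ground truth that real data never has:

- Decoys and incorrect targets draw features from one zero-mean
  multivariate normal with equicorrelation ρ (the core target-decoy
  modeling assumption — this is exactly what makes the TDC estimate
  calibrated, which the FDR tests then verify).
- Correct targets (a fraction `pi1` of targets, exactly
  `round(pi1 · n_targets)`) draw from the same covariance with mean
  `m_p · effect_sizes`, where `m_p` is a per-peptide lognormal
  detectability factor (mean 1, sigma `peptide_effect_sd`) fixed across
  experiments that share a peptide pool.
- Peptides are tryptic-like strings from a finite pool generated from
  `peptide_pool_seed` only, split into correct / incorrect-target /
  decoy strata, so peptide rollup, shared-peptide curves and
  cross-experiment consistency are all exercised. Flanking residues
  vary per PSM to exercise modification-aware rollup keys.

Defaults and why: `pi1 = 1/3` (a well-behaved search assigns roughly a
third of PSMs confidently); `n_features = 16` with
`effect_sizes = 3.3 · 0.82^i` and ρ = 0.2 (a moderately strong lead
feature — Mahalanobis separation 3.3 on its own, 4.7 combined — plus a
decaying tail of weak ones, matching the makeup of real PIN files,
which typically carry 15–25 features none of which is individually
sufficient); `peptide_effect_sd = 0.35` (PSM quality varies widely
between peptides in real data; this spread is also what gives repeat
experiments a stable signal ordering, without which cross-experiment
consistency would be pure noise); `n_peptides = 2500` (a PSM-to-peptide
ratio near 1.2, typical of small experiments). These values were
calibrated once against the intended operating regime — the best single
feature recovers roughly half to two thirds of correct PSMs at 1% FDR
at moderate scale, the full model roughly ninety percent, and model
estimation stays unsaturated into the 10^4–10^5 PSM range so that
training-set size genuinely matters — and then frozen before the
acceptance tests were written.

What the generator does **not** emulate: spectrum-level physics
(retention time, mass error structure, fragment intensities), score
distributions with heavy tails or discreteness, shared spectra between
ranks (all simulated PSMs are rank 1), protein-level structure beyond
cosmetic identifiers, and dataset-to-dataset batch effects. Passing
tests therefore demonstrate the *algorithmic* properties — calibration,
determinism, leak-freedom, scale trends, the static-model mechanism —
under the model's own assumptions, not performance on any particular
real instrument output.

## Evaluation machinery and problem sizes

The downsampling study draws each (size, seed) cell from an independent
seeded stream, runs the dynamic pipeline on the subsample, exports the
fold-averaged model, and applies it to one common held-out test set.
Confident-mode subsampling fixes the total PSM count and varies how many
come from the confident pool (targets accepted at 1% FDR when the base
set is analyzed dynamically). Summaries report across-seed means with
t-distribution 95% intervals (undefined and flagged for a single seed).

The test suite and acceptance script run scaled-down versions of the
full designs: a 100,000-PSM base with a 10,000-PSM common test set and
five seeds per size for the downsampling study (total sizes 10^2–10^5;
confident sizes 40–4,000 at constant 10,000); 50 replicates of n=4,000
for FDR calibration; and 64 simulated experiments of 1,500 PSMs
(`pi1 = 0.25`, reflecting poorer spectra) against a static model trained
on 50,000 PSMs for the static-vs-dynamic comparison. These sizes keep
the full suite under a minute per study while leaving every measured
effect far larger than its Monte-Carlo error.

One caveat found in simulation: at constant total PSMs, a
confident-starved subsample retains its full decoy complement and the
weak tail of correct PSMs, so at matched *confident* counts it can
outperform a tiny *total* subsample. The "rapid vs gradual" contrast
between the two downsampling modes is therefore measured at the onset —
the fractional drop over the first downsampling decade — where it is
large and stable (roughly 5–20% vs 1–2%).

## Known limitations

- Linear scores only; no kernels, no protein-aware training.
- No posterior error probabilities and no protein-level inference.
- The +1-pseudocount estimator is the only FDR method; results at very
  small accepted counts are conservative.
- Static and dynamic modes share one feature schema by name; no
  imputation is performed for missing features (reading fails fast).
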