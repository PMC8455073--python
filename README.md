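# rescore

Semi-supervised SVM rescoring of peptide-spectrum matches (PSMs), with a
train-once/apply-many **static model** mode for small-scale experiments.

## The problem

Database search engines assign peptides to tandem mass spectra and score
each peptide-spectrum match. Rescoring tools such as Percolator improve
the sensitivity of peptide detection by learning, for every dataset, a
linear combination of search-engine features that best separates target
matches from decoy matches: targets confidently accepted below a training
FDR threshold become positive examples, decoys become negatives, an SVM
is refit iteratively, and every PSM receives its new score from a
cross-validation fold that never trained on it. Error rates are estimated
by target-decoy competition, reported as q-values (the minimal FDR at
which a PSM or peptide is accepted).

This *dynamic* learning works well at typical scale, but small
experiments — excised gel bands, single-cell runs, any analysis with few
total or few confident PSMs — give the learner too little to work with.
The result is lost sensitivity and seed-to-seed variability. This package
implements both operating modes and the evaluation machinery to study
them:

- **dynamic** (`brew`): per-dataset semi-supervised training inside a
  seeded 3-fold cross-validation, with per-fold score normalization and
  merging;
- **static** (`train-static` / `apply`): fit once on a large external
  dataset, serialize the linear model to JSON, and apply it unchanged to
  new datasets — q-values are still estimated on each dataset's own
  targets and decoys;
- **confidence**: target-decoy competition q-values at PSM and peptide
  level, with the conservative `(decoys + 1) / targets` estimator;
- **synthetic**: a ground-truth PSM generator (two-population Gaussian
  feature model with per-peptide detectability), so every claim is
  testable without external data;
- **benchmark**: downsampling designs, multi-seed grids, q-value
  concordance, shared-peptide curves and yield-matched comparisons.

## The model

Scores are linear: `s = w · x + b` over the PIN feature columns. Training
selects positives `P = {targets with q ≤ train_fdr}` and negatives
`N = {decoys}`, fits an L2-regularized L2-loss SVM with asymmetric class
costs, rescores, and repeats for a fixed 10 iterations. q-values use
target-decoy competition: with `T(s)` targets and `D(s)` decoys scoring
at least `s`,

```
FDR(s) = (D(s) + 1) / max(T(s), 1),   q(s) = min_{s' ≤ s} FDR(s')
```

with decoys counted before targets at tied scores. Peptide-level
q-values keep the best-scoring PSM per modification-aware peptide
(flanking residues stripped) separately within targets and decoys before
competition.

## Worked example

Simulate a large training corpus and a small experiment, fit a static
model, and analyze the small experiment both ways:

```sh
rescore simulate --n-targets 30000 --n-decoys 30000 --seed 1 --out train.pin
rescore simulate --n-targets 1000  --n-decoys 1000  --seed 2 --out small.pin
rescore train-static train.pin --seed 0 --out static.json
rescore brew  small.pin --seed 0 --out dynamic
rescore apply small.pin --model static.json --out static
```

The dynamic run warns that 2,000 PSMs is below the recommended minimum
experiment size (about 5,000 total PSMs, assuming roughly one third can
be assigned confidently) and then prints:

```
fold 0: positives per iteration [0]
fold 1: positives per iteration [0]
fold 2: positives per iteration [0]
accepted 0 PSMs at 0.01 FDR
```

Each cross-validation fold found zero confident positives to train on,
fell back to its best single feature, and the experiment yields nothing
at 1% FDR. The static model applied to the same file prints:

```
accepted 216 PSMs at 0.01 FDR
```

and writes `static.psms.txt` / `static.peptides.txt`, tab-delimited and
sorted by decreasing score:

```
PSMId       score               q-value     peptide           proteins
s2-001224   23.917235942204986  0.00571429  L.VCVVIYCK.W      sp|P00073|SYN73
s2-001978   21.64656300445216   0.00571429  Y.AMHDNPMWSDQDGK.V  sp|P00015|SYN15
```

The same workflow is available as library calls (`rescore.brew`,
`rescore.fit_static`, `rescore.apply_static`, `rescore.simulate_psms`);
the command-line commands are thin wrappers over them.

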