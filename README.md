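# pssmfold

Protein fold recognition from PSI-BLAST evolutionary profiles.

The pipeline turns each protein's position-specific scoring matrix (PSSM)
into a fixed-length feature vector by fusing two complementary transforms,
selects discriminative features by information gain, and classifies folds
with a grid-tuned one-vs-one RBF support vector machine:

1. **ACC** — lagged auto-covariance (same PSSM column) and cross-covariance
   (ordered column pairs), mean-centered per column; `400 * LG` features
   (1600 at the default lag bound `LG = 4`).
2. **SD** — separated-dimer sums: uncentered products of scores `k`
   residues apart for every ordered column pair; 400 features at `k = 4`.
3. **IG selection** — each feature is discretized (equal-width bins) and
   scored by information gain against the fold labels; features in the
   closed band `[band_fraction * max_IG, max_IG]` are kept (default 0.5).
4. **SVM** — `C` and `gamma` tuned over powers of two (default
   `2^-14 .. 2^14`) by stratified k-fold cross-validation, with scaling and
   selection re-fit inside each training fold; per-class sensitivity,
   precision and F1 are reported.

A synthetic-data module generates labeled PSSM datasets with separately
controllable class signals (column means for SD, short-lag residue-pair
coupling for ACC), so every stage is testable without external downloads.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: feature-count
reproduction, brute-force oracle equivalence of the extractors, analytic
information-gain cases, hand-computed metric values, end-to-end fold
recovery on synthetic data, and the ACC/SD complementarity property.

## CLI

```bash
# generate a synthetic fixture (ASCII PSSMs + FASTA + label TSV)
pssmfold simulate --out-dir fix --n-classes 3 --n-per-class 40 --seed 7

# extract the fused 2000-column feature matrix
pssmfold extract fix/pssm fix/labels.tsv --out features.tsv

# rank by information gain and keep the top band
pssmfold select features.tsv --out-ranking ranking.tsv --out-matrix reduced.tsv

# tune (C, gamma) by 10-fold CV and train the final model
pssmfold train features.tsv --out-model model --c-exp-range -6:2:2 \
    --gamma-exp-range -6:2:2 --seed 7

# score a labeled matrix with a trained model
pssmfold evaluate model features.tsv --out report

# or run everything in one shot (cv or train/test-split evaluation)
pssmfold pipeline fix/pssm fix/labels.tsv --out-dir run --mode cv \
    --c-exp-range -6:2:2 --gamma-exp-range -6:2:2 --seed 7
```

Flags can also come from a JSON config file (`--config`); explicit flags
win. Every output is accompanied by a manifest (effective config, seed,
input hashes) sufficient to reproduce it. Exit codes: 0 success, 2 invalid
input, 3 internal error.

## Library use

```python
from pssmfold import (
    SyntheticSpec, generate_dataset, build_feature_matrix,
    grid_search_train, predict, evaluate,
)

profiles, labels = generate_dataset(SyntheticSpec(seed=7))
data = build_feature_matrix(profiles, labels)
model, cv_table = grid_search_train(
    data, c_exponents=range(-6, 3, 2), gamma_exponents=range(-6, 3, 2),
    folds=10, seed=7,
)
report = evaluate(data.labels, predict(model, data), model.class_labels)
print(report.macro_f1)
```
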