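# twoqsar

Two-QSAR modelling of skin permeability: a predictive **hierarchical
support vector regression** (HSVR) next to an interpretable **partial least
squares** (PLS) regression, with the complete preprocessing, descriptor
selection, data-partitioning and external-validation machinery needed to
build and judge both models.

## The problem

The skin permeability coefficient, `Kp = J_ss / ΔC_v` (steady-state flux
over the donor concentration difference, cm/h), is a key property in
transdermal drug delivery and dermal risk assessment. It is modelled on a
log10 scale from molecular descriptors (lipophilicity `log P`, molecular
volume `V_m`, the zero-order connectivity index `⁰χ`, partial positive
surface area `Jurs_PPSA_1`, ...). The relationship is awkward for a single
linear model: log Kp rises with log P but falls again once log P ≳ 4, size
descriptors are nearly collinear with each other, and molecular polarity
helps permeation in one subgroup of compounds while hindering it in the
rest. The two-QSAR idea is to fit *both* kinds of model: an ensemble of
small RBF-kernel SVR "local" models — each on its own descriptor pair —
whose predictions are stacked under a second-level (meta) SVR for accuracy,
and a PLS model whose affine coefficients stay readable for mechanism.

## What is implemented

- `core_io` — compound/descriptor CSV ingestion and emission, Kp unit
  transforms (`permeability_coefficient`, `log_transform`).
- `preprocess` — missing-value and invariance filters, Spearman
  collinearity pruning (pairwise ρ² > 0.64), autoscaling with stored
  training parameters, ion-class assignment (neutral/acid/base/zwitterion)
  from pKa lists.
- `partition` — PCA chemical-space projection, structural outlier flagging
  (`N_rot ≥ 8` or `N_O ≥ 11`), a diversity-preserving ~4:1 train/test
  split (greedy farthest-point test selection), KS distribution reports.
- `select` — two-stage descriptor selection: a genetic algorithm over
  descriptor masks, then recursive feature elimination.
- `svr_hierarchy` — ε-/ν-SVR fitting, systematic grid search (held-out or
  cross-validated scoring), parsimony-governed ensemble assembly (no
  (m+1)-member combination is scored before every m-member combination has
  a verdict), meta-SVR stacking, JSON model bundles.
- `pls` — PLS with cross-validated component choice, collapsed to an
  affine form, plus the published four-descriptor skin model
  `log Kp = −2.62974 + 1.26972·log P − 0.55661·V_m − 0.554268·⁰χ −
  0.076344·Jurs_PPSA_1` as a built-in fixture.
- `validation` — the full statistic battery: RMSE/MAE/s/Δ_max, r², q²,
  q²_cv, the external coefficients qF1², qF2², qF3², Lin's concordance
  correlation coefficient, through-origin statistics (k, r0², r0′²), the
  Ojha rm² family, the stringent combined acceptance criteria, 10-fold CV
  and Y-scrambling (25 repetitions).
- `synthetic` — a seeded generator reproducing the statistical structure
  above (bilinear response in log P, a 0.98-correlated size-descriptor
  pair, subgroup-signed polarity effects, heavy-tailed outlier counts), so
  the whole toolkit is testable without any dataset download.
- `cli` — `twoqsar` console script chaining everything
  (`synth`, `run`, `published-pls`, `validate`).

## Worked example

```bash
twoqsar synth --out example.csv --n 150 --seed 7
twoqsar run --input example.csv --out example_run --seed 7
```

The run directory contains split CSVs, the HSVR and PLS model bundles,
`reports.json` with the full statistic battery, and a manifest. On this
seed the pipeline flags 11 structural outliers, splits the remaining 139
compounds 111/28, and prints (from `reports.json`):

| model | train r² | q²_cv | test q² | qF1² | qF2² | CCC | ⟨rs²⟩ |
|-------|---------|-------|---------|------|------|-----|-------|
| HSVR  | 0.92    | 0.90  | 0.80    | 0.80 | 0.80 | 0.89| 0.07  |
| PLS   | 0.68    | 0.67  | 0.74    | 0.74 | 0.74 | 0.85| 0.02  |

Read: the stacked SVR ensemble fits the nonlinear response well (train
r² 0.92 against a chance-correlation floor ⟨rs²⟩ of 0.07 from
Y-scrambling) and generalizes to the diversity-selected test set
(q² 0.80), while the linear PLS underfits the bilinear log P dependence
(train r² 0.68). The criteria verdicts in the same file show which of the
stringent acceptance checks each model passes per set.

Evaluating the published four-descriptor model on raw descriptor values:

```bash
twoqsar published-pls --input example.csv
```

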