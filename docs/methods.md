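# Methods

This note records the models, the numerical choices, and the reasoning
behind the design decisions that were genuinely open.

## Response and units

The permeability coefficient is `Kp = J_ss / ΔC_v` in cm/h and is modelled
as `log10 Kp`. Some sources write the logarithm as "pKp" without negating;
this package stores the *signed* log10 value (negative for slow permeants)
and never negates. No unit-conversion layer is provided: inputs are
expected in cm/h.

## Preprocessing cascade

1. **Missing values.** A descriptor missing more than one value is
   dropped; a single missing entry is imputed with the fitting-set column
   mean (the imputation is recorded in the JSON-lines provenance log).
   The choice of column-mean imputation is ours; with at most one gap per
   retained column the influence on any downstream statistic is
   negligible.
2. **Invariance.** Descriptors with fewer than two distinct values or
   sample variance ≤ 1e−12 are dropped (they carry no discrimination and
   break autoscaling).
3. **Collinearity.** Pairwise squared Spearman rank correlations (average
   ranks on ties) above 0.64 are resolved from the most correlated pair
   downward; within a pair the member with the lower |rank correlation
   with the response| is dropped, ties going to the lexicographically
   later name for determinism. The threshold is strict (`> 0.64`): a pair
   at exactly 0.64 survives. Because resolution only ever removes columns,
   a single pass over pairs sorted by descending ρ² is sufficient, and the
   result is insensitive to input column order whenever pair ρ² values are
   distinct.
4. **Autoscaling.** Each column is centered and scaled to unit *sample*
   standard deviation (n−1 denominator). The constants are stored so test,
   outlier and external compounds are always transformed with the
   training-set parameters (`apply_normalization`), never their own.

**Ion classes.** The four pKa-based classes overlap as usually stated
(a single-pKa compound is simultaneously "neutral" by one clause and
acid/base by another). We apply a fixed precedence that turns the clauses
into a partition: empty list → neutral; strongest acid-tagged pKa > 7
together with strongest base-tagged pKa < 7 → zwitterion; all pKa ≤ 7 →
acid; all pKa ≥ 7 → base; anything else → neutral.

## Partitioning

Compounds are projected onto principal components of the autoscaled
descriptor matrix. Structural outliers are flagged by thresholds
(`N_rot ≥ 8` or `N_O ≥ 11`); an optional Mahalanobis rule
(distance above the χ² 0.975 quantile in PC space) operationalizes
"inspection of the chemical space" reproducibly. The remaining compounds
are split at a train fraction of 0.8; the training size is
round-half-away-from-zero of `fraction × n` (91 → 73). The test set is
chosen by greedy max-min (farthest-point) selection in score space with a
seeded start — a deterministic surrogate for proprietary diverse-subset
pickers. Note that farthest-point test selection is deliberately an
*extrapolation stress test*: it concentrates the convex hull of the
chemical space in the test set. Distribution similarity between sets is
reported as two-sample Kolmogorov–Smirnov statistics plus shared-bin
histogram densities.

## Descriptor selection

Stage one is a plain genetic algorithm over fixed-length binary descriptor
masks: tournament selection (size 2), uniform crossover, bit-flip mutation
at rate 1/p, one elite, and a repair step keeping subset sizes inside the
configured range. The fitness functional is pluggable and defaults to the
cross-validated q² of an ordinary least-squares fit on the masked columns.
Population size and generation count are configuration, not doctrine: the
search role is fast subset screening, and any commercial implementation's
internals (spline basis functions, proprietary scoring) are out of scope.
Stage two is recursive feature elimination: every leave-one-descriptor-out
subset is scored, the descriptor whose removal hurts the least is purged
(exactly one per outer iteration, ties dropping the lexicographically
later name), down to the target size.

## HSVR

Members are ε- or ν-SVR models with the RBF kernel
`exp(−γ‖u−v‖²)` (scikit-learn's libsvm backend, solver tolerance 1e−3 —
the dual solver is deterministic, so no seed is involved in a single fit).
The hyperparameter lattice defaults to C ∈ 2⁻⁵…2¹⁵ and γ ∈ 2⁻¹⁵…2³ in
steps of ×4, ε ∈ {0.01, 0.05, 0.1, 0.2} or ν ∈ {0.25, 0.5, 0.75}. Two
grid-search modes exist because the original selection protocol is
ambiguous about whether test-set information entered member selection:
`grid_search` scores on an explicit held-out set (mirroring a
test-set-scored protocol), `grid_search_cv` scores by seeded k-fold
cross-validation on the training rows and is the default in the pipeline
— the honest, leakage-free choice. Ties prefer smaller C, then smaller γ,
then smaller ε (larger ν).

Ensemble assembly is parsimony-governed: all one-member combinations are
judged before any two-member combination, and the search stops at the
first size with a passing combination, so an (m+1)-member ensemble is
never evaluated when an m-member one suffices. The evaluation trace is
logged and attached to the result so the ordering is auditable. A
combination is judged by the stringent criteria checker applied to its
training and test prediction sets; combinations are screened on their
member-mean predictions (cheap and monotone with the stacked model's
quality), and the meta-SVR is fitted once on the winning ensemble: the
n×m matrix of member predictions on the training rows is the meta input,
the meta configuration is chosen from its own grid by cross-validated q²,
and the final model predicts by stacking member outputs through the meta
machine. When no combination passes at any size the search raises an
error carrying the best-found diagnostics; the end-to-end pipeline can
optionally (default) continue with that best-found ensemble, recording
the fallback in the manifest, so a run always produces a fully validated
model object alongside its criteria verdicts.

## PLS

`fit_pls` fits NIPALS PLS for k = 1…max_components (default min(p, 10),
capped at min(n−1, p)), scores each k by pooled out-of-fold q² over seeded
folds, keeps the maximizer, and collapses the winner to an affine form
(intercept + per-descriptor weights). For full-rank X with k = p the
coefficients coincide with OLS (checked against the normal equations in
the tests). The published four-descriptor skin model is shipped as a
fixture evaluating its printed constants exactly; whether those constants
apply to raw or autoscaled descriptor values is not recorded with the
model, so the fixture applies the affine form to whatever values are
supplied and this ambiguity is flagged here.

## Validation battery

With residuals Δi = yi − ŷi: RMSE divides by n; MAE is the mean |Δ|; `s`
is the *sample* standard deviation of the residuals (n−1) — the quantity
is not defined precisely in common usage, and this is the interpretation
used throughout; Δ_max is the largest |Δ|.

`r_squared` computes `1 − ΣΔ²/Σ(yi − c)²`. The centering constant c is
the **observed** mean by default (the conventional definition, matching
the QSARINS lineage of external metrics); centering on the **predicted**
mean — which some texts print — is available behind the
`centering="predicted_mean"` flag. Both are exercised in the tests.

External sets get qF1² (denominator centered on the training mean ⟨y_TR⟩),
qF2² (centered on the external mean), and qF3², implemented exactly as the
per-sample-normalized form `1 − (ΣΔ²/n_EXT) / (Σ_EXT(yi − ⟨y_TR⟩)²/n_TR)`
— note the denominator sum runs over the external set; the prediction-set
container therefore carries only ⟨y_TR⟩ and n_TR, not the training
responses. CCC is Lin's concordance coefficient, symmetric in its
arguments and sensitive to location/scale shifts.

Through-origin statistics follow the Golbraikh–Tropsha formulation:
k = Σyŷ/Σy² (predicted on observed, no intercept),
r0² = 1 − Σ(ŷ − ky)²/Σ(ŷ − ⟨ŷ⟩)², and r0′² with the axes swapped. The rm²
family defaults to `rm² = r²(1 − |r² − r0²|)` (`as_printed`); the original
Ojha definition with the square root of the gap is selectable
(`variant="sqrt"`). ⟨rm²⟩ and Δrm² are the mean and absolute gap of the
pair.

The stringent criteria checker evaluates, per set: every available
r²-family coefficient ≥ 0.70; |r² − q²_cv| < 0.10 (training only);
(r² − r0²)/r² < 0.10 with 0.85 ≤ k ≤ 1.15; |r0² − r0′²| < 0.30;
rm² ≥ 0.65; ⟨rm²⟩ ≥ 0.65 with Δrm² < 0.20; CCC ≥ 0.85 (where a CCC is
computed). Criteria inapplicable to a set are reported as
not-applicable and excluded from the overall verdict. Strict inequalities
are evaluated at printed precision (values rounded to 12 digits first) so
that, e.g., a gap of exactly 0.10 arising from printed two-decimal inputs
fails `< 0.10` as written rather than passing through float
representation error.

Internal validation: `kfold_cv` pools seeded out-of-fold predictions and
scores them once (10 folds by default); `y_scramble` permutes the
responses, refits with unchanged descriptors, and reports the mean
training ⟨rs²⟩ over 25 repetitions by default. The scrambling control must
refit the *same* model family whose unscrambled r² is quoted — for the
HSVR benchmark that means refitting members and meta with their selected
configurations on each permuted response vector.

## Synthetic data

The generator draws log P ~ U(−2, 7); V_m ~ N(0, 1);
⁰χ = r·V_m + √(1−r²)·z with r = 0.98 so the size pair is near-collinear;
Jurs_PPSA_1 ~ N(0, 1); a Bernoulli(0.3) subgroup label; and integer
N_rot/N_O counts (Poisson(3) with a 5% heavy-tail bump) so a few rows trip
the structural outlier thresholds. The response is a continuous hinge in
log P — slope +0.5 below the breakpoint at 4, −0.4 above — plus a size
term (−0.5·V_m), a subgroup-signed polarity term (±0.05·Jurs_PPSA_1), an
intercept of −2.5 (placing values on a realistic log10 cm/h scale), and
N(0, 0.3) noise. The hinge realizes bilinearity with the simplest
continuous functional form; the effect sizes were chosen once so that a
single global linear model visibly underfits while the signal-to-noise
ratio stays realistic for permeability data, and they are all
configurable. The generator emulates the *statistical* structure of real
descriptor tables, not their chemistry: descriptors are Gaussian/uniform
rather than heavy-tailed and mutually dependent, there is no assay
noise heterogeneity, and no chemically valid structures are produced —
so passing tests demonstrate correct machinery and recoverable structure,
not predictive validity on laboratory data.

`hsvr_recovery_benchmark` is the toolkit-level restatement of the central
modelling claim: on generated data (n = 300), member SVRs restricted to
{log P, V_m}, {log P, ⁰χ}, {log P, Jurs_PPSA_1} — grid-searched by 5-fold
CV on a random 4:1 split and stacked — reach test q² ≈ 0.9, beating a
single least-squares fit on all four descriptors by ≈ 0.2 q² units, while
Y-scrambling holds ⟨rs²⟩ near 0.06 against a training r² of ≈ 0.9. A
random split (not the farthest-point split) is used here because the
claim concerns generalization within the sampled space, not extrapolation
to its hull. Problem sizes in the automated checks (n = 300, 5 seeds,
moderate grids) were chosen to exercise the full machinery at desk scale.

## Known limitations

- Descriptor *computation* is out of scope: the package consumes numeric
  descriptor tables and never derives descriptors from structures.
- The published headline statistics of the original 96-compound skin
  study are not reproducible here because the compound-level descriptor
  values live in an appendix that is not machine-readable; the package
  instead verifies every piece of recomputable arithmetic (model
  constants, rm² arithmetic, criteria patterns, partition sizes) and the
  full method on synthetic data.
- One printed Δrm² entry of the published PLS outlier column (0.24) is
  inconsistent with its own printed rm² pair (0.38, 0.63 → 0.25); the
  recomputed value is asserted and the discrepancy documented rather than
  reconciled.
- Applicability-domain leverage analysis and bootstrap confidence
  intervals are not implemented.
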