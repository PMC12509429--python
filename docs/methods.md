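# Methods

This note documents the models, default parameters, numerical choices and
known limitations of the `gapdml` pipeline. It describes what the code
computes; every empirical number quoted here is produced by the test suite
or the `analysis/` drivers.

## Outcome: the standardized intention–behavior gap

PARS-3 activity scores are the product of three ordinal grades. The printed
convention constrains only the maximum (100); the package codes intensity
1–5, duration 0–4 and frequency 1–5 so that 5·4·5 = 100, with the ranges
configurable (`gap.DEFAULT_RANGES`). The outcome is

ΔZ = (Ideal − Actual) / σ_actual,

where σ_actual is the SD of actual scores over the analyzed sample.
σ_actual uses the n−1 (sample) denominator by default; the population
convention is available and recorded on the result, since the choice only
rescales every ΔZ by one constant. Negative raw gaps (actual above ideal)
are permitted and propagate. The un-normalized difference Z is emitted
alongside ΔZ for benchmarking.

## Measurement model and validation

Constructs are measured by 7-point Likert item blocks and scored as item
means. Standardized loadings are **inputs** (the instrument's calibration,
stored in `gapdml.instruments`), not estimates: AVE and CR are exact
functions of λ, and no confirmatory factor model is fitted. Cronbach's α is
computed from observed items; KMO uses anti-image partial correlations from
the inverse correlation matrix (defined as 0 for an exact identity matrix,
avoiding 0/0); Bartlett's χ² uses the standard −(n−1−(2p+5)/6)·ln det R
statistic. Reporting rounds half-away-from-zero to 3 decimals.

Two published AVE values (BAR, PR) and three CR values (AT, EE, UI) are not
reproducible from their own printed loadings under the standard formulas
(e.g. the BAR loadings give AVE ≈ 0.458); the package anchors its checks on
the self-consistent rows only.

Encoding: continuous predictors are z-scored (ddof 0, so the encoded
columns have SD exactly 1 and the transform is idempotent); nominal
predictors (Sex, Career, PA_organize) are one-hot encoded with all levels
kept for reporting and the first level dropped in model matrices. The
pairwise |r| < 0.60 screen is a diagnostic warning, not a hard failure;
within-group one-hot pairs are excluded from it because their collinearity
is by construction.

## Synthetic survey generator

The generator defines the study conditions for every test:

- **Items.** item = λ·F + √(1−λ²)·ε with standard-normal factor and unique
  noise, discretized to 7 levels by equal-probability normal quantile cuts
  (preserves rank correlation with the factor without extra parameters). A
  continuous-item mode exists for loading-recovery checks, where the
  empirical item–factor correlation approaches λ (max deviation < 0.03 at
  n = 5000 over 20 seeds, verified in the suite).
- **Latent correlations.** 0.30 within a theory block (HBM or UTAUT), 0.15
  across, which keeps all pairwise predictor correlations comfortably under
  the 0.60 screen.
- **Covariates.** Sixteen ordinals are drawn from discretized-normal
  categorical distributions whose (μ, σ) are moment-fitted to the published
  means/SDs; exact cell probabilities are a config default, not a data
  claim. BMI is Gaussian. The published coding of Sm_number (1–3) cannot
  carry its published SD of 1.152 (the maximum on that support is 1.0);
  the package codes it 0–3 with 0 = non-user, mirroring Sm_duration.
- **PARS-3 triples.** Actual grades follow skewed categorical
  distributions; ideal = actual + truncated binomial increments over the
  remaining headroom, guaranteeing Ideal ≥ Actual componentwise. Zero
  inflation rates give ΔZ ≡ 0 downstream.
- **Outcome.** A structural specification on the z-scored predictors:
  signed linear coefficients taken from the reference effect pattern
  (BAR +0.186, SE −0.157, UI −0.118, SS −0.076, BEN −0.116,
  Midnight +0.108, PN −0.095, SI −0.026); an inverted-U curvature on UI
  (amplitude 0.15, centered at 0 SD — pure curvature, so UI's average
  marginal effect stays at its linear coefficient while the combined curve
  peaks at an interior point); a −0.25 threshold drop on SS above +0.5 SD;
  a mild U on SI (amplitude 0.03, center +0.8); a +0.08 SE×UI interaction
  (the UI effect is strongest when self-efficacy is low); Gaussian noise
  with SD 0.30, which puts a flexible learner's achievable R² near the
  0.6 range a realistic survey model attains and leaves the boosted-tree
  vs OLS ordering clearly resolvable.

Two outcome modes: `direct` (default) emits the structural signal + noise,
giving exact ground-truth coefficients for estimator recovery tests;
`pars3` drives the ideal-inflation with the structural signal and computes
ΔZ from the generated triples, so the outcome genuinely passes through the
PARS-3 arithmetic (at the cost of only approximate ground truth).

What the generator does **not** emulate: response styles (acquiescence,
straight-lining), item-level missingness, the real joint distribution of
the survey population, and any dependence structure beyond the block
factor model. Passing tests therefore certify the estimators and the
pipeline mechanics, not claims about real respondents.

## Predictive benchmark

Five families (OLS, SVR, decision tree, random forest, gradient boosting)
are compared on held-out MSE/RMSE/MAE/R² over repeated stratified 80:20
splits; stratification of the continuous outcome uses decile bins, falling
back to a plain shuffle when bins are too small. Grid search is exhaustive
CV over grids bracketing the tuned boosted-tree configuration
(300 rounds, depth 5, η 0.05, subsample 0.8, colsample 0.9, λ 3, α 0.1,
min_child_weight 3, γ 0.01), minimising mean CV MSE with ties broken by
grid order; 5-fold CV is the default (10-fold supported). The leaderboard
aggregate is invariant to seed order, and a family that fails to fit is
recorded without aborting the comparison.

## Shapley attribution

The interventional value function with an empirical background (default:
up to 200 rows at a fixed seed) is computed exactly over all 2^p
coalitions for p ≤ 15; the permutation-sampling estimator is unbiased for
the same quantity and reports Monte-Carlo standard errors. The enumeration
oracle is the definition of correctness — the sampler, and any faster
path, is certified against it in the suite (axioms: efficiency, symmetry,
dummy; linear closed form φ_j = w_j(x_j − mean background_j)).
Importance is mean |φ| with stable tie-breaking; dimension sums aggregate
named groups (psychological cognition BAR+SE vs smart-sport UI+SS). A
split-gain ranking of the fitted booster is emitted alongside the Shapley
ranking with their top-10 overlap, since the two orderings need not agree.
Dependence curves use LOWESS (tricube local linear smoothing; span 0.6 and
2 robustness iterations by default — no smoother parameters are published)
evaluated on the sorted unique feature values.

## Double machine learning

Partialling-out with K-fold cross-fitting (default K = 5; the published
fold count is unstated): each observation's nuisance predictions ĝ(W), ĥ(W)
come from models trained on the other folds. The treatment equation is
taken as e_t = T − ĥ(W) with ĥ(W) = E(T|W); the source prints Y in both
residual definitions, which would make θ ≡ 1, so the standard
partialling-out form is implemented. θ is reported both as the mean of
per-fold slopes (default, matching the printed averaging formula) and as
the pooled residual regression; the pooled estimate satisfies
⟨e_t, e_y − θ̂·e_t⟩ = 0 to machine precision. Nuisances default to the
tuned boosted-tree configuration; a linear nuisance is used in the
Monte-Carlo suites where the generating process is linear (consistent and
two orders of magnitude faster). Treatments are z-scored composites, so θ
is an effect per 1 SD of treatment.

Inference: pair-resampling bootstrap of the residuals (default B = 5000;
the Monte-Carlo suites use B = 150–500 for speed), SE = replicate SD, 95%
CI = θ ± 1.96·SE. Resampling residual pairs after cross-fitting keeps the
cost at desk scale; a full-pipeline bootstrap that refits the nuisances
per replicate is available behind `full_pipeline_bootstrap=True`. The
suite verifies calibration directly: over 200 replications of the linear
design (n = 2000, 8 treatments), mean |θ̂ − θ| < 0.05, all signs correct,
and CI coverage within [0.90, 0.98].

Note that with non-linear terms present the partial-linear θ estimates a
variance-weighted average marginal effect: in the default design the SS
threshold contributes its average slope, so θ_SS exceeds |−0.076| in
magnitude (visible in `analysis/06_estimate_ates.py`). This is a property
of the estimand, not an estimator defect.

Subgroups are formed at the median of the split variable with ties to the
lower group (rule recorded on the result); each side must reach 250
respondents (configurable floor) or the analysis is refused. The
per-subgroup "R²" is the out-of-fold outcome-nuisance fit averaged over
treatments — one concrete interpretation of a reported statistic whose
defining model is unstated.

## Pipeline and problem sizes

`pipeline.run_pipeline` sequences the stages with seeds derived from one
run seed via a seed sequence, rejects unknown configuration keys, enforces
the bootstrap floor (100) and writes CSV/JSON artifacts plus a provenance
block (config hash, stage seeds, library versions). Deterministic
artifacts reproduce byte-for-byte under an identical configuration.

Default problem sizes were chosen to keep each stage at desk scale: the
analysis drivers use n = 1334 respondents; the Monte-Carlo recovery suite
uses 200 replications at n = 2000 with linear nuisances; attribution
drivers sample 150 instances against a 100-row background with 40
permutations. Scaling any of these up is a configuration change, not a
code change.

## Limitations

- The absolute metric values of the reference analysis (leaderboard
  metrics, effect sizes, Shapley magnitudes) depend on unavailable survey
  data and are not reproduction targets; only structural and qualitative
  properties are asserted.
- No honest/generalized causal forest: heterogeneity is examined by
  subgroup refits of the partial-linear estimator, not by a forest over
  effect modifiers.
- The residual-pair bootstrap ignores nuisance-estimation variability
  (first-order negligible under cross-fitting, but the full-pipeline
  bootstrap exists for when it is not).
- Exact Shapley cost grows as 2^p; above 15 features only the sampling
  estimator is practical.
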