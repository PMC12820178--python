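# Methods

This note records the statistical procedures implemented in `metabsig`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
choices that matter for reproducing results.

## 1. Synthetic cohorts with planted truth

`generate_cohort(CohortConfig)` draws, per sample i:

- latent adiposity `A_i ~ N(0,1)`;
- log-abundances `L_ij = w_j A_i + ε_ij`, `ε ~ N(0,1)`, with `w_j = 0` for
  non-signal metabolites and `|w_j| ~ U(signal_weight_range)` (default
  0.3–0.9, random sign) for the `n_signal` signal metabolites; stored
  abundances are `exp(m_j + L_ij)` with per-metabolite levels
  `m_j ~ U(12, 18)`, i.e. log-normal, so the pipeline's log transform is the
  exact inverse;
- BMI from the standardized true-weight composite `c = Lw`:
  `BMI = μ + σ·(√r² · z(c) + covariate part + noise)` with the noise
  variance set so the composite explains exactly `signal_r2` of the BMI
  variance. This makes `signal_r2` the *ceiling* any fitted metabolite
  score can reach, which is the operationally meaningful calibration for
  score-recovery and transfer experiments. Defaults μ = 24.6 kg/m²,
  σ = 4 kg/m², r² = 0.4;
- binary outcomes from logits `α + β_BMI·z(BMI) + Σ_med β_med·z(L_j) +
  covariate terms`, with `α` solved by root-finding so the marginal
  prevalence matches the configured value exactly. Each mediator's outcome
  coefficient carries the sign of its loading, so all mediated paths
  contribute risk in the same direction. Default prevalences sit inside
  the ranges the two source cohorts report (GDM 5%, preeclampsia 3.5%,
  cesarean 22%, induction 20%, maternal antibiotics 32%);
- covariates shaped like the cohorts' adjustment set (a continuous social
  circumstances score, binary smoking and child sex, three dietary
  principal components), entering both BMI and outcome models so they
  confound;
- 2% of samples are duplicated twin pregnancies (identical maternal record,
  shared `family_id`), exercising the de-duplication rule;
- missingness is MCAR at `missing_rate`, or outcome-dependent with
  per-sample odds multiplied by `exp(γ·outcome)` (γ = −0.5 by default,
  emulating complication-linked non-random missingness).

Default dimensions are 700×640 (the discovery-cohort scale); the test
suite and pipeline defaults use 200×120 to keep runtimes in seconds to
minutes.

What the generator does **not** emulate: real Metabolon abundance
distributions and batch effects, metabolite–metabolite correlation beyond
the single latent factor, the cohorts' true covariate joint distribution,
or any longitudinal structure. Passing tests therefore demonstrate that the
pipeline recovers known truth under its own modelling assumptions, not that
those assumptions hold in real cohorts.

### The mediator-recovery study condition

Backward elimination can only separate mediators from non-mediating signal
metabolites when removing a non-mediator genuinely raises the population
ACME. Under a single shared factor with homogeneous loadings it does not:
every signal metabolite carries the factor, the composite score channels
the mediation through the factor itself, and the population ACME is almost
flat in the subset (verified numerically at n = 200,000: total span ~0.001).
The "strong effects" recovery condition therefore uses heterogeneous
loadings — mediators at 0.75–0.85, non-mediating signal metabolites at
0.25–0.35 (`mediator_weight_range` / `signal_weight_range`), mediator
log-OR 0.7 per SD, `signal_r2 = 0.85` — under which the population ACME is
monotone in the removals and the procedure has actual signal to follow.
This geometry was chosen by analysing the population-level target
functional, then frozen.

## 2. Preprocessing

Order: missingness filter → twin de-duplication → log transform →
random-forest imputation on the log scale → centre/scale. Rationale for
imputing on the log scale: the imputation model sees approximately Gaussian
columns, and no back-transform is needed downstream.

- **Filter**: metabolites with *strictly more than* 1/3 missing cells are
  dropped (a column at exactly the threshold stays). Survivor order is
  preserved.
- **Random-forest imputation** (`ForestImputer`): missForest-style —
  mean-initialise, revisit columns in descending missingness (ties by
  position), re-predict each incomplete column from all others with a
  random forest fitted on its observed rows, and stop when the normalised
  change in imputed values increases (returning the previous iterate) or
  after `max_iter` (default 10) sweeps. Observed cells are never altered
  (asserted cell-wise in tests). Defaults: 100 trees, `min_samples_leaf`
  5; the pipeline uses 25–30 trees, which loses nothing measurable on the
  synthetic cohorts and dominates the pipeline's runtime budget.
- **Covariate imputation** (`IterativePCAImputer`): iterative rank-1
  truncated-SVD imputation of the centred/scaled table, converging when
  imputed cells move < 1e-6; categorical columns are one-hot expanded and
  re-collapsed to the arg-max indicator. This is the plain (unregularised)
  variant of regularised iterative PCA; with one component and modest
  missingness the ridge term makes no practical difference on our data.
- **Standardisation**: natural log, per-column mean/SD (SD with n−1);
  parameters are stored and can be replayed exactly on external data.
- **Twin de-duplication**: one pregnancy record kept per `family_id`,
  chosen by a seeded uniform draw.
- **Missingness diagnostic**: logistic regression of each outcome on a
  per-sample missingness indicator over a metabolite subset ("any missing",
  or z-scored count via `predictor="count"`); a constant predictor is an
  error, not a silent OR of 1.

## 3. Sparse PLS scoring

One component only. The direction is the soft-thresholded correlation
vector (threshold `η·max|c|`), normalised; the score is regressed on the
response for prediction; weights are sign-fixed so the score correlates
positively with BMI. η = 1 thresholds everything (the maximum attains the
threshold exactly) and is rejected at fit time; during tuning an all-zero
fold falls back to predicting the training-fold mean so the grid stays
evaluable, and if η = 1 ever wins the grid the refit drops to the best
η < 1.

Tuning: repeated (default 10×) 5-fold CV over η ∈ {0, 0.1, …, 1.0}.
Within each fold, both the metabolite matrix and the response are
standardised on training rows only (no leakage); the final reported model
standardises on the full training cohort. RMSECV is reported in
response-SD units; R²CV = 1 − SSE/SST over held-out predictions, which
matches 1 − RMSECV² up to fold-mean-centering. Folds are stratified by
response tertile (configurable off) to stabilise small-n estimates.
Selection takes the lowest RMSECV, ties resolving to the largest (sparsest)
η; `selection="tolerance"` optionally takes the sparsest η within 1% of
the minimum, a useful parsimony rule on the very flat RMSECV profiles
sparse-PLS produces, but it is not the default.

Transfer: the model is re-tuned and refitted from scratch on the training
cohort restricted to the metabolite panel shared with each external cohort
(one model per external panel). External scores are `Z_ext·w` with the
external cohort standardised within itself, then z-scored within cohort —
so per-SD odds ratios are comparable across cohorts.

## 4. Complication associations

Logistic regressions with z-scored exposures, Wald z-tests, and 95%
intervals at z = 1.959964. Numerical policy: Newton with deviance
tolerance 1e-8 and 100 iterations; if Newton stalls or its Hessian goes
singular mid-iteration the fit retries with L-BFGS; separation is reported
as an explicit error when a perfect-separation warning fires or any
|log-odds| exceeds 15. Rank deficiency is detected before fitting and the
error names the aliased columns. The association table carries one row per
(outcome, exposure) with OR, CI, p and n, deliberately without any
multiple-testing adjustment; an `on_error="note"` mode records inestimable
cells (rare outcomes at desk scale) as annotated NaN rows instead of
aborting. LRTs use 2·Δll against χ² with df = parameter difference;
identical models return statistic 0, p = 1.

## 5. Pathway enrichment

Upper-tail hypergeometric probability P(X ≥ k), inclusive of the observed
count — the standard over-representation convention. The background
defaults to the metabolite panel available to the model (e.g. the overlap
set), not the full annotated universe; `background_ids` overrides.
Correction multiplicity m is the number of sub-pathways actually tested
(those with ≥ 1 selected member; `all_pathways=True` widens it).
Benjamini–Hochberg q-values come from the step-up rule; Bonferroni is
min(1, p·m). Unannotated background metabolites fall into an "Unassigned"
pathway rather than being dropped.

## 6. Quasi-Bayesian mediation and backward elimination

Estimand and algorithm: see README §methods. Implementation specifics:

- exposure contrast: control = mean, treat = mean + 1 SD on the z-scored
  BMI scale, matching the per-SD reporting convention (configurable);
- effects are on the probability (risk-difference) scale, averaged over
  the two exposure arms; `total = acme + ade` holds *exactly* per draw by
  the identity `½(δ(1)+δ(0)) + ½(ζ(1)+ζ(0)) = τ`, and tests assert it to
  1e-12;
- parameter draws use an eigen-decomposition square root of the symmetrised
  covariance with negative eigen-noise clipped at zero, which tolerates the
  near-singular information matrices that rare outcomes produce;
- mediator residual-noise draws are shared between the treated and control
  arms of a draw (common random numbers), removing the noise term from the
  ACME difference entirely;
- `prop_mediated` is reported only when ACME and total share a sign;
- backward elimination evaluates every candidate subset in a trace with
  **one** common simulation seed: candidates within an iteration are
  compared like-with-like, and the committed candidate's ACME is exactly
  the incumbent value of the next iteration, so the keep/remove rule is
  free of cross-seed Monte-Carlo noise and the recorded ACME sequence is
  strictly increasing by construction. (Per-iteration seeds were tried
  first; the cross-seed noise in the stopping rule caused premature stops.)
- stopping: strict increase of the ACME point estimate, no look-ahead;
  a `min_size` guard (default 2) keeps the mediator model non-degenerate,
  and a model already at `min_size` returns a zero-step trace;
- composite scores reuse the fitted sparse-PLS weights restricted to the
  remaining subset, re-standardised — the score is a fixed weighting, not
  refitted per step (a refit-per-step variant would confound "removing a
  metabolite" with "re-estimating the weighting");
- default `n_sim` = 10,000 per evaluation; the pipeline and tests use
  500–2,000, which at the test sample sizes leaves Monte-Carlo error well
  below the planted effects.

The full-vs-subset comparison fits the outcome on full score + BMI +
covariates, with and without the subset score, df = 1 LRT.

## 7. Pipeline and reproducibility

`run_pipeline(RunConfig)` executes simulate → preprocess → score →
associate → enrich → mediate; each stage writes its outputs before the next
starts, a failing stage halts the run naming itself, and disabled stages
are recorded as skipped. One global seed fans out to per-stage seeds via
`SeedSequence.spawn`, so stages are independently reproducible; every
stochastic component (generator, fold assignment, forests, mediation draws)
is seeded from this tree, and two runs from the same seed produce
byte-identical models and reports. Cohorts are exchanged as UTF-8 TSV with
empty cells for missing values (tabs tolerate commas inside metabolite
names); models serialise to JSON with their standardisation parameters so
external scoring replays the training transform exactly.

Pipeline defaults are desk-scale: 200 + 200 samples, 120 metabolites (12
signal / 4 mediators), 3 CV repeats, `n_sim` = 500, 25–30 forest trees, and
the mediation outcome's prevalence raised to 10% so the outcome model has
enough events at n = 200; the cohort-scale configuration (700×640, 10
repeats, 10,000 draws, 2–5% prevalences) is reached purely through
`RunConfig`. The acceptance script uses an intermediate 500 + 500 × 120
configuration.

## 8. Known limitations

- The single-factor metabolome is the strongest simplification: real
  metabolomes have block-correlation structure that affects both sparsity
  tuning and elimination behaviour.
- RMSECV profiles are nearly flat over small η, so the lowest-RMSECV rule
  can keep many near-zero weights on noisy data; the tolerance selection
  rule is provided for users who prefer parsimony.
- Sequential ignorability — no unmeasured exposure-outcome or
  mediator-outcome confounding — is assumed, not tested; no sensitivity
  analysis is implemented.
- No exposure–mediator interaction terms; the two mediation models are
  linear/logistic as specified.
- Desk-scale logistic models of rare outcomes can separate; the pipeline
  records such cells as inestimable rather than inventing estimates.
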