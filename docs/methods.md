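# Methods

`survimpute` is a simulation benchmark for single regression imputation of
missing baseline covariates when the analysis model is a Cox proportional
hazards regression on a right-censored time-to-event outcome. This note
documents the generating model, the imputation model, the scoring rules, the
numerical choices, and what the synthetic data do and do not emulate.

## The simulated trial

The generator emulates a two-arm phase III oncology trial in advanced
prostate cancer. Each subject carries 13 baseline covariates — seven
continuous (AGE, HGB, LALP, LPSA, TIME_HORMONE, YRSINCEDIAG, BMI), five
binary (PROG, PAIN, WHITE, CHEMO, MEAS_DIS) and one three-level performance
status (ECOG ∈ {0,1,2}) — plus a balanced randomized treatment indicator
ARM.

**Covariates.** All 13 covariates derive from one latent multivariate
normal draw with an exchangeable correlation matrix (default ρ = 0.2),
which induces dependence across the mixed types. Continuous margins are
affine transforms of the latent normals; categorical margins come from
inverse-transform sampling, thresholding the latent margin at
standard-normal quantiles of the configured category probabilities (a
binary covariate with event probability p is 1 when its latent margin
exceeds Φ⁻¹(1−p); ECOG uses the two cumulative cut points). The default
moments and probabilities (e.g. AGE ~ 68 ± 8 years, HGB ~ 12.5 ± 1.8 g/dL,
ECOG probabilities 0.35/0.55/0.10) were chosen once as clinically plausible
values for this disease setting and are fully config-driven; they are not
estimates from any real trial. ARM is a balanced permutation (⌊n/2⌋
treated), a design factor rather than a latent-Gaussian margin.

**Outcome.** Failure times follow a Weibull proportional-hazards model
S(t|x) = exp(−(t/λ₀)^k e^{x'β}) with shape k = 1.2 for both failure and
censoring. Six covariates carry nonzero true log-hazards (defaults
PROG 0.40, HGB −0.15, LALP 0.35, ECOG 0.45 per level, AGE 0.01 per year,
ARM calibrated); the remaining covariates enter the hazard with zero
coefficients. Censoring is an independent Weibull, so censoring is
non-informative by construction. Observed data are Y = min(T, C) and
δ = I(T ≤ C). Because T and C are continuous, ties occur with probability
zero.

**Calibration.** Three quantities are calibrated rather than set directly:

* *ARM effect*: under Weibull PH the treatment effect rescales every
  failure time by e^{−β_ARM/k}, so the target arm medians (15 months
  experimental, 11 months control) fix β_ARM = −k·ln(15/11) ≈ −0.372 in
  closed form, independent of the covariate distribution.
* *Baseline scale λ₀*: the closed form λ = m(e^{lp}/ln 2)^{1/k} holds at a
  fixed linear predictor, but the *marginal* median over a random covariate
  mix differs from the median at the covariate means whenever other
  coefficients are nonzero. λ₀ is therefore set so the control arm's
  empirical marginal median on a 100,000–200,000-subject fixed-seed
  calibration draw equals 11 months; both arm medians then land on target
  to Monte-Carlo error (≈ ±0.05 months at n = 200,000).
* *Censoring scale*: the censored fraction P(C < T) is monotone decreasing
  in the censoring scale, so a bisection on one large pre-simulated cohort
  reaches the 10% or 30% target within ±0.005. At the 30% level this
  yields the familiar ≈140 events per 200-subject replicate.

**Missingness.** Exactly three covariates — PROG (binary), HGB and LALP
(continuous) — are made missing at random. Each target has a logistic
model on the complete baseline covariates and ARM (default slopes: 0.30
per ECOG level, 0.02 per year of AGE, 0.30 for measurable disease), with
the intercept calibrated by bisection so the cohort-mean missingness
probability equals the 5/10/15% target (achieved within ±0.5 points
empirically at n = 100,000). Masks are independent Bernoulli draws across
subjects and targets. The outcome never enters the missingness model:
probabilities are a deterministic function of always-observed covariates,
which places the mechanism in the MAR class by construction. True values
of masked entries are retained for exact restoration and oracle scoring.

## The imputation model

Each incomplete covariate X_j is regressed, on its observed rows, on

    w = [Z (10 complete baseline covariates), ARM, δ, Ĥ₀(Y)],

i.e. the complete covariates plus survival represented by the event
indicator and the baseline cumulative hazard evaluated at the observed
time — the hazard-augmented form recommended for survival outcomes. The
link g is the identity for continuous targets and the logit for the binary
target. The other two incomplete covariates are excluded from w, so the
design never contains missing entries and no chained conditioning is
needed.

Ĥ₀ comes from a Cox fit on the complete covariates only, using the
Kalbfleisch–Prentice (KP) product-form estimator at the all-zero covariate
reference (covariates are not centered; any scale shift in Ĥ₀ is absorbed
by the imputation regression's coefficients). KP is appropriate because
the simulated data are tie-free; the Nelson–Aalen/Breslow estimator is
also provided, and under the null model KP reduces exactly to −log of the
Kaplan–Meier curve — an identity the tests exploit as an oracle. When the
largest observation is an event, KP reaches −log(0) = ∞ at the last event
time; the design builder caps the hazard column at the largest finite step.
Optionally the hazard can be re-estimated on the imputed data and the
targets re-imputed (`h0_iterations`), stopping when the curve changes by
less than 1e-4 in relative sup-norm at the event times; the default is a
single pass.

**The five engines.**

* **GLM** — unpenalized linear / logistic regression.
* **LASSO** — ℓ₁-penalized fit; penalty chosen by 10-fold cross-validation
  with the one-standard-error rule (largest penalty whose CV error is
  within one SE of the minimum), predictors standardized internally.
* **MARS** — additive multivariate adaptive regression splines: forward
  selection of reflected hinge pairs max(±(x−k), 0) at marginal-quantile
  knots, backward pruning by generalized cross-validation with the
  additive-model penalty of 2 (see `survimpute/mars.py`). Binary targets
  are fit on 0/1 with predictions clipped to [0,1] as probabilities.
* **SVM** — RBF-kernel support-vector regression (continuous) or
  probabilistic classification via Platt scaling (binary); regularization
  C and kernel coefficient γ chosen by 10-fold CV grid search on log₂
  lattices (defaults C ∈ 2⁻³..2⁷, γ ∈ 2⁻⁷..2³).
* **RF** — random forest of 500 trees; the number of candidate split
  variables (mtry) is chosen to minimize out-of-bag error (squared error
  for continuous targets, Brier score for the binary target). The forest
  is fit to the same design w as every other method, keeping all five
  engines under the identical model form.

**Noise injection.** To avoid understating variability, a continuous
imputation is the model prediction plus a residual draw e ~ N(0, sd(X_obs))
where sd(X_obs) is the sample SD of the target's observed values; a binary
imputation is a Bernoulli draw from the predicted probability (an additive
Gaussian residual is ill-defined for a 0/1 variable; the Bernoulli draw
preserves the marginal distribution). Note the marginal-SD rule is
deliberately conservative — it injects more noise than the residual SD
whenever the model has explanatory power, which slightly attenuates
downstream coefficient estimates; this is a property of the benchmarked
procedure itself, not an implementation artifact.

## Scoring

Each method's imputed cohort is scored by refitting the six-covariate Cox
analysis model (PROG, HGB, LALP, ARM, ECOG, AGE; ECOG as one numeric
term) and comparing the estimates β̂ across S replicates to the known
truth β. With v indexing the six coefficients:

* **bias** = mean_{v,s} |β̂_vs − β_v| / |β_v| (average absolute
  proportional bias);
* **MSE** = mean_v [(Q̄_v − β_v)² + W_v + (1 + 1/S)B_v] / β_v², the
  Rubin's-rules combination of within-replicate variance W_v = mean(se²)
  and between-replicate variance B_v, plus squared bias, proportional to
  the squared truth;
* **MSPE** = mean_v (1/S)Σ_s (β̂_vs − β_v)²;
* **MAD** = mean_v median_s |β̂_vs − median_s β̂_vs| (no consistency
  constant);
* **mPCOV** = min_v (fraction of replicates whose Wald 95% interval
  β̂ ± z₀.₉₇₅·se contains β_v).

Proportional statistics refuse zero true coefficients rather than silently
dropping them. Ranking: within each (N, C) block, methods are ranked 1–5
per statistic at each missingness level (ties share the minimum rank;
lower is better except mPCOV, where higher coverage is better); the mode
of the three per-M ranks is the final rank (modal ties resolve to the best
rank), and a final rank of 1 or 2 counts as "good". Over 5 statistics ×
6 blocks each method accrues 30 final rankings.

## Reproducibility and problem sizes

Every stochastic step takes an explicit seed. Replicate seeds derive from
(root_seed, scenario index, replicate index, stream) via numpy
`SeedSequence`, so any single replicate can be re-run in isolation and
sequential or concurrent execution yields identical results. CV fold
assignment, SVM/RF tuning and noise draws use dedicated child streams, so
tuning randomness is independent of masking randomness.

The full-scale study (5000 replicates per scenario, full tuning grids)
is expressed by the default `ImputerConfig`/`GridConfig` and is
compute-intensive (the SVM grid search dominates, ~1 min per replicate at
N = 1000). The shipped tests and examples use desk-scale settings chosen
as such — reduced replicate counts (25–200), 3–5 CV folds, 2×2 SVM grids,
60–100 trees — which preserve every structural property (calibration
targets, determinism, completion contracts, ranking arithmetic) while
keeping runs to minutes. Monte-Carlo noise at these scales is visible in
the summary statistics, which is why the shipped checks assert calibration
targets, oracle identities and ordering trends rather than tabulated
statistic values.

## What the synthetic data do not emulate

The covariate distributions, correlation structure, true coefficient
vector and missingness slopes are plausible defaults, not estimates from
a real trial; absolute statistic values therefore depend on this
configuration and should be compared across methods, not quoted as
field estimates. Real trials also exhibit features the generator omits:
tied event times, informative or administrative censoring patterns,
joint/monotone missingness across covariates, outcome-dependent (MNAR)
missingness, and more than three incomplete covariates. Passing tests
demonstrate correctness of the machinery and the relative behavior of the
methods under MAR and proportional hazards — not performance guarantees
under violations of those assumptions.

## Known limitations

* Single imputation only; no multiple-imputation variance combination at
  the analysis stage (Rubin's rules appear only inside the MSE statistic).
* The MARS engine is additive (degree 1); hinge–hinge interactions are not
  constructed.
* The binary-target SVM uses Platt scaling, whose internal cross-fit adds
  its own smoothing; probabilities near 0/1 are pulled inward.
* KP's infinite terminal step is capped inside the imputation design
  (documented above); analyses that need the raw curve should use the
  `CumHazCurve` object directly.
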