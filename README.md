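# survimpute

Benchmarking **regression imputation of missing baseline covariates** when
the analysis model is a **Cox proportional-hazards regression** on a
right-censored time-to-event outcome.

Baseline covariates in survival studies are routinely incomplete, and
complete-case analysis discards subjects and biases estimates unless data
are missing completely at random. A practical alternative is single
regression imputation: predict each missing covariate from the observed
data and refit the analysis model. This package provides a full simulation
laboratory for comparing five imputation engines — GLM, LASSO, MARS, SVM
and random forest — all fitted to the same hazard-augmented imputation
model

&nbsp;&nbsp;&nbsp;&nbsp; g(E[X_j | w]) = w'β,&nbsp;&nbsp; w = [Z, ARM, δ, Ĥ₀(Y)],

where Z are the complete baseline covariates, ARM the treatment arm, δ the
event indicator and Ĥ₀(Y) the Kalbfleisch–Prentice estimate of the
baseline cumulative hazard at the observed time; g is the identity for
continuous targets and the logit for binary ones.

The pipeline is: simulate a two-arm oncology-trial cohort (13 correlated
mixed-type covariates, Weibull PH failure times calibrated to arm medians
of 15 / 11 months, independent Weibull censoring calibrated to 10% or
30%) → impose calibrated missing-at-random gaps in three covariates (PROG,
HGB, LALP at 5/10/15%) → impute with each method → refit the six-covariate
Cox model (PROG, HGB, LALP, ARM, ECOG, AGE) → score with five statistics
(average absolute proportional bias, Rubin's-rules proportional MSE, MSPE,
MAD, minimum 95% coverage) → rank methods per scenario block by modal
rank. See `docs/methods.md` for the complete model description.

Intended users are biostatisticians and methods researchers who want to
stress-test imputation strategies for survival analyses under controlled,
reproducible conditions.

## Worked example

`examples/` contains one short script per capability. Calibrating the
generator and simulating a large cohort (`examples/01_simulate_cohort.py`)
prints:

```
calibrated baseline scale : 37.252 months
calibrated ARM log-hazard : -0.3722
calibrated censor scale   : 38.000 months

experimental-arm median T : 15.10 months (target 15)
control-arm median T      : 11.07 months (target 11)
censored fraction         : 0.303 (target 0.30)
```

The ARM log-hazard −0.372 = −k·ln(15/11) is the treatment effect implied
by the two target medians under Weibull proportional hazards (shape
k = 1.2); the empirical arm medians and censoring fraction of a fresh
200,000-subject cohort hit their design targets to Monte-Carlo error.

Imputing one incomplete cohort with all five methods and refitting the
analysis model (`examples/04_impute_and_refit.py`, n = 500, 30% censoring,
15% missingness) prints the six log-hazard coefficients per method against
the truth:

```
      truth    GLM  LASSO   MARS    SVM     RF
PROG  0.400  0.399  0.374  0.354  0.379  0.410
HGB  -0.150 -0.103 -0.096 -0.103 -0.100 -0.106
LALP  0.350  0.414  0.386  0.401  0.397  0.390
ARM  -0.372 -0.233 -0.223 -0.226 -0.237 -0.226
ECOG  0.450  0.329  0.334  0.335  0.337  0.332
AGE   0.010  0.009  0.009  0.009  0.008  0.008
```

Deviations mix finite-sample Cox error with imputation error; a full
benchmark averages such fits over many replicates and ranks the methods
(`examples/05_small_grid.py`).

A thin CLI wraps the same library calls:

```bash
survimpute calibrate                 # print calibrated scales/intercepts
survimpute simulate --scenario 500,0.30,0.10 --out cohort.csv
survimpute run --reps 25 --methods GLM,LASSO --out results/
survimpute summarize --summaries results/summaries.csv
```

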