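# Methods

## The estimation problem

A small treated arm of ART-conceived singletons (~7% of the cohort) is
followed alongside a large spontaneously conceiving group. Couples who
conceive by ART differ systematically — older, higher income, more often
nulliparous, more endocrine comorbidity — so the crude contrast mixes
treatment effects with selection. The package attacks this from three
directions that rest on different assumptions: restriction (comparison
arms of putatively subfertile controls, emulating who would enrol in a
pragmatic trial of ART versus expectant management), standardization
(inverse-probability weights for treatment and censoring), and doubly
robust machine-learning estimation (C-TMLE). A parametric g-formula
layer then asks whether any treatment effect is carried by fetal
methylation, with a maternal-methylation negative control to test the
no-unmeasured-confounding assumption itself.

## Structural model

All mechanism analyses use one linear equation system with a shared
confounder vector W (maternal age, education, ethnicity, parity, height,
pre-pregnancy BMI, smoking exposure; household income; paternal height
and weight; child sex; polygenic risk score):

    FG  = b1·A             + Γ1'W + a1 + e1
    SBP = b2·A + b3·FG     + Γ2'W + a2 + e2
    GA  = b4·A + b5·FG + b6·SBP               + Γ3'W + a3 + e3
    CPG = b7·A + b8·FG + b9·SBP + b10·GA      + Γ4'W + a4 + e4
    Y   = b11·A + b12·FG + b13·SBP + b14·GA + b15·CPG + Γ5'W + a5 + e5

with independent Gaussian residuals. Assumptions: linearity, no
exposure–mediator interaction (the equations contain none), correct
causal ordering, and no unmeasured confounding of any arrow — the last
being exactly what the negative control probes. The negative-control
ordering places the maternal blood CpG first (it precedes the pregnancy
course), so its indirect effect sums every path through it; under the
fetal-imprinting hypothesis that sum is zero.

For this all-linear system the counterfactual contrasts have closed
forms by path tracing. Forward recursion gives each mediator's per-unit
treatment response `d_j = b_j^A + Σ_{i<j} b_{j,i} d_i`; backward
recursion gives outcome sensitivities `s_j = b_{Y,j} + Σ_{l>j} b_{l,j}
s_l`; then TE = `b_Y^A + Σ_j b_{Y,j} d_j` and NIE = `s_m d_m` for the
mediator of interest m. The g-computation engine is validated against
these identities to 1e-10 — they are the package's primary oracle.

## The synthetic cohort generator

The generator is first-class, tested code: it draws confounders from
realistic marginals (e.g. maternal age ~N(31, 5) years, height
~N(158, 5.6) cm, three ethnic groups), assigns treatment by a logistic
model on standardized confounders whose intercept is calibrated by root
finding so the expected treated fraction equals 83/1178, then simulates
mediators, fetal and maternal CpG residuals, and visit-level outcomes
through the structural system. Defaults: a −2.0 cm direct effect, a
−0.5 SD treatment effect on the fetal CpG, a 0.5 CpG→outcome
coefficient, and mediator paths of plausible clinical magnitude; residual
SDs 0.45 mmol/L (FG), 8 mmHg (SBP), 1.5 weeks (GA), 0.85 SD (CpG), 4 cm
(outcome). Outcomes are produced at 16 scheduled visits (0–78 months)
as a smooth growth curve plus the structural part scaled by a
visit-indexed multiplier that rises linearly with age (so arm
differences grow over follow-up, and the final visit carries the full
coefficients). Ground truth — coefficients, per-visit multipliers, and
closed-form TE/NDE/NIE — is recorded in the output metadata.

Missingness is applied last: logistic MAR models for covariate cells
(defaults emulate heavy paternal missingness ~35–37%, pre-pregnancy BMI
~9%, sparse sociodemographics) and a monotone per-visit dropout hazard
(~2%/visit, slightly lower for treated and educated mothers). Unobserved
values become NaN with an explicit `observed` flag; the pre-missingness
tables are never mutated.

One RNG stream is consumed in a fixed stage order (confounders →
treatment → flags → mediators → CpGs → outcomes → missingness), so a
seed reproduces the tables byte-for-byte.

What the generator does *not* emulate: non-Gaussian covariate joint
structure, time-varying confounding, measurement error, visit-level
outcome autocorrelation beyond the shared subject-level structural part,
and genotype LD beyond a toy block model. Passing tests therefore
demonstrate correctness of the estimators under the assumed model class,
not performance on real cohort data.

## Estimators: numerical choices

**MICE.** Default m = 10 chains, 10 cycles (5 in the demo pipeline);
initial fill by random observed-value draws. Continuous variables use
proper Bayesian draws — residual variance from a scaled
inverse-chi-square, coefficients from their sampling normal — so
between-imputation variance is not understated; binary and categorical
variables draw from fitted logistic/multinomial class probabilities
without parameter draws (a mild understatement of their imputation
uncertainty, acceptable for covariates that are mostly complete).
Outcomes are not used as imputation predictors by default. Convergence
is inspectable through per-variable mean traces. Predictors are
column-standardized internally purely for solver conditioning.

**IPW.** Treatment and censoring models are unpenalized logistic fits on
complete cases. Fitted treatment probabilities within 1e-3 of 0 or 1 are
clipped with a warning; if more than 5% of them are that extreme the fit
errors out as a positivity violation. Combined weights are truncated at
the [1st, 99th] percentiles by default (off-switchable) because a
~7%-treated cohort makes extreme weights likely. All weighted fits use
HC0 sandwich variance, since weighting invalidates the OLS variance.

**SuperLearner.** Five folds; out-of-fold predictions per learner;
meta-weights by non-negative least squares, normalized to sum to one
(equal weights if NNLS degenerates to all-zero). A learner that throws
during cross-validation or refit is dropped with a logged warning and
the weights renormalized. Desk-scale determinism: the neural net is one
hidden layer of width 5 with a fixed seed and iteration cap behind a
standardizer; boosted trees are depth ≤ 3, 100 rounds.

**C-TMLE.** Outcome min–max scaled to [0, 1] with recorded bounds;
initial predictions clipped to [0.005, 0.995] before the logit;
propensity estimates bounded to [0.01, 0.99] before forming the clever
covariate (unbounded g makes H explode with few treated). The greedy
search starts from the intercept-only propensity (the marginal treated
fraction), adds one encoded covariate at a time, scores each candidate
by 5-fold cross-validated squared error of the fluctuation-updated Q̄ on
the scaled outcome, breaks ties by covariate order, and stops at the
first non-improvement. The propensity inside the path is a plain
logistic regression on the current subset (not the ensemble) —
"sequentially adding covariates" describes a single iterated model. The
fluctuation epsilon solves the intercept-free quasi-binomial score
equation by Newton iteration; at convergence `mean[H·(Y_sc − Q̄*)]`
vanishes below 1e-8, which the tests assert. The SE is the sample SD of
the efficient influence function over √n, rescaled by the outcome span;
min–max scaling makes the ATE exactly invariant to affine outcome
transforms. Covariate columns are standardized for the logistic solver
(affine-invariant for predictions).

**G-computation.** Counterfactuals are propagated as conditional means
(no residual draws): for a linear system this equals the draw-based
estimate in expectation while removing within-replicate Monte-Carlo
noise; a draw mode exists behind a flag for non-linear extensions. The
NDE holds the mediator of interest at the value predicted for each
subject under control — computed with upstream mediators also at their
control values — which preserves TE = NDE + NIE exactly within every
replicate. Point estimates come from the original-sample fit; SEs are
SDs over 100 bootstrap refits (replicates with singular refits are
dropped and counted); a bootstrap-mean point estimate is available
behind a flag. Confounder imputation, where needed, happens once before
resampling. Averaging across several CpGs is supported by passing a
mean-of-residuals pseudo-CpG column.

**Polygenic score.** Clumping windows are ± the stated distance around
the index variant on the same chromosome; allelic correlation is
computed on allele counts (composite LD), with monomorphic markers
treated as unlinked; round 2 re-ranks by published p-value rather than
preserving round-1 order. The per-ethnicity threshold is chosen to
maximize the mean absolute correlation between the standardized score
and the anchor phenotypes (birth weight and BMI) — the mean-of-|r| is
the package's combining rule and is logged with the full grid.

**Reference chart.** The shipped LMS chart is synthetic — smooth
parametric median curves with gently varying L and S — and exists so the
z-score machinery is exercised and the file format fixed; real reference
tables load through the same delimited format but are never bundled.
Degenerate inputs: L = 0 falls back to the log form; ages outside chart
coverage raise a coverage error rather than extrapolating.

## Validation design and problem sizes

The validation suite and the reproduction script use scaled simulation
sizes chosen for a single CPU: the oracle identity on a 2000-subject
dataset; parameter recovery on 2000-subject cohorts with the error
averaged in bootstrap-SE units over five replicate cohorts; NIE interval
coverage over 200 replicates of 500 subjects with 50 bootstraps; null
calibration over 100 replicates of 800 subjects; negative-control
detection over 20 replicates of 1200 subjects with a deliberately strong
planted confounder (the plant must be large relative to sampling noise
for the demonstration to be about bias detection rather than power);
double robustness at n = 5000 over 10 replicates, with the misspecified
outcome model injected directly so the contrast isolates the targeting
step; censoring-weight bias reduction over 60 replicates of 2000; and
estimator cross-agreement on one randomized 1500-subject cohort with the
full learner library. Simulation studies that repeat the C-TMLE hundreds
of times use a reduced two-learner library (GLM + observed mean); the
full six-learner library is exercised in the single-cohort checks.

## Known limitations

- With ~7% treated and strong confounding, the C-TMLE shows a small
  finite-sample bias driven by heavy inverse-propensity tails even after
  bounding g — a known property of targeted estimators near positivity
  violations; interpret single-draw estimates at this treated fraction
  alongside the covariate-adjusted fit.
- Linear mixed models over repeated visits are intentionally out of
  scope; per-visit single-level models are the supported analysis.
- The negative control detects confounders of the maternal-CpG/outcome
  pair; it is silent about confounders affecting only the fetal CpG.
- Binary/categorical imputation draws omit parameter uncertainty (see
  above); congeniality diagnostics beyond trace logs are not provided.
- The per-CpG scan is a candidate-set engine; genome-scale execution is
  possible in principle but not a tested surface.
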