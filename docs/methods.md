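# Methods

## Models

**Linear mixed-effects model.**  For subject *i* with outcomes
*y_i* at ages *t_i*: *y_i = X_i β + Z_i u_i + ε_i*, *u_i ~ N(0, G)*,
*ε_i ~ N(0, σ² I)*.  The fixed-effect design is assembled in a fixed
column order — intercept, time-basis columns, baseline-modifier main
effects, modifier×basis interactions — which is the two-level
formulation (subject growth coefficients linear in baseline covariates)
written as one aggregate regression.  The random-effect design is either
the intercept alone or the intercept plus all basis columns with an
unstructured covariance.

Estimation is maximum likelihood, never REML: BIC comparisons across
different fixed-effect structures, and against the mixture model, need
likelihoods on the same footing.  β is profiled out by GLS at every
variance evaluation; the variance parameters are optimized by L-BFGS-B
in log-Cholesky coordinates (Cholesky factor of G with logged diagonal,
log σ), which enforces positive semi-definiteness by construction.  The
gradient of the profiled deviance is analytic (envelope theorem: the
partial θ-derivative at the GLS β̂).  Fixed-effect covariance is the
inverse GLS information (Σ X_i' V_i⁻¹ X_i)⁻¹; Wald intervals at a
configurable level (default 95%).

**Growth mixture model.**  A K-component mixture of the above with
class-specific fixed effects β_k, shared (G, σ²), and softmax class
weights π_k(w) = exp(w'γ_k)/Σ_l exp(w'γ_l), γ_K = 0, in baseline
covariates w (intercept always included).  Class means carry no
baseline modifiers — the exposure acts through membership, which is the
point of the stochastic-mechanism model; putting exposure in both
places is possible in principle but not what this comparison studies.

Fitting is EM with the class label as missing data.  The E-step forms
responsibilities in log space (log-sum-exp).  The M-step is a cycle of
conditional maximizations of the EM objective: responsibility-weighted
GLS for each β_k (exact), Newton–Raphson with step halving for γ
(ascent-guarded), and a bounded quasi-Newton move in log-Cholesky
variance coordinates (accepted only if the objective improves, at most
12 inner iterations per M-step).  Because each block update can only
increase the EM objective, the observed-data log-likelihood is
non-decreasing across iterations — this is asserted in the tests on
every run and every start.

*Initialization and restarts.*  Per-subject OLS coefficients on
[1, basis] are clustered by k-means into K groups; the first start uses
those labels, subsequent starts resample a random 25% of labels.
Default 20 starts (scaled down explicitly where speed matters), seeds
derived hierarchically from a master seed.  A class whose largest
responsibility falls below 1e-6 marks the start degenerate; if every
start degenerates the fit aborts with advice to lower K.  Convergence:
relative log-likelihood change < 1e-6 (max 500 iterations).

*Label switching.*  Classes are reported in descending-size order;
γ is re-expressed against the new reference class (the softmax is
invariant to permutation plus a common shift).  Tests compare up to the
best permutation.

*Inference.*  The observed information is the negative Hessian of the
observed-data log-likelihood over all free parameters (β's, γ's,
log-Cholesky variance coordinates), computed by central differences of
the *analytic* score.  Membership-probability ratios are exp(δ·γ̂)
with Wald intervals (default 90%) from the γ block of the inverse
information; the γ block is invariant to how the variance block is
parameterized.  No bootstrap.

*K selection* fits K = 2..5 by default and keeps the converged fit with
the smallest BIC, ties toward smaller K.  BIC uses N = number of
subjects (the latent-class mixed-model convention); the
observation-count convention can be had by calling `bic_of` directly.

## Time bases

Linear and quadratic polynomials (optionally centered at a meaningful
age, which makes coefficients level/velocity/acceleration at that age),
and B-splines of any degree with arbitrary interior knots.  The
B-spline convention drops the first basis function and carries a
separate intercept — the common statistical-software convention — so a
quadratic spline with one interior knot contributes exactly three
columns.  Boundary knots default to the data range.  Derivatives are
analytic (polynomial differentiation; the spline derivative via the
standard degree-lowering recurrence, evaluated from the left at the
closed right boundary).  Knot choice is manual; `spline_sse_report`
totals per-subject OLS SSE across candidate bases to support it.

Tertile coding of an exposure uses linear-interpolation empirical 1/3
and 2/3 quantiles with ties assigned to the lower group (a documented
choice; quantile conventions differ across software).

## Synthetic data generator

Emulates a childhood-BMI cohort: default n = 250 subjects, observation
ages (1, 3.25, 5.5, 7.75, 10), w1 ~ Bernoulli(0.5) (sex-like),
w2 ~ N(0, 1) (standardized log2-exposure-like).  Eight conditions cross
mechanism × growth form × exposure form.  Deterministic conditions add
exposure_effect·w2 (or ·w2²) to the generating coefficients and put
independent Gaussian random effects on *every* generating coefficient;
stochastic conditions draw one of three latent classes from a softmax
in (1, w1, w2[, w2²]) and add a random intercept only, mirroring the
usual latent-class specification.  Non-monotonicity is implemented as a
quadratic-in-w2 term (in the coefficients or the class log-odds with
opposing signs across classes) — one concrete choice among many
possible non-monotone forms.

Default effect sizes are the package's own: BMI-like levels
(intercepts 14–19), linear growth ≈ 0.2–0.8 units/year, quadratic
curves with an adiposity-rebound minimum near age 4–6, class curves
separated by ≈ 2–2.5 intercept units against a random-intercept SD of
1.0 and residual SD of 0.8, and deterministic exposure effects of
0.25–0.4 level units and 0.06–0.12 velocity units per unit (or squared
unit) of w2 — strong enough that the non-monotone deterministic
condition shows a clear quadratic pattern in a derived-coefficient
scatter, as intended for that regime.  They are defaults, not
estimates: every number is overridable, and all comparisons made with
the package are relative to whatever generator parameters are in force.

Replicate streams are seeded by (master seed, data type, role,
replicate), so any replicate regenerates identically in isolation and
generation order is irrelevant.  Each condition exposes an exact oracle
mean surface μ(t, w1, w2) and velocity v(t, w1, w2) (random effects and
noise average out; for stochastic conditions the class weights multiply
the class curves).

What the generator does *not* emulate: irregular/missing visit
schedules, dropout, confounding between exposure and other causes of
growth, measurement error in exposure, non-Gaussian outcome tails, and
time-varying covariates.  Passing tests therefore demonstrate
correctness of the machinery and behavior under these idealized
regimes, not robustness to the messiness of real cohort data.

## Evaluation metrics

Validation MSE uses the marginal (population-level) mean for
out-of-sample subjects — random effects integrate to zero; predicting
subject-level BLUPs would be a different (in-sample) notion of
prediction.  MAE and MAVE average |μ̂ − μ| and |v̂ − v| over an
inclusive uniform grid, default 81×81 over t ∈ [1, 9], w2 ∈ [−2, 2]
with w1 = 1, approximating the normalized domain integral by the node
mean.  Fitted-surface velocities are always analytic basis derivatives;
finite differences appear only as test oracles.  The 81-point default
is backed by a convergence test for smooth integrands; when the
estimated and true surfaces cross, |δ| has kinks and the node-mean
converges only first-order in the mesh — refining the resolution is
cheap if the third digit matters.  The grid is deliberately *not*
weighted by the observation or exposure distribution; that is what MSE
already does.

## Benchmark

The model grid crosses model type × mean form (linear/quadratic) ×
random effects (intercept / all coefficients) × exposure coding
(continuous / tertile): labels ME1–ME4 and M1–M4 (suffix T for
tertile), 16 specifications in all.  Growth-mixture specs re-select K
by BIC within every replicate (the per-replicate K is recorded, so a
fixed-K analysis remains recoverable).  Non-convergent fits are retried
up to 3 times with doubled starts, then excluded from that cell's
average with a logged count; cells with >10% exclusions are flagged.
The quick default is 100 replicates; a 1000-replicate run is available
behind the same config with a runtime warning.  Results are bitwise
reproducible for a given (config, seed) on one platform and independent
of parallel execution order, because every (condition, replicate,
model) task derives its own seed substream.

## Problem sizes in shipped checks

The statistical checks in `tests/` and `scripts/acceptance.py` use
scaled problem sizes chosen as the package's own defaults for routine
verification: parameter-recovery at n = 500 with 100 replicates and
K-selection with 50 replicates over K = 2..5; the directional
model-comparison runs use 40 replicates per condition with the
linear-mean half of the grid (the conditions compared generate linear
growth) and K ∈ {2, 3, 4}; the acceptance script's comparison uses 20
replicates per condition.  Averages at these sizes carry Monte-Carlo
error of a few percent, which is why the shipped comparisons are
directional (orderings) rather than cell-value reproductions.

## Known limitations

* Residuals are iid within subject (Σ_i = σ²I); no serial correlation
  or heteroscedasticity.
* G and σ² are shared across mixture classes (class-specific variances
  are a documented non-default extension point, not implemented).
* No REML, no crossed random effects, no penalized or automatic knot
  selection, no time-varying covariates other than the time basis.
* Wald inference only; mixture SEs assume the usual regularity that can
  fail near boundary or weakly separated solutions.
* Derived-variable screens are exploratory by construction: they treat
  estimated per-subject coefficients as data and ignore their
  estimation error.
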