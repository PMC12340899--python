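# Methods

## Problem setting

`repflow` estimates individualized treatment effects (ITEs) of two competing
respiratory-support treatments — non-invasive positive-pressure ventilation
(NIV) and high-flow nasal cannula (HFNC) — on a binary outcome, primarily the
subsequent need for invasive mechanical ventilation (IMV).  The data are
observational: ICU encounters that crossed a high-risk threshold on an hourly
risk-score trajectory (the decision time T0) and whose first respiratory-
support event after T0 was NIV or HFNC.  Treatment choice in such cohorts
depends both on measured covariates and on unmeasured severity factors, so
the estimator has to address measured confounding (by balancing) and to
attempt an adjustment for hidden confounding (by latent recalibration).

The ITE convention throughout is

    ITE(x) = P(IMV | x, do NIV) − P(IMV | x, do HFNC),

so negative values favour NIV.  Patients are categorized as NIV-preferred
(ITE < −0.001), HFNC-preferred (ITE > 0.001) or indifferent (|ITE| ≤ 0.001,
boundary inclusive).

## The three-stage model

**Stage 0 — balanced counterfactual regression.**  Dynamic features are first
passed through a staleness gate, `w_i = exp(−softplus(d_i)·TSLM_i)` with
learnable `d_i`: a freshly measured variable passes unchanged (weight 1), the
weight is monotone non-increasing in the time since last measurement, and
`softplus(d_i) → 0` recovers the identity.  A shared feed-forward encoder maps
the gated features to a representation φ, and two treatment-specific heads
predict the outcome.  The training loss is

    L0 = factual BCE + λ · IPM(φ | A=NIV, φ | A=HFNC),

where the factual binary cross-entropy scores each encounter under its own
arm's head, and the IPM term is a Sinkhorn (entropic-regularised optimal
transport) distance between the two arms' representation samples with
Euclidean ground cost.  During minibatch training the transport plan is held
fixed per step and gradients flow through the cost matrix — the standard
envelope approximation.  Minibatches that happen to contain a single arm skip
the IPM term for that step.  The exposed `ipm_distance` is debiased,
`S(a,b) − (S(a,a)+S(b,b))/2`, and has an exact 1-D sorted-sample mode that
serves as an independent oracle in the tests.

Defaults: representation layers [32, 16], head layers [16], λ = 0.5, Adam at
1e-3, batch 128, early stopping on a (treatment, outcome)-stratified 20%
validation split, Sinkhorn ε = 0.1.  The deliberately small encoder reflects
the near-logistic structure of realistic outcome models; larger encoders
overfit visibly at n ≈ 4,000.

**Stage 1 — conditional outcome flow.**  The binary outcome is lifted to a
continuous target by uniform dequantization, `y* = y + v`, `v ~ U[0,1)`,
decoded by `event ⇔ y* ≥ 1`.  A conditional 1-D normalizing flow models
p(y* | φ, a): a stack of monotone rational-quadratic-spline + affine
transforms (affine-only mode available for closed-form tests) whose
parameters come from a conditioner network on (φ, one-hot a).  The trainable,
analytic direction maps data to latent ("normalize"); identity initialisation
(zero-initialised conditioner output) makes the initial log-likelihood exactly
the standard-normal density of y*.  Training maximises held-out-validated
conditional log-likelihood with dequantization noise resampled every epoch.

**Stage 2 — hidden-confounding adjustment.**  With Stage 1 frozen, a second
flow conditioned on φ *only* is fitted so that composing stage-2 forward with
stage-1 forward maximises the likelihood of the observed outcomes.  Because
Stage 1 is fixed, this reduces to a density fit of the stage-1 latents
z1 = g1(y*) pooled across arms.  Conditioning on φ alone is deliberate: the
adjusted latent is meant to approximate the treatment-free conditional
p(u | φ), which cannot depend on the received treatment.  A switch allows
(φ, a)-conditioning for ablation.

**Inference.**  For each encounter and each arm, latent draws Ũ ~ N(0,1) are
pushed through stage 2 then stage 1 and the decoded events are averaged
(default 100 seeded draws).  Both flows are strictly monotone in 1-D, so
`y* ≥ 1 ⇔ Ũ ≥ g2(g1(1 | φ,a) | φ)`; the sampler uses this threshold form
(a test verifies it agrees with explicitly pushing the draws through both
flows), and an exact mode reports the infinite-sample limit `1 − Φ(g2(g1(1)))`.
The exact mode is used wherever a point estimate rather than a sampling
demonstration is wanted.

### What the Stage-2 adjustment can and cannot do

At the Stage-1 maximum likelihood, the latents z1 are standard normal within
every (φ, a) cell and the Stage-2 optimum is the identity — the tests verify
that on unconfounded data Stage 2 changes held-out composed log-likelihood by
less than 0.02 nats.  The adjustment therefore acts through what Stage 1 has
*not* absorbed: with finite data and early stopping, residual arm-specific
structure remains in the pooled latents, and the φ-conditioned recalibration
shrinks the arm contrast toward the pooled conditional.  Under hidden
confounding that inflates the apparent effect, this shrinkage reduces the
absolute ATE error — in the packaged paired-seed experiment at n = 1,500 the
median |ATE error| of the full pipeline is below that of the Stage-0 heads
(≈ 0.11 vs ≈ 0.13), though the margin is modest and varies with the seed
draw.  As n grows and Stage 1 approaches the observational conditional
exactly, the correction vanishes and the two estimators coincide; a shared
monotone recalibration cannot undo an arm-antisymmetric bias, so this is a
partial adjustment, not an identification result.

## Synthetic cohorts

The generator emulates the causal structure of the study: measured covariates
X ~ N(0, I) drive treatment and outcome through fixed per-seed linear scores
g(X), h(X); a scalar hidden severity factor u ~ N(0,1), independent of X,
pushes treatment assignment with strength `gamma_treat` and both outcomes
with `gamma_outcome`; the heterogeneous effect is
τ(X) = `tau_constant` + `tau_scale`·(linear score of the first ⌈p/4⌉
covariates), so X-only estimators can in principle recover it.  Potential
outcomes are logistic in h(X) + τ(X)·1[a=NIV] + γ·u.  Ground truth is exposed
both conditional on (X, u) and marginalised over u | X by 40-node
Gauss-Hermite quadrature; the marginal version is the fair target for
estimators that see only X.  Adjustment covariates (age, gender, SOFA, CCI,
risk score) are deterministic functions of X plus seeded noise so the
concordance regressions have realistic per-unit inputs.  A second outcome
(mortality-or-hospice) shares τ and u but has its own covariate profile.

What the generator does **not** emulate: real EHR covariate distributions and
correlations, informative missingness (event-stream sampling times are
outcome-independent), time-varying treatment, or multi-level severity
processes.  Passing tests therefore demonstrate correctness of the machinery
and the directional behaviour of the adjustment under the stated causal
structure — not clinical performance.

Default study conditions: n = 4,000 encounters and 20 covariates for
unconfounded recovery; `gamma_treat = gamma_outcome = 1` and n = 1,500 per
seed (10 paired seeds) for the hidden-confounding experiment; base outcome
prevalence 0.25.  With `tau_scale = 0.5` the true ITE spread (sd ≈ 0.055) is
*below* the estimation-noise floor of every estimator at n = 4,000; the
qualitative recovery properties (estimators beating the zero predictor,
flow/head ITE agreement) are therefore exercised at `tau_scale = 1.5`, where
the heterogeneity is recoverable.

## Event streams and feature derivation

Irregular timestamped measurements are binned into half-open hourly windows
[h, h+1) by the median; missing hours are filled by carrying the last
observation forward at most 24 hours (observed flags untouched; the filled
value's TSLM is its age); anything still missing is mean-imputed with means
from the training split only.  Per variable, four features are emitted at the
decision hour: current value, the mean of observed bins in the 72 hours
strictly preceding the reference hour (falling back to the training mean when
the window is empty), the difference between the last two observed bins
(0 with fewer than two), and TSLM capped at 72 h (72 is also the
never-measured sentinel).  Delta is computed over hourly bins, not raw
events, because the grid is the pipeline's contract at that stage; with
at most one extra measurement per hour the two conventions differ only by
within-hour medians.

## Cohort selection

T0 is the first hour whose risk score meets or exceeds the threshold
(monotone in the threshold by construction).  An encounter enters the cohort
iff the first respiratory-support event *strictly after* T0 is NIV or HFNC —
an event at exactly T0 cannot be a response to the alert.  A calibration
utility scans thresholds on labelled trajectories and returns the largest
threshold whose encounter-level sensitivity still meets the target (default
60%).  Risk scores are an input column; the risk model itself is a separately
published component and is not reimplemented.

## Evaluation machinery

AUC and PR-AUC (average-precision convention) come from scikit-learn.  PEHE
is the RMSE of ITE estimates against ground truth; ATE error the difference
of means.  Shapley attributions use permutation sampling with full-background
averaging at every coalition, which makes additive models exact and the
efficiency identity (baseline + Σ attributions = prediction) hold per
permutation; Monte-Carlo standard errors are reported per feature.
Concordance analysis excludes the indifferent category, tabulates outcome
rates for the four (recommended × concordance) groups, and fits one
multivariable logistic model per outcome with both treatments' concordance
indicators plus age, gender, SOFA, CCI and risk score (unstandardised, so
odds ratios are per unit).  The logistic fit is statsmodels' Newton/IRLS MLE
(tol 1e-8, max 100 iterations) with Wald inference; rank-deficient designs
raise an error naming the collinear columns, and perfect separation is
surfaced explicitly.  The regression is an associational adjustment exactly
as in the underlying study design — no causal identification is claimed.

## Numerical choices

* All parameters are float64; every stochastic routine takes an explicit
  seed and is bit-reproducible.
* Neural components run on a small reverse-mode autodiff engine over numpy
  (`repflow._autodiff`), gradient-checked against finite differences.
* Flow inversion (latent → data) uses bracketed bisection (70 iterations)
  on the monotone normalize map; round-trip error is below 1e-10 and the
  C¹ spline gives finite-difference Jacobian agreement at 1e-6 steps.
* Flow training uses reduce-on-plateau (halve the step, restart from the
  best weights after 5 stalled epochs); `early_stop=False` switches the
  monitored metric from validation to training NLL for MLE-style fits where
  validation-based stopping would bias parameter recovery.
* Sinkhorn runs in the log domain with uniform marginals; training plans
  stop at marginal error 1e-6, oracle-grade evaluations at 1e-13.
* The X-learner defaults to seeded gradient-boosted trees with a logistic
  propensity model; base learners are injectable (the linear-recovery tests
  use least squares), and the propensity can be pinned (e.g. 0.5) for
  randomized data.

## Limitations

* The hidden-confounding adjustment is heuristic (see above); it shrinks
  confounding-inflated effects but cannot recover arm-antisymmetric bias.
* Exactly two treatments and a binary outcome; no time-to-event support.
* The Causal Forest baseline is not reimplemented; the estimator interface
  accepts any external implementation with the same fit/predict contract.
* Hyperparameter search is a seeded random/grid scan by the user; no
  Bayesian optimisation is bundled.
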