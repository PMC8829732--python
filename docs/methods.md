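# Methods

## Estimand and data structure

We observe i.i.d. copies of ({W(t), A(t), D(t); t = 1..K}, Y): time-varying
covariates W, a binary exposure A, a monotone delivered-by indicator D with
D(0) = 0 and D(K) = 1 for everyone, and an outcome Y measured at delivery
for every pregnancy (e.g. neonatal survival, Apgar, birthweight). Once a
subject delivers at T_D = min{t : D(t) = 1}, exposure and covariates are
undefined (NA) for t > T_D; at t = T_D itself they may be observed
(exposure precedes delivery within a period) or blanked by the data source
— the validator accepts both.

A *treatment strategy* k ∈ {1, …, K+1} is "initiate exposure at time k
unless delivery has already occurred"; k = K+1 never initiates. S^k(t)
indicates that the observed history through t is compatible with strategy
k: no exposure before min(k, T_D+1), and exposure at k if k was reached
undelivered. Post-initiation exposure values are deliberately ignored: the
intent-to-treat parameter attaches to the *assigned start time*, so a
subject is classified by first initiation only. A never-initiator who
delivered at T_D satisfies every strategy with k > T_D — one history,
many compatible strategies.

The target parameter is E(Y^k), the mean outcome had everyone been
assigned start-time k at baseline (the potential delivery time responds to
the assigned exposure), and differences E(Y^k1) − E(Y^k2).
Identification needs consistency, positivity for future initiation among
undelivered non-initiators, and exchangeability — no unmeasured
confounding of *initiation* and outcome, required only up to initiation
and before delivery. Unmeasured common causes of delivery time and
outcome are permitted; the simulator includes one on purpose.

## Estimators

**IPW.** The per-time strategy-adherence probability is the initiation
model evaluated at A(t) = I(k = t) while t ≤ k and D(t−1) = 0, and exactly
1 otherwise (past the start time, or after delivery, adherence is
automatic). Weights are cumulative inverses times S^k(t); the estimate is
the weighted mean of Y among followers (equivalently the intercept of a
weighted intercept-only regression — implemented as the weighted mean for
binary and continuous Y alike). A marginal-structural variant stacks one
record per (subject, compatible strategy) with that strategy's weight;
saturated in strategy it reproduces the per-strategy weighted means. We
interpret the joint model's summed weights by stacking because a subject
genuinely follows several strategies at once. Optional percentile weight
truncation is off by default and recorded in diagnostics when used.

**G-computation.** Iterated conditional expectations with delivery
pass-through: Q̄_{K+1} = Y; for t = K..1, subjects delivered by t−1 keep
Y, others get the fitted conditional mean of Q̄_{t+1} given W̄(t) with the
exposure history fixed by the strategy (all zero before k, A(k) = 1 once
t ≥ k; post-k exposures never enter the conditioning set — for the ITT
parameter they are irrelevant). The estimate is the mean of Q̄_1.

Two fitting conventions are provided for each backward step. The default
(`mode="intervene"`) fits among all subjects undelivered at t−1 with the
observed exposure history as predictors, then predicts at the
strategy-consistent exposure values. `mode="strict"` fits only on
strategy-consistent subjects with covariate history alone. With saturated
learners on discrete data the two coincide cell-by-cell; they differ only
in how parametric learners borrow strength across exposure patterns.

**TMLE.** The same recursion, but after each fit an intercept-only
logistic fluctuation with the logit of the current predictions as offset
and the cumulative weights w^k(t) as *observation weights* (not a clever
covariate — the weighted variant is implemented) is solved on the
undelivered subset; delivered subjects are reintegrated with their known
outcomes. The fluctuation intercept is found by bracketing + Brent root
finding on the weighted score (the score is strictly decreasing in the
intercept), tolerance 1e−13 on the root and a guaranteed weighted mean
residual below 1e−6; under separation (score with no finite root) the
intercept stops at ±40 on the logit scale and the event is recorded.
Continuous outcomes are affinely mapped to [δ, 1−δ] (δ = 0.005 by
default) so the logistic machinery and the outcome's natural bounds are
both respected; the point estimate is mapped back. Influence-curve
variance is intentionally not implemented — confidence intervals come from
the bootstrap, matching how the methods are used in applications.

With saturated nuisance models on discrete data all three estimators
collapse onto the nonparametric MLE of the g-formula: weighted follower
counts average to one, every fluctuation intercept is zero, and the test
suite checks agreement with an independent direct-enumeration oracle to
1e−8.

## Nuisance models

Initiation models are fit per time t on subjects with D(t−1) = 0 and no
prior initiation, response A(t), features the covariate history W̄(t).
Learners: `saturated` (exact cell frequencies; unseen cells collapse
hierarchically by dropping the *oldest* history columns first, ending at
the subset mean), `logistic` (main-terms GLM), `intercept` (for
deliberate misspecification), `linear` (OLS, unbounded pseudo-outcomes),
or any fit/predict object. Predicted probabilities are clipped to
[ε, 1−ε], ε = 0.001 by default (0 allowed, used by the exactness tests);
this is a disclosed stability knob, not part of the estimand. A time
point where nobody (or everybody) at risk initiates raises a positivity
error naming the time. Per-time models are the default; pooling over time
is the caller's choice via a custom learner.

## Synthetic data-generating process

Four periods, all variables binary. W(1) ~ Bern(0.5) and an unmeasured
U ~ Bern(0.5) are exogenous; initiation has baseline probability 0.25
with a log-odds log 2 effect of the current W(t); W(t) evolves with
log 2 effects of W(t−1) and A(t−1) (baseline 0.4); exposure is sustained
perfectly once initiated. Delivery can occur at t = 2, 3 with baseline
hazard 0.15 per period, log-odds −log 2 for current exposure (exposure
*delays* delivery, as expected for a controller medication) and +log 2
for U; everyone has delivered by t = 4. The outcome depends on W(1),
W(2), U (log 2 each, baseline 0.15), on delivery timing, and optionally
directly on exposure:

* scenario 1 — no delivery-time effect (β = 1), no direct effect: every
  strategy contrast is exactly null;
* scenario 2 — β = 2 per period of earlier delivery (an "earlier delivery,
  higher risk" outcome such as low birth weight); effects of early
  initiation are purely mediated by delivery time;
* scenario 3 — β = 2 plus a direct log 2 effect of A(2);
* scenario 4 — β = 2 plus a direct log 2 effect of A(4).

The delivery-time term is multiplicative per period of earliness
(log β · (K − T_D)); an early-vs-late indicator form is available. Every
coefficient is overridable; the defaults were chosen once as moderate,
realistic effects that keep delivery and outcome prevalences well inside
(0.05, 0.95) so all saturated cells stay populated.

The **truth oracle** reruns the structural equations with exposure forced
to A(t) = I(t ≥ k) while undelivered — delivery still responds to the
forced exposure — and shares one set of uniform draws across strategies
(common random numbers), which realises the per-individual coupling of
potential outcomes and makes contrast Monte-Carlo error small. Structural
consequences worth knowing: strategies k ≥ 2 share W(2) (only A(1) moves
it), so contrasts among k ∈ {2..5} are driven solely by delivery timing
and direct effects; and E(Y^4) − E(Y^5) is exactly zero in scenarios 1–3
because forced A(2), A(3) coincide and A(4) has no outcome arrow there.

What the generator does **not** emulate: censoring/treatment switching
(the real-data censoring process is accepted in input files but ignored),
non-adherence after initiation, continuous or multi-dimensional
covariates, pregnancy loss before the study window, and calendar-time
structure. Passing tests therefore demonstrate correctness of the
estimators under the stated structure, not robustness to those features.

## Problem sizes and study conditions

* Repeated-sampling checks: 250 repetitions of n = 1000 cohorts across
  all four scenarios, truth from the oracle at n = 10⁶. Bias is judged
  against three standard errors of the mean bias (MC SD / √250). The
  bias table reports both the across-repetition SD (`mc_sd`, the
  Monte-Carlo standard error of one estimate) and `bias_se`.
* Misspecification study: scenario 2, 250 repetitions, one nuisance
  family replaced by an intercept-only learner at a time. TMLE stays
  within the unbiasedness band with either single misspecification;
  G-computation with the broken outcome model and IPW with the broken
  treatment model do not.
* Bootstrap coverage: scenario 1, 250 cohorts of n = 500, percentile
  intervals from B = 200 subject-level replicates with all nuisance
  models refit per replicate; empirical coverage of the null is required
  to land in [0.90, 0.99].
* The simulation-study default learners are saturated for both nuisance
  families: with all-binary data they are correctly specified by
  construction, and they make the full study (≈ 50,000 bootstrap
  refits included) run in a few minutes. The estimator functions
  themselves default to main-terms logistic models, the sensible choice
  for non-toy covariates.

## Numerical and design choices

* Probability clipping before logits at 1e−12; fluctuation score
  tolerance 1e−10 for accepting ε = 0 (saturated fits already solve the
  score; keeping ε exactly 0 preserves bit-level agreement with
  G-computation).
* Percentile bootstrap (default B = 1000, level 0.95), resampling whole
  subjects; replicate failures (e.g. positivity in a resample) are
  excluded and counted, with a 20% failure budget before aborting.
  Contrast CIs always use paired replicates.
* Ties/degeneracies: constant Y makes continuous scaling fail loudly;
  degenerate response vectors in logistic fits short-circuit to the
  closed-form intercept; empty fitting subsets raise errors naming
  (t, k).
* Randomness flows from a single seed through named `SeedSequence`
  substreams (per-scenario, per-repetition, truth oracle), so any
  reported number is reproducible from the configuration.

## Known limitations

Sustained-treatment (per-protocol-style) estimands, censoring processes,
mediation/direct-effect decompositions, cross-fitted/CV-TMLE, and
influence-function variance are out of scope. The K-period TMLE is the
inductive extension of the two-period procedure (one targeting step per
backward step); its score equations are verified numerically at every
step rather than derived symbolically. Saturated learners are only
sensible for low-dimensional discrete histories; with many or continuous
covariates use the logistic learners or plug in a custom model.
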