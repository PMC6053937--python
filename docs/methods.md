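# Methods

## The problem

In multi-species communities, prey can eavesdrop on heterospecific alarm
calls. Whether that is worthwhile depends on the signaller–receiver
relationship: how far the two species share predators, how dependably the
caller vocalises when the receiver's predators are present (false
negatives), how often its calls concern predators irrelevant to the
receiver (false positives), how familiar and how acoustically similar the
calls are, and the riskiness of the environment. `alarmnet` implements the
full analysis chain for this question — information-content indices,
behavioural response coding, a mixed-model hypothesis suite, and a directed
communication network — together with a synthetic-community generator that
makes every stage testable without field data.

## Indices

Let `x` index predators, `i` receivers, `j` callers.

* **Vulnerability** ε(i, x) ∈ [0, 1] is an affine transform of the Jacobs
  selectivity index D ∈ [−1, 1]: ε = (D + 1)/2. The affine map is the
  unique one carrying the admissible range onto the unit interval; any
  other monotone map can be plugged in. Explicit per-cell substitution of
  vulnerability values (e.g. proxying an unscored species by a close
  relative) is done on the input table, not by species-specific rules in
  code.
* **Alarm propensity** I(x, j) is the per-cell alarm fraction from
  predator-model presentation trials. Cells without trials are NaN —
  "not measured" is distinct from "never alarms" (a true zero, which is
  informative).
* **Call profile** C(x, j) renormalises the per-predator alarm *rates* of
  each caller to sum to one. Rate-based normalisation equals raw call
  proportions under an exactly balanced design and corrects for unequal
  per-cell trial counts otherwise. A caller with no alarms at all has an
  undefined (all-NaN) profile.
* **Caller consistency** L(i, j) = Σₓ I(x, j) ε(i, x) aₓ / Σₓ ε(i, x) aₓ
  with aₓ the predator abundance share. The normalised form is the
  default because it makes a perfect informant (I ≡ 1) score exactly 1
  regardless of the weights; the raw weighted sum is available behind a
  flag and induces the same within-receiver ranking of callers.
* **Call reliability** V(i, j) = Σₓ C(x, j) ε(i, x), a convex combination
  of vulnerabilities, hence in [0, 1] by construction.
* **Body-size ratio** (Lovich–Gibbons): receiver:caller mass when the
  receiver is larger, 2 − caller:receiver otherwise; continuous at equality
  and used as a predator-overlap proxy.

## Acoustic similarity

Seven per-call features (duration, harmonics visibility, number of
structural components, pulse presence, 25% energy quartile, 25–75%
bandwidth, third dominant frequency) are standardised by their column
maxima, so multiplying any raw feature by a positive constant changes
nothing. Similarity is S(a, b) = 1 − d(a, b)/√7 where d is the Euclidean
distance between per-species feature centroids. Dividing by √7 (the
diameter of the unit feature box) keeps S in [0, 1]; the raw 1 − d variant
and a call-pair-averaged distance are available behind flags. Aggregating
to centroids before measuring distance was a design choice — the
alternative (mean over all between-species call pairs) gives systematically
lower similarities because within-species scatter contributes to every
pair.

## Response coding

A playback trial's event log is coded as: binary response — any new
behaviour (head-up, scratch, other change) starting in the *closed*
interval (onset, onset + 10 s]; latency — time to the first such event;
duration — time to the start of the first post-onset foraging bout of at
least 10 s, with never-resumed trials flagged censored and excluded from
duration models rather than imputed; head-up and scratch counts over the
window; head-lift speed consumed as a supplied measurement. Coding is
invariant to shifting the time origin. Resuming foraging is deliberately
not a "response": the response definition targets interruptions of
relaxed foraging.

## Synthetic communities

The generator emulates the study conditions: 12 herbivores (one non-vocal),
5 predators, 9 trials per herbivore × (predator + control) combination
(648 trials), and a balanced playback design of 12 receivers × (11 vocal
callers + control) at 17 trials per combination (2,448 trials, matching
the ~2,433-trial, ~17.7-per-pair scale of the field experiment). Defaults:

* body masses log-uniform on 15–1200 kg; herbivore abundances lognormal;
  predator abundance weights gamma; Jacobs indices uniform on [−1, 1].
* alarm propensities uniform on [0, 1], or — with the coupling knob —
  I(x, j) = logistic(−c/2 + c·ε(j, x)) so species alarm more to predators
  that prefer them (logit slope c; the adaptive-information scenario).
* binary playback response: logit p = x'β + u(receiver), u ~ N(0, 0.5²).
  The information covariates enter scaled to [0, 1] over the community
  grid (the scale on which coefficients are reported in this literature);
  environmental covariates enter z-standardised. Default β take the
  published point estimates where they are unambiguous (receiver body size
  −0.45, size ratio 6.48, size ratio² −4.35, size×ratio² interaction 0.44,
  caller consistency 1.74, acoustic similarity 0.37) and zero elsewhere;
  `true_betas["control"]` is the control-condition intercept (−2.2,
  i.e. ~10% control response) and a conspecific bonus of 0.96 mirrors the
  reported conspecific–heterospecific contrast.
* conditional on a binary response: latency log-normal truncated at the
  10-s window, duration = latency + a log-normal resumption delay
  (censored with probability 0.05, emulating the reduced sample sizes of
  the duration models), head-lift speed log-normal, and head-up/scratch
  counts NB2 — each with its own intercept, optional shared-covariate
  coefficients and a per-receiver random intercept (SD 0.3 on the log
  scale).
* predator-simulation control trials alarm at rate 0.05 (no value is
  derivable from the source; exposed in config).
* covariates: speaker distance N(35, 5) m (the calibration distance),
  grass height lognormal in cm, cover proximity exponential, wind uniform
  0–8 m s⁻¹, group size 1 + Poisson.

What the generator does *not* emulate: spatial structure, predator
encounters, observation/measurement error in the index ingredients,
imbalance (the field study's 649th trial), sex structure of callers, or any
caller-level random effect. Passing tests therefore demonstrate that the
estimators and models recover the generating process they assume — not
that the assumptions hold in real communities.

## Models and inference

* **M1** (alarm occurrence): binomial GLM with focal species, the focal
  species' own vulnerability to the presented predator, optionally their
  interaction, distance, group size, presence of young. The
  vulnerability-coverage simulation uses the common-slope variant
  (no interaction) because the generator's coupling is a single shared
  logit slope; the interaction model remains the default surface.
* **Preliminary call-type model**: call type with the control sound as the
  reference level; after confirming both alarm contrasts, control trials
  are removed and the heterospecific subset (conspecific trials excluded,
  re-includable by flag) feeds the M2 suite.
* **M2 suite**: one shared covariate set (receiver size, size ratio linear
  + quadratic, their interactions, consistency, reliability, similarity,
  abundance, five environmental covariates) with a per-receiver random
  intercept. Response probability is a binomial-logit GLMM; latency,
  duration and head-lift speed are log-transformed linear mixed models
  (statsmodels MixedLM, ML); head-ups and scratches are NB2 GLMMs with
  ML-estimated dispersion (a warning downgrades the interpretation to
  Poisson if the dispersion estimate diverges).
* **Random-intercept GLMMs** are fitted by direct maximisation of the
  Gauss–Hermite-quadrature marginal likelihood (25 nodes, analytic
  gradient, BFGS warm-started from the fixed-effects GLM). On test data
  the fits agree with lme4/glmmTMB to ~3 decimal places in coefficients,
  SDs and log-likelihood. At σ = 0 the model reduces exactly to the GLM.
* **Per-term inference** is Wald by default (z from the observed
  information); per-term likelihood-ratio tests are available via
  `models.term_lrt`. Kenward–Roger degrees of freedom are out of scope.
  Known limitation: with only 12 receiver groups, tests of covariates that
  vary mostly *between* receivers (receiver body size, and call
  reliability, which carries a strong receiver-level component) are
  anticonservative — simulated null rejection ≈ 11–13% at nominal 5% —
  and this is a property of ML mixed-model asymptotics with few clusters
  (lme4 reproduces it exactly), not of this implementation. Trial-level
  covariates are calibrated (~5%). Conclusions about receiver-structured
  covariates at these sample sizes warrant small-sample corrections that
  are deliberately not implemented here.
* **Selection**: all-subsets enumeration under marginality (interactions
  require main effects, quadratics their linear terms; the random
  intercept is always kept), ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1);
  ties break by fewer parameters then lexicographic term order for
  reproducibility. The enumeration cap raises rather than silently
  truncating.
* **Wilcoxon control check**: V is the sum of ranks of positive
  differences (R's convention); p-values are exact for small samples
  without ties.

## Numerical choices and degenerate inputs

Propensity/profile cells or columns without data are NaN, never zero.
Constant vectors cannot be unit-scaled and zero-SD columns cannot be
standardised (errors, not silent passes). The network threshold comparison
is inclusive (≥). MixedLM fits landing on the σᵤ = 0 boundary are replaced
by the equivalent OLS fit (the boundary ML solution) and flagged. Separation
in logistic fits (|coef| > 15) is flagged on the result, not dropped.
Quadrature seeds: all simulation randomness flows through
`numpy.random.default_rng(seed)`; fitting is deterministic.

## Problem sizes used in the automated checks

Oracle sweeps use 1,000 random 12×5 communities. Recovery and null
calibration simulate the full design (2,448 playbacks, ~2,050
heterospecific trials) with 100 recovery and 200 null replicates in the
test suite (50/100 in the acceptance script, which finishes in a couple of
minutes); vulnerability coverage uses 100 (script: 50) replicates of the
648-trial predator experiment; AICc selection uses 100 (script: 50)
replicates at n = 2,000.
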