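# Methods

This document specifies the statistical model, the sampler, the synthetic
cohort generator, and the evaluation machinery, together with the reasoning
behind every numerical and design choice. The README gives the short
version; this is the reference.

## 1. Observation model

The outcome is the ALSFRS, a functional score bounded in [0, 40] and, in
expectation, non-increasing over the disease course. For subject
*i* = 1…n with visits at times `t_ij` (days from trial start):

    y_ij ~ t3(a_i + b_i * t_ij, sigma^2)  truncated to [0, 40]

`t3(m, sigma^2)` denotes a location–scale Student-t with 3 degrees of
freedom: `(y - m)/sigma ~ t_3`. Two points deserve emphasis:

* **sigma is the scale, not the SD.** The variance of a t3 variate is
  `3 sigma^2`. This matches the convention in which a t-distribution is
  parameterised by its precision.
* **Truncation, not censoring.** The density is renormalised over [0, 40]:
  `f(y) = t3(y; m, sigma) / (F(40) - F(0))` for `y` in [0, 40] and zero
  outside. Scores cannot leave the scale, so mass outside the scale is a
  model artefact to be removed, not piled onto the bounds.

The t3 tail makes single aberrant scores (bad visit days, transcription
slips) nearly harmless to the fit; the `likelihood="normal"` option exists
so this choice can be tested rather than assumed — the acceptance suite
checks that DIC prefers t3 on heavy-tailed data.

For 3 degrees of freedom everything is closed-form:

* log-density: constant `log(2 / (pi * sqrt(3)))` with kernel
  `-2 log(1 + z^2/3)`;
* CDF: `F(z) = 1/2 + (u / (1 + u^2) + atan(u)) / pi` with `u = z / sqrt(3)`;
* quantile via `scipy.stats.t(3).ppf` (used only for simulation and
  predictive draws).

Truncated-normal log-masses use `scipy.special.log_ndtr` with a reflection
so the interval always sits in a left tail — stable out to extreme
standardised bounds. Both truncated densities are verified against
high-precision quadrature (normalisation error < 1e-8; the half-line
truncation of a zero-mean normal reproduces the exact `+log 2` shift).

## 2. Hierarchy and priors

    a_i ~ N(p0, sigma0^2)  truncated to [0, 40]      baseline level
    b_i ~ N(p1, sigma1^2)  truncated to (-inf, 0]    decline rate (pts/day)

    p0 ~ N(33, 3^2)
    p1 ~ N(-0.025, 0.3^2)
    1/sigma^2, 1/sigma0^2, 1/sigma1^2 ~ Gamma(0.001, rate 0.001)

The intercept prior centres on mild impairment at enrolment (trial
populations are screened; a mean of 33/40 with SD 3). The slope prior
centres on −0.025 points/day, i.e. roughly −0.76 points/month, a typical
trial-population decline, and is weak (SD 0.3 spans every plausible rate).
Slopes are constrained non-positive: ALS function does not durably improve,
and the constraint is what lets the onset anchor act as a one-sided
leverage point. The Gamma(0.001, 0.001) precision priors are the standard
vague inverse-gamma choice on variances.

### Model kinds

`ModelSpec(kind=...)` selects one of:

* **linear** — the hierarchy above on the data as given.
* **onset_anchored** — identical, fitted after `add_onset_anchor` appends
  the artificial observation (t = self-reported onset time, y = 40) to each
  subject. The anchor is *treated as data*; there is no special likelihood
  term. Consequently `fit(onset_anchored, C)` is draw-for-draw identical to
  `fit(linear, anchor_cohort(C))` — an exact-equivalence property asserted
  in the tests.
* **mixture** — the slope hypermean becomes a two-component mixture
  (fast/slow progressors):

      b_i ~ pi1 * N(Lambda1, sigma1^2) + (1 - pi1) * N(Lambda1 + c, sigma1^2),
      both components truncated to (-inf, 0]
      Lambda1 ~ N(0, sigma_L1^2),  1/sigma_L1^2 ~ Gamma(0.001, 0.001)
      c ~ half-normal(sd 10)  (c >= 0 orders the components: component 1 fast)
      (pi1, 1 - pi1) ~ Dirichlet(1, 1)

  The per-subject class indicators are marginalised out analytically. This
  avoids label-switching and the poor mixing of discrete indicator updates;
  the ordering constraint `c >= 0` fixes the component identities. At
  `c = 0` the prior collapses exactly to the single-class truncated normal
  (verified in tests).
* **onset_anchored_covariate** — the hypermeans regress on a per-subject
  scalar covariate `X_i`: `a_i ~ N(p00 + p01 X_i, sigma0^2)`,
  `b_i ~ N(p10 + p11 X_i, sigma1^2)`, with `p01, p11 ~ N(0, 100^2)`.
  Covariates are z-scored with *training-set* statistics
  (`normalize_covariates` returns the mean/SD table so the identical
  transform is reapplied to held-out subjects — never recomputed on
  validation data, which would leak).

### Recall error

Self-reported onset dates are recalled imprecisely. With
`recall_error="shared"` a single scalar `delta` shifts every anchor time;
with `"individual"` each subject gets `delta_i`. Either way
`delta ~ N(0, sigma_delta^2)` with the same vague inverse-gamma prior on
`sigma_delta^2`. Only anchor times are shifted; real visit times are exact.

## 3. Inference

No general-purpose gradient-based PPL is a dependency; the posterior is
sampled by an **adaptive Metropolis-within-Gibbs** scheme written directly
against the joint log-density (`alsprog.models.joint_log_density`):

* **Per-subject blocks.** All `a_i` are updated simultaneously by
  independent random-walk proposals (one step size per subject), with
  accept/reject decided per subject from per-subject likelihood segment
  sums — one vectorised pass instead of n scalar updates. Same for `b_i`
  and, under individual recall error, `delta_i`.
* **Scalar hyperparameters** (`p0`, `p1`, `sigma^2`, …, `Lambda1`, `c`,
  `pi1`, `delta`) get univariate random-walk updates against their exact
  conditional terms. Variances use multiplicative (log-scale) proposals
  with the Jacobian correction.
* **Bounded parameters are sampled in their native space**, with proposals
  outside the support rejected (a valid Metropolis move: the target density
  is zero there). The alternative — transforming to unbounded scales —
  avoids boundary sticking, but these posteriors concentrate in the
  interior (scores well inside [0, 40]; slopes bounded away from 0 by the
  data), and native-space rejection keeps the vectorised per-subject update
  exact and simple.
* **Adaptation.** During warmup only, step sizes follow a Robbins–Monro
  recursion targeting 44% acceptance (the optimal rate for univariate
  random walks), with gain `(t + 10)^-0.6`. Freezing adaptation after
  warmup keeps the post-warmup chain a valid time-homogeneous Markov chain.
* **Initialisation** is per-subject OLS with jitter (or prior draws, by
  option). Chains are seeded from `SeedSequence(entropy=seed, spawn_key=
  (chain,))` so runs are exactly reproducible and chains independent.
* **`fixed=`** clamps named parameters at given values while everything
  else updates. This exists for validation: clamping all but one parameter
  in the normal/unbounded limit produces a conjugate posterior that the
  sampler must reproduce (KS-tested in the acceptance suite).

Diagnostics are split-R-hat and FFT-based effective sample size with
Geyer's initial-monotone-pairs truncation, implemented in
`alsprog.inference` and validated against `arviz` in the tests. A fit is
flagged `converged` when every parameter's split-R-hat is ≤ 1.05; short
exploratory runs warn rather than fail.

**DIC** uses the conditional (observation-level) deviance with the
per-subject parameters in focus: `DIC = Dbar + pD`,
`pD = Dbar − D(posterior means of a, b, sigma^2)`. The conditional focus
matches the prediction target (per-subject trajectories).

## 4. Prediction and evaluation

* `predict_score` draws one predictive value per posterior draw: the
  subject's line evaluated at the target time plus truncated observation
  noise (inverse-CDF sampling, so draws respect [0, 40] exactly). With
  `mode="marginal"` a *new* subject's intercept/slope are first drawn from
  the hyperparameter posterior — out-of-cohort prediction.
* The prediction endpoint **FRS365** is a subject's first real (non-anchor)
  visit at or after day 365.
* `posterior_mse` aligns draws across subjects: draw *s* of the MSE uses
  prediction draw *s* of every subject, so the result is a sample from the
  posterior distribution of the validation MSE, not a point estimate.
* `cross_validate` holds out a seeded subset of subjects with observable
  endpoints, truncates *everyone's* visits to the fitting window (so the
  validation subjects' early data inform the hierarchy but their endpoints
  can never leak — an assertion enforces that nothing past the window
  enters the fit), fits every model spec on the identical split, and
  returns bias, coverage and the MSE posterior per spec. `repeated_cv`
  repeats this over derived split seeds and tabulates pairwise MSE
  differences.
* `covariate_screen` mirrors the covariate-selection procedure: repeated
  random subsets, the anchored model with and without one covariate on
  identical splits, reporting the median percentage MSE reduction and the
  DIC adjustment.

## 5. Synthetic cohort generator

Real longitudinal ALS registry data is access-restricted, so
`alsprog.simulate` generates structurally faithful cohorts with known
ground truth. Per subject: a progression class, an intercept
`N(33, 3^2)` truncated to [0, 40], a slope `N(-0.025, 0.01^2)` truncated
to (−inf, 0], an onset time `N(-658.4, 456^2)` truncated above at 0,
~monthly jittered visits (9.3 ± 4.5 per subject), scores from the model's
own truncated-t3 observation law (rejection-free inverse-CDF sampling),
and one extra visit near day 386.7 (SD 23.7) so an FRS365 endpoint exists.
Options: informative dropout (per-visit hazard proportional to decline
rate, so fast progressors exit early), covariate effects on intercept and
slope, two slope classes for mixture studies, onset/baseline correlation.

Deliberate properties:

* **Counter-derived subject streams.** Subject *i*'s randomness comes from
  `SeedSequence(entropy=seed, spawn_key=(i,))`, so subject *i*'s data are
  identical whether the cohort has 5 or 5000 subjects.
* **Truncated onset mean.** `onset_mean_days = -658.4` is the *parent*
  parameter; the upper truncation at 0 shifts the realised mean to ≈ −729
  (inverse-Mills correction). Tests therefore check the sample mean
  against the analytic truncated mean, not the parent value.
* **Anchor violation (`onset_score`).** Anchors are never generated — the
  anchor is an assumption added downstream, and the generator can make it
  deliberately false. With `onset_score = 34`, the true disease course is
  piecewise linear: a slow pre-trial decline from (onset, 34) down to the
  trial baseline (intercepts capped at 34 so this segment is
  non-increasing), then the drawn trial-period slope. Trial-window visits
  are unchanged; only the truth at onset differs from the anchor's 40.
  This is the realistic violation geometry — long, shallow early disease
  followed by steeper decline around enrolment — under which the anchor
  flattens estimated slopes and produces *positive* prediction bias.
* **Onset floor (`onset_latest_days`).** The anchor-implied decline rate
  `(40 - a_i) / |onset_i|` has positive density at `onset -> 0`, so its
  population mean diverges: a handful of subjects with onset days before
  enrolment can dominate any bias average with huge negative errors. Real
  cohorts contain no such subjects (diagnosis alone takes around a year),
  so bias studies set `onset_latest_days = -180`, flooring enrolment at
  six months after onset. The default (0) keeps the plain truncation.

What the generator does **not** emulate: ALSFRS integer granularity
(scores are continuous), item-level sub-scores, non-linear or plateauing
trajectories beyond the single onset_score kink, missing visits that
cluster in time, calendar effects, or any covariate distribution beyond
standard normal.

## 6. Problem sizes and runtime

All studies are sized to run on one CPU in minutes while keeping their
effects identifiable: cohorts of 150–200 subjects, 2 chains with a few
hundred warmup/kept draws for simulation studies (the default
`McmcSettings` — 4 × 1000/1000 — is for final reported fits), 10–20
replicates or splits per property, 30 held-out subjects per split. The
acceptance test suite runs in ≈ 5 minutes; `scripts/acceptance.py` in
≈ 2 minutes.

## 7. Limitations

* **Two-point degeneracy at baseline-only windows.** With window 0 an
  anchored subject has exactly two observations (anchor + baseline), which
  a line interpolates exactly; with every subject in that state the
  residual variance posterior collapses toward zero and predictive
  intervals become overconfident. The model-ordering study still uses
  window 0 (it is the anchored model's headline use-case and MSE
  comparisons remain valid), but bias/coverage studies use 3-month windows
  where `sigma^2` is identified.
* **Linear trajectories.** Both model and generator are linear per
  subject; real trajectories curve. The onset_score mechanism captures
  one consequence (anchor-induced bias) but not general curvature.
* **Native-space sampling** can mix slowly if a posterior genuinely
  concentrates on a support boundary (e.g. slopes at exactly 0 in a stable
  cohort); the diagnostics flag this, but a transformed sampler would be
  the better tool there.
* **DIC** is reported with the conditional focus; marginal-focus DIC (with
  random effects integrated out) would penalise complexity differently.
* The sampler is exact but not gradient-based; for much larger cohorts a
  Hamiltonian Monte Carlo implementation of the same density would scale
  better.
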