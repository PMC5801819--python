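# alsprog — onset-anchored prediction of ALS functional decline

`alsprog` predicts how far a person with amyotrophic lateral sclerosis (ALS)
will have progressed one year into a clinical trial, using only the first few
months of their trial data. Progression is measured on the ALSFRS, a
functional rating scale bounded in [0, 40] (40 = normal function) that
declines roughly linearly over the course of the disease.

The central idea is the **onset anchor**: every patient, by definition, was
essentially unimpaired when their symptoms began. The package therefore adds
an artificial observation — the maximum score of 40 placed at the patient's
self-reported disease-onset date — to their visit history and treats it as
data. This single leverage point dramatically stabilises each patient's
estimated decline rate when only baseline or a few early visits are
available, at the cost of a small, quantifiable bias when the "full score at
onset" assumption is violated.

## The model

Scores are modelled with a Bayesian hierarchical linear model with
heavy-tailed, bounded observations. For subject *i* at time *t* (days from
trial start):

    y_it ~ t3(a_i + b_i t, sigma^2)   truncated to [0, 40]
    a_i  ~ N(p0, sigma0^2)            truncated to [0, 40]       (baseline)
    b_i  ~ N(p1, sigma1^2)            truncated to (-inf, 0]     (decline rate)

    p0 ~ N(33, 3^2),   p1 ~ N(-0.025, 0.3^2)
    1/sigma^2, 1/sigma0^2, 1/sigma1^2 ~ Gamma(0.001, 0.001)

where t3 is a scaled Student-t with 3 degrees of freedom (`sigma` is its
scale, not its SD), robust to the occasional aberrant score. The
**onset-anchored** model is exactly this model fitted after appending the
anchor observation (t = onset time, y = 40) to each subject. Variants:

* **mixture** — the slope hypermean is a two-component mixture
  (fast/slow progressors), with component indicators marginalised out;
* **covariate** — `a_i` and `b_i` regress on a per-subject covariate;
* **recall error** — the anchor time gets a normal shift (shared or
  per-subject), acknowledging that onset dates are recalled imprecisely.

Inference is by an adaptive Metropolis-within-Gibbs sampler written for this
density (vectorised across subjects), with split-R-hat and effective-sample-
size diagnostics. Model comparison uses DIC and the posterior distribution
of the validation mean squared error. See `docs/methods.md` for the full
specification, the synthetic-cohort generator, and all numerical choices.

## Worked example

Generate a synthetic cohort emulating the target population, hold out 20
subjects' one-year endpoints, fit the plain linear and the onset-anchored
model on 3-month windows of everyone's data, and compare:

```python
from alsprog import (CohortSimConfig, McmcSettings, ModelSpec,
                     cross_validate, generate_cohort, predict_score)

cohort, truth = generate_cohort(CohortSimConfig(n_subjects=150, seed=0))

settings = McmcSettings(n_chains=2, n_warmup=500, n_draws=500, seed=0)
results = cross_validate(
    cohort,
    [ModelSpec(kind="linear"), ModelSpec(kind="onset_anchored")],
    window_days=91.0, val_size=20, settings=settings, seed=1)

for label, res in results.items():
    print(f"{label:15s} mean MSE {res.mean_mse:6.1f}   "
          f"bias {res.mean_bias:+5.2f}   95% coverage {res.coverage(0.95):.2f}")

samples = results["onset_anchored"].samples
sid = results["onset_anchored"].validation_ids[0]
pred = predict_score(samples, sid, 365.0, seed=0)
lo, hi = pred.interval(0.95)
print(f"subject {sid}: predicted FRS365 {pred.mean():.1f} [{lo:.1f}, {hi:.1f}]")
```

Output (deterministic for these seeds):

```
linear          mean MSE   54.7   bias +2.26   95% coverage 0.95
onset_anchored  mean MSE   35.1   bias +1.08   95% coverage 0.90
subject S0004: predicted FRS365 13.9 [8.2, 20.4]
```

With only three months of data the anchored model's held-out MSE is far
lower than the plain linear model's — the anchor is doing exactly its job.

The same operations are available from the command line:

```sh
alsprog simulate --n-subjects 150 --seed 0 --out-dir data/
alsprog crossval --visits data/visits.csv --subjects data/subjects.csv \
    --models linear,onset_anchored --window-days 91 --out-dir results/
alsprog predict --visits data/visits.csv --subjects data/subjects.csv \
    --subject-id S0004 --target-day 365 --out-dir results/
```

## Data formats

Cohorts load from delimited text (`alsprog.io.read_cohort`):

* `visits.csv` — `subject_id, time_days, alsfrs`, or the ten revised-scale
  sub-score columns `q1_speech … q9_climbing_stairs, r1_dyspnea`, which are
  converted to the classic 0–40 ALSFRS on load;
* `subjects.csv` — `subject_id, onset_time_days` (≤ 0, days before trial
  start; blank = unknown) plus any scalar covariate columns;
* optional long-format longitudinal covariates, collapsed to per-subject
  intercept/slope pairs over the fitting window.

Real registry data of this shape is access-restricted and is not bundled;
the `alsprog.simulate` module generates structurally matching synthetic
cohorts (visit cadence, onset distribution, bounded noisy trajectories,
endpoint visits, optional informative dropout) with known ground truth.
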