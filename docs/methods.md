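# Methods

## Problem

People with type 1 diabetes label the presumed causes of their hypoglycemia
episodes (self-monitored blood glucose, SMBG, below 4 mmol/L) in a digital
diary: broadly physical activity, food-intake mistakes, or medication-dosing
mistakes. This package implements the full quantitative workflow around that
setting on synthetic diaries: event representation, mixed-effects logistic
association analysis, and subject-grouped cross-validated cause
classification. Real clinical diaries of this kind are not publicly
available, so the package ships a generator that reproduces the *statistical
shape* of such a dataset and the pipeline is validated by parameter- and
sign-recovery against known injected mechanisms.

## Synthetic cohort generator (`hypocause.simulate`)

Each subject keeps a diary for a configurable horizon (default 180 days —
long enough that every episode, which is always placed after day 90, has a
fully populated 3-month lookback):

* 3–6 SMBG readings/day (wake-time reading after a subject-specific wake
  hour, never before 04:30; pre-meal and occasional bedtime readings);
  values follow a lognormal process with subject-specific median in
  6–10 mmol/L;
* 2–4 meals/day, each a carb record (lognormal-ish around a subject mean of
  ~50 g) and a quick-acting (QA) insulin dose near grams / subject carb
  ratio;
* one basal dose/day in the evening; sporadic carb-estimation quiz sessions.

Cohort defaults mirror the emulated clinical setting: 54 subjects, mean 15.2 episodes
per subject (~800 analyzable events), cause mix 0.48/0.36/0.16 over
activity/food/medication, bolus-advisor data attached to 40% of episodes,
and label confidence drawn as P(5)=0.6, P(4)=0.3, P(≤3)=0.1 (only
confidence ≥ 4 events enter the analysis).

Episodes are *injected* with cause-conditional mechanisms whose magnitudes
live in `EffectProfile`:

* activity — daytime-concentrated times (N(14 h, 2.5 h)), exercise tag in
  the preceding advisor record w.p. 0.7, preceding QA dose ~25% below the
  subject mean;
* food — morning/evening-skewed times, preceding QA dose ~35% above the
  subject mean, a fast corrective carb afterwards;
* medication — business-day skew (0.9 vs the 5/7 base rate), the preceding
  basal dose raised by ~15% of the subject mean, a longer gap since the last
  carb.

Two realism choices matter for interpretation. First, every mechanism is
expressed only with probability `penetrance` (default 0.7): a label records
the patient's belief, not a guaranteed signature in the data, and without
this the injected classes become nearly separable — something never seen in
real diaries. Second, magnitudes were chosen so that single-variable Wald
statistics land in the single digits, the territory clinical diary studies
report. `EffectProfile.zeroed()` removes every mechanism and makes the three
categories exchangeable; this null cohort is the calibration control used
throughout the tests.

What the generator does **not** emulate: glucose–insulin physiology (no
meal-absorption or insulin-action kinetics), under-reporting of corrective
snacks, CGM traces, or correlated mechanism co-occurrence. Passing tests
therefore demonstrate that the *pipeline* recovers structure that is present;
they say nothing about how much structure real diaries contain.

## Event representation (`hypocause.features`)

Each filtered episode (confidence ≥ 4, category one of the three analyzable
causes) becomes a canonical 83-slot vector:

* demographics (age, gender, diabetes duration);
* temporal encodings — absolute hour-offsets from noon (`cos_tod`) and
  midnight (`sin_tod`), offset from the subject's usual wake time, business
  day flag. The raw fraction-of-day `tod` suffers a midnight wrap-around
  artifact and is carried only as an extra column outside the canonical
  vector (it is also exactly collinear with the offset pair);
* the BG trajectory in a ±3 h window: readings are interpolated with a
  monotone piecewise cubic Hermite polynomial (PCHIP; shape-preserving, no
  overshoot between fingersticks), resampled on a 5-minute grid, and
  summarized (mean, population SD, range, min, max, least-squares slope in
  mmol/L/h, moment skewness, excess kurtosis). Two knots degrade to a line,
  one knot to a constant with skew/kurtosis undefined;
* nearest readings before/after the event, overall and by glycemic state
  (hypo < 4, in-target [4, 10], hyper > 10 mmol/L; the upper thresholds are
  package defaults, configurable, since no standard applies to every
  clinic);
* nearest QA/basal/carb records before/after, with dose and amount centered
  on the subject's 3-month mean of that signal (between-subject dose scale
  is a nuisance; the science is in the deviation);
* the most recent bolus-advisor record within 6 h (advised food/correction/
  total insulin, advised-minus-logged difference, meal-rise setting,
  exercise-tag flag); three further advisor settings (insulin-on-board,
  allowed BG value, carb counting unit) ride along as extras outside the
  canonical 83;
* 3-month summary statistics per signal (BG, QA, basal, carbs): mean,
  population SD, range, max, min, mean-crossing rate (sign changes of
  consecutive deviations from the window mean, divided by the sample count,
  hence in [0, 1)), skewness, kurtosis; for BG additionally the mean
  negative and mean positive consecutive-reading slope, with pairs more than
  6 h apart excluded as overnight artifacts;
* quiz engagement over 3 months (answers, active days, points mean/SD,
  per-session answer count mean/SD).

All long-horizon and baseline quantities use data strictly before the event
(no look-ahead; a dedicated truncation test enforces this). Missing values
are explicit NaN end to end — a feature that cannot be computed is reported
missing, never silently zero — and each consumer declares its policy:
complete-case rows per model in the association arm, training-fold mean
imputation in the classification arm.

## Mixed-effects logistic association (`hypocause.mixedlogit`, `hypocause.association`)

For each cause k the outcome is the indicator that an episode belongs to k,
and events are clustered within subjects, so the model is a random-intercept
logit:

    logit P(y_ij = 1) = β0 + x_ijᵀβ + b_i,   b_i ~ N(0, σ_b²).

The estimator maximizes the exact marginal likelihood with the random
intercept integrated out by adaptive Gauss–Hermite quadrature (15 nodes by
default): per subject the integrand is re-centered at its mode (safeguarded
Newton, vectorized across subjects) and re-scaled by its curvature before
applying the Hermite rule. The analytic gradient differentiates the
quadrature sum with the centering held fixed; because an exact quadrature is
centering-invariant, the neglected terms are of the order of the quadrature
error. Optimization is L-BFGS-B over (β, log σ_b) on internally
unit-scaled columns (an exact change of variables — reported coefficients
are per-unit-of-predictor), warm-started from a plain-logistic IRLS fit.
Standard errors come from the inverse observed information (numerical
Hessian at the optimum); Wald z = β/SE with two-sided normal p-values;
BIC = k ln n − 2 lnL with k counting fixed effects plus the variance
parameter. The implementation agrees with `lme4::glmer(nAGQ = 15)` to
~1e-4 on simulated panels (a cross-check test runs R when available) and
collapses to plain logistic regression when σ_b → 0.

Analysis arms:

* **single-variable scan** — one fit per feature on that feature's own
  complete cases (maximizes usable events per fit); reports β, z, p, stars
  (* p<0.05, ** p<0.01, *** p<0.001 — raw, uncorrected for multiplicity,
  which is the standard presentation in this literature and a known
  statistical caveat);
* **multiple regression** — advisor features and raw `tod` excluded,
  features ranked by single-feature-model BIC (top 40 by default; both the
  cutoff and per-category vs global screening are configuration choices,
  as no canonical rule exists), shared complete-case rows, then iterative
  VIF filtering (drop the worst column while any VIF ≥ 10). Exactly
  collinear columns get infinite VIF; ties drop the latest column in
  registry order, so of the complementary pair `cos_tod`/`sin_tod`
  (they sum to 12 h identically) the earlier one survives, carrying the
  daytime effect with the opposite sign. The joint fit per category then
  yields the reported coefficients.

The dataset is centered but never scaled before fitting, so coefficients
remain interpretable per unit of the predictor.

## Classification experiments (`hypocause.classify`, `hypocause.nn`)

Design: outer grouped 10-fold CV — subjects are greedily partitioned into
folds balancing episode counts, and no subject ever appears on both sides of
a split — with a grouped 5-fold plan nested inside each outer training set.
Per outer fold:

1. mean-imputation and standardization fitted on the training subjects only
   (optionally followed by a full PCA whose basis is likewise
   training-fold-only);
2. SFFS feature selection: forward-add the feature maximizing the inner-CV
   mean F1 of an extremely randomized trees evaluator (class-weighted
   samples, 100 trees by default, leaf size ≥ 5), then repeatedly float out
   any member whose removal strictly improves the best score recorded at the
   smaller size. The forward phase tolerates one non-improving addition
   (the returned subset is the best-scoring one observed), because with a
   tree-ensemble criterion the score is noisy and a strict first-failure
   stop was observed to drop genuinely informative features;
   `SFFSConfig(patience=0)` restores the strict rule. The subset size is
   capped (default 20) to bound runtime.
3. a small NumPy feed-forward network on the selected columns: three hidden
   layers of width equal to the subset size, ReLU, inverted dropout 0.6,
   output sigmoid (one-vs-rest) or 3-way softmax; trained with
   inverse-class-frequency observation weights w_i = N_obs/(N_cl · N_obs_i)
   and minibatch Adam (lr 1e-2, batch 64, up to 600 epochs). 20% of the
   training subjects are held out internally; the checkpoint — and, for
   binary models, the decision threshold on a 0.05–0.95 grid — maximizing
   the requested objective (F1, recall or precision) on that split is kept,
   with early stopping after 150 stagnant epochs. The schedule was sized on
   separable fixtures: shorter schedules demonstrably undertrain at 60%
   dropout with the narrow widths this design produces.
4. per-class precision, recall, F1 and Matthews correlation on the held-out
   subjects, with zero-denominator conventions (precision/recall/F1 = 0,
   MCC = 0 for a constant predictor); multiclass summaries are unweighted
   class averages. Fold aggregation reports mean ± sample SD (ddof = 1).

SFFS runs once per fold; the objective affects only classifier training.

## Numerical and procedural choices

* Timestamps are timezone-naive local times at minute resolution; every
  offset is a decimal hour.
* Population (n-denominator) moments everywhere; long-horizon SD/range/
  crossing/skew/kurtosis are reported missing below 2 samples.
* PCHIP knots with duplicate timestamps are merged by mean before fitting.
* The quadrature node count (15), Newton tolerances (1e-10), and L-BFGS-B
  tolerances (tighter for ≤10 predictors, relaxed for wide designs where
  the trailing digits are below quadrature error) are fixed constants.
* Complete separation raises an error rather than returning divergent
  coefficients; non-convergence is flagged on the fit object and warned,
  never silent.
* Determinism: every stochastic component (generator, fold plans, tree
  evaluator, network initialization and dropout) is driven by explicit
  seeds; rerunning a pipeline config reproduces byte-identical artifacts.

## Problem sizes used by tests and the acceptance script

The shipped test suite and `scripts/acceptance.py` exercise the full
pipeline at sizes chosen to make each property sharp but cheap: cohorts at
the default 54-subject scale; recovery studies with 100 replicates of
200 subjects × 20 events for the estimator; SFFS recovery with 3 planted
among 30 noise features at n = 800 over 20 seeds with a 10-tree evaluator;
end-to-end classification checks on a ~20-feature column subset with a
10-tree evaluator and subset cap 5. The heavyweight defaults (100 trees,
cap 20, all 83 columns) are what `analysis/04_classification_cv.py full`
runs.

## Limitations

* Synthetic validation only: effect magnitudes are package choices, not
  estimates from clinical data.
* The association arm reports raw p-values across many fits.
* One random intercept per subject; no random slopes, no GEE alternative.
* The PCA variant standardizes before projection; unscaled PCA would be
  dominated by large-unit features and is deliberately not offered.
* Binary gender coding (female = 0, male = 1) follows the emulated cohort's
  recording practice and is configurable at the data layer.
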