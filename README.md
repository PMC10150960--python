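# hypocause

Why did a hypoglycemia episode happen? People with type 1 diabetes who label
the presumed causes of their low-glucose events (below 4 mmol/L) in a
digital self-care diary — physical activity, a food-intake mistake, a
medication-dosing mistake — create a supervised-learning problem over very
irregular data: sparse fingerstick glucose readings, insulin doses, carb
records, bolus-advisor logs and e-learning activity, all clustered within
subjects. `hypocause` implements the complete analysis workflow for this
setting, aimed at biostatisticians and ML researchers working on diabetes
self-care data:

* a **synthetic cohort generator** that emulates such diaries (54 subjects,
  ~800 labeled episodes, cause mix ≈ 0.48/0.36/0.16) and *injects*
  cause-conditional mechanisms — daytime-concentrated activity episodes,
  above-average pre-meal boluses before food mistakes, raised basal doses
  before medication mistakes — so every downstream claim is testable
  against known ground truth;
* an **83-variable event representation** per episode: temporal encodings,
  statistics of the PCHIP-interpolated glucose trajectory in a ±3 h window,
  nearest readings/doses/carbs with subject-specific 3-month centering,
  bolus-advisor context, 3-month behavioral summaries, and quiz engagement
  — with explicit missingness throughout;
* **mixed-effects logistic association analysis**: for cause k and feature x,

      logit P(y_ijk = 1) = β₀ + β₁ x_ij + b_i,   b_i ~ N(0, σ_b²),

  fitted by maximum likelihood with 15-node adaptive Gauss–Hermite
  quadrature (verified against `lme4::glmer`), in a single-variable arm and
  a multiple-regression arm with BIC screening and VIF ≥ 10 collinearity
  filtering; Wald z statistics and significance stars;
* **subject-grouped nested-CV classification**: outer grouped 10-fold CV,
  per-fold SFFS feature selection scored by a class-weighted extremely
  randomized trees evaluator in an inner grouped 5-fold, then a 3-hidden-
  layer dropout (60%) network trained with inverse-frequency weights
  w_i = N_obs/(N_cl·N_obsᵢ) and an F1/recall/precision-objective checkpoint;
  one-vs-rest and exclusive 3-class scenarios, raw or PCA feature space;
  per-class F1, recall, precision and Matthews correlation, mean ± SD over
  folds.

See `docs/methods.md` for the models, assumptions, and every numerical
choice.

## Worked example

The numbered scripts under `analysis/` run the whole analysis on a synthetic
cohort (seed 1):

```bash
python analysis/01_simulate_cohort.py 1
python analysis/02_extract_features.py
python analysis/03_association_analysis.py
python analysis/04_classification_cv.py 1
python analysis/05_render_report.py
```

Output of the first three stages:

```
diaries: 54 subjects, 786 episodes, class mix {'ACTIVITY': 0.505, 'FOOD': 0.35, 'MEDICATION': 0.145}
features.csv: 690 events x 83 canonical features; advisor data on 40% of events; overall missingness 5.1%
single-variable scan: 261 fits; 19% starred
  cos_tod (ACTIVITY): beta=-0.363*** z=-5.39  <- daytime concentration of activity episodes (offset-from-noon sign)
  pre_ins_dosage (FOOD): beta=+0.606*** z=+4.79  <- above-average QA dose before food-related episodes
  pre_bas_dosage (MEDICATION): beta=+0.967*** z=+6.41  <- raised basal dose before medication episodes
  is_bday (MEDICATION): beta=+0.614 z=+1.21  <- business-day concentration of medication episodes
```

Reading this: the generator planted 786 episodes of which 690 carry
high-confidence analyzable labels; bolus-advisor context exists for a
minority of events, as in real diaries. The joint models recover the
injected directions — each unit of quick-acting insulin above the subject's
3-month mean raises the log-odds of a food-related cause by ≈0.61
(***: p < 0.001). The daytime-activity effect is reported through
`cos_tod` because the two time-of-day offsets are exact complements (they
sum to 12 h) and the VIF filter keeps only one: a *negative* offset-from-
noon coefficient is daytime concentration. The classification stage then
prints fold-averaged metrics per scenario:

```
ovr:ACTIVITY     ACTIVITY    F1 0.73±0.09  MCC 0.36±0.26
ovr:FOOD         FOOD        F1 0.52±0.05  MCC 0.04±0.08
ovr:MEDICATION   MEDICATION  F1 0.34±0.18  MCC 0.16±0.24
multiclass       ACTIVITY    F1 0.50±0.28  MCC 0.22±0.25
multiclass       FOOD        F1 0.52±0.24  MCC 0.30±0.26
multiclass       MEDICATION  F1 0.41±0.28  MCC 0.39±0.27
```

The one-vs-rest activity F1 of 0.73 ± 0.09 sits well above the 0.50
prevalence baseline, the majority class is the easiest to detect, and the
rarest (medication) the hardest — the qualitative pattern such diary
studies report. On the matched null cohort (mechanisms zeroed) every MCC
is within ±0.1 of zero.

A `hypocause` CLI exposes the same stages
(`hypocause simulate|featurize|associate|classify|run`).

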