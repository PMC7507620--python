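# etsm — ensemble time-series modelling for early AKI prediction

Acute kidney injury (AKI) is a common ICU complication whose early detection
changes outcomes: a risk flag raised 24–48 hours before onset leaves time for
intervention. `etsm` implements an ensemble time-series model for this task
over routine longitudinal electronic health records — timestamped vital signs
and laboratory values, daily medication administrations, and stay metadata —
for clinical data scientists who want a complete, testable pipeline from raw
long-format tables to evaluated risk models.

## The model

**Outcome.** AKI is labeled from serum creatinine by the KDIGO criteria: a
rise of ≥ 0.3 mg/dl within 48 h (against the minimum of the preceding two
days), or ≥ 1.5× the stay's baseline (first recorded value) within seven
days. Onset is the earliest day on which either criterion fires. Stays with
no usable data or too short for the prediction lead are excluded with full
bookkeeping.

**Features.** Each stay is frozen at its *predictive point* — onset minus the
lead for AKI stays, discharge minus the lead otherwise — and described by two
indicator groups:

* *explicit indicators*: each vital/lab variable contributes its admission-day
  and predictive-point values; missing slots are filled from the nearest
  observation in time, then from derivation-set medians;
* *implicit indicators*: the drugs given on one day form a *drug combination*
  c; the distinct combinations of the derivation corpus form a vocabulary, and
  each patient's medicated days a sequence s. Combination weights follow a
  TF–IDF analogue,

      IF(c, s)  = f_{c,s} / Σ_{c'} f_{c',s}
      ICF(c)    = ln( N / (1 + n_c) )
      IFICF     = IF × ICF,

  with f_{c,s} the number of days combination c appears in s, N the number of
  derivation patients and n_c the number whose sequence contains c. Ablation
  encoders replace IFICF with per-drug booleans, per-drug day counts, or
  nothing (explicit-only).

**Classifier and protocol.** A gradient-boosted tree classifier (XGBoost; 144
estimators, max depth 8, min child weight 5) is trained on a rebalanced
derivation set — random undersampling to 1:1 by default; random oversampling
and cost-sensitive weighting (positive weight = n_neg/n_pos) are also
provided — and scored on the untouched 40% validation split. Metrics are the
rank-form (Mann–Whitney) AUC with mid-rank ties, sensitivity and F1 at
threshold 0.5, and step-summed average precision, aggregated over ten
stratified splits as mean ± 95% CI with paired t-tests between variants.

Because hospital EHR extracts cannot be redistributed, the package ships a
seeded synthetic-cohort generator with the same statistical shape (skewed
drug popularity, AR(1) vitals, missingness, calibrated AKI prevalence, and a
plantable nephrotoxic drug-combination effect) so every stage is testable.

## Worked example

```python
from etsm import AkiRiskModel, GeneratorConfig

model = AkiRiskModel.from_generator(GeneratorConfig(seed=7))
res = model.fit(n_repeats=10, seed=7)
print(res.summary())
print(res.top_importances(k=5, group="implicit").to_string(index=False))
```

```
AKI risk model — repeated stratified-split evaluation
========================================================
samples: 2000 (278 positive)   lead: 24 h
encoder: ificf   resample: undersample 1:1
classifier: gradient-boosted trees (n_estimators=144, max_depth=8, min_child_weight=5)
repeats: 10 (60/40 derivation/validation)
--------------------------------------------------------
                 auc: 0.741 +/- 0.020 (95% CI)
         sensitivity: 0.670 +/- 0.043 (95% CI)
                  f1: 0.360 +/- 0.017 (95% CI)
   average_precision: 0.345 +/- 0.029 (95% CI)

 rank    group          source  importance
    1 implicit      (d05, d09)    4.690476
    2 implicit          (d00,)    1.785861
    3 implicit      (d00, d01)    1.673351
    4 implicit (d00, d01, d02)    0.613589
    5 implicit      (d00, d02)    0.305636
```

The synthetic cohort plants a +2.0 logit AKI hazard effect on the drug pair
`(d05, d09)` after two exposure days: the model recovers it as the top-ranked
implicit indicator, and its validation AUC of 0.741 compares with ~0.60 for
the explicit-only ablation — medication history carries real signal here.

The same pipeline runs from the shell on any artifact directory:

```sh
etsm simulate --out run/ --seed 7
etsm label     --data run/ --lead 24
etsm evaluate  --data run/ --repeats 10 --seed 7
etsm ablate    --data run/ --repeats 10 --seed 7
etsm sweep     --data run/ --repeats 10 --seed 7
```

To use real data instead, place `measurements.csv`, `medications.csv` and
`stays.csv` (comma- or tab-delimited, ISO dates; creatinine as the
measurement variable `creatinine`, in mg/dl) in the directory and start from
`label`.

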