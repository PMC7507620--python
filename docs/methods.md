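# Methods

This note records the modelling choices behind `etsm`: what is computed, the
conventions adopted where several operationalizations exist, what the
synthetic cohort generator does and does not emulate, and the limits of what
green tests demonstrate.

## Time and outcome

All timing is at calendar-day granularity, stored as integer offsets from
admission (day 0). A 24 h prediction lead is one day, 48 h two days; a stay
"shorter than 24 h" is one whose discharge falls on its admission day.

AKI is labeled from serum creatinine (mg/dl) with the two KDIGO criteria —
an absolute rise of ≥ 0.3 mg/dl within 48 h and a relative rise to ≥ 1.5×
baseline within 7 days. Neither criterion fixes a baseline convention for
retrospective data, so the package adopts the most common one: the baseline
is the first recorded creatinine of the stay, and the absolute rise is
tested against the minimum value among observations in the preceding two
days. Onset is the earliest day on which either criterion fires. Values in
µmol/l must be converted upstream (÷ 26.5); the ingester does not guess
units. Urine-output criteria and AKI staging are out of scope — the outcome
is binary.

The labeler is verified against an exhaustive pair-scan oracle on random
series; the two implementations are independent (rolling-window logic vs
brute-force enumeration of observation pairs).

## Predictive points

AKI stays freeze features at onset − lead. For non-AKI stays no anchor is
dictated by the outcome; the package anchors them at discharge − lead, which
mirrors the positive construction and gives each negative its maximal
observation window. This is a package convention, not a property of the
underlying protocol; a deployment scenario would instead score every
patient-day. Stays whose predictive point would precede admission are
excluded and counted.

## Feature generation

Explicit indicators are the raw variable values on the admission day and the
predictive-point day (two columns per variable; the last observation of a
day wins when several fall on it). The label-defining analyte, creatinine,
is deliberately excluded from the explicit block: its predictive-point value
encodes the outcome about to be declared.

Implicit indicators weight daily drug combinations by IFICF (see README for
the formulas). Conventions:

* a combination is the canonical (sorted, distinct) tuple of drug IDs of one
  medicated day; medication-free days contribute nothing to the sequence;
* only days ≤ the predictive point are visible to any medication feature;
* the vocabulary, the document frequencies n_c (counting patients, not
  days), and N are fitted on derivation patients only and frozen for
  validation; validation-only combinations get n_c = 0 and no column. This
  prevents corpus statistics from leaking validation information, at the
  cost of discarding combinations unseen in derivation;
* ICF uses the natural log. The base is a global scale factor on the
  implicit block and is irrelevant to tree splits;
* an empty medication history yields an all-zero implicit row rather than a
  division-by-zero.

Imputation fills a missing explicit slot with the patient's nearest-in-time
observation of the same variable anywhere in the stay (ties prefer the
earlier day — the information available sooner clinically); a patient with
no observation of the variable falls back to the derivation-set median of
the column, and a column with no derivation observations at all is zero-
filled with a warning. Observed values are never altered.

The ablation encoders (`bool`: ever-took-drug indicators; `times`: drug day
counts; `none`: explicit only) share the explicit block and the visibility
cutoff, so variant comparisons isolate the medication representation.

## Classifier, imbalance, evaluation

The backend is XGBoost (`hist`, single thread, seeded) with 144 estimators,
maximum depth 8 and minimum child weight 5 — the hyperparameters used for
every reported experiment. Note that minimum child weight 5 is tuned to
cohorts in the thousands; on toy cohorts of a few hundred samples it can
forbid all splits and yield constant scores, so small-scale tests pass a
lighter spec. Any classifier exposing `fit` / `predict_proba` and gain-style
importances could be substituted behind `ClassifierSpec`.

Imbalance handling operates on derivation indices only: random undersampling
(all minority kept, majority subsampled without replacement to the requested
positives:negatives ratio, clamping with a warning when infeasible), random
oversampling (minority duplicated with replacement), or cost-sensitive
weighting (positive-class weight n_neg/n_pos). The validation set is always
scored at its natural imbalance. The ratio sweep enumerates 10:1 … 1:1 …
1:10 (19 distinct grid points).

Metrics: AUC in the Mann–Whitney rank form with ascending mid-ranks for
ties (equal to pairwise win probability with half-credit ties, verified
against a pairwise oracle to 1e-12); sensitivity and F1 at a fixed 0.5
threshold (configurable; F1 is 0 by convention when precision and
sensitivity both vanish); average precision as the uninterpolated step sum
over distinct-score thresholds. Aggregation over the ten 60/40 stratified
repeats reports mean ± t-based 95% CI (t₀.₉₇₅,df=9 · sd/√10). Variant
comparisons use a two-sided *paired* t-test on per-repeat differences —
splits are shared bit-exactly across variants — with identical series giving
p = 1 and constant nonzero differences flagged as degenerate. Whether to
pair or pool across repeats is a genuine fork; pairing is the more powerful
choice given shared splits. Importances use XGBoost gain, decoded back to
drug-ID sets for implicit columns, ties broken toward the lower column
position.

## Synthetic cohort generator

The generator exists to give every pipeline stage a testbed with the right
statistical shape, not to mimic any hospital system. Defaults (the study
conditions used by the acceptance experiments): 2000 patients, stays uniform
on 3–14 days, 75 drugs, 10 vitals, 15% target AKI prevalence, 20%
missingness, and one planted combination `(d05, d09)` adding +2.0 logits to
the daily AKI hazard once the patient has accumulated two exposure days
(30% of patients exposed, exposure days at probability 0.5).

Mechanics: per-day hazard logit = base + 1.0·z_i + Σ planted effects, with
z_i a standard-normal patient frailty also expressed in the heart-rate
series (mean shift of one between-patient SD), so physiology alone carries
some signal and the explicit-only ablation is a meaningful baseline. The
base logit is solved by bisection so the *expected* prevalence over the
sampled exposures and frailties equals the target exactly; realized
prevalence differs only by binomial noise. Drug days follow a geometric
popularity law (ratio 0.65, chosen so the most-used drug covers roughly
70–90% of patients) with day-to-day regimen persistence 0.7, giving the
repeated daily combinations the IFICF weighting assumes. Creatinine is
generated last, conditional on the sampled event day: non-event trajectories
stay within a band that can satisfy neither KDIGO criterion, and event-day
values are forced over the absolute threshold (or the relative one, with
probability 0.5 when the onset falls within the baseline window) — so the
intended label is reproduced by the labeler by construction, a property the
tests check patient-by-patient. All draws descend from per-patient
`SeedSequence` keys; cohorts are byte-reproducible and patient-wise
order-independent.

What the generator does **not** emulate: inter-drug correlation beyond the
planted set, dose/route, hour-resolution dynamics, informative missingness,
drift between admission and discharge physiology, or real nephrotoxicity.
Passing recovery tests therefore show that the pipeline extracts a planted
medication signal under realistic sparsity and imbalance — not that the
model attains any particular performance on real ICU data.

## Problem sizes

The bundled experiments run at desk scale by design: recovery and sweep
experiments use the 2000-patient cohort with ten paired repeats (one
featurization per encoder per repeat, one fit per variant); oracle
equivalence checks use 500–1200 random miniatures. These sizes give the
acceptance experiments comfortable statistical margins while keeping the
whole suite under a minute of compute on one CPU.

## Known limitations

* Negative-class predictive points anchored at discharge make stay length
  weakly informative; this is inherent to the sample construction.
* Nearest-observation imputation may use a post-predictive-point observation
  for a missing slot; with slots only at day 0 and the predictive point this
  touches the admission slot of sparsely measured patients.
* The derivation-only vocabulary means validation patients whose regimens
  never occur in derivation contribute empty implicit rows.
* Day granularity collapses the 48 h window to two calendar days; hourly
  records would sharpen both labeling and lead times.
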