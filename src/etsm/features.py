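"""Explicit and implicit indicator generation.

Two feature groups are built for every sample, both frozen at the predictive
point:

* the **explicit indicator group** — each vital-sign / laboratory variable
  contributes two columns, its value on the admission day and its value on the
  predictive-point day;
* the **implicit indicator group** — derived from medication records.  The
  drugs a patient receives on one calendar day form a *drug combination*; the
  distinct combinations of the derivation corpus form the vocabulary
  ``C = {c_1..c_M}``, and each patient's medicated days become an ordered
  combination-ID sequence ``s_i``.  The default weighting is IFICF, a TF-IDF
  analogue over medication days:

      IF(c, s)   = f_{c,s} / sum_{c'} f_{c',s}        (within-patient frequency)
      ICF(c)     = ln(N / (1 + n_c))                  (corpus rarity, N patients)
      IFICF(c,s) = IF(c, s) * ICF(c)

  ``n_c`` counts patients (not days) whose sequence contains ``c``.  Two
  simpler encoders are provided for ablation: per-drug booleans ("ever took
  drug d") and per-drug day counts.

Only medication and measurements up to and including the predictive point are
visible to feature generation; vocabulary, document frequencies and imputation
medians are fitted on derivation samples only and frozen for validation.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord, PredictionSample

__all__ = [
    "Combination",
    "CombinationVocabulary",
    "MedicationSequence",
    "FeatureMatrix",
    "build_vocabulary",
    "medication_sequence",
    "indicator_frequency",
    "inverse_cohort_frequency",
    "ificf_weights",
    "bool_drug_features",
    "times_drug_features",
    "explicit_features",
    "impute",
    "assemble",
    "ENCODERS",
]

#: A drug combination in canonical form: the sorted tuple of distinct drug IDs
#: administered on one day.
Combination = tuple[str, ...]

ENCODERS = ("ificf", "bool", "times", "none")


def canonical(drugs: Iterable[str]) -> Combination:
    return tuple(sorted(set(drugs)))


@dataclass
class CombinationVocabulary:
    """The distinct-combination set C with stable IDs and corpus frequencies.

    ``combinations`` is lexicographically ordered, so combination IDs (list
    positions) are reproducible across runs and platforms.  ``doc_freq[k]``
    is n_c: the number of corpus patients whose sequence contains combination
    k.  ``n_corpus_patients`` is N.
    """

    combinations: list[Combination]
    doc_freq: dict[int, int]
    n_corpus_patients: int
    _index: dict[Combination, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {c: k for k, c in enumerate(self.combinations)}

    def __len__(self) -> int:
        return len(self.combinations)

    def combo_id(self, combo: Combination) -> int | None:
        """The vocabulary ID of a canonical combination, or None if unseen."""
        return self._index.get(combo)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_corpus_patients": self.n_corpus_patients,
                "combinations": [list(c) for c in self.combinations],
                "doc_freq": {str(k): v for k, v in self.doc_freq.items()},
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CombinationVocabulary":
        obj = json.loads(text)
        return cls(
            combinations=[tuple(c) for c in obj["combinations"]],
            doc_freq={int(k): v for k, v in obj["doc_freq"].items()},
            n_corpus_patients=obj["n_corpus_patients"],
        )


@dataclass(frozen=True)
class MedicationSequence:
    """A patient's ordered daily combinations up to the predictive point."""

    patient_id: str
    combos: tuple[Combination, ...]

    def __len__(self) -> int:
        return len(self.combos)


def medication_sequence(
    record: PatientRecord, predictive_point: int
) -> MedicationSequence:
    """The day-ordered combination sequence s_i, visible days only.

    One combination per day on which at least one drug was given; medication-
    free days contribute nothing.
    """
    combos = tuple(
        canonical(drugs)
        for day, drugs in sorted(record.daily_drugs.items())
        if day <= predictive_point and drugs
    )
    return MedicationSequence(record.patient_id, combos)


def build_vocabulary(
    records: Sequence[PatientRecord],
    predictive_points: Mapping[str, int],
) -> CombinationVocabulary:
    """Collect the combination set C over the given (derivation) patients.

    Document frequency n_c counts patients whose sequence contains c, not the
    number of days; N is the number of patients supplied (medicated or not).
    Deterministic: IDs follow the lexicographic order of canonical sets and
    are invariant to patient and day order.
    """
    support: dict[Combination, int] = {}
    for rec in records:
        seq = medication_sequence(rec, predictive_points[rec.patient_id])
        for combo in set(seq.combos):
            support[combo] = support.get(combo, 0) + 1
    combos = sorted(support)
    return CombinationVocabulary(
        combinations=combos,
        doc_freq={k: support[c] for k, c in enumerate(combos)},
        n_corpus_patients=len(records),
    )


# ---------------------------------------------------------------------------
# implicit indicator weights


def indicator_frequency(combo: Combination, sequence: MedicationSequence) -> float:
    """IF: the fraction of the sequence's days on which `combo` was the day's
    combination.  An empty sequence yields 0 for every combination (the
    all-zero implicit row convention)."""
    if len(sequence) == 0:
        return 0.0
    return sequence.combos.count(combo) / len(sequence)


def inverse_cohort_frequency(
    combo: Combination, vocab: CombinationVocabulary
) -> float:
    """ICF = ln(N / (1 + n_c)); a combination unseen in the corpus has n_c = 0.

    Strictly decreasing in n_c; negative when the combination occurs in every
    sequence (n_c = N).
    """
    combo_id = vocab.combo_id(combo)
    n_c = vocab.doc_freq[combo_id] if combo_id is not None else 0
    return math.log(vocab.n_corpus_patients / (1 + n_c))


def ificf_weights(
    sequence: MedicationSequence, vocab: CombinationVocabulary
) -> np.ndarray:
    """The IFICF row over the vocabulary: IF(c, s) * ICF(c) per combination.

    Zero wherever IF is zero, so the support is at most the sequence's
    distinct combinations; combinations of the sequence absent from the
    vocabulary get no column (they still count in the IF denominator).
    """
    row = np.zeros(len(vocab))
    if len(sequence) == 0:
        return row
    counts: dict[Combination, int] = {}
    for combo in sequence.combos:
        counts[combo] = counts.get(combo, 0) + 1
    total = len(sequence)
    for combo, f in counts.items():
        k = vocab.combo_id(combo)
        if k is None:
            continue
        icf = math.log(vocab.n_corpus_patients / (1 + vocab.doc_freq[k]))
        row[k] = (f / total) * icf
    return row


def bool_drug_features(
    record: PatientRecord,
    predictive_point: int,
    drug_inventory: Sequence[str],
) -> np.ndarray:
    """One column per drug: 1 iff the drug was ever given on a visible day."""
    seen = set()
    for day, drugs in record.daily_drugs.items():
        if day <= predictive_point:
            seen.update(drugs)
    return np.array([1.0 if d in seen else 0.0 for d in drug_inventory])


def times_drug_features(
    record: PatientRecord,
    predictive_point: int,
    drug_inventory: Sequence[str],
) -> np.ndarray:
    """One column per drug: the number of visible days on which it was given."""
    counts = {d: 0 for d in drug_inventory}
    for day, drugs in record.daily_drugs.items():
        if day <= predictive_point:
            for d in drugs:
                if d in counts:
                    counts[d] += 1
    return np.array([float(counts[d]) for d in drug_inventory])


# ---------------------------------------------------------------------------
# explicit indicators


def explicit_features(
    record: PatientRecord,
    predictive_point: int,
    variables: Sequence[str],
) -> np.ndarray:
    """Admission-day and predictive-point values for each variable.

    Returns a row of length 2 * len(variables): the admission block followed
    by the predictive-point block.  When several observations fall on the
    slot day the last one is taken; an unobserved slot is NaN (imputed
    downstream).  With a zero lead over the whole stay the two blocks
    coincide.
    """
    row = np.full(2 * len(variables), np.nan)
    for j, var in enumerate(variables):
        series = record.measurements.get(var, [])
        for slot, day_wanted in ((0, 0), (1, predictive_point)):
            vals = [v for d, v in series if d == day_wanted]
            if vals:
                row[slot * len(variables) + j] = vals[-1]
    return row


# ---------------------------------------------------------------------------
# matrix assembly and imputation


@dataclass
class FeatureMatrix:
    """Samples x features with per-column provenance.

    ``values`` is indexed by patient_id; ``column_groups[j]`` is one of
    ``explicit_admission``, ``explicit_predpoint``, ``implicit`` and
    ``column_sources[j]`` the variable name, combination ID or drug ID the
    column came from.
    """

    values: pd.DataFrame
    column_groups: list[str]
    column_sources: list[object]
    encoder: str

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def implicit_columns(self) -> list[int]:
        return [j for j, g in enumerate(self.column_groups) if g == "implicit"]

    def metadata(self) -> list[dict]:
        return [
            {"name": str(self.values.columns[j]), "group": g, "source": s}
            for j, (g, s) in enumerate(zip(self.column_groups, self.column_sources))
        ]

    def write(self, values_path, metadata_path) -> None:
        self.values.to_csv(values_path, index_label="patient_id")
        with open(metadata_path, "w") as fh:
            json.dump(
                {"encoder": self.encoder, "columns": self.metadata()},
                fh,
                sort_keys=True,
                default=list,
            )


def assemble(
    samples: Sequence[PredictionSample],
    records: Mapping[str, PatientRecord],
    variables: Sequence[str],
    encoder: str = "ificf",
    vocab: CombinationVocabulary | None = None,
    drug_inventory: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Concatenate the explicit block and the chosen implicit block.

    encoder "ificf" needs a fitted vocabulary; "bool" / "times" need the drug
    inventory; "none" produces the explicit-only matrix (the ablated model).
    Column order is deterministic: admission block, predictive-point block,
    then implicit columns in vocabulary / inventory order.
    """
    if encoder not in ENCODERS:
        raise ValueError(f"unknown encoder {encoder!r}; expected one of {ENCODERS}")
    if encoder == "ificf" and vocab is None:
        raise ValueError("encoder 'ificf' requires a CombinationVocabulary")
    if encoder in ("bool", "times") and drug_inventory is None:
        raise ValueError(f"encoder {encoder!r} requires a drug inventory")

    variables = list(variables)
    names: list[str] = [f"{v}@adm" for v in variables] + [f"{v}@pp" for v in variables]
    groups = ["explicit_admission"] * len(variables) + ["explicit_predpoint"] * len(variables)
    sources: list[object] = variables + variables

    if encoder == "ificf":
        assert vocab is not None
        names += [f"combo{k}" for k in range(len(vocab))]
        groups += ["implicit"] * len(vocab)
        sources += list(vocab.combinations)
    elif encoder in ("bool", "times"):
        assert drug_inventory is not None
        names += [f"drug:{d}" for d in drug_inventory]
        groups += ["implicit"] * len(drug_inventory)
        sources += list(drug_inventory)

    rows = np.empty((len(samples), len(names)))
    for i, sample in enumerate(samples):
        rec = records[sample.patient_id]
        pp = sample.predictive_point
        explicit = explicit_features(rec, pp, variables)
        if encoder == "ificf":
            implicit = ificf_weights(medication_sequence(rec, pp), vocab)  # type: ignore[arg-type]
        elif encoder == "bool":
            implicit = bool_drug_features(rec, pp, drug_inventory)  # type: ignore[arg-type]
        elif encoder == "times":
            implicit = times_drug_features(rec, pp, drug_inventory)  # type: ignore[arg-type]
        else:
            implicit = np.empty(0)
        rows[i] = np.concatenate([explicit, implicit])

    values = pd.DataFrame(
        rows, index=pd.Index([s.patient_id for s in samples], name="patient_id"),
        columns=names,
    )
    return FeatureMatrix(values, groups, sources, encoder)


def impute(
    matrix: FeatureMatrix,
    records: Mapping[str, PatientRecord],
    samples: Sequence[PredictionSample],
    derivation_mask: Sequence[bool],
) -> FeatureMatrix:
    """Fill missing explicit cells; implicit columns are never touched.

    A missing slot is first filled with the same patient's nearest-in-time
    observation of that variable (any day of the stay), preferring the
    earlier day on ties.  A patient with no observation of the variable at
    all falls back to the derivation-set median of the column;
    medians are computed on derivation rows only and reused for validation
    rows.  A column entirely missing in the derivation set is filled with 0
    (with a warning).  Observed values are never altered; the output has no
    missing entries in explicit columns.
    """
    values = matrix.values.copy()
    by_pid = {s.patient_id: s for s in samples}
    slot_day = {"explicit_admission": lambda s: 0,
                "explicit_predpoint": lambda s: s.predictive_point}

    for j, group in enumerate(matrix.column_groups):
        if group not in slot_day:
            continue
        var = matrix.column_sources[j]
        col = values.columns[j]
        missing = values[col].isna()
        for pid in values.index[missing]:
            sample = by_pid[pid]
            day = slot_day[group](sample)
            series = records[pid].measurements.get(var, [])
            if series:
                # nearest day; ties resolved toward the earlier day
                d_best, v_best = min(series, key=lambda dv: (abs(dv[0] - day), dv[0]))
                values.loc[pid, col] = v_best

    deriv = values.loc[np.asarray(derivation_mask, dtype=bool)]
    for j, group in enumerate(matrix.column_groups):
        if group not in slot_day:
            continue
        col = values.columns[j]
        if not values[col].isna().any():
            continue
        median = deriv[col].median()
        if pd.isna(median):
            warnings.warn(
                f"column {col!r} entirely missing in derivation set; filled with 0",
                stacklevel=2,
            )
            median = 0.0
        values[col] = values[col].fillna(median)

    return FeatureMatrix(values, list(matrix.column_groups),
                         list(matrix.column_sources), matrix.encoder)
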