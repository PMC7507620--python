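"""Cohort ingestion, KDIGO creatinine labeling, filtering and predictive points.

An ICU stay is represented as a :class:`PatientRecord` holding daily vital-sign /
laboratory measurements, daily drug sets and the serum-creatinine series.  Time
is handled at calendar-day granularity, stored internally as integer day
offsets from admission (day 0 = admission day); a 24 h prediction lead is one
day and a 48 h lead two days.

Acute kidney injury is labeled from creatinine alone, following the KDIGO
consensus definition: a rise of >= 0.3 mg/dl within 48 hours, or a rise to
>= 1.5 times the baseline value within seven days.  The baseline is the first
recorded creatinine of the stay and the absolute-rise criterion compares each
observation against the minimum value observed in the preceding two days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, UnlabelableError

__all__ = [
    "PatientRecord",
    "CohortLabel",
    "PredictionSample",
    "CohortFilterReport",
    "read_cohort",
    "label_kdigo",
    "label_cohort",
    "filter_cohort",
    "assign_predictive_points",
    "KDIGO_ABS_RISE_MGDL",
    "KDIGO_ABS_WINDOW_DAYS",
    "KDIGO_REL_RATIO",
    "KDIGO_REL_WINDOW_DAYS",
]

#: KDIGO creatinine thresholds (mg/dl and days).  Creatinine must already be
#: in mg/dl; values recorded in umol/l divide by 26.5 kept upstream.
KDIGO_ABS_RISE_MGDL = 0.3
KDIGO_ABS_WINDOW_DAYS = 2  # 48 h at day granularity
KDIGO_REL_RATIO = 1.5
KDIGO_REL_WINDOW_DAYS = 7

#: Variable name under which serum creatinine appears in the measurements table.
CREATININE_VARIABLE = "creatinine"


@dataclass
class PatientRecord:
    """One ICU stay: metadata, measurements, daily drug sets and creatinine.

    ``measurements`` maps a variable name to a day-sorted list of
    ``(day_offset, value)`` pairs; ``daily_drugs`` maps a day offset to the set
    of drug identifiers administered that day; ``creatinine`` is the serum
    creatinine series in mg/dl, kept separate from ``measurements`` because it
    defines the outcome.
    """

    patient_id: str
    admission_date: date
    discharge_date: date
    measurements: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    daily_drugs: dict[int, frozenset[str]] = field(default_factory=dict)
    creatinine: list[tuple[int, float]] = field(default_factory=list)

    @property
    def stay_days(self) -> int:
        """Length of stay in whole days (0 for a sub-day stay)."""
        return (self.discharge_date - self.admission_date).days

    def validate(self) -> None:
        if self.admission_date > self.discharge_date:
            raise IntegrityError(
                f"patient {self.patient_id}: admission after discharge"
            )
        last = self.stay_days
        for var, series in self.measurements.items():
            for day, _ in series:
                if not 0 <= day <= last:
                    raise IntegrityError(
                        f"patient {self.patient_id}: {var} measured on day {day} "
                        f"outside stay [0, {last}]"
                    )
        for day in self.daily_drugs:
            if not 0 <= day <= last:
                raise IntegrityError(
                    f"patient {self.patient_id}: medication on day {day} "
                    f"outside stay [0, {last}]"
                )
        for day, value in self.creatinine:
            if not 0 <= day <= last:
                raise IntegrityError(
                    f"patient {self.patient_id}: creatinine on day {day} "
                    f"outside stay [0, {last}]"
                )
            if value <= 0:
                raise IntegrityError(
                    f"patient {self.patient_id}: non-positive creatinine {value}"
                )


@dataclass(frozen=True)
class CohortLabel:
    """Binary AKI outcome for one stay.

    ``onset_day`` is the day offset of the earliest day on which a KDIGO
    criterion is satisfied; present iff ``is_aki``.  ``timing_days`` equals
    the onset offset (days from admission to onset).
    """

    patient_id: str
    is_aki: bool
    onset_day: int | None = None

    @property
    def timing_days(self) -> int | None:
        return self.onset_day

    def __post_init__(self) -> None:
        if self.is_aki != (self.onset_day is not None):
            raise ValueError("onset_day must be present iff is_aki")


@dataclass(frozen=True)
class PredictionSample:
    """A classification sample: a stay frozen at its predictive point."""

    patient_id: str
    is_positive: bool
    predictive_point: int  # day offset from admission
    lead_hours: int

    @property
    def lead_days(self) -> int:
        return self.lead_hours // 24


@dataclass
class CohortFilterReport:
    """Bookkeeping for cohort exclusions; counts always reconcile."""

    n_original: int
    removed_no_data: list[str]
    removed_short_stay: list[str]
    retained: list[str]

    @property
    def n_removed_no_data(self) -> int:
        return len(self.removed_no_data)

    @property
    def n_removed_short_stay(self) -> int:
        return len(self.removed_short_stay)

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def to_dict(self) -> dict:
        return {
            "n_original": self.n_original,
            "n_removed_no_data": self.n_removed_no_data,
            "n_removed_short_stay": self.n_removed_short_stay,
            "n_retained": self.n_retained,
            "removed_no_data": sorted(self.removed_no_data),
            "removed_short_stay": sorted(self.removed_short_stay),
            "retained": sorted(self.retained),
        }


# ---------------------------------------------------------------------------
# table ingestion


def _read_table(path, required: Sequence[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment=None)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{name} table {path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def _parse_days(df: pd.DataFrame, col: str, name: str) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        bad = df.loc[parsed.isna(), col].head(5).tolist()
        raise SchemaError(f"{name} table: unparseable {col} values, e.g. {bad}")
    return parsed.dt.date


def read_cohort(
    measurements_table,
    medications_table,
    stays_table,
    creatinine_variable: str = CREATININE_VARIABLE,
) -> list[PatientRecord]:
    """Read the three long-format tables into one :class:`PatientRecord` per stay.

    Expected columns: measurements(patient_id, date, variable, value),
    medications(patient_id, date, drug_id), stays(patient_id, admit_date,
    discharge_date); ISO-8601 dates, comma- or tab-delimited.  Rows whose
    ``value`` does not parse as a number are reported via a warning, never
    silently dropped; referential or stay-window violations raise
    :class:`IntegrityError`.
    """
    stays = _read_table(stays_table, ["patient_id", "admit_date", "discharge_date"], "stays")
    meas = _read_table(measurements_table, ["patient_id", "date", "variable", "value"], "measurements")
    meds = _read_table(medications_table, ["patient_id", "date", "drug_id"], "medications")

    stays = stays.assign(
        parsed_admit=_parse_days(stays, "admit_date", "stays"),
        parsed_disch=_parse_days(stays, "discharge_date", "stays"),
    )
    if stays["patient_id"].duplicated().any():
        dups = stays.loc[stays["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"stays table: duplicate patient_id(s) {dups[:5]}")

    records: dict[str, PatientRecord] = {}
    for row in stays.itertuples(index=False):
        records[row.patient_id] = PatientRecord(
            patient_id=row.patient_id,
            admission_date=row.parsed_admit,
            discharge_date=row.parsed_disch,
        )

    def _check_known(df: pd.DataFrame, name: str) -> None:
        unknown = set(df["patient_id"]) - records.keys()
        if unknown:
            raise IntegrityError(
                f"{name} table references patient_id(s) absent from stays: "
                f"{sorted(unknown)[:5]}"
            )

    if len(meas):
        _check_known(meas, "measurements")
        meas = meas.assign(parsed_day=_parse_days(meas, "date", "measurements"))
        values = pd.to_numeric(meas["value"], errors="coerce")
        bad = values.isna() & meas["value"].notna()
        if bad.any():
            warnings.warn(
                f"measurements table: {int(bad.sum())} row(s) with non-numeric "
                f"value dropped (patients {sorted(set(meas.loc[bad, 'patient_id']))[:5]})",
                stacklevel=2,
            )
        meas = meas.loc[~bad].assign(parsed_value=values[~bad])
        for row in meas.itertuples(index=False):
            rec = records[row.patient_id]
            day = (row.parsed_day - rec.admission_date).days
            if row.variable == creatinine_variable:
                rec.creatinine.append((day, float(row.parsed_value)))
            else:
                rec.measurements.setdefault(row.variable, []).append(
                    (day, float(row.parsed_value))
                )

    if len(meds):
        _check_known(meds, "medications")
        meds = meds.assign(parsed_day=_parse_days(meds, "date", "medications"))
        staged: dict[str, dict[int, set[str]]] = {}
        for row in meds.itertuples(index=False):
            rec = records[row.patient_id]
            day = (row.parsed_day - rec.admission_date).days
            staged.setdefault(row.patient_id, {}).setdefault(day, set()).add(row.drug_id)
        for pid, by_day in staged.items():
            records[pid].daily_drugs = {d: frozenset(s) for d, s in sorted(by_day.items())}

    out = []
    for pid in stays["patient_id"]:
        rec = records[pid]
        for var in rec.measurements:
            rec.measurements[var].sort()
        rec.creatinine.sort()
        rec.validate()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# KDIGO labeling


def label_kdigo(record: PatientRecord) -> CohortLabel:
    """Label one stay with the KDIGO creatinine criteria.

    AKI fires on the earliest day where either (a) the creatinine exceeds the
    minimum value of the preceding two days by >= 0.3 mg/dl, or (b) it reaches
    >= 1.5x the first recorded value within seven days of that baseline.

    Raises
    ------
    UnlabelableError
        If the stay has no creatinine observations.
    """
    series = sorted(record.creatinine)
    if not series:
        raise UnlabelableError(
            f"patient {record.patient_id}: no creatinine observations"
        )
    base_day, base_value = series[0]
    onset: int | None = None
    for i, (day, value) in enumerate(series):
        window_min = min(
            (v for d, v in series[:i] if day - d <= KDIGO_ABS_WINDOW_DAYS),
            default=None,
        )
        abs_fires = window_min is not None and value - window_min >= KDIGO_ABS_RISE_MGDL
        rel_fires = (
            day - base_day <= KDIGO_REL_WINDOW_DAYS
            and value >= KDIGO_REL_RATIO * base_value
        )
        if abs_fires or rel_fires:
            onset = day
            break
    if onset is None:
        return CohortLabel(record.patient_id, is_aki=False)
    return CohortLabel(record.patient_id, is_aki=True, onset_day=onset)


def label_cohort(
    records: Iterable[PatientRecord],
) -> tuple[dict[str, CohortLabel], list[str]]:
    """Label every record; returns (labels, ids of unlabelable stays)."""
    labels: dict[str, CohortLabel] = {}
    unlabelable: list[str] = []
    for rec in records:
        try:
            labels[rec.patient_id] = label_kdigo(rec)
        except UnlabelableError:
            unlabelable.append(rec.patient_id)
    return labels, unlabelable


# ---------------------------------------------------------------------------
# cohort filtering and predictive points


def filter_cohort(
    records: Sequence[PatientRecord],
    labels: Mapping[str, CohortLabel],
    lead_hours: int,
) -> tuple[list[PatientRecord], CohortFilterReport]:
    """Apply the cohort exclusion rules for one prediction lead.

    Removes (1) stays with no measurements, no medications, or no label
    (insufficient information); (2) stays shorter than the lead, and AKI
    stays whose onset precedes admission + lead so no valid predictive point
    exists.  Filtering is total and idempotent.
    """
    lead_days = lead_hours // 24
    removed_no_data: list[str] = []
    removed_short: list[str] = []
    retained: list[PatientRecord] = []
    for rec in records:
        label = labels.get(rec.patient_id)
        has_data = bool(rec.measurements) or bool(rec.daily_drugs)
        if not has_data or label is None:
            removed_no_data.append(rec.patient_id)
            continue
        too_short = rec.stay_days < lead_days
        if label.is_aki and label.onset_day is not None:
            too_short = too_short or label.onset_day < lead_days
        if too_short:
            removed_short.append(rec.patient_id)
            continue
        retained.append(rec)
    report = CohortFilterReport(
        n_original=len(records),
        removed_no_data=removed_no_data,
        removed_short_stay=removed_short,
        retained=[r.patient_id for r in retained],
    )
    return retained, report


def assign_predictive_points(
    records: Sequence[PatientRecord],
    labels: Mapping[str, CohortLabel],
    lead_hours: int,
) -> list[PredictionSample]:
    """Fix the feature-freeze day for every stay.

    AKI stays: predictive point = onset - lead.  Non-AKI stays: discharge -
    lead, giving every negative the maximal observation window (the mirrored
    construction; the choice of anchor for negatives is a package convention).
    Stays whose point would precede admission are excluded with a warning.
    """
    lead_days = lead_hours // 24
    samples: list[PredictionSample] = []
    skipped: list[str] = []
    for rec in records:
        label = labels[rec.patient_id]
        if label.is_aki:
            point = label.onset_day - lead_days  # type: ignore[operator]
        else:
            point = rec.stay_days - lead_days
        if point < 0:
            skipped.append(rec.patient_id)
            continue
        samples.append(
            PredictionSample(
                patient_id=rec.patient_id,
                is_positive=label.is_aki,
                predictive_point=point,
                lead_hours=lead_hours,
            )
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} stay(s) excluded: predictive point before admission "
            f"({sorted(skipped)[:5]})",
            stacklevel=2,
        )
    return samples
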