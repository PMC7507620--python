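"""Seeded synthetic ICU cohorts for exercising the full prediction pipeline.

The generator emulates the statistical structure the pipeline assumes, not any
particular hospital system: per-patient daily drug sets drawn from a skewed
(geometric) popularity law so that a handful of drugs are near-universal;
daily vitals/labs as AR(1) series with patient-level offsets and
missing-at-random cells; and serum-creatinine trajectories constructed *after*
the event day is sampled, so that each intended AKI label is guaranteed to be
reproduced by the KDIGO labeler and each intended non-event trajectory
satisfies neither criterion.

AKI risk follows a discrete-time hazard: on each stay day

    logit h_t = base + beta_vitals * z_i + sum_k effect_k * active_k(t)

where ``z_i`` is a patient frailty (also expressed in the heart-rate series,
so physiology alone carries some signal) and ``active_k(t)`` switches on once
the patient has accumulated the planted combination's minimum exposure days.
The base logit is calibrated by bisection so the expected cohort prevalence
equals the configured target exactly; the realised prevalence then differs
only by binomial noise.

All randomness descends from one root seed through per-patient
``SeedSequence`` keys, so any patient's data is reproducible independently of
cohort ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortLabel, PatientRecord, CREATININE_VARIABLE
from .errors import ConfigurationError

__all__ = ["PlantedCombination", "GeneratorConfig", "generate_cohort", "write_fixture"]

# (mean, between-patient sd, within-day noise sd) for the bundled variables
_VITAL_CATALOG = [
    ("heart_rate", 82.0, 9.0, 4.0),
    ("sbp", 118.0, 12.0, 6.0),
    ("dbp", 72.0, 8.0, 4.0),
    ("resp_rate", 18.0, 3.0, 1.5),
    ("spo2", 96.0, 1.5, 0.8),
    ("temp", 37.0, 0.4, 0.2),
    ("wbc", 9.0, 2.5, 1.0),
    ("hemoglobin", 12.5, 1.5, 0.4),
    ("platelets", 240.0, 50.0, 12.0),
    ("lactate", 1.6, 0.6, 0.25),
]


@dataclass(frozen=True)
class PlantedCombination:
    """A nephrotoxic drug-set effect planted into the hazard."""

    drugs: tuple[str, ...]
    effect: float  # additive logit once active
    min_exposure_days: int = 2


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-size single-centre ICU extract: 75 distinct drugs
    with the most popular covering ~90% of patients, ~15% AKI prevalence,
    stays of 3-14 days, and one planted two-drug nephrotoxic combination with
    a +2.0 logit effect after two exposure days.
    """

    n_patients: int = 2000
    n_drugs: int = 75
    n_vitals: int = 10
    stay_length_range: tuple[int, int] = (3, 14)
    target_prevalence: float = 0.15
    missing_rate: float = 0.2
    planted_combinations: tuple[PlantedCombination, ...] = (
        PlantedCombination(drugs=("d05", "d09"), effect=2.0, min_exposure_days=2),
    )
    exposed_fraction: float = 0.3
    exposure_day_prob: float = 0.5
    drug_popularity: float = 0.65  # geometric ratio; smaller = more head-heavy
    regimen_persistence: float = 0.7  # prob. a day repeats yesterday's drug set
    vitals_effect: float = 1.0  # logit coefficient on the patient frailty
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        lo, hi = self.stay_length_range
        if not 1 <= lo <= hi:
            raise ConfigurationError("stay_length_range must satisfy 1 <= min <= max")
        if not 0 < self.drug_popularity < 1:
            raise ConfigurationError("drug_popularity must lie in (0, 1)")
        inventory = set(self.drug_inventory)
        for combo in self.planted_combinations:
            if not set(combo.drugs) <= inventory:
                raise ConfigurationError(
                    f"planted combination {combo.drugs} not within the drug inventory"
                )

    @property
    def drug_inventory(self) -> list[str]:
        return [f"d{k:02d}" for k in range(self.n_drugs)]

    @property
    def vital_names(self) -> list[str]:
        names = [name for name, *_ in _VITAL_CATALOG[: self.n_vitals]]
        names += [f"lab{k:02d}" for k in range(len(names), self.n_vitals)]
        return names

    def to_json(self) -> str:
        obj = asdict(self)
        obj["planted_combinations"] = [asdict(c) for c in self.planted_combinations]
        return json.dumps(obj, sort_keys=True)

    @classmethod
    def from_dict(cls, obj: dict) -> "GeneratorConfig":
        obj = dict(obj)
        if "planted_combinations" in obj:
            obj["planted_combinations"] = tuple(
                PlantedCombination(
                    drugs=tuple(c["drugs"]),
                    effect=c["effect"],
                    min_exposure_days=c.get("min_exposure_days", 2),
                )
                for c in obj["planted_combinations"]
            )
        if "stay_length_range" in obj:
            obj["stay_length_range"] = tuple(obj["stay_length_range"])
        return cls(**obj)


@dataclass
class _PatientDraft:
    """Everything sampled before the hazard base is calibrated."""

    patient_id: str
    stay_days: int
    frailty: float
    daily_drugs: dict[int, frozenset[str]]
    # per hazard day t = 1..stay_days: logit offset excluding the base
    offsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    exposure_days: int = 0
    exposed: bool = False


def _rng(seed: int, patient: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, patient, stream)))


def _draw_drug_schedule(
    cfg: GeneratorConfig, rng: np.random.Generator, stay_days: int, exposed_for: list[PlantedCombination]
) -> dict[int, frozenset[str]]:
    weights = cfg.drug_popularity ** np.arange(cfg.n_drugs)
    weights /= weights.sum()
    inventory = np.array(cfg.drug_inventory)
    schedule: dict[int, frozenset[str]] = {}
    prev: frozenset[str] | None = None
    for day in range(stay_days + 1):
        planted = next(
            (c for c in exposed_for if rng.random() < cfg.exposure_day_prob), None
        )
        if planted is not None:
            today = frozenset(planted.drugs)
        elif prev is not None and rng.random() < cfg.regimen_persistence:
            today = prev
        else:
            m = 1 + rng.binomial(3, 0.4)
            today = frozenset(rng.choice(inventory, size=m, replace=False, p=weights))
        schedule[day] = today
        prev = today
    return schedule


def _hazard_offsets(cfg: GeneratorConfig, draft: _PatientDraft) -> np.ndarray:
    """Per-day logit offsets (frailty + active planted effects), days 1..L."""
    offs = np.full(draft.stay_days, cfg.vitals_effect * draft.frailty)
    for combo in cfg.planted_combinations:
        drugs = set(combo.drugs)
        cum = 0
        for t in range(1, draft.stay_days + 1):
            if drugs <= draft.daily_drugs.get(t, frozenset()):
                cum += 1
            if cum >= combo.min_exposure_days:
                offs[t - 1] += combo.effect
    return offs


def _calibrate_base(cfg: GeneratorConfig, drafts: list[_PatientDraft]) -> float:
    """Bisect the hazard base so the expected prevalence hits the target."""

    def expected(base: float) -> float:
        p_event = [
            1.0 - np.prod(1.0 - expit(base + d.offsets)) for d in drafts
        ]
        return float(np.mean(p_event))

    lo, hi = -25.0, 5.0
    if not expected(lo) <= cfg.target_prevalence <= expected(hi):
        raise ConfigurationError(
            f"target prevalence {cfg.target_prevalence} infeasible for these "
            f"stay lengths and planted effects "
            f"(reachable range [{expected(lo):.4f}, {expected(hi):.4f}])"
        )
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < cfg.target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _creatinine_series(
    rng: np.random.Generator, stay_days: int, onset: int | None
) -> tuple[list[tuple[int, float]], str]:
    """Daily creatinine in mg/dl, constructed to realise the intended label.

    Pre-onset (and non-event) values stay within [c0, c0 + 0.24], so no
    2-day rise reaches 0.3 mg/dl and no value reaches 1.5x the first one
    (c0 >= 0.6).  On the onset day the series is forced over the absolute
    threshold, or over the 1.5x baseline threshold when the onset falls
    within the 7-day baseline window.
    """
    c0 = rng.uniform(0.6, 1.2)
    series = [(0, round(c0, 3))]
    cause = ""
    for t in range(1, stay_days + 1):
        if onset is not None and t == onset:
            if t <= 7 and rng.random() < 0.5:
                value = 1.5 * series[0][1] * (1.0 + rng.uniform(0.03, 0.15))
                cause = "relative"
            else:
                window_min = min(v for d, v in series if t - d <= 2)
                value = window_min + 0.3 + rng.uniform(0.05, 0.3)
                cause = "absolute"
        elif onset is not None and t > onset:
            value = max(series[-1][1] + rng.uniform(-0.05, 0.1), 0.2)
        else:
            value = c0 + rng.uniform(0.0, 0.24)
        series.append((t, round(float(value), 3)))
    return series, cause


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[PatientRecord], dict[str, CohortLabel], pd.DataFrame]:
    """Generate one cohort; deterministic given ``config.seed``.

    Returns the patient records, the intended (by-construction) AKI labels,
    and a truth sheet recording each patient's frailty, planted-combination
    exposure and event cause.
    """
    cfg = config
    base_date = date(2024, 1, 1)
    drafts: list[_PatientDraft] = []
    for i in range(cfg.n_patients):
        rng = _rng(cfg.seed, i, 0)
        stay = int(rng.integers(cfg.stay_length_range[0], cfg.stay_length_range[1] + 1))
        frailty = float(rng.normal())
        exposed_for = [
            c for c in cfg.planted_combinations if rng.random() < cfg.exposed_fraction
        ]
        schedule = _draw_drug_schedule(cfg, rng, stay, exposed_for)
        draft = _PatientDraft(
            patient_id=f"p{i:05d}",
            stay_days=stay,
            frailty=frailty,
            daily_drugs=schedule,
        )
        draft.offsets = _hazard_offsets(cfg, draft)
        if cfg.planted_combinations:
            combo = cfg.planted_combinations[0]
            drugs = set(combo.drugs)
            draft.exposure_days = sum(
                1 for d, s in schedule.items() if drugs <= s
            )
            draft.exposed = draft.exposure_days >= combo.min_exposure_days
        drafts.append(draft)

    base = _calibrate_base(cfg, drafts) if drafts else 0.0

    records: list[PatientRecord] = []
    labels: dict[str, CohortLabel] = {}
    truth_rows: list[dict] = []
    for i, draft in enumerate(drafts):
        rng_event = _rng(cfg.seed, i, 1)
        onset: int | None = None
        hazards = expit(base + draft.offsets)
        for t, h in enumerate(hazards, start=1):
            if rng_event.random() < h:
                onset = t
                break

        rng_meas = _rng(cfg.seed, i, 2)
        creatinine, cause = _creatinine_series(rng_meas, draft.stay_days, onset)
        measurements: dict[str, list[tuple[int, float]]] = {}
        for v, (name, mean, sd_between, sd_within) in enumerate(_pad_catalog(cfg)):
            offset = mean + sd_between * (
                draft.frailty if v == 0 else float(rng_meas.normal())
            )
            level = 0.0
            series = []
            for day in range(draft.stay_days + 1):
                level = 0.6 * level + float(rng_meas.normal(0.0, sd_within))
                if rng_meas.random() >= cfg.missing_rate:
                    series.append((day, round(offset + level, 2)))
            if series:
                measurements[name] = series

        admission = base_date + timedelta(days=i % 365)
        record = PatientRecord(
            patient_id=draft.patient_id,
            admission_date=admission,
            discharge_date=admission + timedelta(days=draft.stay_days),
            measurements=measurements,
            daily_drugs=dict(draft.daily_drugs),
            creatinine=creatinine,
        )
        record.validate()
        records.append(record)
        labels[draft.patient_id] = CohortLabel(
            draft.patient_id, is_aki=onset is not None, onset_day=onset
        )
        truth_rows.append(
            {
                "patient_id": draft.patient_id,
                "stay_days": draft.stay_days,
                "frailty": draft.frailty,
                "exposed": draft.exposed,
                "exposure_days": draft.exposure_days,
                "is_aki": onset is not None,
                "onset_day": onset if onset is not None else -1,
                "event_cause": cause,
            }
        )

    truth_sheet = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id", "stay_days", "frailty", "exposed", "exposure_days",
            "is_aki", "onset_day", "event_cause",
        ],
    )
    return records, labels, truth_sheet


def _pad_catalog(cfg: GeneratorConfig) -> list[tuple[str, float, float, float]]:
    catalog = list(_VITAL_CATALOG[: cfg.n_vitals])
    while len(catalog) < cfg.n_vitals:
        catalog.append((f"lab{len(catalog):02d}", 50.0, 10.0, 4.0))
    return catalog


def write_fixture(
    records: list[PatientRecord],
    labels: dict[str, CohortLabel],
    out_dir,
) -> dict[str, Path]:
    """Emit the three long-format tables (plus the labels) as CSV.

    ``measurements.csv`` carries the creatinine series under the variable
    name ``creatinine``; a round-trip through ``cohort.read_cohort``
    reproduces the records.  An empty cohort yields valid header-only tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    meas_rows, med_rows, stay_rows, label_rows = [], [], [], []
    for rec in records:
        adm = rec.admission_date
        stay_rows.append(
            {
                "patient_id": rec.patient_id,
                "admit_date": adm.isoformat(),
                "discharge_date": rec.discharge_date.isoformat(),
            }
        )
        for var in sorted(rec.measurements):
            for day, value in rec.measurements[var]:
                meas_rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "date": (adm + timedelta(days=day)).isoformat(),
                        "variable": var,
                        "value": value,
                    }
                )
        for day, value in rec.creatinine:
            meas_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "date": (adm + timedelta(days=day)).isoformat(),
                    "variable": CREATININE_VARIABLE,
                    "value": value,
                }
            )
        for day in sorted(rec.daily_drugs):
            for drug in sorted(rec.daily_drugs[day]):
                med_rows.append(
                    {
                        "patient_id": rec.patient_id,
                        "date": (adm + timedelta(days=day)).isoformat(),
                        "drug_id": drug,
                    }
                )
        label = labels.get(rec.patient_id)
        if label is not None:
            label_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "is_aki": int(label.is_aki),
                    "onset_day": label.onset_day if label.is_aki else "",
                }
            )

    paths = {
        "measurements": out / "measurements.csv",
        "medications": out / "medications.csv",
        "stays": out / "stays.csv",
        "labels": out / "labels.csv",
    }
    pd.DataFrame(meas_rows, columns=["patient_id", "date", "variable", "value"]).to_csv(
        paths["measurements"], index=False
    )
    pd.DataFrame(med_rows, columns=["patient_id", "date", "drug_id"]).to_csv(
        paths["medications"], index=False
    )
    pd.DataFrame(stay_rows, columns=["patient_id", "admit_date", "discharge_date"]).to_csv(
        paths["stays"], index=False
    )
    pd.DataFrame(label_rows, columns=["patient_id", "is_aki", "onset_day"]).to_csv(
        paths["labels"], index=False
    )
    return paths
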