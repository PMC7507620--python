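"""Repeated stratified-split evaluation, ablation, ratio sweep and testing.

The evaluation protocol: split the filtered cohort 60/40 into derivation and
validation sets with stratified sampling, fit everything that can leak
(combination vocabulary, drug inventory, variable list, imputation medians,
resampling) on the derivation set only, train the classifier, score the
untouched validation set, and repeat ten times.  Aggregates are reported as
mean +/- 95% CI across repeats and model variants are compared with a paired
two-sided Student t-test on the shared splits.

The ablation compares four feature variants on identical splits:

* ``etsm``        — explicit indicators + IFICF drug-combination weights
* ``etsm_ex``     — explicit indicators only
* ``etsm_bool``   — explicit + per-drug ever-taken booleans
* ``etsm_times``  — explicit + per-drug day counts
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from .classifier import ClassifierSpec, feature_importances, fit_classifier
from .cohort import (
    CohortLabel,
    PatientRecord,
    PredictionSample,
    assign_predictive_points,
    filter_cohort,
)
from .errors import ProtocolError
from .features import assemble, build_vocabulary, impute
from .imbalance import ResampleSpec, default_ratio_grid, resample_indices
from .metrics import METRIC_NAMES, ScoredPredictions, compute_all

__all__ = [
    "MetricsReport",
    "Variant",
    "ABLATION_VARIANTS",
    "prepare_samples",
    "run_variants",
    "run_experiment",
    "ablation",
    "ratio_sweep",
    "paired_ttest",
    "top_importances",
]

#: encoder used by each named ablation variant
ABLATION_VARIANTS = {
    "etsm": "ificf",
    "etsm_ex": "none",
    "etsm_bool": "bool",
    "etsm_times": "times",
}


@dataclass(frozen=True)
class Variant:
    """One model configuration evaluated inside a shared-split harness."""

    name: str
    encoder: str = "ificf"
    resample: ResampleSpec = ResampleSpec()
    classifier: ClassifierSpec = ClassifierSpec()


@dataclass
class MetricsReport:
    """Per-repeat and aggregated validation metrics for one variant."""

    name: str
    lead_hours: int
    per_repeat: pd.DataFrame  # columns: repeat, seed, auc, sensitivity, f1, average_precision
    #: per repeat: list of (group, source, importance) in column order
    importance_records: list[list[tuple[str, object, float]]] = field(default_factory=list)
    #: per repeat: (derivation patient_ids, validation patient_ids); shared
    #: object across variants run in one harness call
    split_ids: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def series(self, metric: str) -> np.ndarray:
        return self.per_repeat[metric].to_numpy()

    def aggregate(self) -> pd.DataFrame:
        """Mean and 95% CI half-width (t-based) per metric across repeats."""
        rows = []
        n = self.n_repeats
        for metric in METRIC_NAMES:
            vals = self.series(metric)
            half = (
                float(stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n))
                if n > 1
                else 0.0
            )
            rows.append({"metric": metric, "mean": float(vals.mean()), "ci95": half})
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            f"{self.name} (lead {self.lead_hours} h, {self.n_repeats} repeats)",
            "-" * 46,
        ]
        for metric, row in agg.iterrows():
            lines.append(f"{metric:>18}: {row['mean']:.3f} +/- {row['ci95']:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        agg = self.aggregate()
        return {
            "name": self.name,
            "lead_hours": self.lead_hours,
            "n_repeats": self.n_repeats,
            "aggregate": {
                m: {"mean": float(agg.loc[m, "mean"]), "ci95": float(agg.loc[m, "ci95"])}
                for m in METRIC_NAMES
            },
            "per_repeat": self.per_repeat.to_dict(orient="list"),
        }


def prepare_samples(
    records: list[PatientRecord],
    labels: dict[str, CohortLabel],
    lead_hours: int,
):
    """Filter the cohort for a lead and fix every predictive point.

    Returns (records by id, samples, filter report).
    """
    retained, report = filter_cohort(records, labels, lead_hours)
    samples = assign_predictive_points(retained, labels, lead_hours)
    by_id = {r.patient_id: r for r in retained}
    return by_id, samples, report


def _derived_seed(seed: int, repeat: int) -> int:
    """A per-repeat child seed, stable and below 2**31."""
    return int(np.random.SeedSequence((seed, repeat)).generate_state(1)[0] % (2**31))


def _featurize_split(
    records: dict[str, PatientRecord],
    samples: list[PredictionSample],
    deriv_idx: np.ndarray,
    encoder: str,
):
    """Assemble + impute one matrix with derivation-fitted statistics."""
    deriv_samples = [samples[i] for i in deriv_idx]
    deriv_records = [records[s.patient_id] for s in deriv_samples]
    pp = {s.patient_id: s.predictive_point for s in deriv_samples}
    variables = sorted(
        {var for rec in deriv_records for var in rec.measurements}
    )
    vocab = None
    inventory = None
    if encoder == "ificf":
        vocab = build_vocabulary(deriv_records, pp)
    elif encoder in ("bool", "times"):
        inventory = sorted(
            {
                d
                for s in deriv_samples
                for day, drugs in records[s.patient_id].daily_drugs.items()
                if day <= s.predictive_point
                for d in drugs
            }
        )
    matrix = assemble(
        samples, records, variables, encoder=encoder, vocab=vocab,
        drug_inventory=inventory,
    )
    mask = np.zeros(len(samples), dtype=bool)
    mask[deriv_idx] = True
    return impute(matrix, records, samples, mask)


def run_variants(
    records: dict[str, PatientRecord],
    samples: list[PredictionSample],
    variants: list[Variant],
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.6,
) -> dict[str, MetricsReport]:
    """Evaluate several variants on shared repeated stratified splits.

    Each repeat performs one 60/40 stratified split and one featurization per
    distinct encoder; every variant is then trained on its own resampling of
    the same derivation rows and scored on the same validation rows, making
    all cross-variant comparisons paired.
    """
    y = np.array([s.is_positive for s in samples])
    if (y.sum() < 2) or ((~y).sum() < 2):
        raise ProtocolError(
            f"protocol needs >= 2 samples per class; got {int(y.sum())} positives "
            f"and {int((~y).sum())} negatives"
        )

    rows: dict[str, list[dict]] = {v.name: [] for v in variants}
    importances: dict[str, list] = {v.name: [] for v in variants}
    split_ids: list[tuple[tuple[str, ...], tuple[str, ...]]] = []

    for r in range(n_repeats):
        rseed = _derived_seed(seed, r)
        idx = np.arange(len(samples))
        deriv_idx, valid_idx = train_test_split(
            idx,
            train_size=train_fraction,
            stratify=y,
            random_state=rseed,
            shuffle=True,
        )
        deriv_idx = np.sort(deriv_idx)
        valid_idx = np.sort(valid_idx)
        split_ids.append(
            (
                tuple(samples[i].patient_id for i in deriv_idx),
                tuple(samples[i].patient_id for i in valid_idx),
            )
        )

        matrices = {}
        for encoder in {v.encoder for v in variants}:
            matrices[encoder] = _featurize_split(records, samples, deriv_idx, encoder)

        for variant in variants:
            matrix = matrices[variant.encoder]
            X = matrix.values.to_numpy()
            spec = replace(variant.resample, seed=rseed)
            local, weight = resample_indices(y[deriv_idx], spec)
            train_rows = deriv_idx[local]
            clf_spec = variant.classifier.with_seed(rseed)
            if weight != 1.0:
                clf_spec = clf_spec.with_weight(weight)
            model = fit_classifier(X[train_rows], y[train_rows], clf_spec)
            scores = model.predict_proba(X[valid_idx])[:, 1]
            preds = ScoredPredictions(y[valid_idx], scores)
            rows[variant.name].append({"repeat": r, "seed": rseed, **compute_all(preds)})
            gains = feature_importances(model, matrix.n_features)
            importances[variant.name].append(
                [
                    (g, s, float(v))
                    for g, s, v in zip(
                        matrix.column_groups, matrix.column_sources, gains
                    )
                ]
            )

    return {
        v.name: MetricsReport(
            name=v.name,
            lead_hours=samples[0].lead_hours if samples else 0,
            per_repeat=pd.DataFrame(rows[v.name]),
            importance_records=importances[v.name],
            split_ids=split_ids,
        )
        for v in variants
    }


def run_experiment(
    records: list[PatientRecord],
    labels: dict[str, CohortLabel],
    lead_hours: int = 24,
    encoder: str = "ificf",
    resample: ResampleSpec = ResampleSpec(),
    classifier: ClassifierSpec = ClassifierSpec(),
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.6,
) -> MetricsReport:
    """The full protocol for a single model configuration."""
    by_id, samples, _ = prepare_samples(records, labels, lead_hours)
    reports = run_variants(
        by_id,
        samples,
        [Variant("model", encoder=encoder, resample=resample, classifier=classifier)],
        n_repeats=n_repeats,
        seed=seed,
        train_fraction=train_fraction,
    )
    return reports["model"]


def ablation(
    records: list[PatientRecord],
    labels: dict[str, CohortLabel],
    lead_hours: int = 24,
    resample: ResampleSpec = ResampleSpec(),
    classifier: ClassifierSpec = ClassifierSpec(),
    n_repeats: int = 10,
    seed: int = 0,
    variants: dict[str, str] = ABLATION_VARIANTS,
) -> dict[str, MetricsReport]:
    """Run the feature-variant ablation on identical (paired) splits."""
    by_id, samples, _ = prepare_samples(records, labels, lead_hours)
    specs = [
        Variant(name, encoder=enc, resample=resample, classifier=classifier)
        for name, enc in variants.items()
    ]
    return run_variants(by_id, samples, specs, n_repeats=n_repeats, seed=seed)


def ratio_sweep(
    records: list[PatientRecord],
    labels: dict[str, CohortLabel],
    lead_hours: int = 24,
    ratios: list[tuple[int, int]] | None = None,
    encoder: str = "ificf",
    classifier: ClassifierSpec = ClassifierSpec(),
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Derivation-set positive:negative ratio sweep (undersampling).

    The validation set is identical across ratios within a repeat.  Returns
    one row per (ratio, repeat) with the four metrics, suitable for plotting
    metric-vs-ratio curves.
    """
    if ratios is None:
        ratios = default_ratio_grid()
    by_id, samples, _ = prepare_samples(records, labels, lead_hours)
    specs = [
        Variant(
            f"{a}:{b}",
            encoder=encoder,
            resample=ResampleSpec(strategy="undersample", ratio=(a, b)),
            classifier=classifier,
        )
        for a, b in ratios
    ]
    with warnings.catch_warnings():
        # extreme ratios legitimately clamp to the available majority size
        warnings.simplefilter("ignore", UserWarning)
        reports = run_variants(by_id, samples, specs, n_repeats=n_repeats, seed=seed)
    frames = []
    for (a, b), spec in zip(ratios, specs):
        df = reports[spec.name].per_repeat.copy()
        df.insert(0, "ratio_neg", b)
        df.insert(0, "ratio_pos", a)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def paired_ttest(series_a, series_b) -> tuple[float, float]:
    """Two-sided paired Student t-test on per-repeat metric differences.

    Returns (t statistic, p value).  Identical series give p = 1; a nonzero
    constant difference (zero variance) is degenerate and returns p = nan
    with a warning.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have identical length")
    diff = a - b
    if np.allclose(diff, diff[0]):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        warnings.warn(
            "paired t-test degenerate: constant nonzero difference", stacklevel=2
        )
        return np.inf, float("nan")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def top_importances(
    report: MetricsReport,
    k: int = 10,
    repeat: int | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Rank features by gain importance, decoding implicit columns.

    ``repeat=None`` averages importances across repeats (keyed by source, so
    combinations present in only some repeats' vocabularies average over all
    repeats with 0 elsewhere).  ``group="implicit"`` restricts to medication
    features, mirroring a drug-combination importance table.  Ties break
    toward the lower column/combination position.
    """
    if not report.importance_records:
        raise ValueError("report carries no importance records")

    def _key(source: object) -> tuple:
        return (0, source) if isinstance(source, str) else (1, tuple(source))

    if repeat is not None:
        records = [report.importance_records[repeat]]
    else:
        records = report.importance_records
    totals: dict[tuple, list] = {}
    for rec in records:
        for pos, (g, source, value) in enumerate(rec):
            if group is not None and g != group:
                continue
            key = _key(source)
            entry = totals.setdefault(key, [g, source, 0.0, pos])
            entry[2] += value
    rows = [
        {
            "group": g,
            "source": tuple(s) if not isinstance(s, str) else s,
            "importance": total / len(records),
            "_pos": pos,
        }
        for g, s, total, pos in totals.values()
    ]
    df = pd.DataFrame(rows, columns=["group", "source", "importance", "_pos"])
    df = df.sort_values(["importance", "_pos"], ascending=[False, True]).head(k)
    df = df.drop(columns="_pos").reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
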