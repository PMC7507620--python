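"""Top-level modelling API: :class:`AkiRiskModel` and :class:`AkiRiskResults`.

The model object is built from a labeled cohort (or directly from the three
long-format tables, or from a synthetic-cohort configuration), carries the
pipeline configuration — prediction lead, implicit-indicator encoder,
imbalance strategy, classifier hyperparameters — and ``fit()`` runs the
repeated stratified-split protocol, returning a results object with
per-repeat metrics, aggregate estimates with confidence intervals, decoded
feature importances and a ``summary()`` table.

Example
-------
>>> from etsm import AkiRiskModel, GeneratorConfig
>>> model = AkiRiskModel.from_generator(GeneratorConfig(n_patients=400, seed=3))
>>> res = model.fit(n_repeats=5, seed=3)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classifier import ClassifierSpec
from .cohort import (
    CohortFilterReport,
    CohortLabel,
    PatientRecord,
    label_cohort,
    read_cohort,
)
from .experiment import (
    ABLATION_VARIANTS,
    MetricsReport,
    Variant,
    paired_ttest,
    prepare_samples,
    run_variants,
    top_importances,
)
from .imbalance import ResampleSpec
from .simulate import GeneratorConfig, generate_cohort

__all__ = ["AkiRiskModel", "AkiRiskResults"]


class AkiRiskModel:
    """Early-AKI risk model over an ICU cohort.

    Parameters
    ----------
    records, labels
        The cohort and its KDIGO labels (see :mod:`etsm.cohort`).
    lead_hours
        Prediction lead, 24 or 48.
    encoder
        Implicit-indicator encoder: ``"ificf"`` (drug-combination weights,
        the default), ``"bool"``, ``"times"`` or ``"none"`` (explicit only).
    resample
        Derivation-set imbalance strategy; default random undersampling to a
        1:1 positive:negative ratio.
    classifier
        Gradient-boosted tree hyperparameters.
    """

    def __init__(
        self,
        records: list[PatientRecord],
        labels: dict[str, CohortLabel],
        lead_hours: int = 24,
        encoder: str = "ificf",
        resample: ResampleSpec = ResampleSpec(),
        classifier: ClassifierSpec = ClassifierSpec(),
    ):
        if lead_hours not in (24, 48):
            raise ValueError("lead_hours must be 24 or 48")
        self.lead_hours = lead_hours
        self.encoder = encoder
        self.resample = resample
        self.classifier = classifier
        self.records_by_id, self.samples, self.filter_report = prepare_samples(
            records, labels, lead_hours
        )
        self.labels = labels

    @classmethod
    def from_tables(
        cls, measurements, medications, stays, **kwargs
    ) -> "AkiRiskModel":
        """Build from the three long-format delimited tables; stays without a
        creatinine series are labeled unlabelable and filtered out."""
        records = read_cohort(measurements, medications, stays)
        labels, _ = label_cohort(records)
        return cls(records, labels, **kwargs)

    @classmethod
    def from_generator(cls, config: GeneratorConfig, **kwargs) -> "AkiRiskModel":
        """Build from a synthetic cohort generated under ``config``."""
        records, labels, _ = generate_cohort(config)
        return cls(records, labels, **kwargs)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_positive(self) -> int:
        return sum(s.is_positive for s in self.samples)

    def fit(
        self, n_repeats: int = 10, seed: int = 0, train_fraction: float = 0.6
    ) -> "AkiRiskResults":
        """Run the repeated stratified-split protocol; returns the results."""
        reports = run_variants(
            self.records_by_id,
            self.samples,
            [
                Variant(
                    "model",
                    encoder=self.encoder,
                    resample=self.resample,
                    classifier=self.classifier,
                )
            ],
            n_repeats=n_repeats,
            seed=seed,
            train_fraction=train_fraction,
        )
        return AkiRiskResults(model=self, report=reports["model"])

    def fit_ablation(
        self, n_repeats: int = 10, seed: int = 0
    ) -> dict[str, "AkiRiskResults"]:
        """Fit the four ablation variants on identical splits (paired)."""
        specs = [
            Variant(name, encoder=enc, resample=self.resample, classifier=self.classifier)
            for name, enc in ABLATION_VARIANTS.items()
        ]
        reports = run_variants(
            self.records_by_id, self.samples, specs, n_repeats=n_repeats, seed=seed
        )
        return {
            name: AkiRiskResults(model=self, report=reports[name])
            for name in ABLATION_VARIANTS
        }


@dataclass
class AkiRiskResults:
    """Fit results: per-repeat metrics, aggregates, importances."""

    model: AkiRiskModel
    report: MetricsReport

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-repeat validation metrics (one row per repeat)."""
        return self.report.per_repeat

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean +/- 95% CI per metric across repeats."""
        return self.report.aggregate()

    def top_importances(
        self, k: int = 10, repeat: int | None = None, group: str | None = None
    ) -> pd.DataFrame:
        """Ranked gain importances; implicit columns decode to drug-ID sets."""
        return top_importances(self.report, k=k, repeat=repeat, group=group)

    def compare(self, other: "AkiRiskResults", metric: str = "auc") -> tuple[float, float]:
        """Paired t-test of a per-repeat metric against another fit."""
        return paired_ttest(self.report.series(metric), other.report.series(metric))

    def summary(self) -> str:
        m = self.model
        agg = self.aggregate
        lines = [
            "AKI risk model — repeated stratified-split evaluation",
            "=" * 56,
            f"samples: {m.n_samples} ({m.n_positive} positive)   lead: {m.lead_hours} h",
            f"encoder: {m.encoder}   resample: {m.resample.strategy} "
            f"{m.resample.ratio[0]}:{m.resample.ratio[1]}",
            f"classifier: gradient-boosted trees "
            f"(n_estimators={m.classifier.n_estimators}, "
            f"max_depth={m.classifier.max_depth}, "
            f"min_child_weight={m.classifier.min_child_weight:g})",
            f"repeats: {self.report.n_repeats} (60/40 derivation/validation)",
            "-" * 56,
        ]
        for metric, row in agg.iterrows():
            lines.append(f"{metric:>20}: {row['mean']:.3f} +/- {row['ci95']:.3f} (95% CI)")
        return "\n".join(lines)
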