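"""Patient-grouped cross-validation, metrics, and the study harnesses.

The evaluation unit is a :class:`FoldPlan` whose validation sets partition
the cohort and never split a patient across the train/validation boundary —
spectra from one tissue sample are strongly correlated, so spectrum-level
folds would leak patient signal and inflate every score.  Two schemes are
provided: leave-one-patient-out (one fold per patient) and patient-grouped,
approximately label-balanced k-fold.

On top of the fold machinery sit the study harnesses: ``run_cv_experiment``
(fit pipeline + model per fold, pool validation predictions into one
confusion matrix), ``run_ablation`` (the cumulative preprocessing ladder
raw -> +baseline -> +L2 -> +median -> +PCA with per-step metric deltas) and
``compare_pipelines`` (side-by-side metrics for named pipeline presets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold

from .classifiers import ModelSpec, TrainRecipe, fit_model
from .core import Cohort
from .dimreduce import fit_pca, transform_pca
from .preprocess import PipelineSpec, StageSpec, apply_spectral_stages, get_preset

__all__ = [
    "FoldPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "CVResult",
    "AblationReport",
    "lopo_splits",
    "grouped_kfold_splits",
    "confusion_and_metrics",
    "run_cv_experiment",
    "run_ablation",
    "compare_pipelines",
]

CLASS_NAMES = ("healthy", "cancerous")


@dataclass(frozen=True)
class FoldPlan:
    """Train/validation spectrum-id splits; patient-disjoint by construction."""

    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    scheme: str
    k: int | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.folds)

    def validate(self, cohort: Cohort) -> None:
        """Assert the partition and patient-disjointness invariants."""
        patient_of = {r.spectrum_id: r.patient_id for r in cohort.records}
        all_val: list[str] = []
        for train_ids, val_ids in self.folds:
            train_p = {patient_of[s] for s in train_ids}
            val_p = {patient_of[s] for s in val_ids}
            if train_p & val_p:
                raise AssertionError(f"patients straddle a fold: {sorted(train_p & val_p)}")
            all_val.extend(val_ids)
        if sorted(all_val) != sorted(patient_of):
            raise AssertionError("validation sets do not partition the cohort")


def lopo_splits(cohort: Cohort) -> FoldPlan:
    """Leave-one-patient-out: each fold holds out all spectra of one patient."""
    by_patient: dict[str, list[str]] = {}
    for r in cohort.records:
        by_patient.setdefault(r.patient_id, []).append(r.spectrum_id)
    if len(by_patient) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")
    all_ids = set(cohort.spectrum_ids)
    folds = []
    for pid in sorted(by_patient):
        val = tuple(by_patient[pid])
        train = tuple(s for s in cohort.spectrum_ids if s not in set(val))
        folds.append((train, val))
    assert sum(len(v) for _, v in folds) == len(all_ids)
    return FoldPlan(folds=tuple(folds), scheme="lopo")


def grouped_kfold_splits(cohort: Cohort, k: int = 10, seed: int = 0) -> FoldPlan:
    """Patient-grouped, approximately label-balanced k-fold splits."""
    n_patients = len(set(cohort.patient_ids))
    if k > n_patients:
        raise ValueError(f"k={k} exceeds the number of patients ({n_patients})")
    ids = np.array(cohort.spectrum_ids)
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [
        (tuple(ids[tr]), tuple(ids[va]))
        for tr, va in splitter.split(ids, cohort.labels, groups=np.array(cohort.patient_ids))
    ]
    return FoldPlan(folds=tuple(folds), scheme="grouped_kfold", k=k, seed=seed)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; rows = true (healthy, cancerous), columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 plus accuracy and support-weighted averages.

    All values are percentages kept at full precision; use :meth:`rounded`
    for one-decimal table display.
    """

    precision: tuple[float, float]
    recall: tuple[float, float]
    f1: tuple[float, float]
    accuracy: float
    support: tuple[int, int]

    @property
    def weighted_precision(self) -> float:
        return float(np.average(self.precision, weights=self.support))

    @property
    def weighted_recall(self) -> float:
        return float(np.average(self.recall, weights=self.support))

    @property
    def weighted_f1(self) -> float:
        return float(np.average(self.f1, weights=self.support))

    def rounded(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 1),
            "per_class": {
                CLASS_NAMES[c]: {
                    "precision": round(self.precision[c], 1),
                    "recall": round(self.recall[c], 1),
                    "f1": round(self.f1[c], 1),
                }
                for c in (0, 1)
            },
            "weighted": {
                "precision": round(self.weighted_precision, 1),
                "recall": round(self.weighted_recall, 1),
                "f1": round(self.weighted_f1, 1),
            },
        }


def confusion_and_metrics(truth, predictions) -> tuple[ConfusionMatrix, MetricsReport]:
    """Confusion counts and the standard derived metrics, straight from counts."""
    y = np.asarray(truth, dtype=int).reshape(-1)
    p = np.asarray(predictions, dtype=int).reshape(-1)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} truth vs {p.shape} predictions")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be 0 (healthy) or 1 (cancerous)")
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (y, p), 1)
    cm = ConfusionMatrix(counts)

    def prf(c: int) -> tuple[float, float, float]:
        tp = counts[c, c]
        fp = counts[1 - c, c]
        fn = counts[c, 1 - c]
        prec = 100.0 * tp / (tp + fp) if tp + fp else 0.0
        rec = 100.0 * tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        return prec, rec, f1

    (p0, r0, f0), (p1, r1, f1) = prf(0), prf(1)
    report = MetricsReport(
        precision=(p0, p1),
        recall=(r0, r1),
        f1=(f0, f1),
        accuracy=100.0 * counts.trace() / cm.total if cm.total else 0.0,
        support=(int(counts[0].sum()), int(counts[1].sum())),
    )
    return cm, report


@dataclass
class CVResult:
    """Pooled cross-validation outcome plus per-fold detail."""

    confusion: ConfusionMatrix
    metrics: MetricsReport
    fold_metrics: list[MetricsReport]
    predictions: dict[str, int]
    probabilities: dict[str, float]
    pipeline: str
    model: str
    scheme: str


def _ids_index(cohort: Cohort) -> dict[str, int]:
    return {sid: i for i, sid in enumerate(cohort.spectrum_ids)}


def run_cv_experiment(
    cohort: Cohort,
    pipeline: PipelineSpec | str,
    model: ModelSpec,
    plan: FoldPlan,
    recipe: TrainRecipe | None = None,
    labels: np.ndarray | None = None,
) -> CVResult:
    """Cross-validate a pipeline+model combination under a fold plan.

    Stateless per-spectrum stages are applied once to the whole cohort (they
    are per-spectrum maps, so this equals applying them per fold); the fitted
    PCA stage, when present, is refit on each training fold only, keeping the
    evaluation leakage-free.  Validation predictions are pooled into a single
    confusion matrix; per-fold metrics are retained.

    ``labels`` optionally overrides the cohort labels (e.g. permutation
    controls) without touching the cohort itself.
    """
    if isinstance(pipeline, str):
        pipeline = get_preset(pipeline)
    plan.validate(cohort)
    processed = apply_spectral_stages(cohort, pipeline)
    X = processed.matrix
    y = cohort.labels if labels is None else np.asarray(labels, dtype=int)
    idx = _ids_index(cohort)
    k = pipeline.pca_components

    preds: dict[str, int] = {}
    probs: dict[str, float] = {}
    fold_metrics: list[MetricsReport] = []
    for fold_no, (train_ids, val_ids) in enumerate(plan.folds):
        tr = np.array([idx[s] for s in train_ids])
        va = np.array([idx[s] for s in val_ids])
        try:
            X_tr, X_va = X[tr], X[va]
            if k is not None:
                state = fit_pca(X_tr, k, source_region=pipeline.region)
                X_tr, X_va = transform_pca(state, X_tr), transform_pca(state, X_va)
            fold_recipe = recipe
            if model.is_deep and fold_recipe is None:
                fold_recipe = TrainRecipe(seed=model.seed + fold_no)
            fitted = fit_model(model, X_tr, y[tr], recipe=fold_recipe)
            p_va = fitted.predict_proba(X_va)
        except Exception as exc:
            raise RuntimeError(
                f"fold {fold_no} ({plan.scheme}) failed for pipeline={pipeline.name!r} "
                f"model={model.family!r}: {exc}"
            ) from exc
        for s, pr in zip(val_ids, p_va):
            probs[s] = float(pr)
            preds[s] = int(pr >= 0.5)
        _, fm = confusion_and_metrics(y[va], [preds[s] for s in val_ids])
        fold_metrics.append(fm)

    order = cohort.spectrum_ids
    cm, metrics = confusion_and_metrics(
        [y[idx[s]] for s in order], [preds[s] for s in order]
    )
    return CVResult(
        confusion=cm,
        metrics=metrics,
        fold_metrics=fold_metrics,
        predictions=preds,
        probabilities=probs,
        pipeline=pipeline.name,
        model=model.family,
        scheme=plan.scheme,
    )


@dataclass
class AblationReport:
    """Cumulative-pipeline ladder: per-step metrics, deltas, and totals.

    The telescoping identity ``total == final - first == sum(deltas)`` holds
    exactly on the stored full-precision values.
    """

    stages: list[str]
    accuracy: list[float]
    recall: list[float]
    results: list[CVResult] = field(default_factory=list)

    @property
    def accuracy_deltas(self) -> list[float]:
        return [b - a for a, b in zip(self.accuracy, self.accuracy[1:])]

    @property
    def recall_deltas(self) -> list[float]:
        return [b - a for a, b in zip(self.recall, self.recall[1:])]

    @property
    def total_accuracy_improvement(self) -> float:
        return self.accuracy[-1] - self.accuracy[0]

    @property
    def total_recall_improvement(self) -> float:
        return self.recall[-1] - self.recall[0]


#: The cumulative preprocessing ladder tracked by the ablation harness.
ABLATION_STAGES: list[tuple[str, list[tuple[str, dict]]]] = [
    ("raw", []),
    ("baseline_correction", [("snip_baseline", {"iterations": 80})]),
    ("l2_normalization", [("snip_baseline", {"iterations": 80}), ("l2_normalize", {})]),
    (
        "median_filter",
        [
            ("snip_baseline", {"iterations": 80}),
            ("l2_normalize", {}),
            ("median_filter", {"window": 5}),
        ],
    ),
    (
        "pca",
        [
            ("snip_baseline", {"iterations": 80}),
            ("l2_normalize", {}),
            ("median_filter", {"window": 5}),
            ("pca", {"n_components": 30}),
        ],
    ),
]


def run_ablation(
    cohort: Cohort,
    model: ModelSpec,
    plan: FoldPlan,
    region: str = "low_plus_high",
    pca_components: int = 30,
) -> AblationReport:
    """Evaluate the cumulative preprocessing ladder on matched folds.

    Each rung re-runs the same model and fold plan with one more
    preprocessing stage switched on (raw, +baseline correction, +L2,
    +median filter, +PCA); the region is selected at every rung for
    comparability.  Reported recall is the support-weighted recall, which
    equals accuracy at exact class balance.
    """
    stages_labels, accs, recs, results = [], [], [], []
    for label, kinds in ABLATION_STAGES:
        stage_specs = []
        for kind, params in kinds:
            if kind == "pca":
                params = {"n_components": pca_components}
            stage_specs.append(StageSpec(kind, params))
        spec = PipelineSpec(f"ablation_{label}", tuple(stage_specs), region=region)
        res = run_cv_experiment(cohort, spec, model, plan)
        stages_labels.append(label)
        accs.append(res.metrics.accuracy)
        recs.append(res.metrics.weighted_recall)
        results.append(res)
    return AblationReport(stages=stages_labels, accuracy=accs, recall=recs, results=results)


def compare_pipelines(
    cohort: Cohort,
    model: ModelSpec,
    plan: FoldPlan,
    pipeline_names: list[str] | None = None,
) -> dict[str, CVResult]:
    """Side-by-side CV metrics for named pipeline presets (same folds/model)."""
    names = pipeline_names or ["pipeline_a", "pipeline_b", "pipeline_c", "suggested_ml"]
    return {name: run_cv_experiment(cohort, get_preset(name), model, plan) for name in names}
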