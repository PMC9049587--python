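"""Classification metrics and the 5-fold cross-validation driver.

Per-class metrics follow the one-vs-rest convention: for class *c*,
``precision = TP/(TP+FP)``, ``accuracy = (TP+TN)/Total``,
``recall = TP/(TP+FN)``, ``F1 = 2PR/(P+R)``, with the 0/0 cases defined
as 0 (flagged).  Macro averages are unweighted means over the nine
classes; note that "macro-average accuracy" is the mean of per-class
one-vs-rest accuracies, which is systematically higher than plain top-1
accuracy.  ROC-AUC is one-vs-rest per class (trapezoidal), micro-pooled
or macro-averaged over classes with support.

Cross-validation builds balanced folds with the oversampler, holds each
fold out once (the held-out fold keeps natural class frequencies — no
replicas), trains the 12 lead models per fold, stacks their
probabilities out-of-fold for fusion training, and scores with the
multi-label credit rule: a prediction matching any of a record's labels
counts as correct against the matched label.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .fusion import (
    FusionHyperparams,
    assemble_features,
    predict_fusion,
    train_fusion,
)
from .hrv import HRVFeatures, hrv_from_lead_ii
from .labels import ALL_CLASSES, ClassLabel, N_CLASSES
from .nn import LeadModelConfig, build_lead_model, train_lead_model
from .preprocess import balance_subsets, preprocess_record
from .record_io import ECGRecord, LEAD_II, N_LEADS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true: Sequence, y_pred: Sequence) -> np.ndarray:
    """9x9 count matrix: entry (i, j) = #{true class i predicted as j}."""
    ti = _as_indices(y_true)
    pi = _as_indices(y_pred)
    if len(ti) != len(pi):
        raise ValueError(f"length mismatch: {len(ti)} true vs {len(pi)} predicted")
    if len(ti) == 0:
        raise ValueError("need at least one prediction")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (ti, pi), 1)
    return cm


def _as_indices(labels: Sequence) -> np.ndarray:
    return np.asarray([
        lab.index if isinstance(lab, ClassLabel) else int(lab)
        for lab in labels
    ])


def class_metrics(confusion: np.ndarray,
                  c: ClassLabel | int) -> tuple[float, float, float, float]:
    """(precision, accuracy, recall, f1) for one class, one-vs-rest."""
    confusion = np.asarray(confusion)
    i = c.index if isinstance(c, ClassLabel) else int(c)
    total = confusion.sum()
    tp = confusion[i, i]
    fp = confusion[:, i].sum() - tp
    fn = confusion[i, :].sum() - tp
    tn = total - tp - fp - fn
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    accuracy = _safe_div(tp + tn, total)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return precision, accuracy, recall, f1


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        logger.debug("0/0 in a rate: defined as 0")
        return 0.0
    return float(num / den)


def roc_auc(y_true: Sequence, score_rows: np.ndarray,
            average: str = "micro") -> float:
    """One-vs-rest ROC-AUC over the 9-class probability rows.

    ``micro`` pools all (sample, class) decisions; ``macro`` averages
    per-class AUCs over classes that appear in the truth.  Raises on a
    single-class truth vector, where ranking quality is undefined.
    """
    ti = _as_indices(y_true)
    scores = np.asarray(score_rows, dtype=float)
    if scores.ndim != 2 or scores.shape != (len(ti), N_CLASSES):
        raise ValueError(
            f"score_rows must be (n, {N_CLASSES}); got {scores.shape}")
    present = np.unique(ti)
    if len(present) < 2:
        raise ValueError("ROC-AUC undefined for single-class truth")
    onehot = np.zeros_like(scores)
    onehot[np.arange(len(ti)), ti] = 1.0
    if average == "micro":
        return float(roc_auc_score(onehot.ravel(), scores.ravel()))
    if average == "macro":
        aucs = [roc_auc_score(onehot[:, c], scores[:, c]) for c in present]
        return float(np.mean(aucs))
    raise ValueError("average must be 'micro' or 'macro'")


@dataclass
class MetricsReport:
    """Per-class and averaged metrics plus the confusion matrix."""

    confusion: np.ndarray
    precision: np.ndarray          # per class, index order
    accuracy: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_accuracy: float
    macro_recall: float
    macro_f1: float
    auc_micro: float | None = None
    auc_macro: float | None = None

    @classmethod
    def from_predictions(cls, y_true: Sequence, y_pred: Sequence,
                         score_rows: np.ndarray | None = None,
                         ) -> "MetricsReport":
        cm = confusion_matrix(y_true, y_pred)
        per = np.array([class_metrics(cm, c) for c in range(N_CLASSES)])
        precision, accuracy, recall, f1 = per.T
        auc_mi = auc_ma = None
        if score_rows is not None:
            try:
                auc_mi = roc_auc(y_true, score_rows, "micro")
                auc_ma = roc_auc(y_true, score_rows, "macro")
            except ValueError as exc:
                logger.warning("AUC unavailable: %s", exc)
        return cls(
            confusion=cm,
            precision=precision, accuracy=accuracy,
            recall=recall, f1=f1,
            macro_precision=float(precision.mean()),
            macro_accuracy=float(accuracy.mean()),
            macro_recall=float(recall.mean()),
            macro_f1=float(f1.mean()),
            auc_micro=auc_mi, auc_macro=auc_ma,
        )

    def macro_f1_over_support(self) -> float:
        """Macro-F1 restricted to classes that actually occur."""
        support = self.confusion.sum(axis=1) > 0
        return float(self.f1[support].mean()) if support.any() else 0.0

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Unweighted mean of fold reports; confusion matrices are summed."""
    if not reports:
        raise ValueError("no reports to average")

    def avg(name):
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            return None
        return np.mean(vals, axis=0) if isinstance(vals[0], np.ndarray) \
            else float(np.mean(vals))

    return MetricsReport(
        confusion=np.sum([r.confusion for r in reports], axis=0),
        precision=avg("precision"), accuracy=avg("accuracy"),
        recall=avg("recall"), f1=avg("f1"),
        macro_precision=avg("macro_precision"),
        macro_accuracy=avg("macro_accuracy"),
        macro_recall=avg("macro_recall"),
        macro_f1=avg("macro_f1"),
        auc_micro=avg("auc_micro"), auc_macro=avg("auc_macro"),
    )


# ---------------------------------------------------------------------------
# prepared records and fold fitting
# ---------------------------------------------------------------------------

@dataclass
class PreparedRecord:
    """A record after the full conditioning chain, ready for modelling."""

    record_id: str
    segments: np.ndarray               # (12, 10, L) z-scored slices
    hrv: HRVFeatures | None
    age: float | None
    sex: str | None
    labels: list[ClassLabel]

    @property
    def primary(self) -> ClassLabel:
        return self.labels[0]


def prepare_record(record: ECGRecord, target_fs: float = 250.0,
                   segment_seconds: float = 6.0) -> PreparedRecord:
    """Condition one record and extract its HRV features (lead II)."""
    segments, conditioned = preprocess_record(
        record, target_fs=target_fs, segment_seconds=segment_seconds)
    hrv = hrv_from_lead_ii(conditioned.signals[LEAD_II], conditioned.fs)
    return PreparedRecord(
        record_id=record.record_id, segments=segments, hrv=hrv,
        age=record.age, sex=record.sex, labels=list(record.labels))


def prepare_records(records: Sequence[ECGRecord], **kw) -> list[PreparedRecord]:
    return [prepare_record(r, **kw) for r in records]


def _hrv_medians(items: Sequence[PreparedRecord]) -> tuple[np.ndarray, float]:
    """Per-feature HRV medians and median age over a training set."""
    mats = [p.hrv.as_array() for p in items if p.hrv is not None]
    hrv_med = (np.median(mats, axis=0) if mats
               else np.zeros(len(HRVFeatures.field_names())))
    ages = [p.age for p in items if p.age is not None]
    age_med = float(np.median(ages)) if ages else 60.0
    return hrv_med, age_med


@dataclass
class FoldFit:
    """Artifacts of one fitted fold, enough to score every variant."""

    lead_models: list
    stack_probas: np.ndarray       # (n_stack, 12, 9) for fusion training
    stack_items: list[PreparedRecord]
    test_probas: np.ndarray        # (n_test, 12, 9)
    test_items: list[PreparedRecord]
    hrv_median: np.ndarray
    age_median: float
    seed: int


def _lead_probas(models, items: Sequence[PreparedRecord]) -> np.ndarray:
    out = np.zeros((len(items), N_LEADS, N_CLASSES))
    if not items:
        return out
    for li, model in enumerate(models):
        batch = np.stack([p.segments[li] for p in items])
        out[:, li, :] = model.predict_proba(batch)
    return out


def fit_fold(train_items: list[PreparedRecord],
             test_items: list[PreparedRecord],
             lead_config: LeadModelConfig,
             seed: int,
             stack_fraction: float = 0.2) -> FoldFit:
    """Train the 12 lead models and produce stacked probabilities.

    The training fold is split by source record into a model part and a
    stacking part (default 80/20, stratified by class); lead models
    learn on the former and their out-of-fold probabilities on the
    latter become the fusion training matrix, avoiding the optimism of
    fusing in-sample probabilities.  Set ``stack_fraction=0`` for the
    naive in-sample protocol.
    """
    rng = np.random.default_rng(seed)
    if stack_fraction > 0:
        by_class: dict[ClassLabel, list[int]] = {}
        for i, p in enumerate(train_items):
            by_class.setdefault(p.primary, []).append(i)
        stack_idx: list[int] = []
        for cls in sorted(by_class, key=lambda c: c.index):
            idx = np.array(by_class[cls])
            rng.shuffle(idx)
            n_stack = max(1, int(round(stack_fraction * len(idx))))
            stack_idx.extend(idx[:n_stack])
        stack_set = set(stack_idx)
        model_items = [p for i, p in enumerate(train_items)
                       if i not in stack_set]
        stack_items = [train_items[i] for i in sorted(stack_set)]
    else:
        model_items = list(train_items)
        stack_items = list(train_items)

    y_model = np.array([p.primary.index for p in model_items])
    models = []
    for lead in range(N_LEADS):
        cfg = dataclasses.replace(lead_config, seed=seed * N_LEADS + lead)
        model = build_lead_model(cfg, lead_index=lead)
        x = np.stack([p.segments[lead] for p in model_items])
        train_lead_model(model, x, y_model, cfg)
        models.append(model)

    hrv_med, age_med = _hrv_medians(train_items)
    return FoldFit(
        lead_models=models,
        stack_probas=_lead_probas(models, stack_items),
        stack_items=stack_items,
        test_probas=_lead_probas(models, test_items),
        test_items=test_items,
        hrv_median=hrv_med, age_median=age_med, seed=seed,
    )


def _fusion_matrix(probas: np.ndarray, items: Sequence[PreparedRecord],
                   fit: FoldFit, include_dfs: bool) -> np.ndarray:
    return np.stack([
        assemble_features(probas[i], p.hrv, p.age, p.sex,
                          include_dfs=include_dfs,
                          age_fill=fit.age_median, hrv_fill=fit.hrv_median)
        for i, p in enumerate(items)
    ])


def credit_labels(items: Sequence[PreparedRecord],
                  preds: Sequence[ClassLabel]) -> list[ClassLabel]:
    """Multi-label credit rule: score against whichever true label was hit.

    A prediction equal to any of the record's labels is treated as
    correct (scored against that label); otherwise the primary label is
    the truth.
    """
    out = []
    for p, pred in zip(items, preds):
        out.append(pred if pred in p.labels else p.labels[0])
    return out


def score_variant(fit: FoldFit, variant: str,
                  fusion_hp: FusionHyperparams | None = None,
                  lead: int | None = None) -> MetricsReport:
    """Score one fitted fold under a model variant.

    ``variant`` is ``'single_lead'`` (needs ``lead``), ``'fused'``
    (probabilities only) or ``'fused_dfs'`` (probabilities + HRV/age/sex).
    """
    if variant == "single_lead":
        if lead is None:
            raise ValueError("single_lead variant needs a lead index")
        proba = fit.test_probas[:, lead, :]
        preds = [ALL_CLASSES[i] for i in proba.argmax(axis=1)]
    elif variant in ("fused", "fused_dfs"):
        include = variant == "fused_dfs"
        if fusion_hp is None:
            fusion_hp = (FusionHyperparams.default() if include
                         else FusionHyperparams.probs_only())
        x_stack = _fusion_matrix(fit.stack_probas, fit.stack_items, fit, include)
        y_stack = [p.primary for p in fit.stack_items]
        fusion = train_fusion(x_stack, y_stack, fusion_hp, seed=fit.seed)
        x_test = _fusion_matrix(fit.test_probas, fit.test_items, fit, include)
        preds, proba = predict_fusion(fusion, x_test)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    y_eff = credit_labels(fit.test_items, preds)
    return MetricsReport.from_predictions(y_eff, preds, proba)


def make_folds(items: Sequence[PreparedRecord], k: int, seed: int,
               ) -> list[tuple[list[PreparedRecord], list[PreparedRecord]]]:
    """Balanced (train, test) item lists per fold.

    Training folds contain oversampled replicas (shared segment arrays,
    no copying); held-out folds contain originals only.
    """
    by_id = {p.record_id: p for p in items}
    pairs = [(p.record_id, p.primary) for p in items]
    assignments = balance_subsets(pairs, n_folds=k, seed=seed)
    folds = []
    for f in range(k):
        train = [by_id[a.source_id] for a in assignments if a.fold != f]
        test = [by_id[a.record_id] for a in assignments
                if a.fold == f and a.replica_of is None]
        folds.append((train, test))
    return folds


def cross_validate(items: Sequence[PreparedRecord],
                   lead_config: LeadModelConfig,
                   k: int = 5,
                   seed: int = 0,
                   variant: str = "fused_dfs",
                   fusion_hp: FusionHyperparams | None = None,
                   lead: int | None = None,
                   stack_fraction: float = 0.2,
                   ) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation of one model variant.

    Returns the per-fold reports and their unweighted mean.
    """
    reports = []
    for f, (train, test) in enumerate(make_folds(items, k, seed)):
        fit = fit_fold(train, test, lead_config, seed=seed + f,
                       stack_fraction=stack_fraction)
        reports.append(score_variant(fit, variant, fusion_hp, lead))
    return reports, mean_report(reports)


def run_ablation(items: Sequence[PreparedRecord],
                 lead_config: LeadModelConfig,
                 k: int = 5,
                 seed: int = 0,
                 stack_fraction: float = 0.2) -> "pd.DataFrame":
    """All 14 variants from one set of fold fits.

    Twelve single-lead rows, the probability-only fusion, and the full
    fusion with domain-specific features, each scored by mean macro-F1
    over the same k folds (lead models trained once per fold and shared
    across variants).
    """
    import pandas as pd

    from .record_io import LEAD_NAMES

    per_variant: dict[str, list[MetricsReport]] = {}
    for f, (train, test) in enumerate(make_folds(items, k, seed)):
        fit = fit_fold(train, test, lead_config, seed=seed + f,
                       stack_fraction=stack_fraction)
        for li, name in enumerate(LEAD_NAMES):
            per_variant.setdefault(f"lead:{name}", []).append(
                score_variant(fit, "single_lead", lead=li))
        per_variant.setdefault("fused", []).append(
            score_variant(fit, "fused"))
        per_variant.setdefault("fused_dfs", []).append(
            score_variant(fit, "fused_dfs"))
    rows = []
    for name, reps in per_variant.items():
        mr = mean_report(reps)
        rows.append({
            "model": name,
            "macro_f1": np.mean([r.macro_f1_over_support() for r in reps]),
            "macro_precision": mr.macro_precision,
            "macro_recall": mr.macro_recall,
            "macro_accuracy": mr.macro_accuracy,
            "auc_micro": mr.auc_micro,
        })
    return pd.DataFrame(rows)
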