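"""Fusion-vector assembly and the gradient-boosted-tree fusion classifier.

Stage two of the method: each of the 12 per-lead networks emits a
9-class softmax vector; because each vector sums to 1, its last entry is
redundant and only the first eight probabilities per lead are kept
(12 x 8 = 96 values).  Appending the seven HRV statistics plus age and
sex yields the 105-dimensional fusion vector on which a multiclass
XGBoost model is trained.  The 96-value variant (probabilities only,
no domain-specific features) is the ablation switch.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import xgboost as xgb

from .hrv import HRVFeatures
from .labels import ALL_CLASSES, ClassLabel, N_CLASSES
from .record_io import N_LEADS

logger = logging.getLogger(__name__)

#: Probabilities kept per lead (last class dropped as redundant).
PROBS_PER_LEAD = N_CLASSES - 1

#: Length of the full fusion vector: 96 probabilities + 7 HRV + age + sex.
FUSION_DIM = N_LEADS * PROBS_PER_LEAD + 7 + 2

#: Column names of the fusion matrix, frozen order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{lead}_p{c}" for lead in range(N_LEADS) for c in range(PROBS_PER_LEAD)
) + HRVFeatures.field_names() + ("age", "sex")

SEX_CODE = {"female": 0.0, "male": 1.0}
SEX_MISSING = 0.5
DEFAULT_AGE = 60.0


@dataclass
class FusionHyperparams:
    """Booster settings; two profiles, one per fusion variant.

    ``default()`` is the profile with domain-specific features,
    ``probs_only()`` the profile tuned for the probability-only variant.
    """

    booster: str = "gbtree"
    learning_rate: float = 0.1
    max_depth: int = 5
    min_child_weight: float = 4.0
    colsample_bytree: float = 0.8
    colsample_bynode: float = 0.2
    subsample: float = 0.6
    max_delta_step: float = 0.0
    eval_metric: str = "merror"
    gamma: float = 0.4
    num_round: int = 108

    @classmethod
    def default(cls) -> "FusionHyperparams":
        return cls()

    @classmethod
    def probs_only(cls) -> "FusionHyperparams":
        """Profile for the fusion variant without HRV/age/sex features."""
        return cls(max_depth=10, min_child_weight=2.6, colsample_bytree=0.7,
                   colsample_bynode=1.0, subsample=0.7, max_delta_step=5.0,
                   gamma=0.3, num_round=120)

    def to_xgb_params(self, seed: int) -> dict:
        return {
            "booster": self.booster,
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "colsample_bytree": self.colsample_bytree,
            "colsample_bynode": self.colsample_bynode,
            "subsample": self.subsample,
            "max_delta_step": self.max_delta_step,
            "eval_metric": self.eval_metric,
            "gamma": self.gamma,
            "objective": "multi:softprob",
            "num_class": N_CLASSES,
            "seed": int(seed),
            "nthread": 1,
        }


def assemble_features(lead_probas: np.ndarray,
                      hrv: HRVFeatures | None,
                      age: float | None,
                      sex: str | None,
                      include_dfs: bool = True,
                      age_fill: float = DEFAULT_AGE,
                      hrv_fill: np.ndarray | None = None) -> np.ndarray:
    """Build one fusion vector from per-lead probabilities and side features.

    Parameters
    ----------
    lead_probas : ndarray, shape (12, 9)
        One softmax vector per lead, rows summing to 1.
    hrv : HRVFeatures or None
        ``None`` means QRS detection failed; the seven features are then
        imputed from *hrv_fill* (e.g. the training-set medians) and the
        imputation is logged.
    age, sex : demographics; missing age is imputed with *age_fill*
        (a training-set median in pipeline use), missing sex is encoded
        0.5 between female=0 and male=1.
    include_dfs : bool
        ``True`` -> 105 values; ``False`` -> the 96 lead probabilities
        only (the ablation variant).
    """
    lead_probas = np.asarray(lead_probas, dtype=float)
    if lead_probas.shape != (N_LEADS, N_CLASSES):
        raise ValueError(
            f"lead_probas must be ({N_LEADS}, {N_CLASSES}); "
            f"got {lead_probas.shape}")
    sums = lead_probas.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("each lead probability vector must sum to 1")
    probs = lead_probas[:, :PROBS_PER_LEAD].reshape(-1)
    if not include_dfs:
        return probs
    if hrv is None:
        if hrv_fill is None:
            raise ValueError(
                "HRV features missing and no hrv_fill (median) provided")
        logger.info("imputing HRV features from training medians")
        hrv_vals = np.asarray(hrv_fill, dtype=float)
        if hrv_vals.shape != (7,):
            raise ValueError("hrv_fill must have 7 entries")
    else:
        hrv_vals = hrv.as_array()
    age_val = float(age_fill if age is None else age)
    sex_val = SEX_MISSING if sex is None else SEX_CODE[sex]
    return np.concatenate([probs, hrv_vals, [age_val, sex_val]])


@dataclass
class FusionModel:
    """Trained booster plus the settings needed to apply it."""

    booster: xgb.Booster
    hyperparams: FusionHyperparams
    n_features: int

    def save(self, path) -> None:
        self.booster.save_model(str(path))


def train_fusion(vectors: np.ndarray,
                 labels: Sequence[ClassLabel | int],
                 hp: FusionHyperparams | None = None,
                 seed: int = 0,
                 require_all_classes: bool = False) -> FusionModel:
    """Train the multiclass boosted-tree fuser.

    ``labels`` may be :class:`ClassLabel` members or their indices; the
    model always predicts over the full 9-index vocabulary.  With
    ``require_all_classes`` the call fails, naming the absent classes,
    when any of the nine is unrepresented.
    """
    hp = hp or FusionHyperparams.default()
    if hp.num_round < 1:
        raise ValueError(f"num_round must be >= 1, got {hp.num_round}")
    x = np.asarray(vectors, dtype=float)
    y = np.asarray([lab.index if isinstance(lab, ClassLabel) else int(lab)
                    for lab in labels])
    if x.ndim != 2 or len(x) != len(y):
        raise ValueError("vectors must be 2-D with one label per row")
    present = set(np.unique(y))
    if len(present) < 2:
        raise ValueError("training data must contain at least 2 classes")
    if require_all_classes:
        missing = [c.code for c in ALL_CLASSES if c.index not in present]
        if missing:
            raise ValueError(f"class(es) absent from labels: {missing}")
    dtrain = xgb.DMatrix(x, label=y)
    booster = xgb.train(hp.to_xgb_params(seed), dtrain,
                        num_boost_round=hp.num_round)
    return FusionModel(booster=booster, hyperparams=hp, n_features=x.shape[1])


def predict_fusion(model: FusionModel,
                   vectors: np.ndarray) -> tuple[list[ClassLabel], np.ndarray]:
    """Predicted classes (argmax) and 9-class probability rows."""
    x = np.asarray(vectors, dtype=float)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {x.shape[1]}")
    proba = model.booster.predict(xgb.DMatrix(x))
    proba = np.asarray(proba).reshape(len(x), N_CLASSES)
    preds = [ALL_CLASSES[i] for i in proba.argmax(axis=1)]
    return preds, proba


def hyperparams_dict(hp: FusionHyperparams) -> dict:
    """Serializable view of a hyperparameter profile."""
    return asdict(hp)
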