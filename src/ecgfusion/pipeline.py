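"""End-to-end orchestration: one flat config drives every stage.

Stages: ``synth`` (write a synthetic dataset) -> ``preprocess``
(condition records, cache segments + HRV) -> ``train`` (12 lead models
+ fusion) -> ``predict`` / ``cv`` / ``ablation``.  Every constant of the
method appears exactly once in the defaults below; each stage is
idempotent under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import evaluate
from .evaluate import (
    FoldFit,
    MetricsReport,
    PreparedRecord,
    fit_fold,
    prepare_records,
)
from .fusion import FusionHyperparams
from .labels import ClassLabel
from .nn import LeadModelConfig
from .record_io import LEAD_NAMES, read_record
from .synth import SynthSpec, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full run; serializable to/from YAML or JSON."""

    data_dir: str = "data"
    out_dir: str = "out"
    target_fs: float = 250.0          # analysis sampling rate, Hz
    segment_seconds: float = 6.0      # slice length
    seed: int = 0
    k_folds: int = 5
    variant: str = "fused_dfs"        # fused_dfs | fused | single:<LEAD>
    stack_fraction: float = 0.2
    synth: SynthSpec = field(default_factory=SynthSpec)
    lead_model: LeadModelConfig = field(default_factory=LeadModelConfig)
    fusion: FusionHyperparams = field(default_factory=FusionHyperparams)

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return {k2: conv(v2) for k2, v2
                        in dataclasses.asdict(v).items()}
            if isinstance(v, ClassLabel):
                return v.code
            if isinstance(v, dict):
                return {conv(k2): conv(v2) for k2, v2 in v.items()}
            if isinstance(v, tuple):
                return [conv(x) for x in v]
            if isinstance(v, list):
                return [conv(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v
        return {f.name: conv(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            sd = dict(d["synth"])
            if "class_mix" in sd:
                sd["class_mix"] = {ClassLabel.from_code(k): v
                                   for k, v in sd["class_mix"].items()}
            sd.pop("class_params", None)   # per-class overrides stay in code
            if "duration_range" in sd:
                sd["duration_range"] = tuple(sd["duration_range"])
            d["synth"] = SynthSpec(**sd)
        if "lead_model" in d and isinstance(d["lead_model"], dict):
            d["lead_model"] = LeadModelConfig(**d["lead_model"])
        if "fusion" in d and isinstance(d["fusion"], dict):
            d["fusion"] = FusionHyperparams(**d["fusion"])
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))


def _log_run(config: RunConfig, stage: str) -> None:
    """Stage-boundary log line: config hash + library versions."""
    import hashlib

    import xgboost

    digest = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
    logger.info("%s: config %s (numpy %s, xgboost %s)", stage, digest,
                np.__version__, xgboost.__version__)


def run_synth(config: RunConfig) -> Path:
    """Generate and write the synthetic dataset; returns its directory."""
    _log_run(config, "synth")
    out = Path(config.data_dir)
    manifest = generate_dataset(config.synth, out)
    hist = manifest["true_class"].value_counts().to_dict()
    logger.info("synth: %d records, class histogram %s", len(manifest), hist)
    return out


def load_dataset(config: RunConfig) -> list:
    """Read every csvmat record in the data directory (sorted, stable)."""
    data_dir = Path(config.data_dir)
    bases = sorted(p.with_suffix("") for p in data_dir.glob("*.json")
                   if p.stem != "truth")
    records = [read_record(b, format="csvmat") for b in bases]
    if not records:
        raise FileNotFoundError(
            f"no csvmat records in {data_dir}; run the synth stage first")
    return records


def run_preprocess(config: RunConfig) -> list[PreparedRecord]:
    """Condition every record in the dataset (segments + HRV features)."""
    records = load_dataset(config)
    items = prepare_records(records, target_fs=config.target_fs,
                            segment_seconds=config.segment_seconds)
    n_hrv = sum(p.hrv is not None for p in items)
    logger.info("preprocess: %d records conditioned, HRV available for %d",
                len(items), n_hrv)
    return items


def _parse_variant(variant: str) -> tuple[str, int | None]:
    if variant.startswith("single:"):
        name = variant.split(":", 1)[1]
        if name not in LEAD_NAMES:
            raise ValueError(f"unknown lead {name!r}; one of {LEAD_NAMES}")
        return "single_lead", LEAD_NAMES.index(name)
    if variant in ("fused", "fused_dfs"):
        return variant, None
    raise ValueError(
        f"variant must be 'fused_dfs', 'fused' or 'single:<LEAD>'; "
        f"got {variant!r}")


def run_train(config: RunConfig,
              items: Sequence[PreparedRecord] | None = None) -> FoldFit:
    """Train lead models + fusion on the full dataset (single split).

    Uses the whole dataset as one training fold with an internal
    stacking split; returns the fitted artifacts for prediction.
    """
    _log_run(config, "train")
    if items is None:
        items = run_preprocess(config)
    return fit_fold(list(items), [], config.lead_model, seed=config.seed,
                    stack_fraction=config.stack_fraction)


def run_predict(config: RunConfig, fit: FoldFit,
                items: Sequence[PreparedRecord]) -> "pd.DataFrame":
    """Predictions CSV rows for *items* under the configured variant."""
    import pandas as pd

    from .evaluate import _fusion_matrix, _lead_probas
    from .fusion import predict_fusion, train_fusion
    from .labels import ALL_CLASSES

    variant, lead = _parse_variant(config.variant)
    probas = _lead_probas(fit.lead_models, list(items))
    if variant == "single_lead":
        proba = probas[:, lead, :]
        preds = [ALL_CLASSES[i] for i in proba.argmax(axis=1)]
    else:
        include = variant == "fused_dfs"
        hp = config.fusion if include else FusionHyperparams.probs_only()
        x_stack = _fusion_matrix(fit.stack_probas, fit.stack_items, fit,
                                 include)
        fusion = train_fusion(x_stack, [p.primary for p in fit.stack_items],
                              hp, seed=config.seed)
        x = np.stack([
            _fusion_matrix(probas[i:i + 1], [p], fit, include)[0]
            for i, p in enumerate(items)
        ])
        preds, proba = predict_fusion(fusion, x)
    rows = []
    for i, p in enumerate(items):
        row = {
            "record_id": p.record_id,
            "true_labels": "|".join(lab.code for lab in p.labels),
            "predicted": preds[i].code,
        }
        row.update({f"prob_{c}": proba[i, c] for c in range(proba.shape[1])})
        rows.append(row)
    return pd.DataFrame(rows)


def run_cv(config: RunConfig,
           items: Sequence[PreparedRecord] | None = None,
           ) -> tuple[list[MetricsReport], MetricsReport]:
    """k-fold cross-validation under the configured variant."""
    _log_run(config, "cv")
    if items is None:
        items = run_preprocess(config)
    variant, lead = _parse_variant(config.variant)
    hp = config.fusion if variant == "fused_dfs" else None
    return evaluate.cross_validate(
        list(items), config.lead_model, k=config.k_folds, seed=config.seed,
        variant=variant, fusion_hp=hp, lead=lead,
        stack_fraction=config.stack_fraction)


def run_ablation(config: RunConfig,
                 items: Sequence[PreparedRecord] | None = None,
                 ) -> "pd.DataFrame":
    """The 14-row comparison: 12 single leads + both fusion variants."""
    _log_run(config, "ablation")
    if items is None:
        items = run_preprocess(config)
    return evaluate.run_ablation(list(items), config.lead_model,
                                 k=config.k_folds, seed=config.seed,
                                 stack_fraction=config.stack_fraction)


def write_reports(reports: list[MetricsReport], mean: MetricsReport,
                  out_dir: str | Path) -> None:
    """Serialize fold reports + mean report as JSON under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, rep in enumerate(reports):
        (out_dir / f"fold{i}.json").write_text(
            json.dumps(rep.to_dict(), indent=1))
    (out_dir / "mean.json").write_text(json.dumps(mean.to_dict(), indent=1))
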