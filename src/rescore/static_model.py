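"""Train-once/apply-many ("static") models.

A static model is learned once from a large external dataset, serialized
to JSON, and later applied unchanged to new datasets.  Because the model
never scores its own training data, the cross-validation machinery of the
dynamic pipeline is unnecessary: the fit uses the full training table.
Error rates are still estimated afresh on each dataset's own targets and
decoys, so the fixed model carries no FDR threshold with it.
"""

from __future__ import annotations

import json

import numpy as np

from . import confidence as conf
from .engine import BrewResult, LinearModel, TrainConfig, fit_semisupervised
from .exceptions import ModelFileError, ModelVersionError, SchemaError
from .pin_io import PsmTable, validate_schema

__all__ = [
    "SCHEMA_VERSION",
    "fit_static",
    "save_model",
    "load_model",
    "apply_static",
    "average_fold_models",
]

SCHEMA_VERSION = "1"


def fit_static(train_table: PsmTable, config: TrainConfig) -> LinearModel:
    """Fit a static model on the full external training set.

    Runs the semi-supervised loop without cross-validation (valid because
    the model will never score its own training PSMs); the training-set
    size and configuration are recorded in the model's provenance.
    """
    model = fit_semisupervised(train_table, config)
    model.provenance.update(
        {
            "static": True,
            "fit": "single full-data fit (no cross-validation)",
            "training_psms": len(train_table),
            "seed": config.seed,
        }
    )
    return model


def average_fold_models(models: list[LinearModel] | BrewResult) -> LinearModel:
    """Collapse the (score-normalized) per-fold models of a dynamic run
    into one exportable static-form model by averaging weights."""
    if isinstance(models, BrewResult):
        models = models.fold_models
    if not models:
        raise ValueError("no models to average")
    names = models[0].feature_names
    if any(m.feature_names != names for m in models):
        raise SchemaError("fold models disagree on feature names")
    return LinearModel(
        feature_names=names,
        weights=np.mean([m.weights for m in models], axis=0),
        intercept=float(np.mean([m.intercept for m in models])),
        norm_mean=np.mean([m.norm_mean for m in models], axis=0),
        norm_scale=np.mean([m.norm_scale for m in models], axis=0),
        provenance={
            "static": True,
            "fit": f"mean of {len(models)} score-normalized fold models",
            "degraded_folds": sum(m.degraded for m in models),
        },
        degraded=any(m.degraded for m in models),
    )


def save_model(model: LinearModel, path) -> None:
    """Serialize a model to JSON with full-precision floats."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "feature_names": list(model.feature_names),
        "weights": [float(w) for w in model.weights],
        "intercept": float(model.intercept),
        "normalization": {
            "mean": [float(m) for m in model.norm_mean],
            "scale": [float(s) for s in model.norm_scale],
        },
        "degraded": bool(model.degraded),
        "provenance": model.provenance,
    }
    with open(path, "w", encoding="utf-8") as out:
        json.dump(payload, out, indent=1)
        out.write("\n")


def load_model(path) -> LinearModel:
    """Load a model saved by :func:`save_model`; exact round-trip.

    Raises :class:`ModelFileError` on corrupt files and
    :class:`ModelVersionError` on an unknown schema version.
    """
    try:
        with open(path, "r", encoding="utf-8") as handle:
            payload = json.load(handle)
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise ModelFileError(f"{path}: missing schema_version")
    if payload["schema_version"] != SCHEMA_VERSION:
        raise ModelVersionError(
            f"{path}: unsupported model schema_version "
            f"{payload['schema_version']!r} (expected {SCHEMA_VERSION!r})"
        )
    try:
        return LinearModel(
            feature_names=list(payload["feature_names"]),
            weights=np.array(payload["weights"], dtype=float),
            intercept=float(payload["intercept"]),
            norm_mean=np.array(payload["normalization"]["mean"], dtype=float),
            norm_scale=np.array(payload["normalization"]["scale"], dtype=float),
            provenance=dict(payload.get("provenance", {})),
            degraded=bool(payload.get("degraded", False)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFileError(f"{path}: malformed model payload ({exc})") from exc


def apply_static(table: PsmTable, model: LinearModel, eval_fdr: float = 0.01) -> conf.ConfidenceResult:
    """Score a dataset with a fixed model and estimate its own q-values.

    A single deterministic pass (no training, no folds, no seed): scores
    are ``weights . features + intercept`` and target-decoy competition
    runs on the new dataset's own targets and decoys.
    """
    report = validate_schema(table, model.feature_names)
    if not report.compatible:
        raise SchemaError(
            f"table is missing features required by the model: {report.missing}"
        )
    scores = model.decision_function(table.features)
    return conf.assign_confidence(table, scores, eval_fdr)
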