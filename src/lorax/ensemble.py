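"""Stage-2 gradient-boosted-tree ensemble over three fixed feature sets.

After the transformer is frozen, three XGBoost models are trained on:

* ``CLS`` — the transformer's <cls> token per interaction,
* ``ORIG`` — the concatenated original (non-adapted) chemical and protein
  representations,
* ``CLS_PLUS_ORIG`` — the concatenation of both.

The final prediction is a weighted sum with weights on the 2-simplex, chosen
by exhaustive grid search (step 0.05, 231 candidates) maximizing the
validation metric; the first candidate in lexicographic order wins ties.
The ORIG-only weight is the introspection statistic: a large value means the
learned <cls> representation is being ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import xgboost as xgb

from .data_model import ValidationError
from .evaluation import matthews_corrcoef, r2_score

__all__ = [
    "FEATURE_SET_IDS",
    "EnsembleWeights",
    "EnsembleBundle",
    "DEFAULT_GBT_PARAMS",
    "build_feature_sets",
    "fit_ensemble",
    "optimize_weights",
    "ensemble_predict",
    "ensemble_report",
    "simplex_grid",
]

FEATURE_SET_IDS = ("CLS", "ORIG", "CLS_PLUS_ORIG")

Task = Literal["regression", "classification"]

DEFAULT_GBT_PARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.9,
    "n_jobs": 1,
}


@dataclass(frozen=True)
class EnsembleWeights:
    w: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, float)
        if arr.shape != (3,) or np.any(arr < 0) or abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must be on the 2-simplex, got {self.w}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.w, float)


@dataclass
class EnsembleBundle:
    models: dict[str, object]  # FeatureSetId -> fitted tree model
    weights: EnsembleWeights
    task: Task
    validation_scores: dict[str, float]
    combined_validation_score: float
    transformer_val_score: float | None = None
    flags: list[str] = field(default_factory=list)


def build_feature_sets(
    cls_mat: np.ndarray, chem: np.ndarray, prot: np.ndarray
) -> dict[str, np.ndarray]:
    """Assemble the three fixed feature sets, rows aligned to interactions."""
    cls_mat, chem, prot = (np.asarray(m, float) for m in (cls_mat, chem, prot))
    n = cls_mat.shape[0]
    if chem.shape[0] != n or prot.shape[0] != n:
        raise ValidationError(
            f"row mismatch: cls {cls_mat.shape[0]}, chem {chem.shape[0]}, "
            f"prot {prot.shape[0]}"
        )
    orig = np.hstack([chem, prot])
    return {
        "CLS": cls_mat,
        "ORIG": orig,
        "CLS_PLUS_ORIG": np.hstack([cls_mat, orig]),
    }


def _make_model(task: Task, params: Mapping, seed: int):
    kwargs = dict(DEFAULT_GBT_PARAMS)
    kwargs.update(params or {})
    kwargs["random_state"] = seed
    if task == "regression":
        return xgb.XGBRegressor(**kwargs)
    return xgb.XGBClassifier(**kwargs, eval_metric="logloss")


def fit_ensemble(
    feature_sets: Mapping[str, np.ndarray],
    y_train: np.ndarray,
    weights_train: np.ndarray | None = None,
    task: Task = "regression",
    gbt_params: Mapping | None = None,
    seed: int = 0,
) -> dict[str, object]:
    """Fit one tree model per feature set, identical hyperparameters and seed."""
    models: dict[str, object] = {}
    y_train = np.asarray(y_train)
    for fid in FEATURE_SET_IDS:
        X = np.asarray(feature_sets[fid], float)
        if not np.all(np.isfinite(X)):
            raise ValidationError(f"feature set {fid}: non-finite entries")
        model = _make_model(task, gbt_params or {}, seed)
        model.fit(X, y_train, sample_weight=weights_train)
        models[fid] = model
    return models


def _model_predict(model, X: np.ndarray, task: Task) -> np.ndarray:
    if task == "classification":
        return model.predict_proba(X)[:, 1]
    return model.predict(X)


def simplex_grid(step: float = 0.05) -> list[tuple[float, float, float]]:
    """All weight triples on the 2-simplex with the given step, lexicographic."""
    m = round(1.0 / step)
    if abs(m * step - 1.0) > 1e-9:
        raise ValidationError(f"grid step {step} does not divide 1")
    out = []
    for i in range(m + 1):
        for j in range(m + 1 - i):
            out.append((i * step, j * step, (m - i - j) * step))
    return out


def _score(y, pred, task: Task) -> float:
    if task == "regression":
        return r2_score(y, pred)
    return float(matthews_corrcoef(np.asarray(y, int), (pred >= 0.5).astype(int)))


def optimize_weights(
    val_preds: Mapping[str, np.ndarray],
    y_val: np.ndarray,
    task: Task = "regression",
    grid_step: float = 0.05,
) -> tuple[EnsembleWeights, float]:
    """Exhaustive simplex search for the validation-optimal weighted sum.

    Returns the first lexicographic candidate attaining the best metric and
    that metric's value.
    """
    y_val = np.asarray(y_val)
    if y_val.size == 0:
        raise ValidationError("empty validation set")
    P = np.stack([np.asarray(val_preds[fid], float) for fid in FEATURE_SET_IDS])
    if P.shape[1] != y_val.size:
        raise ValidationError("prediction/target length mismatch")
    best_w, best_s = None, -np.inf
    for w in simplex_grid(grid_step):
        combined = np.asarray(w) @ P
        s = _score(y_val, combined, task)
        if s > best_s + 1e-15:
            best_w, best_s = w, s
    return EnsembleWeights(best_w), float(best_s)


def fit_weighted_ensemble(
    feature_sets_train: Mapping[str, np.ndarray],
    y_train: np.ndarray,
    feature_sets_val: Mapping[str, np.ndarray],
    y_val: np.ndarray,
    weights_train: np.ndarray | None = None,
    task: Task = "regression",
    gbt_params: Mapping | None = None,
    seed: int = 0,
    grid_step: float = 0.05,
    transformer_val_score: float | None = None,
) -> EnsembleBundle:
    """Fit the three models and optimize their simplex weights on validation."""
    models = fit_ensemble(feature_sets_train, y_train, weights_train, task,
                          gbt_params, seed)
    val_preds = {
        fid: _model_predict(models[fid], np.asarray(feature_sets_val[fid], float), task)
        for fid in FEATURE_SET_IDS
    }
    val_scores = {fid: _score(y_val, val_preds[fid], task) for fid in FEATURE_SET_IDS}
    weights, combined = optimize_weights(val_preds, y_val, task, grid_step)
    return EnsembleBundle(
        models=models,
        weights=weights,
        task=task,
        validation_scores=val_scores,
        combined_validation_score=combined,
        transformer_val_score=transformer_val_score,
    )


def ensemble_predict(
    bundle: EnsembleBundle, feature_sets: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Weighted sum of per-model predictions (probabilities in classification)."""
    preds = np.stack(
        [
            _model_predict(bundle.models[fid], np.asarray(feature_sets[fid], float),
                           bundle.task)
            for fid in FEATURE_SET_IDS
        ]
    )
    return bundle.weights.as_array() @ preds


def ensemble_report(bundle: EnsembleBundle) -> dict:
    """JSON-serializable summary incl. the ORIG-only weight (w2 statistic)."""
    w = bundle.weights.as_array()
    return {
        "weights": {fid: float(wi) for fid, wi in zip(FEATURE_SET_IDS, w)},
        "orig_only_weight": float(w[1]),
        "validation_scores": {k: float(v) for k, v in bundle.validation_scores.items()},
        "combined_validation_score": float(bundle.combined_validation_score),
        "transformer_val_score": (
            None if bundle.transformer_val_score is None
            else float(bundle.transformer_val_score)
        ),
        "task": bundle.task,
    }
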