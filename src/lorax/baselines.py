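"""Feature-based benchmark models.

Two ridge-regression benchmarks probe what a fixed odorant representation
can predict:

* **MO (molecule only)** — one ridge model per receptor using only odorant
  features; tests whether chemical information alone predicts activation.
  Fold scores are the unweighted mean of per-receptor R^2.
* **MP (molecule + protein)** — a single ridge model on the concatenation
  [chem || protein] over all interactions; tests the odorant representation
  with receptor identity available.

Ridge is solved in closed form on internally standardized features with an
unpenalized intercept; the regularization strength is chosen per fit by
inner cross-validation over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .data_model import InteractionDataset, RepresentationMatrix, ValidationError
from .evaluation import make_splits, r2_score

__all__ = [
    "RidgeModel",
    "BenchmarkResult",
    "DEFAULT_LAMBDA_GRID",
    "ridge_fit",
    "select_lambda",
    "run_mo",
    "run_mp",
]

DEFAULT_LAMBDA_GRID: np.ndarray = np.logspace(-3, 3, 13)


@dataclass
class RidgeModel:
    coefficients: np.ndarray
    intercept: float
    lam: float
    feature_means: np.ndarray
    feature_scales: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        Xs = (X - self.feature_means) / self.feature_scales
        return Xs @ self.coefficients + self.intercept


def ridge_fit(X: np.ndarray, y: np.ndarray, lam: float) -> RidgeModel:
    """Closed-form ridge on standardized features with unpenalized intercept.

    Constant columns get a unit scale guard (their standardized column is
    all-zero, so they receive a zero coefficient rather than dividing by 0).
    With ``lam=0`` the standardized design must have full column rank.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 samples")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales == 0, 1.0, scales)
    Xs = (X - means) / scales
    if lam == 0 and np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        raise ValidationError("lambda=0 requires full column rank (use lambda > 0)")
    yc = y - y.mean()
    A = Xs.T @ Xs + lam * np.eye(Xs.shape[1])
    beta = scipy.linalg.solve(A, Xs.T @ yc, assume_a="pos")
    return RidgeModel(
        coefficients=beta,
        intercept=float(y.mean()),
        lam=float(lam),
        feature_means=means,
        feature_scales=scales,
    )


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    inner_folds: int = 3,
    seed: int = 0,
) -> float:
    """Pick lambda by inner k-fold CV (mean validation R^2, ties -> smaller lam)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    k = min(inner_folds, n // 2)
    if k < 2:
        return float(np.median(lambda_grid))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    chunks = np.array_split(perm, k)
    grid = sorted(float(l) for l in lambda_grid)
    best_lam, best_score = grid[0], -np.inf
    for lam in grid:
        scores = []
        for chunk in chunks:
            tr = np.setdiff1d(perm, chunk)
            if len(chunk) < 2 or len(tr) < 2:
                continue
            try:
                model = ridge_fit(X[tr], y[tr], lam)
            except ValidationError:
                scores.append(-np.inf)
                continue
            scores.append(r2_score(y[chunk], model.predict(X[chunk])))
        score = float(np.mean(scores)) if scores else -np.inf
        if score > best_score + 1e-12:
            best_lam, best_score = lam, score
    return best_lam


@dataclass
class BenchmarkResult:
    representation_name: str
    model: str  # "MO" or "MP"
    per_fold_r2: list[float]
    mean_r2: float
    sd_r2: float
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_folds(cls, name: str, model: str, per_fold: Sequence[float], flags=()):
        arr = np.asarray(per_fold, float)
        return cls(
            representation_name=name,
            model=model,
            per_fold_r2=[float(v) for v in arr],
            mean_r2=float(arr.mean()),
            sd_r2=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            flags=list(flags),
        )

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _interaction_features(
    dataset: InteractionDataset, rep: RepresentationMatrix
) -> np.ndarray:
    """Per-interaction odorant feature rows, joined on odorant_id."""
    idx = {oid: i for i, oid in enumerate(rep.item_ids)}
    missing = [it.odorant_id for it in dataset.interactions if it.odorant_id not in idx]
    if missing:
        raise ValidationError(f"representation missing odorants: {sorted(set(missing))[:5]}")
    rows = [idx[it.odorant_id] for it in dataset.interactions]
    return rep.values[rows]


def run_mo(
    dataset: InteractionDataset,
    chem_rep: RepresentationMatrix,
    folds: int = 5,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> BenchmarkResult:
    """Molecule-only benchmark: per-receptor ridge, averaged over receptors."""
    if dataset.mode != "regression":
        raise ValidationError("MO benchmark requires a regression dataset")
    X_all = _interaction_features(dataset, chem_rep)
    y_all = dataset.responses()
    rids = np.array([it.receptor_id for it in dataset.interactions])
    split = make_splits(dataset, "random", k=folds, seed=seed, val_fraction=0.0)
    flags: list[str] = []
    fold_scores = []
    for fold in split:
        tr = np.concatenate([fold.train_idx, fold.val_idx]).astype(int)
        te = fold.test_idx
        receptor_scores = []
        for rid in dataset.receptor_ids:
            tr_r = tr[rids[tr] == rid]
            te_r = te[rids[te] == rid]
            if len(te_r) < 2 or len(tr_r) < 2:
                continue
            y_tr = y_all[tr_r]
            if np.allclose(y_tr, y_tr[0]):
                pred = np.full(len(te_r), y_tr[0])
                flags.append(f"receptor {rid}: constant training response")
            else:
                lam = select_lambda(X_all[tr_r], y_tr, lambda_grid, seed=seed)
                model = ridge_fit(X_all[tr_r], y_tr, lam)
                pred = model.predict(X_all[te_r])
            receptor_scores.append(r2_score(y_all[te_r], pred))
        if not receptor_scores:
            raise ValidationError("no receptor had enough interactions in a fold")
        fold_scores.append(float(np.mean(receptor_scores)))
    return BenchmarkResult.from_folds(chem_rep.name, "MO", fold_scores, flags)


def run_mp(
    dataset: InteractionDataset,
    chem_rep: RepresentationMatrix,
    prot_rep: RepresentationMatrix,
    folds: int = 5,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    seed: int = 0,
) -> BenchmarkResult:
    """Molecule+protein benchmark: one ridge on [chem || protein] per fold."""
    if dataset.mode != "regression":
        raise ValidationError("MP benchmark requires a regression dataset")
    chem = _interaction_features(dataset, chem_rep)
    pidx = {rid: i for i, rid in enumerate(prot_rep.item_ids)}
    missing = [
        it.receptor_id for it in dataset.interactions if it.receptor_id not in pidx
    ]
    if missing:
        raise ValidationError(
            f"protein representation missing receptors: {sorted(set(missing))[:5]}"
        )
    prot = prot_rep.values[[pidx[it.receptor_id] for it in dataset.interactions]]
    X_all = np.hstack([chem, prot])
    y_all = dataset.responses()
    split = make_splits(dataset, "random", k=folds, seed=seed, val_fraction=0.0)
    fold_scores = []
    for fold in split:
        tr = np.concatenate([fold.train_idx, fold.val_idx]).astype(int)
        te = fold.test_idx
        lam = select_lambda(X_all[tr], y_all[tr], lambda_grid, seed=seed)
        model = ridge_fit(X_all[tr], y_all[tr], lam)
        fold_scores.append(r2_score(y_all[te], model.predict(X_all[te])))
    name = f"{chem_rep.name}+{prot_rep.name}"
    return BenchmarkResult.from_folds(name, "MP", fold_scores)
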