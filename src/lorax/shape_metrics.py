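"""Angular shape distances between representation matrices.

Two dissimilarity metrics over representations of a common item set:

* **Orthogonal Procrustes distance** — after centering and scaling each
  matrix to unit Frobenius norm, the angular residual of the best orthogonal
  alignment: ``arccos(||X' Y||_*)`` where ``||.||_*`` is the nuclear norm.
  Invariant to orthogonal transforms and isotropic scaling of either input.

* **CCA distance** — after whitening each matrix onto its retained principal
  subspace, ``arccos(sum(rho_i) / sqrt(k_x k_y))`` where ``rho_i`` are the
  canonical correlations.  Invariant to any invertible linear transform of
  either input.

Both are angular (radians in [0, pi/2]) so self-distance is exactly 0 and the
range is bounded.  Matrices of unequal width are zero-padded to a common
column count, which preserves both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .data_model import RepresentationMatrix, ValidationError

__all__ = [
    "ShapeDistance",
    "DistanceMatrix",
    "align_and_center",
    "procrustes_distance",
    "cca_distance",
    "pairwise_distances",
]


@dataclass
class ShapeDistance:
    value: float
    metric: Literal["procrustes", "cca"]
    rank_x: int
    rank_y: int
    rho: np.ndarray | None = None  # canonical correlations, descending (cca)
    Q: np.ndarray | None = None  # optimal orthogonal map (procrustes)

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.value <= np.pi / 2 + 1e-9):
            raise ValidationError(f"distance {self.value} outside [0, pi/2]")


@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.names), len(self.names)):
            raise ValidationError("distance matrix shape mismatch")
        if np.max(np.abs(v - v.T)) > 1e-8:
            raise ValidationError("distance matrix not symmetric within 1e-8")
        if np.max(np.abs(np.diag(v))) > 1e-8:
            raise ValidationError("distance matrix diagonal not zero")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.names, columns=self.names)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf)


def align_and_center(
    X: RepresentationMatrix, Y: RepresentationMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Reorder to a common item order, center columns, zero-pad to equal width."""
    sx, sy = set(X.item_ids), set(Y.item_ids)
    if sx != sy:
        diff = sorted(sx.symmetric_difference(sy))
        raise ValidationError(f"item sets differ; symmetric difference: {diff}")
    if len(X.item_ids) < 3:
        raise ValidationError("need at least 3 items")
    order = list(X.item_ids)
    Xv = X.values.copy()
    Yv = Y.reorder(order).values
    Xv = Xv - Xv.mean(axis=0)
    Yv = Yv - Yv.mean(axis=0)
    d = max(Xv.shape[1], Yv.shape[1])
    if Xv.shape[1] < d:
        Xv = np.pad(Xv, ((0, 0), (0, d - Xv.shape[1])))
    if Yv.shape[1] < d:
        Yv = np.pad(Yv, ((0, 0), (0, d - Yv.shape[1])))
    return Xv, Yv


def _as_centered(X, Y):
    if isinstance(X, RepresentationMatrix):
        return align_and_center(X, Y)
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    return X - X.mean(axis=0), Y - Y.mean(axis=0)


def procrustes_distance(X, Y) -> ShapeDistance:
    """Angular orthogonal-Procrustes distance between two representations.

    Accepts :class:`RepresentationMatrix` pairs (aligned internally) or raw
    arrays over identical items.
    """
    Xc, Yc = _as_centered(X, Y)
    nx = np.linalg.norm(Xc)
    ny = np.linalg.norm(Yc)
    if nx == 0 or ny == 0:
        raise ValidationError("zero matrix has no Procrustes distance")
    Xn, Yn = Xc / nx, Yc / ny
    C = Xn.T @ Yn
    U, s, Vt = np.linalg.svd(C)
    value = float(np.arccos(np.clip(s.sum(), 0.0, 1.0)))
    return ShapeDistance(
        value=value,
        metric="procrustes",
        rank_x=int(np.linalg.matrix_rank(Xc)),
        rank_y=int(np.linalg.matrix_rank(Yc)),
        Q=U @ Vt,
    )


def _whiten(Xc: np.ndarray, rank_tol: float) -> tuple[np.ndarray, int]:
    # Project onto the retained principal subspace and scale to identity
    # covariance there (relative eigenvalue cutoff).
    cov = Xc.T @ Xc
    w, E = scipy.linalg.eigh(cov)
    w = np.maximum(w, 0.0)
    keep = w > rank_tol * (w.max() if w.size else 0.0)
    k = int(keep.sum())
    if k == 0:
        raise ValidationError("retained rank 0 (constant or zero matrix)")
    E = E[:, keep]
    w = w[keep]
    return Xc @ E / np.sqrt(w), k


def cca_distance(X, Y, rank_tol: float = 1e-9) -> ShapeDistance:
    """Angular CCA distance between two representations.

    Whitens each matrix on its retained principal subspace; canonical
    correlations are the singular values of the whitened cross-product.
    """
    Xc, Yc = _as_centered(X, Y)
    Xw, kx = _whiten(Xc, rank_tol)
    Yw, ky = _whiten(Yc, rank_tol)
    if Xc.shape[0] <= max(kx, ky):
        raise ValidationError(
            f"need n > max retained rank ({Xc.shape[0]} items, ranks {kx}, {ky})"
        )
    rho = np.clip(np.linalg.svd(Xw.T @ Yw, compute_uv=False), 0.0, 1.0)
    value = float(np.arccos(np.clip(rho.sum() / np.sqrt(kx * ky), 0.0, 1.0)))
    return ShapeDistance(
        value=value, metric="cca", rank_x=kx, rank_y=ky, rho=np.sort(rho)[::-1]
    )


def pairwise_distances(
    reps: Sequence[RepresentationMatrix],
    metric: Literal["procrustes", "cca"] = "procrustes",
    rank_tol: float = 1e-9,
) -> DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over a list of representations."""
    if len(reps) < 2:
        raise ValidationError("need at least 2 representations")
    names = [r.name or f"rep{i}" for i, r in enumerate(reps)]
    n = len(reps)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                if metric == "procrustes":
                    d = procrustes_distance(reps[i], reps[j]).value
                else:
                    d = cca_distance(reps[i], reps[j], rank_tol=rank_tol).value
            except ValidationError as exc:
                raise ValidationError(
                    f"distance({names[i]}, {names[j]}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = d
    return DistanceMatrix(names=names, values=out)
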