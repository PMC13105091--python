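"""Cross-validation splits, metrics, the naive baseline, and model comparison.

Three split scenarios are supported: plain random folding of interactions,
and two entity-level generalization scenarios in which all interactions of a
held-out odorant (or receptor) land in the same test fold, so test entities
are never seen during training — the harder and more realistic deployment
setting for receptor-affinity models.

Metric conventions (they matter for reproducing signed values):

* R^2 = 1 - SSres/SStot with SStot taken about the *test-set* mean, so a
  model can score below zero and the naive train-mean predictor scores
  exactly zero only when train and test means coincide.
* MCC returns 0 whenever a denominator factor is 0.
* Classification threshold 0.5 for precision/recall/F/MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import scipy.stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .data_model import Interaction, InteractionDataset, ValidationError

__all__ = [
    "CVSplit",
    "Fold",
    "MetricReport",
    "TierWeighting",
    "ComparisonReport",
    "make_splits",
    "r2_score",
    "matthews_corrcoef",
    "compute_metrics",
    "naive_baseline",
    "apply_tier_weights",
    "compare_models",
]

Scenario = Literal["random", "unseen_odorant", "unseen_receptor"]


@dataclass(frozen=True)
class Fold:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass
class CVSplit:
    scenario: Scenario
    k: int
    seed: int
    folds: list[Fold]

    def __iter__(self):
        return iter(self.folds)


def _carve_val(pool: np.ndarray, frac: float, rng: np.random.Generator):
    pool = rng.permutation(pool)
    n_val = int(round(frac * len(pool)))
    return np.sort(pool[n_val:]), np.sort(pool[:n_val])


def make_splits(
    dataset: InteractionDataset,
    scenario: Scenario = "random",
    k: int = 5,
    seed: int = 0,
    val_fraction: float = 0.15,
) -> CVSplit:
    """Build k-fold splits; test folds are disjoint and cover every interaction.

    Under the entity scenarios, folding happens at the entity level and the
    validation carve-out is entity-respecting too (whole odorants/receptors
    move into validation).
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(dataset.interactions)
    folds: list[Fold] = []

    if scenario == "random":
        perm = rng.permutation(n)
        test_chunks = np.array_split(perm, k)
        for chunk in test_chunks:
            rest = np.setdiff1d(perm, chunk)
            train, val = _carve_val(rest, val_fraction, rng)
            folds.append(Fold(train, val, np.sort(chunk)))
    else:
        key = "odorant_id" if scenario == "unseen_odorant" else "receptor_id"
        entities = sorted({getattr(it, key) for it in dataset.interactions})
        if len(entities) < k:
            raise ValidationError(
                f"{scenario}: only {len(entities)} distinct entities for k={k}"
            )
        ent_perm = rng.permutation(entities)
        ent_chunks = np.array_split(ent_perm, k)
        by_entity: dict[str, list[int]] = {}
        for i, it in enumerate(dataset.interactions):
            by_entity.setdefault(getattr(it, key), []).append(i)
        for chunk in ent_chunks:
            test_ents = set(chunk)
            rest_ents = [e for e in ent_perm if e not in test_ents]
            n_val_ents = int(round(val_fraction * len(rest_ents)))
            val_ents = set(rng.permutation(rest_ents)[:n_val_ents])
            test = np.sort(np.concatenate([by_entity[e] for e in sorted(test_ents)]))
            val_list = [by_entity[e] for e in sorted(val_ents)]
            val = np.sort(np.concatenate(val_list)) if val_list else np.array([], dtype=int)
            train_ents = [e for e in rest_ents if e not in val_ents]
            train = np.sort(np.concatenate([by_entity[e] for e in sorted(train_ents)]))
            folds.append(Fold(train, val, test))

    return CVSplit(scenario=scenario, k=k, seed=seed, folds=folds)


# ---------------------------------------------------------------------------
# Metrics


def r2_score(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValidationError("r2_score needs matching vectors of length >= 2")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def matthews_corrcoef(y_true, y_hat) -> float:
    """MCC from a thresholded confusion matrix; 0 when any factor is 0."""
    y_true = np.asarray(y_true, int)
    y_hat = np.asarray(y_hat, int)
    tp = int(np.sum((y_true == 1) & (y_hat == 1)))
    tn = int(np.sum((y_true == 0) & (y_hat == 0)))
    fp = int(np.sum((y_true == 0) & (y_hat == 1)))
    fn = int(np.sum((y_true == 1) & (y_hat == 0)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


@dataclass
class MetricReport:
    r2: float | None = None
    auroc: float | None = None
    avep: float | None = None
    precision: float | None = None
    recall: float | None = None
    f_score: float | None = None
    mcc: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "flags" and v is not None
        }
        if self.flags:
            out["flags"] = list(self.flags)
        return out


def compute_metrics(
    y_true,
    y_pred,
    mode: Literal["regression", "classification"],
    threshold: float = 0.5,
) -> MetricReport:
    """Standard metric panel; classification predictions are probabilities."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValidationError("compute_metrics needs matching vectors of length >= 2")
    if mode == "regression":
        return MetricReport(r2=r2_score(y_true, y_pred))

    yt = y_true.astype(int)
    yh = (y_pred >= threshold).astype(int)
    tp = int(np.sum((yt == 1) & (yh == 1)))
    fp = int(np.sum((yt == 0) & (yh == 1)))
    fn = int(np.sum((yt == 1) & (yh == 0)))
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )
    report = MetricReport(
        precision=precision,
        recall=recall,
        f_score=f_score,
        mcc=float(matthews_corrcoef(yt, yh)),
    )
    if len(np.unique(yt)) < 2:
        report.flags.append("single-class y_true: AUROC/AveP undefined")
    else:
        report.auroc = float(roc_auc_score(yt, y_pred))
        report.avep = float(average_precision_score(yt, y_pred))
    return report


def naive_baseline(train_y, test_y) -> MetricReport:
    """Predict the training-set mean for every test record."""
    train_y = np.asarray(train_y, float)
    test_y = np.asarray(test_y, float)
    if train_y.size == 0:
        raise ValidationError("empty training set")
    pred = np.full_like(test_y, train_y.mean())
    return MetricReport(r2=r2_score(test_y, pred))


# ---------------------------------------------------------------------------
# Quality-tier weighting


TierWeighting = Mapping[str, float]


def apply_tier_weights(
    dataset: InteractionDataset, weighting: TierWeighting
) -> InteractionDataset:
    """Assign per-record weights from a tier -> weight map.

    Weights flow into training losses and tree-model fitting downstream.
    """
    for tier, w in weighting.items():
        if w < 0:
            raise ValidationError(f"tier {tier!r}: negative weight {w}")
    tiers = {it.tier for it in dataset.interactions}
    unmapped = sorted(t for t in tiers if t is not None and t not in weighting)
    if unmapped:
        raise ValidationError(f"unmapped tiers: {unmapped}")
    new = [
        replace(it, weight=float(weighting[it.tier]) if it.tier is not None else it.weight)
        for it in dataset.interactions
    ]
    return InteractionDataset(
        odorants=dataset.odorants,
        receptors=dataset.receptors,
        interactions=new,
        mode=dataset.mode,
        warnings=list(dataset.warnings),
    )


# ---------------------------------------------------------------------------
# Statistical model comparison


@dataclass
class ComparisonReport:
    test: str
    global_p: float | None
    pairwise: dict[tuple[str, str], float]  # adjusted where the procedure adjusts
    significant: list[tuple[str, str]]
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "global_p": self.global_p,
            "pairwise": {f"{a} vs {b}": p for (a, b), p in self.pairwise.items()},
            "significant": [f"{a} vs {b}" for a, b in self.significant],
            "alpha": self.alpha,
            "flags": list(self.flags),
        }


def compare_models(
    score_table: Mapping[str, Sequence[float]],
    test: Literal["paired_t", "friedman_bh", "anova_tukey_bonferroni"] = "paired_t",
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare per-fold scores of several models.

    ``score_table`` maps model name -> fold scores; folds must be aligned
    across models (same split per position) for the paired procedures.
    """
    names = list(score_table)
    if len(names) < 2:
        raise ValidationError("need at least 2 models")
    scores = {m: np.asarray(score_table[m], float) for m in names}
    lengths = {len(v) for v in scores.values()}
    if len(lengths) != 1:
        raise ValidationError("models have unequal fold counts")
    pairs = list(combinations(names, 2))
    flags: list[str] = []
    pairwise: dict[tuple[str, str], float] = {}
    global_p: float | None = None

    if test == "paired_t":
        for a, b in pairs:
            diff = scores[a] - scores[b]
            if np.allclose(diff, diff[0]):
                if np.allclose(diff, 0):
                    pairwise[(a, b)] = 1.0
                    flags.append(f"{a} vs {b}: identical scores (degenerate)")
                else:
                    pairwise[(a, b)] = 0.0
                    flags.append(f"{a} vs {b}: constant nonzero difference (degenerate)")
            else:
                pairwise[(a, b)] = float(
                    scipy.stats.ttest_rel(scores[a], scores[b]).pvalue
                )
    elif test == "anova_tukey_bonferroni":
        groups = [scores[m] for m in names]
        global_p = float(scipy.stats.f_oneway(*groups).pvalue)
        res = scipy.stats.tukey_hsd(*groups)
        m = len(pairs)
        for a, b in pairs:
            p = float(res.pvalue[names.index(a), names.index(b)])
            pairwise[(a, b)] = min(1.0, p * m)  # Bonferroni on top of Tukey
    elif test == "friedman_bh":
        groups = [scores[m] for m in names]
        if len(names) >= 3:
            global_p = float(scipy.stats.friedmanchisquare(*groups).pvalue)
        raw = []
        for a, b in pairs:
            diff = scores[a] - scores[b]
            if np.allclose(diff, 0):
                raw.append(1.0)
                flags.append(f"{a} vs {b}: identical scores (degenerate)")
            else:
                raw.append(float(scipy.stats.wilcoxon(scores[a], scores[b]).pvalue))
        adj = multipletests(raw, method="fdr_bh")[1]
        for (a, b), p in zip(pairs, adj):
            pairwise[(a, b)] = float(p)
    else:
        raise ValidationError(f"unknown test {test!r}")

    significant = [pair for pair, p in pairwise.items() if p < alpha]
    return ComparisonReport(
        test=test, global_p=global_p, pairwise=pairwise,
        significant=significant, alpha=alpha, flags=flags,
    )
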