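"""Model/Results surface for the two-stage affinity predictor.

:class:`LoraxAffinityModel` is constructed from an :class:`InteractionDataset`
plus featurizer choices; ``fit()`` runs stage 1 (transformer training with
LoRA adapters) and stage 2 (XGBoost ensemble with validation-optimized
simplex weights) on one train/validation/test fold and returns a
:class:`LoraxAffinityResults` carrying the training history, ensemble
weights and diagnostics, test metrics, the naive baseline, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import InteractionDataset, RepresentationMatrix, ValidationError
from .ensemble import (
    EnsembleBundle,
    build_feature_sets,
    ensemble_predict,
    ensemble_report,
    fit_weighted_ensemble,
)
from .evaluation import Fold, MetricReport, compute_metrics, make_splits, naive_baseline
from .featurization import kmer_protein_featurizer, reference_count_featurizer
from .lorax_core import (
    EncoderConfig,
    FusionConfig,
    LoRAConfig,
    LoraxModel,
    TrainConfig,
    train_stage1,
)

__all__ = ["LoraxAffinityModel", "LoraxAffinityResults"]


def _interaction_rows(dataset, rep: RepresentationMatrix, key: str) -> np.ndarray:
    idx = {item: i for i, item in enumerate(rep.item_ids)}
    return rep.values[[idx[getattr(it, key)] for it in dataset.interactions]]


@dataclass
class LoraxAffinityResults:
    """Fit artifacts for one fold of the two-stage model."""

    model: "LoraxAffinityModel"
    fold: Fold
    history: list[dict]
    transformer_val_score: float
    bundle: EnsembleBundle
    test_metrics: MetricReport
    naive_metrics: MetricReport | None
    predictions: pd.DataFrame
    stage1_net: LoraxModel = field(repr=False, default=None)

    @property
    def ensemble_weights(self) -> np.ndarray:
        return self.bundle.weights.as_array()

    @property
    def orig_only_weight(self) -> float:
        return float(self.ensemble_weights[1])

    def report(self) -> dict:
        rep = ensemble_report(self.bundle)
        rep["test_metrics"] = self.test_metrics.to_dict()
        if self.naive_metrics is not None:
            rep["naive_metrics"] = self.naive_metrics.to_dict()
        return rep

    def summary(self) -> str:
        lines = ["Two-stage LORAX affinity fit", "=" * 34]
        lines.append(f"interactions: {len(self.model.dataset.interactions)} "
                     f"(train {len(self.fold.train_idx)}, val {len(self.fold.val_idx)}, "
                     f"test {len(self.fold.test_idx)})")
        lines.append(f"stage-1 epochs run: {len(self.history)}")
        lines.append(f"transformer validation score: {self.transformer_val_score:+.4f}")
        lines.append("ensemble weights (CLS, ORIG, CLS+ORIG): "
                     + ", ".join(f"{w:.2f}" for w in self.ensemble_weights))
        for k, v in self.bundle.validation_scores.items():
            lines.append(f"  validation score [{k}]: {v:+.4f}")
        lines.append(f"combined validation score: "
                     f"{self.bundle.combined_validation_score:+.4f}")
        for k, v in self.test_metrics.to_dict().items():
            if isinstance(v, float):
                lines.append(f"test {k}: {v:+.4f}")
        if self.naive_metrics is not None and self.naive_metrics.r2 is not None:
            lines.append(f"naive-baseline test R2: {self.naive_metrics.r2:+.4f}")
        return "\n".join(lines)


class LoraxAffinityModel:
    """Two-stage odorant-receptor affinity model over an interaction dataset.

    Parameters
    ----------
    dataset
        The interaction data (regression or classification mode).
    chem_featurizer, prot_featurizer
        Functions producing the *original* (non-adapted) representations the
        ORIG feature set and the ensemble use; default to the reference
        character-count and 1-mer composition featurizers.
    lora_chem, lora_prot
        Adapter configurations; ``lora_chem=None`` or ``enabled=False`` plus
        a head-and-fusion-only training scope gives the frozen-representation
        comparator.
    """

    def __init__(
        self,
        dataset: InteractionDataset,
        chem_featurizer=None,
        prot_featurizer=None,
        lora_chem: LoRAConfig | None = LoRAConfig(),
        lora_prot: LoRAConfig | None = None,
        fusion: FusionConfig | None = None,
        chem_encoder_cfg: EncoderConfig | None = None,
        prot_encoder_cfg: EncoderConfig | None = None,
        gbt_params: Mapping | None = None,
        seed: int = 0,
    ):
        self.dataset = dataset
        head = "regression_linear" if dataset.mode == "regression" else "classification_logit"
        self.fusion = fusion or FusionConfig(head=head)
        self.chem_encoder_cfg = chem_encoder_cfg or EncoderConfig()
        self.prot_encoder_cfg = prot_encoder_cfg or EncoderConfig()
        self.lora_chem = lora_chem
        self.lora_prot = lora_prot
        self.gbt_params = dict(gbt_params or {})
        self.seed = seed

        chem_fn = chem_featurizer or reference_count_featurizer()
        prot_fn = prot_featurizer or kmer_protein_featurizer(k=1)
        chem_out = chem_fn(dataset.odorants)
        if isinstance(chem_out, RepresentationMatrix):
            chem_rep = chem_out
        else:
            chem_rep = RepresentationMatrix(
                dataset.odorant_ids, np.asarray(chem_out, float), "chem_orig"
            )
        prot_out = prot_fn(dataset.receptors)
        if isinstance(prot_out, RepresentationMatrix):
            prot_rep = prot_out
        else:
            prot_rep = RepresentationMatrix(dataset.receptor_ids,
                                            np.asarray(prot_out, float), "prot_orig")
        self.chem_rep = chem_rep
        self.prot_rep = prot_rep
        self._chem_rows = _interaction_rows(dataset, chem_rep, "odorant_id")
        self._prot_rows = _interaction_rows(dataset, prot_rep, "receptor_id")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, mode: str, **kwargs) -> "LoraxAffinityModel":
        """Build from a canonical-column dataframe (see data_model loaders)."""
        import io

        from .data_model import load_interaction_table

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(load_interaction_table(buf, mode=mode), **kwargs)

    def build_network(self) -> LoraxModel:
        return LoraxModel(
            lora_chem=self.lora_chem,
            lora_prot=self.lora_prot,
            fusion=self.fusion,
            chem_encoder_cfg=self.chem_encoder_cfg,
            prot_encoder_cfg=self.prot_encoder_cfg,
            seed=self.seed,
        )

    def _targets(self) -> np.ndarray:
        if self.dataset.mode == "regression":
            return self.dataset.responses()
        return self.dataset.labels().astype(float)

    def fit(
        self,
        fold: Fold | None = None,
        train_cfg: TrainConfig | None = None,
    ) -> LoraxAffinityResults:
        """Run both training stages on one fold and evaluate on its test set."""
        if fold is None:
            split = make_splits(self.dataset, "random", k=5, seed=self.seed)
            fold = split.folds[0]
        loss = "mse" if self.dataset.mode == "regression" else "weighted_bce"
        cfg = train_cfg or TrainConfig(loss=loss, seed=self.seed)
        if cfg.loss != loss:
            cfg = TrainConfig(**{**cfg.__dict__, "loss": loss})

        net = self.build_network()
        net, history = train_stage1(net, self.dataset, fold, cfg)
        transformer_val = max((h["val_metric"] for h in history), default=-np.inf)

        tok = net.tokenize_dataset(self.dataset)
        y = self._targets()
        feats = {}
        for name, idx in (("train", fold.train_idx), ("val", fold.val_idx),
                          ("test", fold.test_idx)):
            _, cls = net.predict_batch(tok, idx)
            feats[name] = build_feature_sets(
                cls, self._chem_rows[idx], self._prot_rows[idx]
            )
        task = self.dataset.mode
        bundle = fit_weighted_ensemble(
            feats["train"], y[fold.train_idx],
            feats["val"], y[fold.val_idx],
            weights_train=self.dataset.weights()[fold.train_idx],
            task=task,
            gbt_params=self.gbt_params,
            seed=self.seed,
            transformer_val_score=transformer_val,
        )
        test_pred = ensemble_predict(bundle, feats["test"])
        test_metrics = compute_metrics(y[fold.test_idx], test_pred, task)
        naive = (
            naive_baseline(y[fold.train_idx], y[fold.test_idx])
            if task == "regression" else None
        )
        preds = pd.DataFrame(
            {
                "odorant_id": [self.dataset.interactions[i].odorant_id
                               for i in fold.test_idx],
                "receptor_id": [self.dataset.interactions[i].receptor_id
                                for i in fold.test_idx],
                "y_true": y[fold.test_idx],
                "y_pred": test_pred,
            }
        )
        return LoraxAffinityResults(
            model=self,
            fold=fold,
            history=history,
            transformer_val_score=float(transformer_val),
            bundle=bundle,
            test_metrics=test_metrics,
            naive_metrics=naive,
            predictions=preds,
            stage1_net=net,
        )
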