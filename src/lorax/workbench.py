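"""Experiment orchestration: benchmark sweeps, shape analyses, k-fold runs.

Functions here reproduce the *structure* of the study tables on any dataset
(real or simulated): a representation-by-model benchmark table, pairwise
representation distance matrices (optionally including the neural-response
representation and the fine-tuned chemical embedding), and a k-fold
comparison of the adapted model against the frozen comparator and the naive
baseline.  Every run is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .baselines import DEFAULT_LAMBDA_GRID, BenchmarkResult, run_mo, run_mp
from .data_model import (
    InteractionDataset,
    RepresentationMatrix,
    ValidationError,
    build_neural_representation,
)
from .ensemble import ensemble_report
from .evaluation import compare_models, make_splits, naive_baseline
from .featurization import FeaturizerRegistry, default_registry, kmer_protein_featurizer
from .lorax_core import EncoderConfig, FusionConfig, LoRAConfig, TrainConfig
from .model import LoraxAffinityModel
from .shape_metrics import DistanceMatrix, pairwise_distances
from .synthetic_data import gen_panel, gen_sparse_screen, planted_bilinear

__all__ = [
    "ExperimentConfig",
    "load_config",
    "simulate_preset",
    "run_representation_benchmark",
    "run_shape_analysis",
    "run_lorax_experiment",
]


@dataclass
class ExperimentConfig:
    """Config-file schema for orchestrated runs (YAML-serializable)."""

    seed: int = 0
    dataset: str | None = None  # path to CSV, or None to simulate
    preset: str | None = None  # hallem | carey | m2or-like
    featurizers: list[str] = field(default_factory=lambda: ["reference_counts", "random"])
    models: list[str] = field(default_factory=lambda: ["MO", "MP"])
    scenario: Literal["random", "unseen_odorant", "unseen_receptor"] = "random"
    k: int = 5
    out_dir: str | None = None
    train: dict = field(default_factory=dict)
    lora: dict = field(default_factory=dict)
    gbt: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def load_config(path) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
    return ExperimentConfig(**raw)


PRESETS: dict[str, dict] = {
    # full-factorial electrophysiology panels at the published dimensions
    "hallem": {"n_odorants": 110, "n_receptors": 24, "kind": "panel"},
    "carey": {"n_odorants": 110, "n_receptors": 50, "kind": "panel"},
    # sparse imbalanced screen shaped like the large mammalian compilation
    "m2or-like": {
        "n_odorants": 120, "n_receptors": 80, "kind": "screen",
        "density": 0.08, "positive_rate": 0.2,
        "tiers": {"ec50": 0.1, "primary": 0.6, "secondary": 0.3},
    },
}


def simulate_preset(preset: str, seed: int, noise_sd: float = 0.3):
    """Generate a dataset with the named study-shaped preset."""
    if preset not in PRESETS:
        raise ValidationError(f"unknown preset {preset!r}; known: {sorted(PRESETS)}")
    p = PRESETS[preset]
    planted = planted_bilinear(seed=seed, noise_sd=noise_sd)
    if p["kind"] == "panel":
        return gen_panel(p["n_odorants"], p["n_receptors"], planted, seed)
    return gen_sparse_screen(
        p["n_odorants"], p["n_receptors"], p["density"], p["positive_rate"],
        p["tiers"], seed, planted=planted,
    )


def run_representation_benchmark(
    dataset: InteractionDataset,
    featurizers: Sequence[str] = ("reference_counts", "random"),
    models: Sequence[str] = ("MO", "MP"),
    k: int = 5,
    seed: int = 0,
    registry: FeaturizerRegistry | None = None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    out_dir: str | None = None,
) -> pd.DataFrame:
    """One row per (featurizer, model) with mean +/- SD R^2 over k folds.

    Per-cell failures are recorded in the ``error`` column and the sweep
    continues.
    """
    reg = registry or default_registry()
    prot_rep = kmer_protein_featurizer(k=1)(dataset.receptors)
    rows = []
    for fname in featurizers:
        chem_rep = reg.featurize(fname, dataset.odorants)
        for model in models:
            row = {"featurizer": fname, "model": model}
            try:
                if model == "MO":
                    res = run_mo(dataset, chem_rep, folds=k, lambda_grid=lambda_grid,
                                 seed=seed)
                elif model == "MP":
                    res = run_mp(dataset, chem_rep, prot_rep, folds=k,
                                 lambda_grid=lambda_grid, seed=seed)
                else:
                    raise ValidationError(f"unknown benchmark model {model!r}")
                row.update(mean_r2=res.mean_r2, sd_r2=res.sd_r2,
                           per_fold=res.per_fold_r2, error=None)
            except ValidationError as exc:
                row.update(mean_r2=np.nan, sd_r2=np.nan, per_fold=None,
                           error=str(exc))
            rows.append(row)
    table = pd.DataFrame(rows)
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "benchmark.csv", index=False)
        (out / "benchmark.json").write_text(table.to_json(orient="records", indent=2))
    return table


def run_shape_analysis(
    dataset: InteractionDataset,
    featurizers: Sequence[str] = ("reference_counts", "random"),
    metrics: Sequence[str] = ("procrustes", "cca"),
    include_neural: bool = False,
    extra_reps: Sequence[RepresentationMatrix] = (),
    registry: FeaturizerRegistry | None = None,
    out_dir: str | None = None,
) -> dict[str, DistanceMatrix]:
    """Pairwise distance matrices over the requested odorant representations.

    ``include_neural`` adds the neural-response representation (requires a
    full-factorial regression panel); ``extra_reps`` lets callers pass e.g.
    the fine-tuned chemical embedding extracted from a trained run.
    """
    if len(featurizers) + len(extra_reps) + include_neural < 2:
        raise ValidationError("need at least 2 representations")
    reg = registry or default_registry()
    reps = [reg.featurize(f, dataset.odorants) for f in featurizers]
    reps.extend(extra_reps)
    if include_neural:
        reps.append(build_neural_representation(dataset, missing_policy="error"))
    out = {m: pairwise_distances(reps, metric=m) for m in metrics}
    if out_dir:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        for m, dm in out.items():
            dm.to_csv(d / f"distances_{m}.csv")
    return out


def run_lorax_experiment(
    dataset: InteractionDataset,
    scenario: Literal["random", "unseen_odorant", "unseen_receptor"] = "random",
    k: int = 5,
    seed: int = 0,
    train_cfg: TrainConfig | None = None,
    lora_chem: LoRAConfig | None = LoRAConfig(),
    fusion: FusionConfig | None = None,
    chem_encoder_cfg: EncoderConfig | None = None,
    prot_encoder_cfg: EncoderConfig | None = None,
    gbt_params: Mapping | None = None,
    include_frozen: bool = True,
    out_dir: str | None = None,
) -> dict:
    """k-fold comparison: adapted model vs frozen comparator vs naive baseline.

    Returns per-fold metric scores per method, summary statistics in the
    layout of a per-split score table, ensemble reports, and (for >= 2
    methods) the paired comparison statistics.
    """
    split = make_splits(dataset, scenario, k=k, seed=seed)
    task = dataset.mode
    metric_key = "r2" if task == "regression" else "mcc"
    scores: dict[str, list[float]] = {"LORAX": []}
    if include_frozen:
        scores["LORAX_frozen"] = []
    if task == "regression":
        scores["naive"] = []
    reports = []
    y = dataset.responses() if task == "regression" else dataset.labels().astype(float)

    for fold_i, fold in enumerate(split):
        base_kwargs = dict(
            fusion=fusion, chem_encoder_cfg=chem_encoder_cfg,
            prot_encoder_cfg=prot_encoder_cfg, gbt_params=gbt_params,
            seed=seed + fold_i,
        )
        loss = "mse" if task == "regression" else "weighted_bce"
        cfg = train_cfg or TrainConfig(loss=loss, seed=seed + fold_i)
        fold_report = {"fold": fold_i}

        model = LoraxAffinityModel(dataset, lora_chem=lora_chem, **base_kwargs)
        res = model.fit(fold, cfg)
        scores["LORAX"].append(getattr(res.test_metrics, metric_key))
        fold_report["LORAX"] = res.report()

        if include_frozen:
            frozen_cfg = TrainConfig(**{**cfg.__dict__,
                                        "trainable_scope": "head_and_fusion_only"})
            frozen_model = LoraxAffinityModel(dataset, lora_chem=None, **base_kwargs)
            fres = frozen_model.fit(fold, frozen_cfg)
            scores["LORAX_frozen"].append(getattr(fres.test_metrics, metric_key))
            fold_report["LORAX_frozen"] = fres.report()

        if task == "regression":
            nres = naive_baseline(y[fold.train_idx], y[fold.test_idx])
            scores["naive"].append(nres.r2)
        reports.append(fold_report)

    summary = pd.DataFrame(
        {
            name: vals + [float(np.mean(vals)),
                          float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0]
            for name, vals in scores.items()
        },
        index=[f"split_{i + 1}" for i in range(k)] + ["avg", "std"],
    ).T
    comparison = (
        compare_models(scores, test="friedman_bh").to_dict()
        if len(scores) >= 2 else None
    )
    result = {
        "scenario": scenario,
        "metric": metric_key,
        "scores": {m: [float(v) for v in vals] for m, vals in scores.items()},
        "summary": summary,
        "fold_reports": reports,
        "comparison": comparison,
    }
    if out_dir:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        summary.to_csv(d / "summary.csv")
        serializable = {kk: vv for kk, vv in result.items() if kk != "summary"}
        (d / "experiment.json").write_text(json.dumps(serializable, indent=2))
    return result
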