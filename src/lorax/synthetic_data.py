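"""Synthetic molecules, receptors, and planted interaction structure.

These generators emulate the *shapes* of the datasets the pipeline targets —
full-factorial electrophysiology panels (every odorant measured against every
receptor, continuous responses) and sparse, imbalanced binary screens with
quality tiers — without any chemically realistic structure-activity model.
The planted ground truth (interaction matrix, feature maps) is returned
alongside each dataset so recovery can be tested end to end.

Molecules come from a small template grammar (alkanes, alcohols, aldehydes,
ketones, esters, ethers, amines, nitriles, substituted benzenes); every
generated SMILES parses under the reference character-count featurizer, which
is also the feature map the planted signal is built from — so the signal is
learnable from SMILES tokens by any competent encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np

from .data_model import (
    AMINO_ACIDS,
    Interaction,
    InteractionDataset,
    OdorantRecord,
    ReceptorRecord,
    ValidationError,
)
from .featurization import kmer_protein_featurizer, reference_count_featurizer

__all__ = [
    "PlantedModel",
    "planted_bilinear",
    "planted_linear",
    "planted_receptor_only",
    "gen_molecules",
    "gen_receptors",
    "gen_panel",
    "gen_sparse_screen",
    "smiles_grammar_capacity",
]


def _enumerate_grammar() -> list[str]:
    """Enumerate the template grammar in a fixed, deterministic order."""
    out: list[str] = []
    chain = lambda n: "C" * n
    for n in range(1, 13):
        out.append(chain(n))  # alkanes
    for n in range(1, 13):
        out.append(chain(n) + "O")  # primary alcohols
    for n in range(1, 11):
        out.append(chain(n) + "C=O")  # aldehydes
    for n in range(1, 11):
        out.append("CC(=O)" + chain(n))  # methyl ketones
    for a in range(1, 7):
        for b in range(1, 7):
            out.append(chain(a) + "C(=O)O" + chain(b))  # esters
    for a in range(1, 7):
        for b in range(a, 7):
            out.append(chain(a) + "O" + chain(b))  # ethers
    for n in range(1, 11):
        out.append(chain(n) + "N")  # primary amines
    for n in range(1, 9):
        out.append(chain(n) + "C#N")  # nitriles
    out.append("c1ccccc1")  # benzene + substitutions
    for sub in ["C", "CC", "CCC", "O", "CO", "CCO", "N", "C=O", "C(=O)O", "CC=O"]:
        out.append(sub + "c1ccccc1")
    for sub in ["C", "O", "N"]:
        for sub2 in ["C", "O", "N"]:
            out.append(sub + "c1ccc(" + sub2 + ")cc1")  # para-disubstituted
    # deduplicate preserving order (ethers with a==b appear once by design)
    seen: set[str] = set()
    uniq = [s for s in out if not (s in seen or seen.add(s))]
    return uniq


_GRAMMAR = _enumerate_grammar()


def smiles_grammar_capacity() -> int:
    return len(_GRAMMAR)


def gen_molecules(n: int, seed: int) -> list[OdorantRecord]:
    """Draw ``n`` distinct template-grammar SMILES, deterministic in ``seed``."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if n > len(_GRAMMAR):
        raise ValidationError(
            f"requested {n} molecules but the grammar enumerates only "
            f"{len(_GRAMMAR)} distinct SMILES"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(_GRAMMAR))[:n]
    return [OdorantRecord(f"od{i:04d}", _GRAMMAR[j]) for i, j in enumerate(idx)]


def gen_receptors(m: int, length: int, seed: int) -> list[ReceptorRecord]:
    """Uniform-random amino-acid sequences, deterministic in ``seed``."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if length < 5:
        raise ValidationError("length must be >= 5")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(m):
        seq = "".join(letters[rng.integers(0, len(letters), size=length)])
        records.append(ReceptorRecord(f"or{i:04d}", seq))
    return records


FeatureFn = Callable[[Sequence], np.ndarray]


def _default_chem_features(odorants: Sequence[OdorantRecord]) -> np.ndarray:
    return reference_count_featurizer()(odorants)


def _default_prot_features(receptors: Sequence[ReceptorRecord]) -> np.ndarray:
    return kmer_protein_featurizer(k=1)(receptors).values


@dataclass
class PlantedModel:
    """Ground-truth generative structure for synthetic panels.

    Responses are built from standardized odorant features ``u`` and receptor
    features ``v``: bilinear structure gives ``u' M v``; linear structure
    gives ``a.u + b.v`` (a form a concatenation-linear model can fit exactly).
    ``noise_sd`` is relative to the unit-variance planted signal.
    """

    structure: Literal["bilinear", "linear"] = "bilinear"
    M: np.ndarray | None = None
    a: np.ndarray | None = None
    b: np.ndarray | None = None
    chem_feature_fn: FeatureFn = field(default=_default_chem_features)
    prot_feature_fn: FeatureFn = field(default=_default_prot_features)
    noise_sd: float = 0.0
    link: Literal["identity", "threshold_logistic"] = "identity"
    positive_rate_target: float = 0.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.link == "threshold_logistic" and not (0 < self.positive_rate_target < 1):
            raise ValidationError("positive_rate_target must be in (0, 1)")


def planted_bilinear(
    d_u: int = 19, d_v: int = 20, seed: int = 0, noise_sd: float = 0.0, rank: int | None = 3,
) -> PlantedModel:
    """Random bilinear interaction matrix, low-rank by default.

    Rank 3 emulates low-dimensional receptor tuning: responses live on a few
    shared chemical axes, as in measured receptor panels.  ``rank=None``
    gives a full-rank M.
    """
    rng = np.random.default_rng(seed)
    if rank is None:
        M = rng.standard_normal((d_u, d_v))
    else:
        M = rng.standard_normal((d_u, rank)) @ rng.standard_normal((rank, d_v))
    return PlantedModel(structure="bilinear", M=M, noise_sd=noise_sd)


def planted_linear(
    d_u: int = 19, d_v: int = 20, seed: int = 0, noise_sd: float = 0.0
) -> PlantedModel:
    rng = np.random.default_rng(seed)
    return PlantedModel(
        structure="linear",
        a=rng.standard_normal(d_u),
        b=rng.standard_normal(d_v),
        noise_sd=noise_sd,
    )


def planted_chem_only(d_u: int = 19, seed: int = 0, noise_sd: float = 0.0,
                      d_v: int = 20) -> PlantedModel:
    """Responses depend only on the odorant: identical across receptors."""
    rng = np.random.default_rng(seed)
    return PlantedModel(
        structure="linear",
        a=rng.standard_normal(d_u),
        b=np.zeros(d_v),
        noise_sd=noise_sd,
    )


def planted_receptor_only(d_v: int = 20, seed: int = 0, noise_sd: float = 0.0,
                          d_u: int = 19) -> PlantedModel:
    """Responses depend only on the receptor (chemistry carries no signal)."""
    rng = np.random.default_rng(seed)
    return PlantedModel(
        structure="linear",
        a=np.zeros(d_u),
        b=rng.standard_normal(d_v),
        noise_sd=noise_sd,
    )


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def gen_panel(
    n_odorants: int,
    n_receptors: int,
    planted: PlantedModel,
    seed: int,
) -> tuple[InteractionDataset, dict]:
    """Full-factorial panel with planted structure.

    Every odorant is paired with every receptor (``n_odorants * n_receptors``
    interactions).  The planted parameters are rescaled so the noiseless
    signal has population SD 1 over the panel; the rescaled parameters are
    returned in the truth dict, so noiseless responses reproduce them exactly.
    """
    rng = np.random.default_rng(seed)
    odorants = gen_molecules(n_odorants, seed)
    receptors = gen_receptors(n_receptors, length=30, seed=seed + 1)

    U = _standardize(np.asarray(planted.chem_feature_fn(odorants), dtype=float))
    V = _standardize(np.asarray(planted.prot_feature_fn(receptors), dtype=float))

    if planted.structure == "bilinear":
        M = np.asarray(planted.M, dtype=float)
        if M.shape != (U.shape[1], V.shape[1]):
            raise ValidationError(
                f"M shape {M.shape} does not match feature dims "
                f"({U.shape[1]}, {V.shape[1]})"
            )
        signal = U @ M @ V.T
    else:
        a = np.asarray(planted.a, dtype=float)
        b = np.asarray(planted.b, dtype=float)
        signal = (U @ a)[:, None] + (V @ b)[None, :]

    scale = signal.std(ddof=0)
    if scale > 0:
        signal = signal / scale
    else:
        scale = 1.0
    noise = rng.normal(0.0, planted.noise_sd, size=signal.shape) if planted.noise_sd > 0 else 0.0
    raw = signal + noise

    truth = {
        "U": U,
        "V": V,
        "signal": signal,
        "scale": scale,
        "odorant_ids": [o.odorant_id for o in odorants],
        "receptor_ids": [r.receptor_id for r in receptors],
    }
    if planted.structure == "bilinear":
        truth["M"] = planted.M / scale
    else:
        truth["a"] = planted.a / scale
        truth["b"] = planted.b / scale

    interactions = []
    if planted.link == "identity":
        for i, od in enumerate(odorants):
            for j, rec in enumerate(receptors):
                interactions.append(
                    Interaction(od.odorant_id, rec.receptor_id, response=float(raw[i, j]))
                )
        mode: Literal["regression", "classification"] = "regression"
    else:
        thresh = np.quantile(raw, 1.0 - planted.positive_rate_target)
        truth["threshold"] = float(thresh)
        for i, od in enumerate(odorants):
            for j, rec in enumerate(receptors):
                interactions.append(
                    Interaction(
                        od.odorant_id, rec.receptor_id, label=int(raw[i, j] > thresh)
                    )
                )
        mode = "classification"

    dataset = InteractionDataset(
        odorants=odorants, receptors=receptors, interactions=interactions, mode=mode
    )
    return dataset, truth


def gen_sparse_screen(
    n_odorants: int,
    n_receptors: int,
    density: float,
    positive_rate: float,
    tiers: Mapping[str, float],
    seed: int,
    planted: PlantedModel | None = None,
) -> tuple[InteractionDataset, dict]:
    """Sparse imbalanced binary screen with quality tiers.

    A random subset of the full grid is observed (each pair kept with
    probability ``density``); labels come from thresholding a planted score
    at the empirical quantile matching ``positive_rate`` (exact in
    expectation, tie-limited in practice); tiers are drawn from the supplied
    tier -> probability distribution.
    """
    if not (0 < density < 1) or not (0 < positive_rate < 1):
        raise ValidationError("density and positive_rate must be in (0, 1)")
    if planted is None:
        planted = planted_bilinear(seed=seed)
    rng = np.random.default_rng(seed)
    odorants = gen_molecules(n_odorants, seed)
    receptors = gen_receptors(n_receptors, length=30, seed=seed + 1)

    U = _standardize(np.asarray(planted.chem_feature_fn(odorants), dtype=float))
    V = _standardize(np.asarray(planted.prot_feature_fn(receptors), dtype=float))
    if planted.structure == "bilinear":
        score = U @ planted.M @ V.T
    else:
        score = (U @ planted.a)[:, None] + (V @ planted.b)[None, :]
    sd = score.std(ddof=0)
    if sd > 0:
        score = score / sd
    if planted.noise_sd > 0:
        score = score + rng.normal(0.0, planted.noise_sd, size=score.shape)

    keep = rng.random((n_odorants, n_receptors)) < density
    obs_scores = score[keep]
    thresh = np.quantile(obs_scores, 1.0 - positive_rate)

    tier_names = list(tiers)
    tier_p = np.array([tiers[t] for t in tier_names], dtype=float)
    tier_p = tier_p / tier_p.sum()

    interactions = []
    ii, jj = np.nonzero(keep)
    tier_draws = rng.choice(len(tier_names), size=len(ii), p=tier_p)
    for (i, j, t) in zip(ii, jj, tier_draws):
        interactions.append(
            Interaction(
                odorants[i].odorant_id,
                receptors[j].receptor_id,
                label=int(score[i, j] > thresh),
                tier=tier_names[t],
            )
        )
    dataset = InteractionDataset(
        odorants=odorants, receptors=receptors, interactions=interactions,
        mode="classification",
    )
    truth = {"U": U, "V": V, "threshold": float(thresh), "score": score}
    return dataset, truth
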