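"""Molecule and protein featurizer registry.

Featurizers are pure functions from records to a :class:`RepresentationMatrix`
with rows aligned to input order.  The registry houses the benchmark's
representation enumeration abstractly: reference featurizers (character
counts, k-mer composition), the random lower-bound baseline, and optional
chemistry backends (Morgan fingerprints via RDKit when available).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Literal, Sequence

import numpy as np

from .data_model import OdorantRecord, ReceptorRecord, RepresentationMatrix, ValidationError

__all__ = [
    "FeaturizerSpec",
    "FeaturizerRegistry",
    "default_registry",
    "register_featurizer",
    "featurize_molecules",
    "random_featurizer",
    "reference_count_featurizer",
    "kmer_protein_featurizer",
    "REFERENCE_ALPHABET",
]

# Characters counted by the reference SMILES featurizer.  Covers the synthetic
# grammar plus common organic-subset SMILES tokens.
REFERENCE_ALPHABET = "CONScons=#()123[]+-"


@dataclass(frozen=True)
class FeaturizerSpec:
    name: str
    kind: Literal["physchem", "transformer", "gnn", "random", "reference"]
    dim: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValidationError(f"featurizer {self.name!r}: dim must be >= 1")


FeaturizerFn = Callable[[Sequence[OdorantRecord]], np.ndarray]


class FeaturizerRegistry:
    """Insertion-ordered name -> (spec, fn) registry."""

    def __init__(self) -> None:
        self._entries: dict[str, tuple[FeaturizerSpec, FeaturizerFn]] = {}

    def register(self, spec: FeaturizerSpec, fn: FeaturizerFn) -> FeaturizerSpec:
        if spec.name in self._entries:
            raise ValidationError(f"featurizer {spec.name!r} already registered")
        self._entries[spec.name] = (spec, fn)
        return spec

    def get(self, name: str) -> tuple[FeaturizerSpec, FeaturizerFn]:
        if name not in self._entries:
            raise KeyError(
                f"featurizer {name!r} not registered; known: {self.names()}"
            )
        return self._entries[name]

    def spec(self, name: str) -> FeaturizerSpec:
        return self.get(name)[0]

    def names(self) -> list[str]:
        return list(self._entries)

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def featurize(
        self, name: str, odorants: Sequence[OdorantRecord]
    ) -> RepresentationMatrix:
        spec, fn = self.get(name)
        values = np.asarray(fn(odorants), dtype=float)
        if values.shape != (len(odorants), spec.dim):
            raise ValidationError(
                f"featurizer {name!r} returned shape {values.shape}, "
                f"expected {(len(odorants), spec.dim)}"
            )
        return RepresentationMatrix(
            [o.odorant_id for o in odorants], values, name=name
        )


# ---------------------------------------------------------------------------
# Reference featurizers


def reference_count_featurizer(alphabet: str = REFERENCE_ALPHABET) -> FeaturizerFn:
    """Character-count vector over a fixed alphabet.

    Deliberately simple: the planted synthetic signal is built from these
    counts so any competent SMILES encoder can recover it from tokens.
    """

    def fn(odorants: Sequence[OdorantRecord]) -> np.ndarray:
        out = np.zeros((len(odorants), len(alphabet)))
        allowed = set(alphabet)
        for i, od in enumerate(odorants):
            unknown = set(od.smiles) - allowed
            if unknown:
                raise ValidationError(
                    f"SMILES {od.smiles!r} (odorant {od.odorant_id!r}) contains "
                    f"characters outside the reference alphabet: {sorted(unknown)}"
                )
            for ch in od.smiles:
                out[i, alphabet.index(ch)] += 1
        return out

    return fn


def _molecule_rng(seed: int, smiles: str) -> np.random.Generator:
    # Stream keyed to the molecule, not the row: identical SMILES get
    # identical vectors across calls, folds and datasets.
    digest = hashlib.sha256(f"{seed}|{smiles}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def random_featurizer(dim: int, seed: int = 0) -> FeaturizerFn:
    """Random lower-bound representation: i.i.d. standard normal per molecule."""
    if dim < 1:
        raise ValidationError("random featurizer: dim must be >= 1")

    def fn(odorants: Sequence[OdorantRecord]) -> np.ndarray:
        return np.stack(
            [_molecule_rng(seed, od.smiles).standard_normal(dim) for od in odorants]
        )

    return fn


def kmer_protein_featurizer(
    k: int = 1, alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
) -> Callable[[Sequence[ReceptorRecord]], RepresentationMatrix]:
    """Normalized k-mer composition of receptor sequences.

    A fixed, deterministic protein representation used where a frozen
    protein-embedding model would sit in a full-scale run.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    kmers = ["".join(p) for p in product(alphabet, repeat=k)]
    index = {km: i for i, km in enumerate(kmers)}

    def fn(receptors: Sequence[ReceptorRecord]) -> RepresentationMatrix:
        out = np.zeros((len(receptors), len(kmers)))
        for i, rec in enumerate(receptors):
            seq = rec.sequence
            if len(seq) < k:
                raise ValidationError(
                    f"receptor {rec.receptor_id!r}: sequence length {len(seq)} < k={k}"
                )
            n = len(seq) - k + 1
            for j in range(n):
                km = seq[j : j + k]
                if km in index:  # skip k-mers containing X
                    out[i, index[km]] += 1
            total = out[i].sum()
            if total > 0:
                out[i] /= total
        return RepresentationMatrix(
            [r.receptor_id for r in receptors], out, name=f"kmer{k}"
        )

    return fn


def _morgan_featurizer(dim: int = 256, radius: int = 2) -> FeaturizerFn:
    """ECFP-style Morgan fingerprint backend (requires rdkit)."""

    def fn(odorants: Sequence[OdorantRecord]) -> np.ndarray:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=dim)
        rows = []
        for od in odorants:
            mol = Chem.MolFromSmiles(od.smiles)
            if mol is None:
                raise ValidationError(
                    f"unparseable SMILES {od.smiles!r} (odorant {od.odorant_id!r})"
                )
            rows.append(np.array(gen.GetFingerprint(mol), dtype=float))
        return np.stack(rows)

    return fn


def default_registry(random_dim: int = 64, random_seed: int = 0) -> FeaturizerRegistry:
    """Registry pre-populated with the self-contained featurizers.

    The ECFP backend is added only when rdkit imports cleanly.
    """
    reg = FeaturizerRegistry()
    reg.register(
        FeaturizerSpec("reference_counts", "reference", len(REFERENCE_ALPHABET)),
        reference_count_featurizer(),
    )
    reg.register(
        FeaturizerSpec("random", "random", random_dim, {"seed": random_seed}),
        random_featurizer(random_dim, random_seed),
    )
    try:
        import rdkit  # noqa: F401

        reg.register(
            FeaturizerSpec("ecfp", "physchem", 256, {"radius": 2}),
            _morgan_featurizer(256, 2),
        )
    except ImportError:  # pragma: no cover
        pass
    return reg


_GLOBAL_REGISTRY: FeaturizerRegistry | None = None


def _global_registry() -> FeaturizerRegistry:
    global _GLOBAL_REGISTRY
    if _GLOBAL_REGISTRY is None:
        _GLOBAL_REGISTRY = default_registry()
    return _GLOBAL_REGISTRY


def register_featurizer(spec: FeaturizerSpec, fn: FeaturizerFn) -> FeaturizerSpec:
    """Register into the process-wide default registry."""
    return _global_registry().register(spec, fn)


def featurize_molecules(
    name: str,
    odorants: Sequence[OdorantRecord],
    registry: FeaturizerRegistry | None = None,
) -> RepresentationMatrix:
    """Featurize molecules with a registered featurizer, rows in input order."""
    reg = registry if registry is not None else _global_registry()
    return reg.featurize(name, odorants)
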