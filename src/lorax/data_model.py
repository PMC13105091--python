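"""Dataset schemas, I/O, normalization, and the neural-response representation.

The universal experiment currency is the :class:`InteractionDataset`: a set of
odorants (SMILES strings), receptors (amino-acid sequences), and measured
interactions between them.  Interactions carry either a continuous response
(electrophysiology-panel style, ``mode="regression"``) or a binary label
(screening style, ``mode="classification"``), plus an optional per-record
weight and quality tier.

All joins key on string IDs, never on row position.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "OdorantRecord",
    "ReceptorRecord",
    "Interaction",
    "InteractionDataset",
    "NormalizationParams",
    "RepresentationMatrix",
    "SchemaError",
    "ValidationError",
    "load_interaction_table",
    "write_interaction_table",
    "load_receptor_fasta",
    "zscore_global",
    "build_neural_representation",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

Mode = Literal["regression", "classification"]


class SchemaError(ValueError):
    """A required column could not be resolved from the input table."""


class ValidationError(ValueError):
    """The input data violates a dataset invariant."""


@dataclass(frozen=True)
class OdorantRecord:
    odorant_id: str
    smiles: str

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValidationError(f"odorant {self.odorant_id!r}: empty SMILES")


@dataclass(frozen=True)
class ReceptorRecord:
    receptor_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValidationError(f"receptor {self.receptor_id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValidationError(
                f"receptor {self.receptor_id!r}: non-amino-acid letters {sorted(bad)}"
            )


@dataclass(frozen=True)
class Interaction:
    odorant_id: str
    receptor_id: str
    response: float | None = None
    label: int | None = None
    weight: float = 1.0
    tier: str | None = None

    def __post_init__(self) -> None:
        if (self.response is None) == (self.label is None):
            raise ValidationError(
                f"({self.odorant_id}, {self.receptor_id}): exactly one of "
                "response/label must be set"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(
                f"({self.odorant_id}, {self.receptor_id}): label must be 0 or 1, "
                f"got {self.label!r}"
            )
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValidationError(
                f"({self.odorant_id}, {self.receptor_id}): weight must be finite "
                f"and >= 0, got {self.weight!r}"
            )


@dataclass(frozen=True)
class NormalizationParams:
    """Global z-score parameters (pooled over all interactions)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")


@dataclass
class InteractionDataset:
    odorants: list[OdorantRecord]
    receptors: list[ReceptorRecord]
    interactions: list[Interaction]
    mode: Mode
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        oids = [o.odorant_id for o in self.odorants]
        rids = [r.receptor_id for r in self.receptors]
        if len(set(oids)) != len(oids):
            raise ValidationError("duplicate odorant IDs")
        if len(set(rids)) != len(rids):
            raise ValidationError("duplicate receptor IDs")
        oset, rset = set(oids), set(rids)
        pairs: set[tuple[str, str]] = set()
        for it in self.interactions:
            if it.odorant_id not in oset:
                raise ValidationError(f"interaction references unknown odorant {it.odorant_id!r}")
            if it.receptor_id not in rset:
                raise ValidationError(f"interaction references unknown receptor {it.receptor_id!r}")
            key = (it.odorant_id, it.receptor_id)
            if key in pairs:
                raise ValidationError(f"duplicate interaction pair {key}")
            pairs.add(key)
            if self.mode == "regression" and it.response is None:
                raise ValidationError(f"{key}: regression dataset requires a response")
            if self.mode == "classification" and it.label is None:
                raise ValidationError(f"{key}: classification dataset requires a label")

    # -- convenience accessors -------------------------------------------------

    @property
    def odorant_ids(self) -> list[str]:
        return [o.odorant_id for o in self.odorants]

    @property
    def receptor_ids(self) -> list[str]:
        return [r.receptor_id for r in self.receptors]

    def odorant_by_id(self, oid: str) -> OdorantRecord:
        return {o.odorant_id: o for o in self.odorants}[oid]

    def receptor_by_id(self, rid: str) -> ReceptorRecord:
        return {r.receptor_id: r for r in self.receptors}[rid]

    def responses(self) -> np.ndarray:
        if self.mode != "regression":
            raise ValidationError("responses() requires a regression dataset")
        return np.array([it.response for it in self.interactions], dtype=float)

    def labels(self) -> np.ndarray:
        if self.mode != "classification":
            raise ValidationError("labels() requires a classification dataset")
        return np.array([it.label for it in self.interactions], dtype=int)

    def weights(self) -> np.ndarray:
        return np.array([it.weight for it in self.interactions], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        smiles = {o.odorant_id: o.smiles for o in self.odorants}
        seqs = {r.receptor_id: r.sequence for r in self.receptors}
        rows = []
        for it in self.interactions:
            rows.append(
                {
                    "odorant_id": it.odorant_id,
                    "smiles": smiles[it.odorant_id],
                    "receptor_id": it.receptor_id,
                    "sequence": seqs[it.receptor_id],
                    ("response" if self.mode == "regression" else "label"): (
                        it.response if self.mode == "regression" else it.label
                    ),
                    "weight": it.weight,
                    "tier": it.tier if it.tier is not None else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RepresentationMatrix:
    """Items-by-features numeric matrix with aligned item IDs."""

    item_ids: list[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(f"{self.name}: values must be 2-D")
        if self.values.shape[0] != len(self.item_ids):
            raise ValidationError(
                f"{self.name}: {self.values.shape[0]} rows but {len(self.item_ids)} item IDs"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.name}: non-finite entries")

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def reorder(self, item_ids: Iterable[str]) -> "RepresentationMatrix":
        idx = {v: i for i, v in enumerate(self.item_ids)}
        order = [idx[i] for i in item_ids]
        return RepresentationMatrix(list(item_ids), self.values[order], self.name)

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(self.values, index=pd.Index(self.item_ids, name="item_id"))
        df.to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf, name: str = "") -> "RepresentationMatrix":
        df = pd.read_csv(path_or_buf, index_col="item_id")
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), name)

    def save_npz(self, path) -> None:
        """Compact binary cache (numpy .npz)."""
        np.savez_compressed(
            path, item_ids=np.array(self.item_ids, dtype=object), values=self.values, name=self.name
        )

    @classmethod
    def load_npz(cls, path) -> "RepresentationMatrix":
        with np.load(path, allow_pickle=True) as z:
            return cls(list(z["item_ids"]), z["values"], str(z["name"]))


DEFAULT_SCHEMA: dict[str, str] = {
    "odorant_id": "odorant_id",
    "smiles": "smiles",
    "receptor_id": "receptor_id",
    "sequence": "sequence",
    "response": "response",
    "label": "label",
    "weight": "weight",
    "tier": "tier",
}


def load_interaction_table(
    stream: IO[str] | str,
    mode: Mode,
    schema: Mapping[str, str] | None = None,
    sep: str = ",",
    receptors: list[ReceptorRecord] | None = None,
) -> InteractionDataset:
    """Load a delimited interaction table into a validated dataset.

    ``schema`` maps canonical column roles (keys of :data:`DEFAULT_SCHEMA`) to
    the actual column names in the file.  Receptor sequences may come from a
    ``sequence`` column or from a separate FASTA-derived ``receptors`` list
    keyed by ``receptor_id``.

    Identical repeated (odorant, receptor) rows are deduplicated by averaging
    responses (regression) or majority label (classification); a warning is
    recorded per collapsed pair.  A duplicate pair with a tied label vote is a
    validation error.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(stream, sep=sep, dtype=str, keep_default_na=False)

    value_role = "response" if mode == "regression" else "label"
    required = ["odorant_id", "smiles", "receptor_id", value_role]
    for role in required:
        if cols[role] not in df.columns:
            raise SchemaError(
                f"required column {cols[role]!r} (role {role!r}) not found; "
                f"available: {list(df.columns)}"
            )
    have_seq = cols["sequence"] in df.columns
    if not have_seq and receptors is None:
        raise SchemaError(
            f"no {cols['sequence']!r} column and no receptor list supplied"
        )

    odorants: dict[str, OdorantRecord] = {}
    rec_map: dict[str, ReceptorRecord] = (
        {r.receptor_id: r for r in receptors} if receptors else {}
    )
    groups: dict[tuple[str, str], list[dict]] = {}
    for _, row in df.iterrows():
        oid = row[cols["odorant_id"]]
        rid = row[cols["receptor_id"]]
        smiles = row[cols["smiles"]]
        if oid in odorants and odorants[oid].smiles != smiles:
            raise ValidationError(f"odorant {oid!r} has conflicting SMILES")
        odorants.setdefault(oid, OdorantRecord(oid, smiles))
        if have_seq:
            seq = row[cols["sequence"]].upper()
            if rid in rec_map and rec_map[rid].sequence != seq:
                raise ValidationError(f"receptor {rid!r} has conflicting sequences")
            rec_map.setdefault(rid, ReceptorRecord(rid, seq))
        elif rid not in rec_map:
            raise ValidationError(f"receptor {rid!r} not in supplied receptor list")
        rec = {"weight": 1.0, "tier": None}
        if cols["weight"] in df.columns and row[cols["weight"]] != "":
            rec["weight"] = float(row[cols["weight"]])
        if cols["tier"] in df.columns and row[cols["tier"]] != "":
            rec["tier"] = row[cols["tier"]]
        if mode == "regression":
            rec["response"] = float(row[cols["response"]])
        else:
            raw = row[cols["label"]]
            if raw not in ("0", "1"):
                raise ValidationError(
                    f"({oid}, {rid}): label must be 0 or 1, got {raw!r}"
                )
            rec["label"] = int(raw)
        groups.setdefault((oid, rid), []).append(rec)

    warnings: list[str] = []
    interactions: list[Interaction] = []
    for (oid, rid), recs in groups.items():
        if len(recs) > 1:
            warnings.append(f"collapsed {len(recs)} duplicate rows for ({oid}, {rid})")
        first = recs[0]
        if mode == "regression":
            value = float(np.mean([r["response"] for r in recs]))
            interactions.append(
                Interaction(oid, rid, response=value, weight=first["weight"], tier=first["tier"])
            )
        else:
            votes = [r["label"] for r in recs]
            ones = sum(votes)
            if len(recs) > 1 and ones * 2 == len(votes):
                raise ValidationError(
                    f"({oid}, {rid}): conflicting duplicate labels with no majority"
                )
            label = 1 if ones * 2 > len(votes) else 0
            interactions.append(
                Interaction(oid, rid, label=label, weight=first["weight"], tier=first["tier"])
            )

    receptors_out = list(rec_map.values())
    return InteractionDataset(
        odorants=list(odorants.values()),
        receptors=receptors_out,
        interactions=interactions,
        mode=mode,
        warnings=warnings,
    )


def write_interaction_table(dataset: InteractionDataset, path_or_buf, sep: str = ",") -> None:
    """Write a dataset in the canonical column layout (round-trips with the loader)."""
    dataset.to_frame().to_csv(path_or_buf, sep=sep, index=False)


def dataset_to_csv_string(dataset: InteractionDataset) -> str:
    buf = io.StringIO()
    write_interaction_table(dataset, buf)
    return buf.getvalue()


def load_receptor_fasta(stream: IO[str] | str) -> list[ReceptorRecord]:
    """Parse receptors from FASTA; ID = first whitespace token of the header."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ReceptorRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"FASTA entry {rec.id!r}: empty sequence")
        seen[rec.id] = seen.get(rec.id, 0) + 1
        records.append(ReceptorRecord(rec.id, seq))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValidationError(f"duplicate FASTA IDs: {dups}")
    return records


def zscore_global(
    dataset: InteractionDataset,
) -> tuple[InteractionDataset, NormalizationParams]:
    """Z-score responses using the mean and SD of the entire dataset pooled.

    All receptors share one (mu, sigma) pair — responses are deliberately not
    standardized per receptor, so between-receptor gain differences survive
    normalization.  Population (ddof=0) standard deviation.
    """
    if dataset.mode != "regression":
        raise ValidationError("zscore_global requires a regression dataset")
    y = dataset.responses()
    if y.size < 2:
        raise ValidationError("need at least 2 interactions to z-score")
    mu = float(np.mean(y))
    sigma = float(np.std(y, ddof=0))
    if sigma == 0.0:
        raise ValidationError("all responses equal: sigma = 0")
    params = NormalizationParams(mu=mu, sigma=sigma)
    scaled = [
        replace(it, response=(it.response - mu) / sigma) for it in dataset.interactions
    ]
    out = InteractionDataset(
        odorants=dataset.odorants,
        receptors=dataset.receptors,
        interactions=scaled,
        mode="regression",
        warnings=list(dataset.warnings),
    )
    return out, params


def build_neural_representation(
    dataset: InteractionDataset,
    missing_policy: Literal["error", "fill_zero"] = "error",
) -> RepresentationMatrix:
    """Represent each odorant as the vector of responses it elicits.

    Returns an ``n_odorants x n_receptors`` matrix; entry (i, j) is the
    measured response of odorant i at receptor j, columns ordered by the
    dataset's receptor declaration order.
    """
    if dataset.mode != "regression":
        raise ValidationError("neural representation requires a regression dataset")
    oids = dataset.odorant_ids
    rids = dataset.receptor_ids
    oidx = {o: i for i, o in enumerate(oids)}
    ridx = {r: j for j, r in enumerate(rids)}
    mat = np.zeros((len(oids), len(rids)))
    seen = np.zeros_like(mat, dtype=bool)
    for it in dataset.interactions:
        i, j = oidx[it.odorant_id], ridx[it.receptor_id]
        mat[i, j] = it.response
        seen[i, j] = True
    if missing_policy == "error" and not seen.all():
        i, j = np.argwhere(~seen)[0]
        raise ValidationError(
            f"missing response for pair ({oids[i]}, {rids[j]}); "
            f"{int((~seen).sum())} pairs missing in total"
        )
    return RepresentationMatrix(list(oids), mat, name="neural_representation")
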