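"""LORAX stage 1: the LoRA-adapted multi-modal cross-attention transformer.

Architecture: a chemical token encoder (SMILES characters) and a protein
token encoder (amino acids) — frozen, standing where pre-trained foundation
models would attach — are projected into a shared model dimension and fused
through bidirectional cross-attention.  A learned ``<cls>`` token reads the
fused sequence out through attention; a linear head maps it to the
prediction.  LoRA adapters on the chemical (optionally protein) encoder's
attention query/value projections are the only way training can move the
encoders; everything else trainable lives in the fusion stack and head.

With adapters disabled (or B still zero), the forward pass is exactly the
frozen-representation comparator: same architecture, no encoder adaptation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from ._autograd import Adam, Tensor, concat, embedding
from .data_model import (
    AMINO_ACIDS,
    InteractionDataset,
    OdorantRecord,
    RepresentationMatrix,
    ValidationError,
)
from .evaluation import Fold, matthews_corrcoef, r2_score
from .featurization import REFERENCE_ALPHABET
from .nn import (
    CrossAttentionLayer,
    FeedForward,
    LayerNorm,
    Linear,
    LoRALinear,
    Module,
    MultiHeadAttention,
    TokenEncoder,
)

__all__ = [
    "LoRAConfig",
    "FusionConfig",
    "EncoderConfig",
    "TrainConfig",
    "CharTokenizer",
    "SMILES_VOCAB",
    "PROTEIN_VOCAB",
    "LoraxModel",
    "apply_lora",
    "lora_param_count",
    "fuse_forward",
    "train_stage1",
    "extract_cls_features",
    "extract_chem_embeddings",
]


@dataclass(frozen=True)
class LoRAConfig:
    r: int = 4
    alpha: float | None = None  # None -> alpha = r (unit effective scale)
    target_matrices: tuple[str, ...] = ("q", "v")
    dropout: float = 0.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.r < 1:
            raise ValidationError("LoRA rank r must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")

    @property
    def effective_alpha(self) -> float:
        return self.r if self.alpha is None else self.alpha


@dataclass(frozen=True)
class EncoderConfig:
    dim: int = 32
    n_layers: int = 2
    n_heads: int = 4
    ff_dim: int = 64
    max_len: int = 64


@dataclass(frozen=True)
class FusionConfig:
    model_dim: int = 32
    n_cross_attention_layers: int = 1
    n_heads: int = 4
    feedforward_dim: int = 64
    cls_mode: Literal["learned_token"] = "learned_token"
    head: Literal["regression_linear", "classification_logit"] = "regression_linear"

    def __post_init__(self) -> None:
        if self.model_dim % self.n_heads != 0:
            raise ValidationError("model_dim must be divisible by n_heads")


TrainableScope = Literal["lora_chem_only", "lora_chem_and_protein", "head_and_fusion_only"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    seed: int = 0
    loss: Literal["mse", "weighted_bce"] = "mse"
    early_stop_patience: int = 8
    trainable_scope: TrainableScope = "lora_chem_only"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValidationError("epochs must be >= 0")


class CharTokenizer:
    """Character-level tokenizer with PAD=0."""

    def __init__(self, alphabet: str):
        self.alphabet = alphabet
        self.index = {ch: i + 1 for i, ch in enumerate(alphabet)}
        self.vocab_size = len(alphabet) + 1

    def encode(self, text: str, length: int) -> tuple[np.ndarray, np.ndarray]:
        unknown = set(text) - set(self.alphabet)
        if unknown:
            raise ValidationError(f"cannot tokenize {text!r}: unknown {sorted(unknown)}")
        if len(text) > length:
            raise ValidationError(f"sequence {text!r} longer than pad length {length}")
        ids = np.zeros(length, dtype=np.intp)
        for i, ch in enumerate(text):
            ids[i] = self.index[ch]
        mask = np.zeros(length, dtype=bool)
        mask[: len(text)] = True
        return ids, mask

    def encode_batch(self, texts: Sequence[str], length: int | None = None):
        length = length if length is not None else max(len(t) for t in texts)
        ids = np.zeros((len(texts), length), dtype=np.intp)
        mask = np.zeros((len(texts), length), dtype=bool)
        for i, t in enumerate(texts):
            ids[i], mask[i] = self.encode(t, length)
        return ids, mask


SMILES_VOCAB = CharTokenizer(REFERENCE_ALPHABET)
PROTEIN_VOCAB = CharTokenizer(AMINO_ACIDS + "X")


# ---------------------------------------------------------------------------
# Standalone LoRA algebra (matrix convention: columns are inputs)


def apply_lora(W: np.ndarray, A: np.ndarray, B: np.ndarray, alpha: float,
               r: int, x: np.ndarray) -> np.ndarray:
    """``W x + (alpha/r) B (A x)`` — the adapted linear map, base untouched."""
    W, A, B, x = (np.asarray(m, float) for m in (W, A, B, x))
    d_out, d_in = W.shape
    if A.shape != (r, d_in) or B.shape != (d_out, r):
        raise ValidationError(
            f"LoRA shapes inconsistent: W {W.shape}, A {A.shape}, B {B.shape}, r={r}"
        )
    if x.shape[0] != d_in:
        raise ValidationError(f"input dim {x.shape[0]} != d_in {d_in}")
    return W @ x + (alpha / r) * (B @ (A @ x))


def lora_param_count(encoder_dims: Mapping[str, tuple[int, int]],
                     config: LoRAConfig) -> int:
    """Trainable adapter parameters: sum of r*(d_in + d_out) over targets."""
    total = 0
    for name in config.target_matrices:
        if name not in encoder_dims:
            raise ValidationError(
                f"unknown target matrix {name!r}; declared: {list(encoder_dims)}"
            )
        d_out, d_in = encoder_dims[name]
        total += config.r * (d_in + d_out)
    return total


# ---------------------------------------------------------------------------
# The model


class LoraxModel(Module):
    """Multi-modal transformer with LoRA-adapted chemical encoder."""

    def __init__(
        self,
        lora_chem: LoRAConfig | None = LoRAConfig(),
        lora_prot: LoRAConfig | None = None,
        fusion: FusionConfig = FusionConfig(),
        chem_encoder_cfg: EncoderConfig = EncoderConfig(),
        prot_encoder_cfg: EncoderConfig = EncoderConfig(),
        seed: int = 0,
        chem_tokenizer: CharTokenizer = SMILES_VOCAB,
        prot_tokenizer: CharTokenizer = PROTEIN_VOCAB,
    ):
        rng = np.random.default_rng(seed)
        self.lora_chem = lora_chem
        self.lora_prot = lora_prot
        self.fusion_cfg = fusion
        self.chem_tokenizer = chem_tokenizer
        self.prot_tokenizer = prot_tokenizer

        def lora_dict(cfg: LoRAConfig | None):
            # Adapters are always constructed (so models differing only in
            # the enabled flag share identical base weights); the flag gates
            # the forward pass.
            cfg = cfg if cfg is not None else LoRAConfig(enabled=False)
            return {"r": cfg.r, "alpha": cfg.effective_alpha,
                    "dropout": cfg.dropout, "enabled": cfg.enabled}

        self.chem_encoder = TokenEncoder(
            chem_tokenizer.vocab_size, chem_encoder_cfg.dim, chem_encoder_cfg.n_layers,
            chem_encoder_cfg.n_heads, chem_encoder_cfg.ff_dim, chem_encoder_cfg.max_len,
            rng, lora=lora_dict(lora_chem),
        )
        self.prot_encoder = TokenEncoder(
            prot_tokenizer.vocab_size, prot_encoder_cfg.dim, prot_encoder_cfg.n_layers,
            prot_encoder_cfg.n_heads, prot_encoder_cfg.ff_dim, prot_encoder_cfg.max_len,
            rng, lora=lora_dict(lora_prot),
        )
        D = fusion.model_dim
        self.chem_proj = Linear(chem_encoder_cfg.dim, D, rng)
        self.prot_proj = Linear(prot_encoder_cfg.dim, D, rng)
        self.cross_layers = [
            CrossAttentionLayer(D, fusion.n_heads, fusion.feedforward_dim, rng)
            for _ in range(fusion.n_cross_attention_layers)
        ]
        # <cls>: one learned token, looked up per batch row
        self.cls = Tensor(rng.standard_normal((1, D)) / np.sqrt(D), requires_grad=True)
        self.cls_ln_kv = LayerNorm(D)
        self.cls_attn = MultiHeadAttention(D, fusion.n_heads, rng)
        self.cls_ln = LayerNorm(D)
        self.cls_ff = FeedForward(D, fusion.feedforward_dim, rng)
        self.cls_ln_out = LayerNorm(D)
        self.head = Linear(D, 1, rng)

    # -- forward -------------------------------------------------------------

    def encode_chem(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        return self.chem_encoder(ids, mask)

    def forward(self, chem_ids, chem_mask, prot_ids, prot_mask):
        """Returns (prediction (B,), cls_vector (B, model_dim)) tensors."""
        if chem_ids.shape != chem_mask.shape or prot_ids.shape != prot_mask.shape:
            raise ValidationError("token/mask shape mismatch")
        B = chem_ids.shape[0]
        c = self.chem_proj(self.chem_encoder(chem_ids, chem_mask))
        p = self.prot_proj(self.prot_encoder(prot_ids, prot_mask))
        for layer in self.cross_layers:
            c, p = layer(c, chem_mask, p, prot_mask)
        fused = concat([c, p], axis=1)
        fmask = np.concatenate([chem_mask, prot_mask], axis=1)
        cls_b = embedding(self.cls, np.zeros((B, 1), dtype=np.intp))
        h = cls_b + self.cls_attn(cls_b, self.cls_ln_kv(fused), fmask)
        h = h + self.cls_ff(self.cls_ln(h))
        cls_vec = self.cls_ln_out(h)[:, 0, :]
        pred = self.head(cls_vec)[:, 0]
        return pred, cls_vec

    # -- parameter scoping ----------------------------------------------------

    def chem_adapters(self) -> list[LoRALinear]:
        return self.chem_encoder.adapters()

    def prot_adapters(self) -> list[LoRALinear]:
        return self.prot_encoder.adapters()

    def _adapter_params(self, adapters: list[LoRALinear]) -> list[Tensor]:
        out = []
        for ad in adapters:
            out.extend([ad.A, ad.B])
        return out

    def fusion_head_params(self) -> list[Tensor]:
        adapter = set(map(id, self._adapter_params(self.chem_adapters())
                          + self._adapter_params(self.prot_adapters())))
        return [p for p in self.trainable_parameters() if id(p) not in adapter]

    def scoped_parameters(self, scope: TrainableScope) -> list[Tensor]:
        params = self.fusion_head_params()
        if scope in ("lora_chem_only", "lora_chem_and_protein"):
            params += self._adapter_params(self.chem_adapters())
        if scope == "lora_chem_and_protein":
            params += self._adapter_params(self.prot_adapters())
        return params

    def set_train_mode(self, mode: bool) -> None:
        for ad in self.chem_adapters() + self.prot_adapters():
            ad._train_mode = mode

    def lora_parameter_count(self) -> int:
        """Trainable adapter parameters across the enabled adapters."""
        enabled = [ad for ad in self.chem_adapters() + self.prot_adapters()
                   if ad.enabled]
        return sum(ad.A.data.size + ad.B.data.size for ad in enabled)

    # -- tokenization helpers --------------------------------------------------

    def tokenize_dataset(self, dataset: InteractionDataset):
        """Pre-tokenize every odorant and receptor; returns per-interaction
        index arrays into the token tables."""
        chem_ids, chem_mask = self.chem_tokenizer.encode_batch(
            [o.smiles for o in dataset.odorants]
        )
        prot_ids, prot_mask = self.prot_tokenizer.encode_batch(
            [r.sequence for r in dataset.receptors]
        )
        oidx = {o: i for i, o in enumerate(dataset.odorant_ids)}
        ridx = {r: i for i, r in enumerate(dataset.receptor_ids)}
        oi = np.array([oidx[it.odorant_id] for it in dataset.interactions])
        ri = np.array([ridx[it.receptor_id] for it in dataset.interactions])
        return {
            "chem_ids": chem_ids, "chem_mask": chem_mask,
            "prot_ids": prot_ids, "prot_mask": prot_mask,
            "oi": oi, "ri": ri,
        }

    def predict_batch(self, tok: dict, idx: np.ndarray, batch_size: int = 256):
        """Eval-mode predictions and cls vectors for interaction indices."""
        self.set_train_mode(False)
        preds, clss = [], []
        for lo in range(0, len(idx), batch_size):
            sel = idx[lo : lo + batch_size]
            oi, ri = tok["oi"][sel], tok["ri"][sel]
            pred, cls = self.forward(
                tok["chem_ids"][oi], tok["chem_mask"][oi],
                tok["prot_ids"][ri], tok["prot_mask"][ri],
            )
            preds.append(pred.data)
            clss.append(cls.data)
        return np.concatenate(preds), np.vstack(clss)


def fuse_forward(model: LoraxModel, chem_tokens, chem_mask, prot_tokens, prot_mask):
    """Single fused forward pass: (prediction, cls_vector) as numpy arrays."""
    model.set_train_mode(False)
    pred, cls = model.forward(chem_tokens, chem_mask, prot_tokens, prot_mask)
    return pred.data, cls.data


# ---------------------------------------------------------------------------
# Stage-1 training


def _loss_tensor(pred: Tensor, y: np.ndarray, w: np.ndarray, kind: str) -> Tensor:
    wt = Tensor(w / w.sum())
    if kind == "mse":
        diff = pred - Tensor(y)
        return (diff * diff * wt).sum()
    # weighted binary cross-entropy on probabilities
    p = pred.sigmoid()
    eps = 1e-12
    yb = Tensor(y)
    nll = -(yb * (p + eps).log() + (1.0 - yb) * (1.0 - p + eps).log())
    return (nll * wt).sum()


def _val_metric(model: LoraxModel, tok, idx, y, kind: str) -> float:
    pred, _ = model.predict_batch(tok, idx)
    if kind == "mse":
        return r2_score(y[idx], pred)
    prob = 1.0 / (1.0 + np.exp(-pred))
    return float(matthews_corrcoef(y[idx].astype(int), (prob >= 0.5).astype(int)))


def train_stage1(
    model: LoraxModel,
    dataset: InteractionDataset,
    fold: Fold,
    cfg: TrainConfig,
) -> tuple[LoraxModel, list[dict]]:
    """Train the transformer on the fold's train set, early-stopping on the
    validation metric (R^2 for MSE loss, MCC for weighted BCE); the best
    checkpoint is restored before returning.  Only parameters in the
    trainable scope (plus fusion, head and <cls>) are ever updated; frozen
    encoder base weights are untouched."""
    if len(fold.train_idx) == 0 or len(fold.val_idx) == 0:
        raise ValidationError("train and validation sets must be non-empty")
    tok = model.tokenize_dataset(dataset)
    y = dataset.responses() if cfg.loss == "mse" else dataset.labels().astype(float)
    w = dataset.weights()
    history: list[dict] = []
    if cfg.epochs == 0:
        return model, history

    params = model.scoped_parameters(cfg.trainable_scope)
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    best_state = model.state_dict()
    best_metric = -np.inf
    since_best = 0

    for epoch in range(cfg.epochs):
        model.set_train_mode(True)
        order = rng.permutation(fold.train_idx)
        total, count = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            if len(sel) < 2:
                continue
            oi, ri = tok["oi"][sel], tok["ri"][sel]
            pred, _ = model.forward(
                tok["chem_ids"][oi], tok["chem_mask"][oi],
                tok["prot_ids"][ri], tok["prot_mask"][ri],
            )
            loss = _loss_tensor(pred, y[sel], w[sel], cfg.loss)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(sel)
            count += len(sel)
        val_metric = _val_metric(model, tok, fold.val_idx, y, cfg.loss)
        history.append(
            {"epoch": epoch, "train_loss": total / max(count, 1), "val_metric": val_metric}
        )
        if val_metric > best_metric:
            best_metric = val_metric
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.early_stop_patience:
                break
    model.load_state_dict(best_state)
    model.set_train_mode(False)
    return model, history


def best_val_metric(history: Sequence[dict]) -> float:
    """The standalone-transformer validation score (pre-ensemble)."""
    if not history:
        raise ValidationError("empty training history")
    return max(h["val_metric"] for h in history)


# ---------------------------------------------------------------------------
# Feature extraction


def extract_cls_features(
    model: LoraxModel,
    dataset: InteractionDataset,
    idx: np.ndarray | None = None,
) -> RepresentationMatrix:
    """One <cls> row per interaction (deterministic, eval mode)."""
    tok = model.tokenize_dataset(dataset)
    if idx is None:
        idx = np.arange(len(dataset.interactions))
    _, cls = model.predict_batch(tok, np.asarray(idx))
    ids = [
        f"{dataset.interactions[i].odorant_id}::{dataset.interactions[i].receptor_id}"
        for i in np.asarray(idx)
    ]
    return RepresentationMatrix(ids, cls, name="cls")


def extract_chem_embeddings(
    model: LoraxModel, odorants: Sequence[OdorantRecord], batch_size: int = 256
) -> RepresentationMatrix:
    """Per-odorant embedding: masked mean of (adapted) chemical encoder tokens."""
    model.set_train_mode(False)
    ids, mask = model.chem_tokenizer.encode_batch([o.smiles for o in odorants])
    rows = []
    for lo in range(0, len(odorants), batch_size):
        sl = slice(lo, lo + batch_size)
        out = model.encode_chem(ids[sl], mask[sl]).data
        m = mask[sl][..., None]
        rows.append((out * m).sum(axis=1) / m.sum(axis=1))
    return RepresentationMatrix(
        [o.odorant_id for o in odorants], np.vstack(rows), name="lorax_chem"
    )
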