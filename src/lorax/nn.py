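"""Neural building blocks for the desk-scale multi-modal transformer.

Layers are composed from :mod:`lorax._autograd` tensors.  Base weights of a
LoRA-wrapped projection are frozen (``requires_grad=False``); the rank-r
update ``(alpha/r) * B A`` is the only trainable part, with ``B`` zero-
initialized so the wrapped layer starts exactly equal to its frozen base.

Attention uses key-side padding masks throughout, so padded positions can
never influence valid positions or the readout.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat, embedding

__all__ = [
    "Module",
    "Linear",
    "LoRALinear",
    "LayerNorm",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderLayer",
    "CrossAttentionLayer",
    "TokenEncoder",
]

NEG_INF = -1e9


class Module:
    """Minimal parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Tensor):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}[{i}]")
                    elif isinstance(item, Tensor):
                        yield f"{full}[{i}]", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = state[name].copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 trainable: bool = True):
        self.W = Tensor(rng.standard_normal((d_in, d_out)) / np.sqrt(d_in),
                        requires_grad=trainable)
        self.b = Tensor(np.zeros(d_out), requires_grad=trainable)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LoRALinear(Module):
    """Frozen linear layer with a trainable rank-r low-rank update.

    forward(x) = x W + b + (alpha/r) * (x A^T) B^T   with B zero-initialized,
    so the layer equals its frozen base until training moves B.
    """

    def __init__(self, d_in: int, d_out: int, r: int, alpha: float,
                 rng: np.random.Generator, dropout: float = 0.0,
                 enabled: bool = True):
        if r < 1 or r > min(d_in, d_out):
            raise ValueError(f"LoRA rank {r} outside [1, min({d_in}, {d_out})]")
        self.W = Tensor(rng.standard_normal((d_in, d_out)) / np.sqrt(d_in),
                        requires_grad=False)
        self.b = Tensor(np.zeros(d_out), requires_grad=False)
        # A drawn from a child stream so base weights downstream do not
        # depend on the adapter rank
        a_rng = np.random.default_rng(rng.integers(0, 2**63 - 1))
        self.A = Tensor(a_rng.standard_normal((r, d_in)) / np.sqrt(d_in),
                        requires_grad=True)
        self.B = Tensor(np.zeros((d_out, r)), requires_grad=True)
        self.r = r
        self.alpha = alpha
        self.dropout = dropout
        self.enabled = enabled
        self._train_mode = False
        self._rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        base = x @ self.W + self.b
        if not self.enabled:
            return base
        h = x
        if self.dropout > 0 and self._train_mode:
            mask = (self._rng.random(x.shape) >= self.dropout) / (1 - self.dropout)
            h = h * Tensor(mask)
        update = (h @ self.A.swapaxes(0, 1)) @ self.B.swapaxes(0, 1)
        return base + update * (self.alpha / self.r)

    def delta_weight(self) -> np.ndarray:
        """The effective update matrix (alpha/r) B A, shape (d_out, d_in)."""
        return (self.alpha / self.r) * (self.B.data @ self.A.data)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, trainable: bool = True):
        self.g = Tensor(np.ones(dim), requires_grad=trainable)
        self.b = Tensor(np.zeros(dim), requires_grad=trainable)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps).power(-0.5) * self.g + self.b


def _make_proj(d_in, d_out, rng, lora=None, trainable=True):
    if lora is not None:
        return LoRALinear(d_in, d_out, r=lora["r"], alpha=lora["alpha"], rng=rng,
                          dropout=lora.get("dropout", 0.0),
                          enabled=lora.get("enabled", True))
    return Linear(d_in, d_out, rng, trainable=trainable)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; queries may come from a different
    sequence than keys/values (cross-attention).  ``lora_targets`` wraps the
    named projections ("q", "v" by default when a lora config is given)."""

    def __init__(self, model_dim: int, n_heads: int, rng: np.random.Generator,
                 lora: dict | None = None,
                 lora_targets: tuple[str, ...] = ("q", "v"),
                 trainable: bool = True):
        if model_dim % n_heads != 0:
            raise ValueError(f"model_dim {model_dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = model_dim // n_heads
        mk = lambda t: _make_proj(model_dim, model_dim, rng,
                                  lora if (lora and t in lora_targets) else None,
                                  trainable=trainable)
        self.q_proj = mk("q")
        self.k_proj = mk("k")
        self.v_proj = mk("v")
        self.o_proj = mk("o")

    def _split(self, x: Tensor):  # (B, L, D) -> (B, H, L, dh)
        B, L, _ = x.shape
        return x.reshape(B, L, self.n_heads, self.d_head).transpose((0, 2, 1, 3))

    def __call__(self, x_q: Tensor, x_kv: Tensor, kv_mask: np.ndarray) -> Tensor:
        B, Lq, D = x_q.shape
        q = self._split(self.q_proj(x_q))
        k = self._split(self.k_proj(x_kv))
        v = self._split(self.v_proj(x_kv))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / np.sqrt(self.d_head))
        bias = np.where(np.asarray(kv_mask, bool), 0.0, NEG_INF)[:, None, None, :]
        attn = (scores + Tensor(bias)).softmax(axis=-1)
        out = attn @ v  # (B, H, Lq, dh)
        out = out.transpose((0, 2, 1, 3)).reshape(B, Lq, D)
        return self.o_proj(out)


class FeedForward(Module):
    def __init__(self, model_dim: int, hidden: int, rng, trainable=True):
        self.fc1 = Linear(model_dim, hidden, rng, trainable)
        self.fc2 = Linear(hidden, model_dim, rng, trainable)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class EncoderLayer(Module):
    """Pre-norm self-attention block."""

    def __init__(self, model_dim, n_heads, ff_dim, rng, lora=None, trainable=True):
        self.ln1 = LayerNorm(model_dim, trainable=trainable)
        self.attn = MultiHeadAttention(model_dim, n_heads, rng, lora=lora,
                                       trainable=trainable)
        self.ln2 = LayerNorm(model_dim, trainable=trainable)
        self.ff = FeedForward(model_dim, ff_dim, rng, trainable=trainable)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        h = self.ln1(x)
        x = x + self.attn(h, h, mask)
        return x + self.ff(self.ln2(x))


class CrossAttentionLayer(Module):
    """Bidirectional cross-attention: each modality attends to the other."""

    def __init__(self, model_dim, n_heads, ff_dim, rng):
        self.ln_a = LayerNorm(model_dim)
        self.ln_b = LayerNorm(model_dim)
        self.attn_ab = MultiHeadAttention(model_dim, n_heads, rng)
        self.attn_ba = MultiHeadAttention(model_dim, n_heads, rng)
        self.ln_fa = LayerNorm(model_dim)
        self.ln_fb = LayerNorm(model_dim)
        self.ff_a = FeedForward(model_dim, ff_dim, rng)
        self.ff_b = FeedForward(model_dim, ff_dim, rng)

    def __call__(self, a: Tensor, a_mask, b: Tensor, b_mask):
        an, bn = self.ln_a(a), self.ln_b(b)
        a2 = a + self.attn_ab(an, bn, b_mask)
        b2 = b + self.attn_ba(bn, an, a_mask)
        a2 = a2 + self.ff_a(self.ln_fa(a2))
        b2 = b2 + self.ff_b(self.ln_fb(b2))
        return a2, b2


class TokenEncoder(Module):
    """Tiny frozen token encoder: embeddings + positional embeddings +
    self-attention layers.  Stands where a pre-trained foundation model would
    attach; LoRA adapters on its attention projections are the only trainable
    pieces (when configured)."""

    def __init__(self, vocab_size: int, dim: int, n_layers: int, n_heads: int,
                 ff_dim: int, max_len: int, rng: np.random.Generator,
                 lora: dict | None = None):
        self.tok = Tensor(rng.standard_normal((vocab_size, dim)) / np.sqrt(dim),
                          requires_grad=False)
        self.pos = Tensor(rng.standard_normal((max_len, dim)) / np.sqrt(dim),
                          requires_grad=False)
        self.layers = [
            EncoderLayer(dim, n_heads, ff_dim, rng, lora=lora, trainable=False)
            for _ in range(n_layers)
        ]
        self.dim = dim
        self.max_len = max_len

    def __call__(self, ids: np.ndarray, mask: np.ndarray) -> Tensor:
        L = ids.shape[1]
        if L > self.max_len:
            raise ValueError(f"sequence length {L} exceeds max_len {self.max_len}")
        x = embedding(self.tok, ids) + self.pos[:L]
        for layer in self.layers:
            x = layer(x, mask)
        return x

    def adapters(self) -> list[LoRALinear]:
        out = []
        for layer in self.layers:
            for proj in (layer.attn.q_proj, layer.attn.k_proj,
                         layer.attn.v_proj, layer.attn.o_proj):
                if isinstance(proj, LoRALinear):
                    out.append(proj)
        return out
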