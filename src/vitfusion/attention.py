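"""Scaled dot-product attention: self, cross, multi-head, and the encoder block.

Self-attention projects one token sequence X into queries, keys and values
(Q = X W_Q, K = X W_K, V = X W_V) and returns softmax(Q K^T / sqrt(d_k)) V.
Cross-attention draws queries from one modality's tokens and keys/values
from the other's, so an n-token structural stream can interrogate an
m-token functional stream and return n updated tokens with an n x m score
matrix. Multi-head variants run the same computation on per-head slices of
the projections and merge heads with an output map W_O.

Every forward pass exposes its row-stochastic score matrices through an
optional capture list; capturing is side-effect-free (scores are detached
copies) and feeds the attention-rollout saliency pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .nn import MLP, LayerNorm, Linear, Module

__all__ = ["AttentionProjection", "AttentionStack", "EncoderBlock",
           "self_attention", "multi_head_self_attention",
           "cross_attention", "multi_head_cross_attention"]


class AttentionProjection(Module):
    """The trainable maps of one attention operation.

    ``d_q`` must equal ``d_k`` (the score logits contract them against each
    other), and each width must split evenly across ``heads``. ``w_out`` maps
    the concatenated per-head values (total width ``d_v``) to ``d_out``.
    """

    def __init__(self, d_model: int, rng: np.random.Generator, heads: int = 1,
                 d_qk: int | None = None, d_v: int | None = None,
                 d_out: int | None = None, name: str = "attn"):
        d_qk = d_model if d_qk is None else d_qk
        d_v = d_model if d_v is None else d_v
        d_out = d_model if d_out is None else d_out
        if heads < 1:
            raise ValueError("heads must be >= 1")
        if d_qk % heads or d_v % heads:
            raise ValueError(
                f"head count {heads} must divide d_qk={d_qk} and d_v={d_v}")
        self.heads = heads
        self.d_model = d_model
        self.d_qk = d_qk
        self.d_v = d_v
        self.w_q = Linear(d_model, d_qk, rng, bias=False, name=f"{name}.w_q")
        self.w_k = Linear(d_model, d_qk, rng, bias=False, name=f"{name}.w_k")
        self.w_v = Linear(d_model, d_v, rng, bias=False, name=f"{name}.w_v")
        self.w_out = Linear(d_v, d_out, rng, bias=False, name=f"{name}.w_o")


@dataclass
class AttentionStack:
    """Per-layer, per-head row-stochastic attention matrices.

    ``weights[l][h]`` is the (T_q, T_k) score matrix of head h in layer l —
    or (B, T_q, T_k) when captured from a batched forward pass.
    """

    weights: list[list[np.ndarray]] = field(default_factory=list)
    layer_kind: str = "self_3d"

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_heads(self) -> int:
        return len(self.weights[0]) if self.weights else 0

    def append_layer(self, head_scores: list[np.ndarray]) -> None:
        self.weights.append([np.asarray(s) for s in head_scores])

    def validate(self, atol: float = 1e-6) -> None:
        for layer in self.weights:
            for w in layer:
                if np.any(w < -atol):
                    raise ValueError("attention weights must be nonnegative")
                if not np.allclose(w.sum(axis=-1), 1.0, atol=atol):
                    raise ValueError("attention rows must sum to 1")


def _scores(q: Tensor, k: Tensor, d_k: int) -> Tensor:
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    return logits.softmax(axis=-1)


def self_attention(x: Tensor | np.ndarray,
                   proj: AttentionProjection) -> tuple[Tensor, Tensor]:
    """Single-head self-attention; returns (output tokens, T x T scores)."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.shape[-1] != proj.d_model:
        raise ValueError(f"token width {x.shape[-1]} != d_model {proj.d_model}")
    q, k, v = proj.w_q(x), proj.w_k(x), proj.w_v(x)
    scores = _scores(q, k, proj.d_qk)
    return scores @ v, scores


def cross_attention(x: Tensor | np.ndarray, y: Tensor | np.ndarray,
                    proj: AttentionProjection) -> tuple[Tensor, Tensor]:
    """Queries from ``x`` (n tokens), keys/values from ``y`` (m tokens).

    Returns n output tokens and the n x m score matrix. With ``y is x`` and
    shared weights this reduces exactly to :func:`self_attention`.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if not isinstance(y, Tensor):
        y = Tensor(y)
    if x.shape[-1] != proj.d_model or y.shape[-1] != proj.d_model:
        raise ValueError("both streams must carry d_model-wide tokens")
    q, k, v = proj.w_q(x), proj.w_k(y), proj.w_v(y)
    scores = _scores(q, k, proj.d_qk)
    return scores @ v, scores


def _multi_head(x, y, proj: AttentionProjection) -> tuple[Tensor, list[np.ndarray]]:
    q_full, k_full, v_full = proj.w_q(x), proj.w_k(y), proj.w_v(y)
    h = proj.heads
    dh_qk, dh_v = proj.d_qk // h, proj.d_v // h
    outputs, head_scores = [], []
    for i in range(h):
        q = q_full[..., i * dh_qk:(i + 1) * dh_qk]
        k = k_full[..., i * dh_qk:(i + 1) * dh_qk]
        v = v_full[..., i * dh_v:(i + 1) * dh_v]
        scores = _scores(q, k, dh_qk)
        outputs.append(scores @ v)
        head_scores.append(scores.data.copy())
    merged = outputs[0] if h == 1 else concat(outputs, axis=-1)
    return proj.w_out(merged), head_scores


def multi_head_self_attention(x: Tensor | np.ndarray, proj: AttentionProjection,
                              ) -> tuple[Tensor, list[np.ndarray]]:
    """Heads computed on per-head projection slices, concatenated, mapped by W_O.

    The second return value is this layer's slice of the attention stack:
    one detached score matrix per head.
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if x.shape[-1] != proj.d_model:
        raise ValueError(f"token width {x.shape[-1]} != d_model {proj.d_model}")
    return _multi_head(x, x, proj)


def multi_head_cross_attention(x: Tensor | np.ndarray, y: Tensor | np.ndarray,
                               proj: AttentionProjection,
                               ) -> tuple[Tensor, list[np.ndarray]]:
    """Multi-head cross-attention: Q from ``x``, K and V from ``y``."""
    if not isinstance(x, Tensor):
        x = Tensor(x)
    if not isinstance(y, Tensor):
        y = Tensor(y)
    if x.shape[-1] != proj.d_model or y.shape[-1] != proj.d_model:
        raise ValueError("both streams must carry d_model-wide tokens")
    return _multi_head(x, y, proj)


class EncoderBlock(Module):
    """Pre-norm transformer encoder block.

    out = x1 + MLP(norm2(x1)) where x1 = x + MHSA(norm1(x)). With all
    attention and MLP weights zero the block is the identity map (both
    residual branches contribute nothing).
    """

    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0, name: str = "block"):
        self.norm1 = LayerNorm(d_model, name=f"{name}.norm1")
        self.attn = AttentionProjection(d_model, rng, heads=heads,
                                        name=f"{name}.attn")
        self.norm2 = LayerNorm(d_model, name=f"{name}.norm2")
        self.mlp = MLP(d_model, int(round(d_model * mlp_ratio)), rng,
                       name=f"{name}.mlp")

    def __call__(self, x: Tensor,
                 capture: AttentionStack | None = None) -> Tensor:
        attn_out, head_scores = multi_head_self_attention(self.norm1(x), self.attn)
        x1 = x + attn_out
        out = x1 + self.mlp(self.norm2(x1))
        if capture is not None:
            capture.append_layer(head_scores)
        return out
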