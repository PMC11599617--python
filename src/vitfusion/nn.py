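"""Neural-network building blocks and the AdamW optimizer.

Layers hold :class:`~vitfusion.autodiff.Tensor` parameters and compose into
modules with recursive parameter discovery. Initialization follows the usual
transformer conventions (truncated-normal-free Xavier/Glorot for projections,
ones/zeros for layer norms), driven by an explicit ``numpy.random.Generator``
so every model build is reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "MLP", "AdamW", "cross_entropy"]


class Module:
    """Base class: anything with discoverable parameters."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)
    elif isinstance(value, dict):
        for v in value.values():
            yield from _collect(v)


def xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    """Affine map ``x @ W + b`` applied to the trailing axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "linear"):
        self.weight = Tensor(xavier(rng, d_in, d_out), requires_grad=True,
                             name=f"{name}.weight")
        self.bias = (Tensor(np.zeros(d_out), requires_grad=True,
                            name=f"{name}.bias") if bias else None)

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    """Per-token normalization over the embedding axis with learned scale/shift."""

    def __init__(self, d: int, eps: float = 1e-5, name: str = "ln"):
        self.gain = Tensor(np.ones(d), requires_grad=True, name=f"{name}.gain")
        self.shift = Tensor(np.zeros(d), requires_grad=True, name=f"{name}.shift")
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


class MLP(Module):
    """Two-layer feed-forward block with GELU, the ViT encoder's second sublayer."""

    def __init__(self, d: int, hidden: int, rng: np.random.Generator,
                 d_out: int | None = None, name: str = "mlp"):
        self.fc1 = Linear(d, hidden, rng, name=f"{name}.fc1")
        self.fc2 = Linear(hidden, d_out if d_out is not None else d, rng,
                          name=f"{name}.fc2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean two-class (or k-class) cross-entropy from raw logits."""
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), np.asarray(labels, dtype=int)]
    return -picked.mean()


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay multiplies parameters by ``(1 - lr_t * weight_decay)`` each
    step, independent of the gradient moments; ``lr_t`` is the base learning
    rate scaled by the external schedule multiplier.
    """

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-3):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr_multiplier: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        lr_t = self.lr * lr_multiplier
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1.0 - b1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            mhat = self.m[i] / (1.0 - b1**self.t)
            vhat = self.v[i] / (1.0 - b2**self.t)
            p.data *= 1.0 - lr_t * self.weight_decay
            p.data -= lr_t * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
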