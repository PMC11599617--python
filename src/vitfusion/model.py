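"""The multimodal two-stream vision transformer.

A 3D stream tokenizes a gray-matter volume (default 128^3 into 16^3 patches,
n = 512 tokens) and a 2D stream tokenizes a padded 54x54 functional network
connectivity (FNC) matrix (27x27 patches, m = 4 tokens). Each stream runs
its own stack of pre-norm encoder blocks. Fusion then combines the streams:

* ``cross_attention`` (default): queries come from the structural tokens and
  keys/values from the functional tokens; the n updated structural tokens are
  concatenated with the m functional tokens, giving n + m fused tokens and an
  n x m cross-attention score matrix per layer/head.
* ``concat``: plain token concatenation, no scores.
* ``weighted_mlp``: learned softmax-normalized scalar gates scale each
  stream before concatenation.

Fused tokens are mean-pooled and classified by an MLP head into two classes
(patient vs. control). There is no class token; token counts are exactly
n, m and n + m throughout. All attention score matrices can be captured
without altering outputs, which feeds the saliency-map pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .autodiff import Tensor, concat
from .attention import (AttentionProjection, AttentionStack, EncoderBlock,
                        multi_head_cross_attention)
from .nn import MLP, LayerNorm, Module
from .patches import PatchEmbedding, PatchGrid, pad_to_patch_multiple, patchify

__all__ = ["ModelConfig", "FusedRepresentation", "ModelOutputs", "MultiModalViT"]

FUSION_MODES = ("cross_attention", "concat", "weighted_mlp")


@dataclass
class ModelConfig:
    """Architecture hyperparameters; defaults give the full-size pipeline."""

    volume_shape: tuple[int, int, int] = (128, 128, 128)
    patch3d: tuple[int, int, int] = (16, 16, 16)
    fnc_shape: tuple[int, int] = (53, 53)
    patch2d: tuple[int, int] = (27, 27)
    d_model: int = 256
    depth_3d: int = 4
    depth_2d: int = 4
    heads: int = 8
    fusion_mode: str = "cross_attention"
    ca_layers: int = 1
    ca_heads: int = 8
    mlp_ratio: float = 2.0
    head_hidden: int = 64
    n_classes: int = 2
    resize_mode: str = "pad"  # 'pad' (trailing zeros) or 'interpolate'

    def __post_init__(self):
        self.volume_shape = tuple(self.volume_shape)
        self.patch3d = tuple(self.patch3d)
        self.fnc_shape = tuple(self.fnc_shape)
        self.patch2d = tuple(self.patch2d)
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(
                f"unknown fusion_mode {self.fusion_mode!r}; choose from {FUSION_MODES}")
        if self.resize_mode not in ("pad", "interpolate"):
            raise ValueError("resize_mode must be 'pad' or 'interpolate'")
        for axis, (s, p) in enumerate(zip(self.volume_shape, self.patch3d)):
            if s % p:
                raise ValueError(
                    f"volume_shape axis {axis} ({s}) not divisible by patch {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class FusedRepresentation:
    """(B, n+m, d) fused tokens plus which indices came from which stream."""

    tokens: Tensor
    n_structural: int
    n_functional: int

    @property
    def provenance(self) -> np.ndarray:
        return np.array(["structural"] * self.n_structural
                        + ["functional"] * self.n_functional)


@dataclass
class ModelOutputs:
    """Everything one forward pass produces, including captured attention."""

    logits: Tensor
    fused: FusedRepresentation
    stack_3d: AttentionStack
    stack_2d: AttentionStack
    stack_cross: AttentionStack | None


class MultiModalViT(Module):
    """Two-stream ViT with cross-attention fusion and a classification head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.config = config
        d = config.d_model

        self.grid3d = PatchGrid(config.volume_shape, config.volume_shape,
                                config.patch3d)
        padded2d = tuple(-(-s // p) * p
                         for s, p in zip(config.fnc_shape, config.patch2d))
        self.grid2d = PatchGrid(config.fnc_shape, padded2d, config.patch2d)

        self.embed3d = PatchEmbedding(self.grid3d, d, rng, name="embed3d")
        self.embed2d = PatchEmbedding(self.grid2d, d, rng, name="embed2d")
        self.blocks3d = [EncoderBlock(d, config.heads, rng, config.mlp_ratio,
                                      name=f"enc3d.{i}")
                         for i in range(config.depth_3d)]
        self.blocks2d = [EncoderBlock(d, config.heads, rng, config.mlp_ratio,
                                      name=f"enc2d.{i}")
                         for i in range(config.depth_2d)]

        if config.fusion_mode == "cross_attention":
            self.ca_norms_q = [LayerNorm(d, name=f"ca.{i}.norm_q")
                               for i in range(config.ca_layers)]
            self.ca_norms_kv = [LayerNorm(d, name=f"ca.{i}.norm_kv")
                                for i in range(config.ca_layers)]
            self.ca_projs = [AttentionProjection(d, rng, heads=config.ca_heads,
                                                 name=f"ca.{i}")
                             for i in range(config.ca_layers)]
        elif config.fusion_mode == "weighted_mlp":
            # two stream-gate logits, softmax-normalized at fusion time
            self.stream_logits = Tensor(np.zeros(2), requires_grad=True,
                                        name="fusion.stream_logits")

        self.head = MLP(d, config.head_hidden, rng, d_out=config.n_classes,
                        name="head")

    # -- input conditioning ---------------------------------------------------

    def prepare_volume(self, volume: np.ndarray) -> np.ndarray:
        """Bring a raw volume to the configured model input shape.

        Inputs no larger than the target on every axis are zero-padded at the
        trailing edge (``resize_mode='pad'``); otherwise, or when
        ``resize_mode='interpolate'``, the volume is resampled with cubic
        spline interpolation (this is how a 121x145x121 native map reaches
        128^3 when any axis overshoots the target).
        """
        volume = np.asarray(volume, dtype=np.float64)
        if volume.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {volume.ndim}D")
        target = self.config.volume_shape
        if volume.shape == target:
            return volume
        if self.config.resize_mode == "pad" and all(
                s <= t for s, t in zip(volume.shape, target)):
            pad = [(0, t - s) for s, t in zip(volume.shape, target)]
            return np.pad(volume, pad, mode="constant")
        zoom = [t / s for s, t in zip(volume.shape, target)]
        out = ndimage.zoom(volume, zoom, order=3, grid_mode=True, mode="grid-constant")
        # spline zoom can land off by one voxel on awkward ratios
        out = out[tuple(slice(0, t) for t in target)]
        if out.shape != target:
            pad = [(0, t - s) for s, t in zip(out.shape, target)]
            out = np.pad(out, pad, mode="constant")
        return out

    def prepare_fnc(self, fnc: np.ndarray) -> np.ndarray:
        """Zero-pad a raw C x C matrix (e.g. 53x53) to the padded grid (54x54)."""
        fnc = np.asarray(fnc, dtype=np.float64)
        if fnc.ndim != 2:
            raise ValueError(f"expected a 2D matrix, got {fnc.ndim}D")
        if fnc.shape == self.grid2d.padded_shape:
            return fnc
        if fnc.shape != tuple(self.config.fnc_shape):
            raise ValueError(
                f"FNC shape {fnc.shape} matches neither the raw "
                f"{self.config.fnc_shape} nor padded {self.grid2d.padded_shape}")
        padded, _ = pad_to_patch_multiple(fnc, self.config.patch2d)
        return padded

    # -- the two encoder streams ----------------------------------------------

    def _tokenize(self, arrays: np.ndarray, grid: PatchGrid,
                  prepare) -> np.ndarray:
        rows = [patchify(prepare(a), grid) for a in arrays]
        return np.stack(rows)  # (B, T, patch_size)

    def forward_structural(self, volumes: np.ndarray,
                           ) -> tuple[Tensor, AttentionStack]:
        """(B, X, Y, Z) volumes -> ((B, n, d) tokens, self-attention stack)."""
        stack = AttentionStack(layer_kind="self_3d")
        tokens = self._tokenize(volumes, self.grid3d, self.prepare_volume)
        x = self.embed3d(tokens)
        for block in self.blocks3d:
            x = block(x, capture=stack)
        return x, stack

    def forward_functional(self, fncs: np.ndarray,
                           ) -> tuple[Tensor, AttentionStack]:
        """(B, C, C) matrices -> ((B, m, d) tokens, self-attention stack)."""
        stack = AttentionStack(layer_kind="self_2d")
        tokens = self._tokenize(fncs, self.grid2d, self.prepare_fnc)
        x = self.embed2d(tokens)
        for block in self.blocks2d:
            x = block(x, capture=stack)
        return x, stack

    # -- fusion and head ------------------------------------------------------

    def fuse(self, struct_feats: Tensor, func_feats: Tensor,
             ) -> tuple[FusedRepresentation, AttentionStack | None]:
        if struct_feats.shape[-1] != func_feats.shape[-1]:
            raise ValueError("streams disagree on embedding width")
        n, m = struct_feats.shape[-2], func_feats.shape[-2]
        mode = self.config.fusion_mode
        cross_stack: AttentionStack | None = None

        if mode == "cross_attention":
            cross_stack = AttentionStack(layer_kind="cross")
            x = struct_feats
            for norm_q, norm_kv, proj in zip(self.ca_norms_q, self.ca_norms_kv,
                                             self.ca_projs):
                out, head_scores = multi_head_cross_attention(
                    norm_q(x), norm_kv(func_feats), proj)
                x = x + out
                cross_stack.append_layer(head_scores)
            fused_tokens = concat([x, func_feats], axis=-2)
        elif mode == "concat":
            fused_tokens = concat([struct_feats, func_feats], axis=-2)
        else:  # weighted_mlp
            gates = self.stream_logits.softmax(axis=-1)
            fused_tokens = concat([struct_feats * (2.0 * gates[0]),
                                   func_feats * (2.0 * gates[1])], axis=-2)
        return FusedRepresentation(fused_tokens, n, m), cross_stack

    def classify(self, fused: FusedRepresentation) -> Tensor:
        """Mean-pool the n+m fused tokens and apply the MLP head -> (B, 2)."""
        pooled = fused.tokens.mean(axis=-2)
        return self.head(pooled)

    def forward(self, volumes: np.ndarray, fncs: np.ndarray) -> ModelOutputs:
        if len(volumes) != len(fncs):
            raise ValueError("volume and FNC batches differ in length")
        struct_feats, stack3d = self.forward_structural(volumes)
        func_feats, stack2d = self.forward_functional(fncs)
        fused, cross_stack = self.fuse(struct_feats, func_feats)
        logits = self.classify(fused)
        return ModelOutputs(logits=logits, fused=fused, stack_3d=stack3d,
                            stack_2d=stack2d, stack_cross=cross_stack)

    def __call__(self, volumes: np.ndarray, fncs: np.ndarray) -> ModelOutputs:
        return self.forward(volumes, fncs)

    def predict_proba(self, volumes: np.ndarray, fncs: np.ndarray) -> np.ndarray:
        """(B, 2) class probabilities (softmax over the head logits)."""
        return self.forward(volumes, fncs).logits.softmax(axis=-1).data

    # -- serialization --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.parameters()):
            out[p.name or f"param.{i}"] = p.data
        if len(out) != len(self.parameters()):
            raise RuntimeError("parameter names are not unique")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            key = p.name or f"param.{i}"
            if key not in state:
                raise KeyError(f"checkpoint is missing parameter {key!r}")
            arr = np.asarray(state[key], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {key!r}")
            p.data = arr.copy()

    def save(self, path) -> None:
        import json
        state = {k: v for k, v in self.state_dict().items()}
        np.savez(path, __config__=json.dumps(self.config.to_dict()), **state)

    @classmethod
    def load(cls, path) -> "MultiModalViT":
        import json
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(config, rng=0)
            model.load_state_dict({k: data[k] for k in data.files
                                   if k != "__config__"})
        return model
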