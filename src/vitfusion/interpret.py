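"""From captured attention to voxel-space and connectivity-space saliency.

The pipeline: (1) aggregate the per-layer, per-head row-stochastic attention
matrices into one weight per token — by plain layer/head averaging (default)
or by multiplicative rollout with residual identity; (2) project token
weights back onto the voxel grid by spreading each token's weight uniformly
over its patch extent, which conserves total mass; (3) combine the
structural self-attention map A3D and the cross-attention map ACA_3D as
Acomb = alpha * A3D + beta * ACA_3D; (4) compare per-subject maps with
voxelwise one- or two-sample t-tests; (5) build attention-based
connectivity matrices by back-projecting the 2D stream's token weights onto
the padded matrix grid, cropping the padding, symmetrizing, and (by
default) weighting elementwise by each subject's connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .attention import AttentionStack
from .domains import block_means
from .patches import PatchGrid, unpatchify

__all__ = ["SaliencyVolume", "GroupStatMap", "FNCAttentionMatrix",
           "rollout_average", "map_tokens_to_volume",
           "map_cross_attention_to_volume", "combine_maps", "group_ttest",
           "fnc_attention", "fnc_group_difference", "attention_saliency"]


@dataclass
class SaliencyVolume:
    """Per-subject voxel saliency maps and their mixing weights."""

    a3d: np.ndarray
    aca_3d: np.ndarray | None
    acomb: np.ndarray
    alpha: float
    beta: float
    grid: PatchGrid


@dataclass
class GroupStatMap:
    """Voxelwise t/p maps with the thresholded significance mask."""

    t_values: np.ndarray
    p_values: np.ndarray
    mask: np.ndarray
    test_kind: str
    threshold_p: float
    group_sizes: tuple[int, ...]


@dataclass
class FNCAttentionMatrix:
    """Attention salience on the connectivity grid with its domain partition."""

    values: np.ndarray
    partition: np.ndarray
    group_tag: str = ""

    def domain_block_means(self, exclude_diagonal: bool = True):
        return block_means(self.values, self.partition, exclude_diagonal)


# -- token-weight aggregation -------------------------------------------------

def _layer_means(stack: AttentionStack) -> list[np.ndarray]:
    if stack.n_layers == 0:
        raise ValueError("empty attention stack")
    return [np.mean(layer, axis=0) for layer in stack.weights]


def rollout_average(stack: AttentionStack, mode: str = "average",
                    reduce: str = "mean") -> np.ndarray:
    """Aggregate an attention stack into one weight per (key) token.

    ``mode='average'``: mean of W_{l,h} over all layers and heads, then the
    matrix is reduced over its query dimension. ``mode='rollout'``: the
    head-averaged matrices are composed multiplicatively across layers as
    prod_l (W_l + I) / 2 (row-stochastic at every step; square stacks only)
    before the same reduction. ``reduce`` is 'mean' or 'max'. Works on
    single matrices (T_q, T_k) and batched ones (B, T_q, T_k), returning
    (T_k,) or (B, T_k).
    """
    layers = _layer_means(stack)
    if mode == "average":
        mat = np.mean(layers, axis=0)
    elif mode == "rollout":
        if layers[0].shape[-1] != layers[0].shape[-2]:
            raise ValueError("multiplicative rollout needs square attention")
        eye = np.eye(layers[0].shape[-1])
        mat = None
        for w in layers:
            step = (w + eye) / 2.0
            mat = step if mat is None else step @ mat
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    if reduce == "mean":
        return mat.mean(axis=-2)
    if reduce == "max":
        return mat.max(axis=-2)
    raise ValueError(f"unknown reduction {reduce!r}")


# -- back-projection ----------------------------------------------------------

def map_tokens_to_volume(weights: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Spread each token's weight uniformly over its patch extent.

    Every voxel of token i's patch receives weight_i / patch_size, so the
    voxel sum equals the token sum exactly (mass conservation) and the map
    is linear in the weights. Returns an array of the grid's padded shape.
    """
    weights = np.asarray(weights, dtype=np.float64)
    if weights.ndim != 1 or weights.size != grid.n_tokens:
        raise ValueError(
            f"need {grid.n_tokens} token weights, got shape {weights.shape}")
    rows = np.repeat(weights[:, None] / grid.patch_size, grid.patch_size, axis=1)
    return unpatchify(rows, grid)


def map_cross_attention_to_volume(ca_scores: np.ndarray, grid: PatchGrid,
                                  reduce: str = "mean") -> np.ndarray:
    """Reduce each query token's row over the keys, then back-project.

    ``ca_scores`` is the (n, m) cross-attention matrix whose rows are the n
    structural query tokens; the row reduction ('mean' or 'max') yields one
    weight per structural token, placed by :func:`map_tokens_to_volume`.
    """
    ca_scores = np.asarray(ca_scores)
    if ca_scores.ndim != 2:
        raise ValueError("ca_scores must be a 2D (queries x keys) matrix")
    if ca_scores.shape[0] != grid.n_tokens:
        raise ValueError(
            f"{ca_scores.shape[0]} query rows != {grid.n_tokens} grid tokens")
    if reduce == "mean":
        w = ca_scores.mean(axis=1)
    elif reduce == "max":
        w = ca_scores.max(axis=1)
    else:
        raise ValueError(f"unknown reduction {reduce!r}")
    return map_tokens_to_volume(w, grid)


def combine_maps(a3d: np.ndarray, aca_3d: np.ndarray, alpha: float = 0.5,
                 beta: float = 0.5) -> np.ndarray:
    """Voxelwise weighted sum alpha * A3D + beta * ACA_3D."""
    a3d = np.asarray(a3d)
    aca_3d = np.asarray(aca_3d)
    if a3d.shape != aca_3d.shape:
        raise ValueError("saliency maps differ in shape")
    if alpha < 0 or beta < 0:
        raise ValueError("mixing weights must be nonnegative")
    return alpha * a3d + beta * aca_3d


def attention_saliency(outputs, grid: PatchGrid, alpha: float = 0.5,
                       beta: float = 0.5, mode: str = "average",
                       ) -> list[SaliencyVolume]:
    """Per-subject saliency volumes from one forward pass's captured stacks.

    ``outputs`` is a :class:`~vitfusion.model.ModelOutputs`. The structural
    self-attention stack gives A3D; the cross-attention stack (if the model
    fused with cross-attention) gives ACA_3D, else ACA_3D is zero and Acomb
    reduces to alpha * A3D.
    """
    w3d = rollout_average(outputs.stack_3d, mode=mode)  # (B, n)
    batch = np.atleast_2d(w3d)
    if outputs.stack_cross is not None and outputs.stack_cross.n_layers:
        # average cross scores over layers/heads, then row-reduce per subject
        ca = np.mean([np.mean(layer, axis=0)
                      for layer in outputs.stack_cross.weights], axis=0)
        ca_batch = ca if ca.ndim == 3 else ca[None]
    else:
        ca_batch = None
    out = []
    for b in range(batch.shape[0]):
        a3d = map_tokens_to_volume(batch[b], grid)
        if ca_batch is not None:
            aca = map_cross_attention_to_volume(ca_batch[b], grid)
            acomb = combine_maps(a3d, aca, alpha, beta)
        else:
            aca = None
            acomb = alpha * a3d
        out.append(SaliencyVolume(a3d=a3d, aca_3d=aca, acomb=acomb,
                                  alpha=alpha, beta=beta, grid=grid))
    return out


# -- group statistics ---------------------------------------------------------

def group_ttest(maps: np.ndarray, labels: np.ndarray | None = None,
                test_kind: str = "two_sample", popmean: float | None = None,
                threshold_p: float = 0.02, normalize: str | None = "sum",
                fdr: bool = False) -> GroupStatMap:
    """Voxelwise t-tests over per-subject maps.

    ``maps`` is (subjects, *spatial). ``two_sample`` runs an unequal-variance
    (Welch) test of patients (label code 1) minus controls (0); ``one_sample``
    tests against ``popmean`` (default: the grand mean across subjects and
    voxels). ``normalize='sum'`` scales each subject map to unit sum first
    (attention maps arrive on arbitrary scales); pass ``None`` for raw maps.
    Zero-variance voxels yield NaN t/p and are excluded from the mask.
    ``fdr=True`` thresholds Benjamini-Hochberg-adjusted p-values instead of
    raw ones (off by default: maps are reported at the raw threshold).
    """
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim < 2:
        raise ValueError("maps must be (subjects, *spatial)")
    if normalize == "sum":
        sums = maps.reshape(len(maps), -1).sum(axis=1)
        if np.any(sums == 0):
            raise ValueError("cannot sum-normalize an all-zero subject map")
        maps = maps / sums.reshape(-1, *([1] * (maps.ndim - 1)))
    elif normalize is not None:
        raise ValueError(f"unknown normalization {normalize!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        if test_kind == "one_sample":
            if len(maps) < 2:
                raise ValueError("one-sample test needs >= 2 subjects")
            mu = float(maps.mean()) if popmean is None else float(popmean)
            t, p = stats.ttest_1samp(maps, mu, axis=0)
            sizes = (len(maps),)
        elif test_kind == "two_sample":
            if labels is None:
                raise ValueError("two-sample test needs labels")
            codes = np.asarray(labels)
            if codes.dtype.kind in "US":
                codes = np.array([{"control": 0, "patient": 1}[str(v)]
                                  for v in codes])
            a = maps[codes == 1]  # patients
            b = maps[codes == 0]  # controls
            if len(a) < 2 or len(b) < 2:
                raise ValueError("each group needs >= 2 subjects")
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
            sizes = (len(a), len(b))
        else:
            raise ValueError(f"unknown test_kind {test_kind!r}")
    t = np.asarray(t, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    p_for_mask = p
    if fdr:
        finite = np.isfinite(p)
        adjusted = np.full_like(p, np.nan)
        adjusted[finite] = stats.false_discovery_control(p[finite].ravel()
                                                         ).reshape(p[finite].shape)
        p_for_mask = adjusted
    mask = np.isfinite(t) & (p_for_mask < threshold_p)
    return GroupStatMap(t_values=t, p_values=p, mask=mask, test_kind=test_kind,
                        threshold_p=threshold_p, group_sizes=sizes)


# -- connectivity-space attention ---------------------------------------------

def fnc_attention(stack: AttentionStack, grid2d: PatchGrid,
                  partition: np.ndarray, fnc: np.ndarray | None = None,
                  weight_by_fnc: bool = True, mode: str = "average",
                  group_tag: str = "") -> FNCAttentionMatrix:
    """Attention-based connectivity matrix for one subject.

    Token weights from the 2D stream (or per-key weights of a cross stack)
    are back-projected onto the padded matrix grid, cropped to the raw C x C
    size, and symmetrized by averaging with the transpose. With
    ``weight_by_fnc`` (default) the salience is multiplied elementwise by the
    subject's connectivity matrix, giving the attention-weighted FNC the
    group-difference analysis works on; otherwise the raw (piecewise
    constant at patch resolution) salience is returned.
    """
    n_comp = len(np.asarray(partition))
    if grid2d.original_shape != (n_comp, n_comp):
        raise ValueError(
            f"partition has {n_comp} components but grid covers "
            f"{grid2d.original_shape}")
    weights = rollout_average(stack, mode=mode)
    if weights.ndim != 1:
        raise ValueError("fnc_attention expects a single subject's stack")
    padded = map_tokens_to_volume(weights, grid2d)
    cropped = padded[:n_comp, :n_comp]
    sal = (cropped + cropped.T) / 2.0
    if weight_by_fnc:
        if fnc is None:
            raise ValueError("weight_by_fnc=True requires the subject's FNC")
        fnc = np.asarray(fnc)
        if fnc.shape != (n_comp, n_comp):
            raise ValueError("FNC shape does not match the partition")
        sal = sal * fnc
    return FNCAttentionMatrix(values=sal, partition=np.asarray(partition),
                              group_tag=group_tag)


def subject_stack(stack: AttentionStack, subject: int) -> AttentionStack:
    """Slice one subject's matrices out of a batched attention stack."""
    return AttentionStack(
        weights=[[np.asarray(h)[subject] for h in layer]
                 for layer in stack.weights],
        layer_kind=stack.layer_kind)


def fnc_group_difference(matrices: list[FNCAttentionMatrix],
                         labels: np.ndarray) -> FNCAttentionMatrix:
    """Mean patient matrix minus mean control matrix."""
    codes = np.asarray(labels)
    if codes.dtype.kind in "US":
        codes = np.array([{"control": 0, "patient": 1}[str(v)] for v in codes])
    values = np.stack([m.values for m in matrices])
    diff = values[codes == 1].mean(axis=0) - values[codes == 0].mean(axis=0)
    return FNCAttentionMatrix(values=diff, partition=matrices[0].partition,
                              group_tag="patient_minus_control")
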