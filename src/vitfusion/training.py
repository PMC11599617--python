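"""Training and evaluation protocol.

Label-stratified 8:1:1 train/validation/test splits rotated over k folds,
AdamW with decoupled weight decay, a linear warmup into a step-decay
learning-rate schedule, volume-only augmentation (random shift-crop, small
affine, axis flips, additive Gaussian noise — connectivity matrices are
never augmented), two-class cross-entropy, and the metric set used for
case-control classification: accuracy, balanced accuracy, rank-statistic
AUC, F1 and precision. Model selection keeps the best-validation
balanced-accuracy checkpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import AdamW, cross_entropy
from .model import MultiModalViT
from .synthetic import SubjectRecord

__all__ = ["AugmentConfig", "TrainConfig", "MetricsReport", "split",
           "warmup_step_lr", "augment_volume", "train", "evaluate",
           "binary_metrics", "cross_validate"]

LABEL_CODES = {"control": 0, "patient": 1}


@dataclass
class AugmentConfig:
    """Volume augmentation parameters (applied at training time only)."""

    enabled: bool = True
    crop_shift: int = 2          # voxels of random translation via shift-crop
    affine_degrees: float = 5.0  # max rotation about a random axis pair
    affine_scale: float = 0.05   # max isotropic log-scale perturbation
    flip_prob: float = 0.5       # probability of flipping the first axis
    noise_sd: float = 0.02       # additive Gaussian intensity noise


@dataclass
class TrainConfig:
    learning_rate: float = 3e-4
    weight_decay: float = 1e-3
    total_epochs: int = 200
    warmup_epochs: int = 30
    lr_step: int = 50
    lr_gamma: float = 0.5
    batch_size: int = 16
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)
    n_folds: int = 10
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.warmup_epochs < max(self.total_epochs, 1):
            raise ValueError("warmup_epochs must be < total_epochs")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_folds < 3:
            raise ValueError("n_folds must be >= 3 (test, val and train chunks)")


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    auc: float | None
    f1: float
    precision: float
    n: int = 0

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "balanced_accuracy": self.balanced_accuracy,
                "auc": self.auc, "f1": self.f1, "precision": self.precision,
                "n": self.n}


# -- splitting ----------------------------------------------------------------

def split(labels: list[str] | np.ndarray, config: TrainConfig,
          ) -> list[dict[str, np.ndarray]]:
    """Stratified rotating train/val/test folds.

    Each class's shuffled indices are cut into ``n_folds`` nearly equal
    chunks; fold f uses chunk f as test, chunk f+1 (mod k) as validation and
    the rest as training, realizing the 8:1:1 ratio at k = 10. Deterministic
    given ``config.seed``; the three sets are disjoint and cover the cohort.
    """
    labels = np.asarray(labels)
    k = config.n_folds
    rng = np.random.default_rng(config.seed)
    per_class_chunks: list[list[np.ndarray]] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} subjects, fewer than {k} folds")
        rng.shuffle(idx)
        per_class_chunks.append(np.array_split(idx, k))
    folds = []
    for f in range(k):
        test = np.concatenate([c[f] for c in per_class_chunks])
        val = np.concatenate([c[(f + 1) % k] for c in per_class_chunks])
        train_idx = np.concatenate(
            [c[j] for c in per_class_chunks for j in range(k)
             if j not in (f, (f + 1) % k)])
        folds.append({"train": np.sort(train_idx), "val": np.sort(val),
                      "test": np.sort(test)})
    return folds


# -- schedule -----------------------------------------------------------------

def warmup_step_lr(epoch: int, config: TrainConfig) -> float:
    """Learning-rate multiplier: linear ramp, then gamma decay every lr_step.

    The ramp is (epoch + 1) / warmup_epochs so epoch 0 already trains with a
    small nonzero rate and epoch == warmup_epochs is exactly 1.
    """
    if not 0 <= epoch < config.total_epochs:
        raise ValueError("epoch out of range")
    if config.warmup_epochs > 0 and epoch < config.warmup_epochs:
        return (epoch + 1) / config.warmup_epochs
    return config.lr_gamma ** ((epoch - config.warmup_epochs) // config.lr_step)


# -- augmentation -------------------------------------------------------------

def augment_volume(volume: np.ndarray, aug: AugmentConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Apply the four volume augmentations; output shape equals input shape."""
    if not aug.enabled:
        return volume
    out = volume
    if aug.crop_shift > 0:
        shift = rng.integers(-aug.crop_shift, aug.crop_shift + 1, size=3)
        out = ndimage.shift(out, shift, order=0, mode="constant")
    if aug.affine_degrees > 0 or aug.affine_scale > 0:
        angle = rng.uniform(-aug.affine_degrees, aug.affine_degrees)
        axes = tuple(rng.choice(3, size=2, replace=False))
        out = ndimage.rotate(out, angle, axes=axes, reshape=False, order=1,
                             mode="constant")
        scale = float(np.exp(rng.uniform(-aug.affine_scale, aug.affine_scale)))
        if abs(scale - 1.0) > 1e-6:
            zoomed = ndimage.zoom(out, scale, order=1, mode="constant")
            out = _fit_to(zoomed, volume.shape)
    if aug.flip_prob > 0 and rng.random() < aug.flip_prob:
        out = out[::-1].copy()
    if aug.noise_sd > 0:
        out = out + aug.noise_sd * rng.standard_normal(out.shape)
    return out


def _fit_to(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop or zero-pad ``arr`` to ``shape``."""
    out = arr
    for ax, target in enumerate(shape):
        size = out.shape[ax]
        if size > target:
            lo = (size - target) // 2
            out = np.take(out, range(lo, lo + target), axis=ax)
        elif size < target:
            pad = [(0, 0)] * out.ndim
            lo = (target - size) // 2
            pad[ax] = (lo, target - size - lo)
            out = np.pad(out, pad, mode="constant")
    return out


# -- metrics ------------------------------------------------------------------

def _rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with midranks for ties."""
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n1 = int(y_true.sum())
    n0 = len(y_true) - n1
    return float((ranks[y_true == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def binary_metrics(y_true: np.ndarray, scores: np.ndarray,
                   threshold: float = 0.5) -> MetricsReport:
    """Metric set from positive-class scores in [0, 1].

    Balanced accuracy is (sensitivity + specificity) / 2; AUC is the rank
    statistic over the positive-class score; F1 and precision come from
    thresholding at ``threshold``. A single-class truth vector yields
    ``auc=None`` with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    n = len(y_true)
    accuracy = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    bal_acc = (sens + spec) / 2.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * precision * sens / (precision + sens)
          if precision + sens else 0.0)
    if len(np.unique(y_true)) < 2:
        warnings.warn("single-class truth vector: AUC undefined", RuntimeWarning)
        auc = None
    else:
        auc = _rank_auc(y_true, scores)
    return MetricsReport(accuracy=accuracy, balanced_accuracy=bal_acc, auc=auc,
                         f1=f1, precision=precision, n=n)


# -- the loop -----------------------------------------------------------------

def _batch_arrays(records: list[SubjectRecord], idx: np.ndarray,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    vols = np.stack([records[i].volume for i in idx])
    fncs = np.stack([records[i].fnc for i in idx])
    y = np.array([LABEL_CODES[records[i].label] for i in idx])
    return vols, fncs, y


def evaluate(model: MultiModalViT, records: list[SubjectRecord],
             idx: np.ndarray | None = None, batch_size: int = 16,
             ) -> MetricsReport:
    """Score subjects with the model and compute the metric set."""
    if idx is None:
        idx = np.arange(len(records))
    idx = np.asarray(idx)
    scores = np.empty(len(idx))
    y = np.empty(len(idx), dtype=int)
    for lo in range(0, len(idx), batch_size):
        chunk = idx[lo:lo + batch_size]
        vols, fncs, yc = _batch_arrays(records, chunk)
        scores[lo:lo + len(chunk)] = model.predict_proba(vols, fncs)[:, 1]
        y[lo:lo + len(chunk)] = yc
    return binary_metrics(y, scores)


def train(model: MultiModalViT, records: list[SubjectRecord],
          config: TrainConfig, train_idx: np.ndarray,
          val_idx: np.ndarray | None = None,
          ) -> tuple[MultiModalViT, list[dict]]:
    """Fit the model with AdamW + warmup/step schedule; returns (model, log).

    Augmentations touch volumes only. When a validation set is given, the
    parameters with the best validation balanced accuracy are restored at
    the end. Raises on a non-finite loss.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    train_idx = np.asarray(train_idx)
    log: list[dict] = []
    best = {"bal_acc": -1.0, "state": None, "epoch": -1}

    for epoch in range(config.total_epochs):
        mult = warmup_step_lr(epoch, config)
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), config.batch_size):
            chunk = order[lo:lo + config.batch_size]
            vols, fncs, y = _batch_arrays(records, chunk)
            if config.augmentation.enabled:
                vols = np.stack([augment_volume(v, config.augmentation, rng)
                                 for v in vols])
            out = model(vols, fncs)
            loss = cross_entropy(out.logits, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr multiplier {mult:.3g} — lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step(lr_multiplier=mult)
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "lr": config.learning_rate * mult,
                 "loss": float(np.mean(losses))}
        if val_idx is not None and len(val_idx):
            vm = evaluate(model, records, val_idx, config.batch_size)
            entry.update(val_accuracy=vm.accuracy,
                         val_balanced_accuracy=vm.balanced_accuracy,
                         val_auc=vm.auc, val_f1=vm.f1,
                         val_precision=vm.precision)
            if vm.balanced_accuracy > best["bal_acc"]:
                best = {"bal_acc": vm.balanced_accuracy,
                        "state": {k: v.copy()
                                  for k, v in model.state_dict().items()},
                        "epoch": epoch}
        log.append(entry)

    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return model, log


def cross_validate(model_factory, records: list[SubjectRecord],
                   config: TrainConfig) -> tuple[list[MetricsReport], dict]:
    """k-fold protocol: fit on train, select on val, report test metrics.

    ``model_factory(fold_seed)`` must return a fresh model. Returns per-fold
    test reports and the mean of each metric across folds.
    """
    labels = [r.label for r in records]
    folds = split(labels, config)
    reports = []
    for f, fold in enumerate(folds):
        model = model_factory(config.seed + f)
        model, _ = train(model, records, config, fold["train"], fold["val"])
        reports.append(evaluate(model, records, fold["test"],
                                config.batch_size))
    mean = {k: float(np.mean([getattr(r, k) for r in reports
                              if getattr(r, k) is not None]))
            for k in ("accuracy", "balanced_accuracy", "auc", "f1", "precision")}
    return reports, mean
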