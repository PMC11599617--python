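"""Synthetic paired-modality cohorts with planted, recoverable group effects.

Each subject gets (i) a 3D "gray-matter" volume: a shared smooth template of
Gaussian bumps plus i.i.d. voxel noise, with the patient group's template
intensity reduced by a known fraction inside a chosen voxel set; and (ii) a
C x C connectivity matrix computed from simulated component time courses.

Connectivity effects are planted through a domain-factor model. Every
component i in domain d follows

    x_i(t) = sqrt(w) * g_d(t) + sqrt(1 - w) * e_i(t)

with unit-variance domain factors g_d, i.i.d. noise e_i, and within-domain
coupling w (so any two components of one domain correlate at w in both
groups). In patients the factors of each planted domain pair (a, b) are
correlated at c = effect / w, which makes the patient-minus-control
correlation difference inside the (a, b) cross block equal the requested
effect size exactly in population, while the covariance stays positive
semi-definite by construction. Effects larger than w are impossible in this
model and are clipped (with a warning) to the attainable maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .domains import block_mask, domain_slices, make_partition

__all__ = ["CohortConfig", "SubjectRecord", "GroundTruth", "generate_cohort",
           "compute_fnc", "default_effect_cube"]


def default_effect_cube(volume_shape: tuple[int, int, int],
                        side: int | None = None) -> np.ndarray:
    """A centered cube mask of ``side`` voxels per axis (default: shape/4).

    With the default 32^3 test volumes and 8^3 patches this lands exactly on
    one patch of the token lattice, which makes attention-recovery checks
    interpretable at patch resolution.
    """
    mask = np.zeros(volume_shape, dtype=bool)
    sides = [side if side is not None else max(1, s // 4) for s in volume_shape]
    # start at the side-aligned block nearest the center, so the cube sits on
    # the token lattice whenever the patch side divides the cube side
    starts = [((s - c) // 2 // c) * c for s, c in zip(volume_shape, sides)]
    sl = tuple(slice(st, st + c) for st, c in zip(starts, sides))
    mask[sl] = True
    return mask


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_subjects_per_group: int = 20
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    n_components: int = 53
    n_timepoints: int = 200
    effect_voxels: np.ndarray | None = None  # boolean mask or (k, 3) coords
    effect_size_structural: float = 0.3
    effect_blocks: tuple[tuple[str, str], ...] = (("SC", "SM"),)
    effect_size_fnc: float = 0.4
    noise_sd: float = 0.1
    within_domain_corr: float = 0.5
    n_template_bumps: int = 12
    seed: int = 0

    def __post_init__(self):
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3 (correlation undefined)")
        if not 0.0 < self.within_domain_corr < 1.0:
            raise ValueError("within_domain_corr must lie in (0, 1)")
        if abs(self.effect_size_fnc) >= 1.0:
            raise ValueError("|effect_size_fnc| must be < 1")
        self.effect_blocks = tuple((str(a), str(b)) for a, b in self.effect_blocks)

    def effect_mask(self) -> np.ndarray:
        """Planted structural effect as a boolean volume mask."""
        if self.effect_voxels is None:
            return default_effect_cube(self.volume_shape)
        ev = np.asarray(self.effect_voxels)
        if ev.dtype == bool:
            if ev.shape != self.volume_shape:
                raise ValueError("effect mask shape differs from volume_shape")
            return ev
        coords = np.atleast_2d(ev).astype(int)
        if coords.shape[1] != 3:
            raise ValueError("effect_voxels coordinates must be (k, 3)")
        if np.any(coords < 0) or np.any(coords >= np.array(self.volume_shape)):
            raise ValueError("effect_voxels outside volume_shape")
        mask = np.zeros(self.volume_shape, dtype=bool)
        mask[tuple(coords.T)] = True
        return mask


@dataclass
class SubjectRecord:
    """One simulated subject: paired volume + connectivity + label."""

    id: str
    label: str  # 'patient' or 'control'
    volume: np.ndarray
    fnc: np.ndarray
    timecourses: np.ndarray | None = None


@dataclass
class GroundTruth:
    """Where the effects were planted; the acceptance surface for recovery."""

    voxel_mask: np.ndarray
    block_mask: np.ndarray
    partition: np.ndarray
    effect_blocks: tuple[tuple[str, str], ...]


def compute_fnc(timecourses: np.ndarray) -> np.ndarray:
    """Pairwise Pearson cross-correlation of component time courses.

    (C, T) in, symmetric unit-diagonal (C, C) out, entries clipped to [-1, 1]
    against floating-point overshoot.
    """
    tc = np.asarray(timecourses, dtype=np.float64)
    if tc.ndim != 2:
        raise ValueError("timecourses must be a (components, timepoints) array")
    if tc.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    sd = tc.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"zero-variance time course for component(s) {dead.tolist()}")
    fnc = np.corrcoef(tc)
    fnc = np.clip((fnc + fnc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(fnc, 1.0)
    return fnc


def _template(rng: np.random.Generator, shape: tuple[int, int, int],
              n_bumps: int) -> np.ndarray:
    """Smooth anatomical stand-in: superposition of Gaussian bumps in [0, ~1]."""
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    vol = np.zeros(shape)
    for _ in range(n_bumps):
        center = rng.uniform(0.15, 0.85, size=3) * np.array(shape)
        width = rng.uniform(0.10, 0.25) * min(shape)
        sq = sum((g - c) ** 2 for g, c in zip(grids, center))
        vol += rng.uniform(0.4, 1.0) * np.exp(-sq / (2.0 * width**2))
    return vol / max(vol.max(), 1e-12)


def _factor_correlation(config: CohortConfig, partition: np.ndarray,
                        patient: bool) -> tuple[np.ndarray, list[str]]:
    """Correlation matrix of the domain factors for one group."""
    slices = domain_slices(partition)
    names = list(slices)
    k = len(names)
    corr = np.eye(k)
    if patient:
        w = config.within_domain_corr
        c = config.effect_size_fnc / w
        if abs(c) > 1.0:
            warnings.warn(
                f"effect_size_fnc={config.effect_size_fnc} exceeds the attainable "
                f"maximum within_domain_corr={w}; clipping factor correlation",
                RuntimeWarning)
            c = float(np.clip(c, -1.0, 1.0))
        for a, b in config.effect_blocks:
            if a not in names or b not in names:
                raise ValueError(f"unknown domain in effect block ({a}, {b})")
            if a == b:
                raise ValueError(
                    "same-domain effect blocks are not expressible in the "
                    "factor model; choose two distinct domains")
            i, j = names.index(a), names.index(b)
            corr[i, j] = corr[j, i] = c
        # multiple planted blocks can make the factor correlation indefinite
        evals = np.linalg.eigvalsh(corr)
        if evals.min() < -1e-10:
            warnings.warn("planted block combination is indefinite; "
                          "projecting factor correlation to nearest PSD",
                          RuntimeWarning)
            vals, vecs = np.linalg.eigh(corr)
            corr = vecs @ np.diag(np.clip(vals, 0.0, None)) @ vecs.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
    return corr, names


def _simulate_timecourses(rng: np.random.Generator, config: CohortConfig,
                          partition: np.ndarray, patient: bool) -> np.ndarray:
    corr, names = _factor_correlation(config, partition, patient)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    t = config.n_timepoints
    factors = chol @ rng.standard_normal((len(corr), t))
    w = config.within_domain_corr
    tc = np.sqrt(1.0 - w) * rng.standard_normal((config.n_components, t))
    slices = domain_slices(partition)
    for i, name in enumerate(names):
        tc[slices[name]] += np.sqrt(w) * factors[i]
    return tc


def generate_cohort(config: CohortConfig,
                    ) -> tuple[list[SubjectRecord], GroundTruth]:
    """Simulate a balanced two-group cohort; deterministic given config.seed.

    Controls: volume = template + N(0, noise_sd) per voxel; patients: the
    template is scaled by (1 - effect_size_structural) inside the planted
    voxel mask before noise. Connectivity comes from :func:`compute_fnc` on
    factor-model time courses (module docstring); with both effect sizes at
    zero the two groups' generative distributions are identical.
    """
    mask = config.effect_mask()
    partition = make_partition(config.n_components)
    root = np.random.SeedSequence(config.seed)
    template_rng = np.random.default_rng(root.spawn(1)[0])
    template = _template(template_rng, config.volume_shape,
                         config.n_template_bumps)
    patient_template = template.copy()
    patient_template[mask] *= 1.0 - config.effect_size_structural

    n = config.n_subjects_per_group
    subject_seeds = root.spawn(1 + 2 * n)[1:]
    records: list[SubjectRecord] = []
    for k in range(2 * n):
        patient = k >= n
        rng = np.random.default_rng(subject_seeds[k])
        base = patient_template if patient else template
        volume = base + config.noise_sd * rng.standard_normal(config.volume_shape)
        tc = _simulate_timecourses(rng, config, partition, patient)
        records.append(SubjectRecord(
            id=f"sub-{k + 1:04d}",
            label="patient" if patient else "control",
            volume=volume,
            fnc=compute_fnc(tc),
            timecourses=tc,
        ))

    bmask = np.zeros((config.n_components, config.n_components), dtype=bool)
    for a, b in config.effect_blocks:
        bmask |= block_mask(partition, a, b)
    truth = GroundTruth(voxel_mask=mask, block_mask=bmask, partition=partition,
                        effect_blocks=config.effect_blocks)
    return records, truth
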