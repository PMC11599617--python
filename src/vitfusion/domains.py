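"""Functional-domain partition of connectivity components.

Intrinsic connectivity networks from spatially constrained ICA are grouped
into seven canonical functional domains: subcortical (SC), auditory (AUD),
sensorimotor (SM), visual (VS), cognitive control (CC), default mode (DM)
and cerebellar (CB). The default 53-component template uses the standard
domain sizes 5/2/9/9/17/7/4; other component counts get a proportional
split so synthetic cohorts of any size carry a valid partition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DOMAINS", "DOMAIN_SIZES_53", "make_partition", "domain_slices",
           "block_mask", "iter_domain_pairs", "block_means"]

DOMAINS = ("SC", "AUD", "SM", "VS", "CC", "DM", "CB")
DOMAIN_SIZES_53 = {"SC": 5, "AUD": 2, "SM": 9, "VS": 9, "CC": 17, "DM": 7, "CB": 4}


def make_partition(n_components: int = 53) -> np.ndarray:
    """Domain label per component, components ordered by domain."""
    if n_components == 53:
        sizes = [DOMAIN_SIZES_53[d] for d in DOMAINS]
    else:
        if n_components < len(DOMAINS):
            raise ValueError(
                f"need at least {len(DOMAINS)} components for a full partition")
        weights = np.array([DOMAIN_SIZES_53[d] for d in DOMAINS], dtype=float)
        sizes = np.maximum(1, np.floor(weights / weights.sum() * n_components)
                           ).astype(int)
        # distribute the remainder to the largest domains first
        order = np.argsort(-weights)
        i = 0
        while sizes.sum() < n_components:
            sizes[order[i % len(DOMAINS)]] += 1
            i += 1
        while sizes.sum() > n_components:
            j = order[i % len(DOMAINS)]
            if sizes[j] > 1:
                sizes[j] -= 1
            i += 1
        sizes = sizes.tolist()
    return np.repeat(DOMAINS, sizes)


def domain_slices(partition: np.ndarray) -> dict[str, slice]:
    """Contiguous index range of each domain (partition must be domain-ordered)."""
    out: dict[str, slice] = {}
    labels = np.asarray(partition)
    for d in DOMAINS:
        idx = np.flatnonzero(labels == d)
        if idx.size == 0:
            continue
        if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
            raise ValueError(f"domain {d} is not contiguous in the partition")
        out[d] = slice(int(idx[0]), int(idx[-1] + 1))
    return out


def block_mask(partition: np.ndarray, domain_a: str, domain_b: str) -> np.ndarray:
    """Symmetric boolean C x C mask of the (domain_a, domain_b) block."""
    labels = np.asarray(partition)
    in_a = labels == domain_a
    in_b = labels == domain_b
    if not in_a.any() or not in_b.any():
        raise ValueError(f"unknown or empty domain in pair ({domain_a}, {domain_b})")
    mask = np.outer(in_a, in_b)
    return mask | mask.T


def iter_domain_pairs(partition: np.ndarray):
    """All unordered domain pairs (including same-domain pairs) present."""
    present = [d for d in DOMAINS if (np.asarray(partition) == d).any()]
    for i, a in enumerate(present):
        for b in present[i:]:
            yield a, b


def block_means(matrix: np.ndarray, partition: np.ndarray,
                exclude_diagonal: bool = True) -> dict[tuple[str, str], float]:
    """Mean matrix value over every domain-pair block (off-diagonal cells only
    for same-domain blocks when ``exclude_diagonal``)."""
    matrix = np.asarray(matrix)
    out: dict[tuple[str, str], float] = {}
    for a, b in iter_domain_pairs(partition):
        mask = block_mask(partition, a, b)
        if a == b and exclude_diagonal:
            mask = mask & ~np.eye(len(matrix), dtype=bool)
        out[(a, b)] = float(matrix[mask].mean())
    return out
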