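"""Shared permutation and randomization machinery.

All Monte-Carlo p-values in this package are produced by
:func:`addone_pvalue`, and every restricted (block-respecting) permutation
test draws its permutations from :func:`blocked_permutations` /
:class:`PermutationScheme`.  Restricting label permutations to blocks (here,
taxa) controls for block identity: a label never moves between blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "addone_pvalue",
    "blocked_permutation_indices",
    "blocked_permutations",
    "PermutationScheme",
]


def addone_pvalue(observed: float, null_values, side: str = "greater") -> float:
    """Add-one Monte-Carlo p-value: ``(1 + #{null at least as extreme}) / (n + 1)``.

    The add-one convention guarantees p >= 1/(n+1), so no reported p is
    exactly zero.  ``side`` is one of ``greater``, ``less``, ``two-sided``;
    the two-sided value is ``min(1, 2 * min(p_greater, p_less))``.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("need at least one null value")
    n = null_values.size
    p_greater = (1 + np.sum(null_values >= observed)) / (n + 1)
    p_less = (1 + np.sum(null_values <= observed)) / (n + 1)
    if side == "greater":
        return float(p_greater)
    if side == "less":
        return float(p_less)
    if side == "two-sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown side {side!r}")


def blocked_permutation_indices(blocks: Sequence, rng: np.random.Generator) -> np.ndarray:
    """One permutation of ``range(len(blocks))`` that only moves indices within a block."""
    blocks = np.asarray(blocks)
    perm = np.arange(blocks.size)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        perm[idx] = rng.permutation(idx)
    return perm


def blocked_permutations(
    blocks: Sequence, n_perm: int, seed: int | np.random.Generator | None = None
) -> Iterator[np.ndarray]:
    """Stream of ``n_perm`` within-block permutations (index arrays)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(n_perm):
        yield blocked_permutation_indices(blocks, rng)


@dataclass
class PermutationScheme:
    """Units with block structure and labels; permutations move labels only within blocks."""

    units: list
    blocks: list
    labels: list
    seed: int | None = None
    n_perm: int = 10_000

    def __post_init__(self) -> None:
        if not (len(self.units) == len(self.blocks) == len(self.labels)):
            raise ValueError("units, blocks and labels must have equal length")

    def __iter__(self) -> Iterator[np.ndarray]:
        """Yield permuted label arrays (labels shuffled within each block)."""
        labels = np.asarray(self.labels, dtype=object)
        for perm in blocked_permutations(self.blocks, self.n_perm, self.seed):
            yield labels[perm]
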