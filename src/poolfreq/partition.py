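"""Partition-ligation for long marker windows.

The full dictionary has ``2**L`` candidates, which is unusable for large L.
Partition-ligation splits the loci into ``Q = ceil(L / W)`` adjacent blocks of
(near-)equal width, estimates haplotype frequencies within each block with the
full dictionary over that block, then hierarchically merges consecutive block
pairs: the merged block's dictionary contains every concatenation of a
surviving left haplotype (estimated population frequency above a support
threshold) with a surviving right haplotype, and the chosen ADMM variant is
re-run on the merged loci.  The recursion ends when a single block spans all
loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Callable, Sequence

import numpy as np

from .dictionary import HaplotypeDictionary, build_full_dictionary, concatenate
from .evaluate import aggregate_population_frequencies
from .pools import PoolSet
from .solvers import Diagnostics, SolverConfig, solve, solve_missing, solve_noisy

logger = logging.getLogger(__name__)

#: Default support threshold: below the resolution 1/(2*sum n_i) of any
#: realizable population frequency in the regimes this tool targets.
DEFAULT_SUPPORT_THRESHOLD = 1e-4

#: Default hard cap on a merged dictionary's size.
DEFAULT_MERGE_CAP = 4096

_SOLVERS: dict[str, Callable] = {
    "core": solve,
    "noisy": solve_noisy,
    "missing": solve_missing,
}


@dataclass(frozen=True)
class PartitionPlan:
    """Adjacent, non-overlapping blocks covering loci 1..L (1-based inclusive)."""

    boundaries: tuple[tuple[int, int], ...]
    W: int

    def __post_init__(self) -> None:
        bounds = tuple((int(a), int(b)) for a, b in self.boundaries)
        if not bounds:
            raise ValueError("at least one block required")
        if bounds[0][0] != 1:
            raise ValueError("first block must start at locus 1")
        for (a, b), (a2, _) in zip(bounds, bounds[1:]):
            if a2 != b + 1:
                raise ValueError("blocks must be adjacent and non-overlapping")
        for a, b in bounds:
            if b < a:
                raise ValueError("empty block")
            if b - a + 1 > self.W:
                raise ValueError("block wider than W")
        object.__setattr__(self, "boundaries", bounds)

    @property
    def Q(self) -> int:
        return len(self.boundaries)

    @property
    def L(self) -> int:
        return self.boundaries[-1][1]


def make_partition(L: int, W: int) -> PartitionPlan:
    """``Q = ceil(L / W)`` blocks of equal-as-possible width (earlier blocks
    take the extra locus)."""
    if W < 1:
        raise ValueError("W must be at least 1")
    if L < 1:
        raise ValueError("L must be at least 1")
    W = min(W, L)
    Q = ceil(L / W)
    base, extra = divmod(L, Q)
    widths = [base + 1 if q < extra else base for q in range(Q)]
    bounds = []
    start = 1
    for w in widths:
        bounds.append((start, start + w - 1))
        start += w
    return PartitionPlan(boundaries=tuple(bounds), W=W)


@dataclass(frozen=True)
class BlockSolution:
    """One block's span (1-based inclusive loci), dictionary, and proportions."""

    start: int
    stop: int
    dictionary: HaplotypeDictionary
    X: np.ndarray


def _slice_pools(pool_set: PoolSet, start: int, stop: int) -> PoolSet:
    rows = slice(start - 1, stop)
    return PoolSet(
        A=pool_set.A[rows, :],
        sizes=pool_set.sizes,
        missing_mask=pool_set.missing_mask[rows, :],
    )


def _run_solver(variant: str, pool_set: PoolSet, dictionary: HaplotypeDictionary,
                config: SolverConfig) -> tuple[np.ndarray, Diagnostics]:
    try:
        solver = _SOLVERS[variant]
    except KeyError:
        raise ValueError(f"unknown solver variant {variant!r}") from None
    if variant != "missing" and pool_set.has_missing:
        solver = solve_missing
    return solver(pool_set, dictionary, config)


def _surviving(block: BlockSolution, sizes: np.ndarray,
               support_threshold: float) -> tuple[list[str], np.ndarray]:
    dist = aggregate_population_frequencies(block.X, sizes, block.dictionary)
    keep = dist.freqs > support_threshold
    if not keep.any():
        raise ValueError(
            f"no haplotype in block {block.start}-{block.stop} survives the "
            f"support threshold {support_threshold}; lower support_threshold"
        )
    labels = [h for h, k in zip(dist.haplotypes, keep) if k]
    return labels, dist.freqs[keep]


def _trim_to_cap(left: list[str], lf: np.ndarray, right: list[str],
                 rf: np.ndarray, cap: int) -> tuple[list[str], list[str]]:
    lo = list(np.argsort(lf)[::-1])
    ro = list(np.argsort(rf)[::-1])
    nl, nr = len(lo), len(ro)
    while nl * nr > cap:
        # drop the lowest-frequency haplotype from the larger side
        if nl >= nr and nl > 1:
            nl -= 1
        elif nr > 1:
            nr -= 1
        else:
            break
    if (nl, nr) != (len(lo), len(ro)):
        logger.warning(
            "merged dictionary capped at %d: keeping %d x %d haplotypes", cap, nl, nr
        )
    return [left[i] for i in sorted(lo[:nl])], [right[i] for i in sorted(ro[:nr])]


def ligate(solutions: Sequence[BlockSolution], pool_set: PoolSet,
           config: SolverConfig | None = None,
           support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
           variant: str = "core",
           merge_cap: int = DEFAULT_MERGE_CAP,
           ) -> tuple[HaplotypeDictionary, np.ndarray, Diagnostics | None]:
    """Hierarchically merge adjacent block solutions until one spans all loci.

    Consecutive blocks are paired (1,2), (3,4), ...; an unpaired trailing
    block is carried forward unchanged.  Each merged dictionary is the
    Cartesian concatenation of the surviving haplotypes from the two sides
    (capped at ``merge_cap`` columns by dropping lowest-frequency survivors),
    and the chosen solver variant is re-run on the merged loci with ``rho``
    re-resolved from the merged sub-problem when not set explicitly.
    """
    config = config or SolverConfig()
    blocks = sorted(solutions, key=lambda b: b.start)
    if not blocks:
        raise ValueError("no block solutions given")
    if blocks[0].start != 1 or blocks[-1].stop != pool_set.L:
        raise ValueError("block solutions must cover all loci in order")
    for b, b2 in zip(blocks, blocks[1:]):
        if b2.start != b.stop + 1:
            raise ValueError("block solutions must be adjacent")

    last_diag: Diagnostics | None = None
    while len(blocks) > 1:
        merged: list[BlockSolution] = []
        for j in range(0, len(blocks) - 1, 2):
            left, right = blocks[j], blocks[j + 1]
            lh, lf = _surviving(left, pool_set.sizes, support_threshold)
            rh, rf = _surviving(right, pool_set.sizes, support_threshold)
            lh, rh = _trim_to_cap(lh, lf, rh, rf, merge_cap)
            cat = concatenate(
                HaplotypeDictionary(
                    H=np.array([[int(c) for c in h] for h in lh]).T, labels=tuple(lh)
                ),
                HaplotypeDictionary(
                    H=np.array([[int(c) for c in h] for h in rh]).T, labels=tuple(rh)
                ),
            )
            sub = _slice_pools(pool_set, left.start, right.stop)
            X, last_diag = _run_solver(variant, sub, cat, config)
            merged.append(BlockSolution(left.start, right.stop, cat, X))
        if len(blocks) % 2 == 1:
            merged.append(blocks[-1])
        blocks = merged
    final = blocks[0]
    return final.dictionary, final.X, last_diag


def solve_partition_ligation(
    pool_set: PoolSet,
    config: SolverConfig | None = None,
    W: int = 8,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    variant: str = "core",
    merge_cap: int = DEFAULT_MERGE_CAP,
) -> tuple[HaplotypeDictionary, np.ndarray, Diagnostics | None]:
    """Partition the loci, solve every block with its full dictionary, ligate.

    With ``W >= L`` this is exactly one direct solve with the full ``2**L``
    dictionary.
    """
    config = config or SolverConfig()
    plan = make_partition(pool_set.L, W)
    blocks = []
    for start, stop in plan.boundaries:
        width = stop - start + 1
        dictionary = build_full_dictionary(width)
        sub = _slice_pools(pool_set, start, stop)
        X, diag = _run_solver(variant, sub, dictionary, config)
        blocks.append(BlockSolution(start, stop, dictionary, X))
    if plan.Q == 1:
        return blocks[0].dictionary, blocks[0].X, diag
    return ligate(blocks, pool_set, config, support_threshold, variant, merge_cap)
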