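"""Observed DNA pools: per-locus allele-1 frequencies with optional missing cells.

A pool of ``n`` diploid individuals carries ``2n`` haplotypes; a single
genotyping experiment on the pool yields, per locus, the relative frequency of
allele 1 among those ``2n`` chromosomes.  Counts are the canonical input
(clustering of pooled intensities outputs discrete calls on the ``k/(2n)``
grid); relative frequencies are accepted directly and are not validated
against that grid.  Loci are 1-based in files and error messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dictionary import HaplotypeDictionary

#: Missing-value sentinel used in pool files.
MISSING = "NA"


@dataclass(frozen=True)
class PoolSet:
    """``O`` pools over ``L`` loci.

    Attributes
    ----------
    A : ndarray of shape (L, O)
        Observed relative frequency of allele 1; entries at masked cells are
        carried but never read by the solvers.
    sizes : ndarray of shape (O,)
        Individuals per pool (``n_i``); pool ``i`` contributes ``2*n_i``
        haplotypes.
    missing_mask : ndarray of shape (L, O), bool
        True where the observation is absent.
    """

    A: np.ndarray
    sizes: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2:
            raise ValueError("A must be an L x O matrix")
        sizes = np.asarray(self.sizes, dtype=int)
        if sizes.ndim != 1 or sizes.shape[0] != A.shape[1]:
            raise ValueError("sizes must have one entry per pool")
        if (sizes <= 0).any():
            raise ValueError("pool sizes must be strictly positive")
        mask = self.missing_mask
        if mask is None:
            mask = np.zeros_like(A, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != A.shape:
            raise ValueError("missing_mask shape must match A")
        observed = A[~mask]
        if observed.size and ((observed < -1e-9) | (observed > 1 + 1e-9)).any():
            raise ValueError("non-missing frequencies must lie in [0, 1]")
        A = np.clip(A, 0.0, 1.0)  # absorb float round-off at the boundaries
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "missing_mask", mask)

    @property
    def L(self) -> int:
        return self.A.shape[0]

    @property
    def O(self) -> int:
        return self.A.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing_mask.any())

    def mean_observed_frequency(self) -> float:
        """Mean allele-1 relative frequency over all non-missing cells (a-bar)."""
        observed = self.A[~self.missing_mask]
        if observed.size == 0:
            raise ValueError("pool set has no observed entries")
        return float(observed.mean())


def counts_to_frequencies(counts: np.ndarray, sizes: Sequence[int],
                          missing_sentinel: int = -1) -> PoolSet:
    """Convert per-locus allele-1 counts to relative frequencies.

    ``counts[l, i]`` is the number of allele-1 chromosomes at locus ``l`` in
    pool ``i`` and must lie in ``[0, 2*n_i]``; cells equal to
    ``missing_sentinel`` become masked.
    """
    counts = np.asarray(counts)
    sizes = np.asarray(sizes, dtype=int)
    mask = counts == missing_sentinel
    chroms = 2 * sizes[np.newaxis, :]
    bad = (~mask) & ((counts < 0) | (counts > chroms))
    if bad.any():
        l, i = np.argwhere(bad)[0]
        raise ValueError(
            f"count {counts[l, i]} at locus {l + 1}, pool {i + 1} "
            f"outside [0, {2 * sizes[i]}]"
        )
    A = np.where(mask, 0.0, counts / chroms)
    return PoolSet(A=A, sizes=sizes, missing_mask=mask)


def reduced_view(pool_set: PoolSet, dictionary: HaplotypeDictionary,
                 pool_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-pool reduced system ``(H_i, a~_i)`` with missing loci removed.

    Rows of ``H`` and entries of the pool's frequency vector at that pool's
    masked loci are dropped; the order of retained loci is preserved.  Pools
    with different masks therefore see different constraint matrices.
    """
    if not 0 <= pool_index < pool_set.O:
        raise IndexError(f"pool index {pool_index} out of range")
    if dictionary.L != pool_set.L:
        raise ValueError("dictionary and pool set disagree on the number of loci")
    keep = ~pool_set.missing_mask[:, pool_index]
    if not keep.any():
        raise ValueError(
            f"pool {pool_index + 1} has all loci missing and carries no information"
        )
    return dictionary.H[keep, :], pool_set.A[keep, pool_index]


def read_pool_table(path: str | Path, frequencies: bool = False) -> PoolSet:
    """Read the pool TSV: columns ``pool_id``, ``n``, then one column per SNP.

    Per-SNP cells hold allele-1 counts (default dialect) or relative
    frequencies (``frequencies=True``); the literal string ``NA`` marks a
    missing observation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"pool_id", "n"}
    if not required.issubset(df.columns):
        raise ValueError(f"pool table must have columns {sorted(required)}")
    snp_cols = [c for c in df.columns if c not in required]
    if not snp_cols:
        raise ValueError("pool table has no SNP columns")
    sizes = df["n"].astype(int).to_numpy()
    cells = df[snp_cols].to_numpy(dtype=object).T  # L x O
    mask = np.array([[str(v).strip() == MISSING for v in row] for row in cells])
    values = np.where(mask, "0", cells).astype(float)
    if frequencies:
        return PoolSet(A=values, sizes=sizes, missing_mask=mask)
    counts = values.astype(int)
    counts[mask] = -1
    return counts_to_frequencies(counts, sizes)


def write_pool_table(pool_set: PoolSet, path: str | Path,
                     frequencies: bool = False) -> None:
    """Write a pool set in the TSV dialect that :func:`read_pool_table` reads."""
    L, O = pool_set.L, pool_set.O
    data: dict[str, list] = {
        "pool_id": [f"pool{i + 1}" for i in range(O)],
        "n": list(pool_set.sizes),
    }
    for l in range(L):
        col = []
        for i in range(O):
            if pool_set.missing_mask[l, i]:
                col.append(MISSING)
            elif frequencies:
                col.append(repr(float(pool_set.A[l, i])))
            else:
                col.append(str(int(round(pool_set.A[l, i] * 2 * pool_set.sizes[i]))))
        data[f"snp{l + 1}"] = col
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
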