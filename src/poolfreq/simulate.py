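"""Synthetic pooled-DNA data with the error structure of real pooling assays.

Pools are formed by drawing haplotypes i.i.d. from a known population
distribution: each of the ``n`` diploid individuals in a pool contributes two
independent draws, so a pool carries ``2n`` chromosomes and its noiseless
allele-1 frequency at every locus is a multiple of ``1/(2n)``.  Measurement
error is modelled downstream of the assay's clustering step: Gaussian
perturbation of each called frequency with standard deviation ``sigma``
followed by discretization back to the nearest allowed call ``k/(2n)``
(realistic sigma: 0 to 0.06).  Missing genotype calls are introduced by
masking a fixed fraction of (locus, pool) cells uniformly at random
(realistic rates: 1-2%).

The module ships the 11-haplotype angiotensinogen (AGT) gene distribution
over 10 SNPs that is the package's standard worked example
(:func:`agt_distribution`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dictionary import HaplotypeDictionary, dictionary_from_haplotypes
from .pools import PoolSet


@dataclass(frozen=True)
class FrequencyDistribution:
    """A population distribution over binary haplotypes.

    ``freqs`` must be nonnegative and sum to 1 within 1e-9.
    """

    haplotypes: tuple[str, ...]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        haps = tuple(self.haplotypes)
        freqs = np.asarray(self.freqs, dtype=float)
        if len(haps) != freqs.shape[0]:
            raise ValueError("one frequency per haplotype required")
        if (freqs < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {freqs.sum()!r}, not 1")
        if len(set(len(h) for h in haps)) > 1:
            raise ValueError("haplotypes must share one length")
        object.__setattr__(self, "haplotypes", haps)
        object.__setattr__(self, "freqs", freqs)

    @property
    def L(self) -> int:
        return len(self.haplotypes[0])

    def dictionary(self) -> HaplotypeDictionary:
        return dictionary_from_haplotypes(self.haplotypes)

    def as_series(self) -> pd.Series:
        return pd.Series(self.freqs, index=list(self.haplotypes), name="frequency")


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian frequency perturbation SD and missing-call rate."""

    sigma: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def agt_distribution() -> FrequencyDistribution:
    """The packaged AGT gene table: 11 haplotypes over 10 SNPs."""
    path = resources.files("poolfreq").joinpath("data/agt_frequencies.tsv")
    with resources.as_file(path) as p:
        return read_distribution(p)


def read_distribution(path: str | Path) -> FrequencyDistribution:
    """Read a gold-standard TSV with columns ``haplotype`` and ``frequency``."""
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
    return FrequencyDistribution(
        haplotypes=tuple(df["haplotype"]),
        freqs=df["frequency"].to_numpy(dtype=float),
    )


def write_distribution(dist: FrequencyDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {"haplotype": list(dist.haplotypes), "frequency": dist.freqs}
    ).to_csv(path, sep="\t", index=False)


def random_distribution(D: int, L: int, seed: int | None = None,
                        concentration: float = 1.0) -> FrequencyDistribution:
    """A random population of ``D`` distinct haplotypes over ``L`` loci.

    Haplotypes are drawn uniformly without replacement from ``{0,1}^L`` and
    frequencies from a symmetric Dirichlet.  Stands in for haplotype blocks
    estimated from reference panels when a generic test population is needed.
    """
    if D > 2 ** L:
        raise ValueError("cannot draw more distinct haplotypes than 2^L")
    rng = np.random.default_rng(seed)
    seen: dict[str, None] = {}
    while len(seen) < D:
        hap = "".join(str(b) for b in rng.integers(0, 2, size=L))
        seen.setdefault(hap, None)
    freqs = rng.dirichlet(np.full(D, concentration))
    return FrequencyDistribution(haplotypes=tuple(seen), freqs=freqs)


def simulate_pools(dist: FrequencyDistribution, O: int, n_per_pool: int,
                   seed: int | None = None) -> tuple[PoolSet, np.ndarray]:
    """Draw ``O`` pools of ``n_per_pool`` diploid individuals from ``dist``.

    Every individual contributes two i.i.d. haplotype draws.  Returns the
    noiseless pool set (frequencies exactly on the ``k/(2n)`` grid) and the
    realized per-pool proportion matrix (rows aligned with
    ``dist.haplotypes``), whose entries are multiples of ``1/(2n)``.
    """
    if O < 1 or n_per_pool < 1:
        raise ValueError("O and n_per_pool must be at least 1")
    rng = np.random.default_rng(seed)
    H = dist.dictionary().H  # L x D
    D = len(dist.haplotypes)
    chroms = 2 * n_per_pool
    X_true = np.empty((D, O))
    for i in range(O):
        counts = rng.multinomial(chroms, dist.freqs)
        X_true[:, i] = counts / chroms
    A = H @ X_true
    sizes = np.full(O, n_per_pool)
    return PoolSet(A=A, sizes=sizes), X_true


def perturb_and_discretize(pool_set: PoolSet, noise: NoiseSpec,
                           seed: int | None = None) -> PoolSet:
    """Apply the measurement-error model to a noiseless pool set.

    Adds independent ``N(0, sigma^2)`` noise to each non-missing frequency,
    snaps every value to the nearest allowed call ``k/(2*n_i)`` (ties round
    up; values below 0 snap to 0, above 1 to 1), then masks a uniformly
    random ``missing_rate`` fraction of cells.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    A = pool_set.A.copy()
    mask = pool_set.missing_mask.copy()
    L, O = A.shape
    if noise.sigma > 0:
        A = A + rng.normal(0.0, noise.sigma, size=A.shape)
    # snap to the per-pool grid {k/(2n_i)}; floor(v + 1/2) rounds halves up
    chroms = 2 * pool_set.sizes[np.newaxis, :]
    counts = np.floor(A * chroms + 0.5)
    A = np.clip(counts, 0, chroms) / chroms
    if noise.missing_rate > 0:
        n_mask = int(round(noise.missing_rate * L * O))
        flat = rng.choice(L * O, size=n_mask, replace=False)
        mask = mask.copy()
        mask.ravel()[flat] = True
    return PoolSet(A=A, sizes=pool_set.sizes, missing_mask=mask)
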