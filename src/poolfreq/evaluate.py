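"""Population-level frequency aggregation and distribution distances.

An estimate is per-pool proportions; the population-level haplotype frequency
of haplotype j is its share among all ``2 * sum(n_i)`` sampled chromosomes,
i.e. the ``2 n_i``-weighted mean of the per-pool proportions.  Estimates are
scored against a gold standard ``g`` with the chi-square distance
``sum_{g_j != 0} (f_j - g_j)^2 / g_j`` (asymmetric: mass placed on
zero-``g`` haplotypes contributes nothing) and the l1 distance
``sum_j |f_j - g_j|`` (twice the total-variation distance).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .dictionary import HaplotypeDictionary
from .simulate import FrequencyDistribution

FreqLike = FrequencyDistribution | Mapping[str, float]


def aggregate_population_frequencies(
    X: np.ndarray,
    sizes: np.ndarray,
    dictionary: HaplotypeDictionary,
) -> FrequencyDistribution:
    """Chromosome-count-weighted mean of per-pool proportion columns.

    ``f_j = sum_i 2 n_i X[j, i] / sum_i 2 n_i``; reduces to the plain column
    mean when all pools share one size.
    """
    X = np.asarray(X, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if X.ndim != 2 or X.shape[1] != sizes.shape[0]:
        raise ValueError("X must be M x O with one size per pool")
    if X.shape[0] != dictionary.M:
        raise ValueError("X rows must match the dictionary's haplotype count")
    weights = 2.0 * sizes
    f = X @ (weights / weights.sum())
    f = np.clip(f, 0.0, None)
    f = f / f.sum()
    return FrequencyDistribution(haplotypes=dictionary.labels, freqs=f)


def _as_mapping(dist: FreqLike) -> dict[str, float]:
    if isinstance(dist, FrequencyDistribution):
        return dict(zip(dist.haplotypes, dist.freqs))
    return dict(dist)


def align(f: FreqLike, g: FreqLike) -> tuple[np.ndarray, np.ndarray]:
    """Zero-filled frequency arrays over the union of the two supports.

    Haplotype strings must share one length across both inputs; the union is
    ordered with ``f``'s haplotypes first, then ``g``-only strings.
    """
    fm, gm = _as_mapping(f), _as_mapping(g)
    lengths = {len(h) for h in list(fm) + list(gm)}
    if len(lengths) > 1:
        raise ValueError(
            f"cannot align distributions over different locus counts {sorted(lengths)}"
        )
    union = list(fm) + [h for h in gm if h not in fm]
    fv = np.array([fm.get(h, 0.0) for h in union])
    gv = np.array([gm.get(h, 0.0) for h in union])
    return fv, gv


def chi2_distance(f: FreqLike, g: FreqLike) -> float:
    """``sum_{j: g_j != 0} (f_j - g_j)^2 / g_j`` — only nonzero-g terms count."""
    fv, gv = align(f, g)
    nz = gv != 0
    return float(((fv[nz] - gv[nz]) ** 2 / gv[nz]).sum())


def l1_distance(f: FreqLike, g: FreqLike) -> float:
    """``sum_j |f_j - g_j|`` over the union of supports."""
    fv, gv = align(f, g)
    return float(np.abs(fv - gv).sum())
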