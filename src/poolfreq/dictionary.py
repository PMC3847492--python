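"""Haplotype dictionaries over L diallelic loci.

A haplotype over ``L`` diallelic loci is encoded as a binary string: 0 for the
wild-type (most common) allele, 1 for the mutant allele.  A dictionary collects
``M`` candidate haplotypes as the columns of an ``L x M`` binary matrix ``H``;
pooled observations are then modelled as nonnegative combinations of these
columns.  Inputs are expected to be pre-recoded to the 0/1 convention — no
nucleotide-level recoding happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Largest L for which the full 2^L dictionary may be built directly.
FULL_DICTIONARY_CAP = 20


@dataclass(frozen=True)
class HaplotypeDictionary:
    """Binary ``L x M`` matrix whose columns are candidate haplotypes.

    Attributes
    ----------
    H : ndarray of shape (L, M)
        Float 0/1 matrix; column ``j`` is the allele vector of haplotype
        ``labels[j]``.
    labels : tuple of str
        The binary strings, one per column.
    """

    H: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.ndim != 2:
            raise ValueError("H must be a 2-D matrix")
        if not np.isin(H, (0.0, 1.0)).all():
            raise ValueError("dictionary entries must all be 0 or 1")
        labels = tuple(self.labels) or tuple(
            "".join(str(int(v)) for v in col) for col in H.T
        )
        if len(labels) != H.shape[1]:
            raise ValueError("one label per column required")
        if len(set(labels)) != len(labels):
            raise ValueError("dictionary columns must be pairwise distinct")
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "labels", labels)

    @property
    def L(self) -> int:
        """Number of loci (rows)."""
        return self.H.shape[0]

    @property
    def M(self) -> int:
        """Number of candidate haplotypes (columns)."""
        return self.H.shape[1]

    def index_of(self, label: str) -> int:
        """Column index of a haplotype string; raises ``KeyError`` if absent."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(label) from None


def build_full_dictionary(L: int, cap: int = FULL_DICTIONARY_CAP) -> HaplotypeDictionary:
    """All ``2**L`` haplotypes of length ``L``, in lexicographic label order.

    Parameters
    ----------
    L : int
        Number of loci, ``1 <= L <= cap``.
    cap : int
        Guard against building an astronomically large dictionary; for windows
        longer than ``cap`` loci use partition-ligation instead.
    """
    if L < 1:
        raise ValueError("L must be a positive integer")
    if L > cap:
        raise ValueError(
            f"L={L} exceeds the full-dictionary cap ({cap}); "
            "use partition-ligation (pl_width) for long marker windows"
        )
    # itertools.product over '01' yields strings already in lexicographic order
    labels = ["".join(bits) for bits in product("01", repeat=L)]
    H = np.array([[int(c) for c in lab] for lab in labels], dtype=float).T
    return HaplotypeDictionary(H=H, labels=tuple(labels))


def dictionary_from_haplotypes(haplotypes: Sequence[str]) -> HaplotypeDictionary:
    """Dictionary from user-supplied binary strings, deduplicated, order kept.

    Duplicate strings are dropped (first occurrence wins) with a logged
    warning — database exports often contain repeats.  Ragged lengths or
    non-binary characters raise ``ValueError`` naming the offending entry.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise ValueError("empty haplotype list")
    L = len(haplotypes[0])
    seen: dict[str, None] = {}
    for idx, hap in enumerate(haplotypes):
        if len(hap) != L:
            raise ValueError(
                f"haplotype #{idx + 1} ({hap!r}) has length {len(hap)}, expected {L}"
            )
        if set(hap) - {"0", "1"}:
            raise ValueError(f"haplotype #{idx + 1} ({hap!r}) contains non-binary characters")
        if hap in seen:
            logger.warning("duplicate haplotype %r dropped (first occurrence kept)", hap)
        else:
            seen[hap] = None
    labels = tuple(seen)
    H = np.array([[int(c) for c in lab] for lab in labels], dtype=float).T
    return HaplotypeDictionary(H=H, labels=labels)


def read_haplotype_list(path: str | Path) -> HaplotypeDictionary:
    """Read a plain-text haplotype list: one binary string per line, '#' comments."""
    lines = Path(path).read_text().splitlines()
    haps = [s.strip() for s in lines if s.strip() and not s.lstrip().startswith("#")]
    return dictionary_from_haplotypes(haps)


def write_haplotype_list(dictionary: HaplotypeDictionary, path: str | Path) -> None:
    """Write the dictionary back in the same one-string-per-line format."""
    Path(path).write_text("\n".join(dictionary.labels) + "\n")


def concatenate(left: HaplotypeDictionary, right: HaplotypeDictionary,
                pairs: Iterable[tuple[int, int]] | None = None) -> HaplotypeDictionary:
    """Cartesian (or selected) concatenation of two dictionaries' haplotypes.

    Used by the ligation phase: each merged candidate is a left haplotype
    followed by a right haplotype.  ``pairs`` restricts to specific
    (left index, right index) combinations; default is the full product.
    """
    if pairs is None:
        pairs = product(range(left.M), range(right.M))
    labels = ["".join((left.labels[i], right.labels[j])) for i, j in pairs]
    return dictionary_from_haplotypes(labels)
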