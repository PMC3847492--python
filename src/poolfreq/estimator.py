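"""Scikit-learn style estimator wrapping the ADMM solvers.

:class:`PooledHaplotypeFrequencies` is the package's main user surface: fit it
on pooled allele-frequency observations (pools as samples, loci as features)
and read off the per-pool haplotype proportions and the population-level
haplotype frequency estimate.  The underlying solver functions in
:mod:`poolfreq.solvers` and :mod:`poolfreq.partition` remain available
directly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dictionary import (
    FULL_DICTIONARY_CAP,
    HaplotypeDictionary,
    build_full_dictionary,
)
from .evaluate import aggregate_population_frequencies
from .partition import (
    DEFAULT_MERGE_CAP,
    DEFAULT_SUPPORT_THRESHOLD,
    solve_partition_ligation,
)
from .pools import PoolSet
from .solvers import SolverConfig, solve, solve_missing, solve_noisy


class PooledHaplotypeFrequencies(BaseEstimator):
    """Maximum-parsimony haplotype frequency estimation from DNA pools.

    Parameters
    ----------
    dictionary : HaplotypeDictionary or None
        Candidate haplotypes.  ``None`` builds the full ``2**L`` dictionary
        (requires ``L <= dict_cap`` unless ``pl_width`` is set).
    variant : {"auto", "core", "noisy", "missing"}
        ``auto`` picks ``missing`` when the data carry missing cells, else
        ``noisy`` when ``delta`` is given, else ``core``.
    rho : float or None
        ADMM penalty; ``None`` means the data-driven ``1 / a_bar``.
    delta : float or None
        Squared-Frobenius noise-ball radius.  ``None`` requests the exact
        data constraint; a value requests the noise-tolerant solver
        (``variant="noisy"`` with ``delta=None`` uses 0.1).
    tol, max_iter : float, int
        Stopping rule of the iteration (relative change / iteration cap).
    pl_width : int
        Partition-ligation block width; 0 disables partition-ligation.
        Only available with ``dictionary=None`` (per-block full dictionaries).
    support_threshold : float
        Population frequency below which a haplotype is treated as absent
        (ligation survivor selection and the ``top_haplotypes`` view).
    dict_cap : int
        Largest ``L`` for which the full dictionary may be built directly.
    random_state : int or None
        Carried into the solver configuration for provenance.

    Attributes
    ----------
    dictionary_ : HaplotypeDictionary
        Candidate haplotypes actually used (post-ligation for PL runs).
    proportions_ : ndarray of shape (M, O)
        Per-pool haplotype proportion columns, each exactly on the simplex.
    frequencies_ : ndarray of shape (M,)
        Population-level frequencies (chromosome-count-weighted pool mean).
    labels_ : tuple of str
        Haplotype strings aligned with ``frequencies_``.
    diagnostics_ : Diagnostics
        Convergence record of the (final) solve.
    n_iter_ : int
        Iterations used by the (final) solve.

    Examples
    --------
    >>> from poolfreq import PooledHaplotypeFrequencies, simulate
    >>> dist = simulate.agt_distribution()
    >>> pools, _ = simulate.simulate_pools(dist, O=50, n_per_pool=2, seed=0)
    >>> est = PooledHaplotypeFrequencies(max_iter=2000).fit(pools)
    >>> est.proportions_.shape
    (1024, 50)
    """

    def __init__(self, dictionary: HaplotypeDictionary | None = None,
                 variant: str = "auto", rho: float | None = None,
                 delta: float | None = None, tol: float = 1e-20,
                 max_iter: int = 8000, pl_width: int = 0,
                 support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                 merge_cap: int = DEFAULT_MERGE_CAP,
                 dict_cap: int = FULL_DICTIONARY_CAP,
                 random_state: int | None = None):
        self.dictionary = dictionary
        self.variant = variant
        self.rho = rho
        self.delta = delta
        self.tol = tol
        self.max_iter = max_iter
        self.pl_width = pl_width
        self.support_threshold = support_threshold
        self.merge_cap = merge_cap
        self.dict_cap = dict_cap
        self.random_state = random_state

    def _as_pool_set(self, X, sizes) -> PoolSet:
        if isinstance(X, PoolSet):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (pools as rows, loci as columns)")
        O = X.shape[0]
        if sizes is None:
            sizes = np.ones(O, dtype=int)
        mask = np.isnan(X)
        A = np.where(mask, 0.0, X).T
        return PoolSet(A=A, sizes=np.asarray(sizes, dtype=int), missing_mask=mask.T)

    def _resolve_variant(self, pool_set: PoolSet) -> str:
        if self.variant != "auto":
            return self.variant
        if pool_set.has_missing:
            return "missing"
        if self.delta is not None:
            return "noisy"
        return "core"

    def _solver_config(self) -> SolverConfig:
        delta = 0.1 if self.delta is None else self.delta
        return SolverConfig(rho=self.rho, tol=self.tol, max_iter=self.max_iter,
                            delta=delta, seed=self.random_state)

    def fit(self, X, y=None, *, sizes=None):
        """Estimate per-pool proportions and population frequencies.

        Parameters
        ----------
        X : PoolSet or array-like of shape (n_pools, n_loci)
            Observed allele-1 relative frequencies; ``NaN`` marks a missing
            cell when an array is given.
        sizes : array-like of shape (n_pools,), optional
            Individuals per pool for array input (default: 1 per pool).
        """
        pool_set = self._as_pool_set(X, sizes)
        variant = self._resolve_variant(pool_set)
        if variant == "missing" and not pool_set.has_missing:
            variant = "core"
        if variant != "missing" and pool_set.has_missing:
            raise ValueError(
                f"variant={variant!r} cannot handle missing cells; "
                "use variant='missing' or 'auto'"
            )
        config = self._solver_config()

        if self.pl_width and self.pl_width < pool_set.L:
            if self.dictionary is not None:
                raise ValueError(
                    "partition-ligation builds per-block dictionaries; "
                    "pass dictionary=None when pl_width is set"
                )
            dictionary, X_hat, diag = solve_partition_ligation(
                pool_set, config, W=self.pl_width,
                support_threshold=self.support_threshold, variant=variant,
                merge_cap=self.merge_cap,
            )
        else:
            dictionary = self.dictionary
            if dictionary is None:
                if pool_set.L > self.dict_cap:
                    raise ValueError(
                        f"L={pool_set.L} exceeds the full-dictionary cap "
                        f"({self.dict_cap}); set pl_width to use "
                        "partition-ligation"
                    )
                dictionary = build_full_dictionary(pool_set.L, cap=self.dict_cap)
            solver = {"core": solve, "noisy": solve_noisy,
                      "missing": solve_missing}[variant]
            X_hat, diag = solver(pool_set, dictionary, config)

        self.variant_ = variant
        self.dictionary_ = dictionary
        self.proportions_ = X_hat
        self.sizes_ = pool_set.sizes
        dist = aggregate_population_frequencies(X_hat, pool_set.sizes, dictionary)
        self.frequencies_ = dist.freqs
        self.labels_ = dictionary.labels
        self.diagnostics_ = diag
        self.n_iter_ = diag.n_iter if diag is not None else 0
        return self

    def population_distribution(self):
        """The fitted population frequencies as a :class:`FrequencyDistribution`."""
        from .simulate import FrequencyDistribution

        self._check_fitted()
        return FrequencyDistribution(haplotypes=self.labels_, freqs=self.frequencies_)

    def top_haplotypes(self, threshold: float | None = None) -> pd.Series:
        """Haplotypes with population frequency above the support threshold,
        sorted by frequency descending."""
        self._check_fitted()
        threshold = self.support_threshold if threshold is None else threshold
        s = pd.Series(self.frequencies_, index=list(self.labels_), name="frequency")
        return s[s > threshold].sort_values(ascending=False)

    def _check_fitted(self) -> None:
        if not hasattr(self, "frequencies_"):
            raise AttributeError("estimator is not fitted; call fit first")


def estimate_frequencies(pool_set: PoolSet, **params) -> pd.Series:
    """One-call convenience wrapper: fit and return the thresholded estimate."""
    est = PooledHaplotypeFrequencies(**params).fit(pool_set)
    return est.top_haplotypes()
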