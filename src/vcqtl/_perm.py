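"""Genome-wide permutation helpers shared by the variance and covariance scans.

The family-wise null is the distribution of the per-scan maximum statistic:
each permutation shuffles whole phenotype rows (single trait values or full
trait vectors) against the genotype matrix, the statistic is recomputed at
every marker, and the genome-wide maximum is recorded. A marker's p-value is
the fraction of permutation maxima that reach or exceed its observed
statistic (ties count as exceeding).
"""

from __future__ import annotations

import numpy as np


def permutation_indices(n: int, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n, n_perm) matrix whose columns are independent permutations of 0..n-1."""
    idx = np.empty((n, n_perm), dtype=np.intp)
    for b in range(n_perm):
        idx[:, b] = rng.permutation(n)
    return idx


def perm_pvalues(observed: np.ndarray, maxima: np.ndarray,
                 add_one: bool = False) -> np.ndarray:
    """Genome-wide p-values from the permutation-maximum null.

    With ``add_one`` the observed scan is counted among the permutations
    (guaranteeing p > 0); the default reports the raw exceedance fraction,
    which can be exactly zero.
    """
    observed = np.asarray(observed, float)
    maxima = np.sort(np.asarray(maxima, float))
    n_perm = maxima.size
    # count maxima >= obs via right-side search on the sorted maxima
    n_ge = n_perm - np.searchsorted(maxima, observed, side="left")
    if add_one:
        return (n_ge + 1.0) / (n_perm + 1.0)
    return n_ge / float(n_perm)
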