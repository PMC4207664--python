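"""Mapping QTL that alter multi-trait covariance structure.

At every marker the family-mean trait vectors are split by homozygote class
and the two within-class covariance (G) matrices are compared by:

* a trace-form Box's M — ``N*ln(S) - sum(V_i*ln(S_i))`` with ``S_i`` the
  trace of class i's matrix and ``S`` the degrees-of-freedom-weighted pooled
  trace — contrasting the overall multivariate "volume" (size) of the two
  matrices;
* the angle between the leading eigenvectors (G_max), folded into
  [0, pi/2] because eigenvectors are axes, contrasting orientation;
* the Krzanowski common-subspace index — the sum of eigenvalues of
  ``A^T B B^T A`` for the first-k-eigenvector bases A, B — contrasting
  whole k-dimensional subspaces (scanned as its negative so that larger
  means more dissimilar).

Genome-wide significance for each statistic comes from the same
maximum-statistic permutation null as the variance scan, with whole trait
vectors shuffled against the genotype rows so inter-trait correlations are
preserved under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._perm import perm_pvalues, permutation_indices
from .dataio import CO, MT, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("vcqtl")

METHODS = ("boxm", "gmax_angle", "krzanowski")


@dataclass
class GMatrixPair:
    """Within-class covariance matrices at one marker, with degrees of freedom."""

    G_CO: np.ndarray
    G_MT: np.ndarray
    V_CO: int            # n_CO - 1
    V_MT: int            # n_MT - 1
    trait_ids: list[str]

    def __post_init__(self):
        self.G_CO = np.atleast_2d(np.asarray(self.G_CO, float))
        self.G_MT = np.atleast_2d(np.asarray(self.G_MT, float))
        if self.G_CO.shape != self.G_MT.shape:
            raise ValueError("G matrices must have equal dimensions")
        for g, name in ((self.G_CO, "G_CO"), (self.G_MT, "G_MT")):
            if not np.allclose(g, g.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
        if min(self.V_CO, self.V_MT) < 1:
            raise ValueError("each class needs at least 2 families (V_i >= 1)")

    @property
    def n_traits(self) -> int:
        return self.G_CO.shape[0]


def estimate_g_pair(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                    marker: str, trait_ids,
                    min_class: int = 3) -> GMatrixPair:
    """Sample covariance of family-mean trait vectors within each class.

    Families with any missing value in the trait set are dropped
    (complete-case); a class with fewer than ``min_class`` complete families
    raises ValueError (scans skip such markers with a warning).
    """
    trait_ids = list(trait_ids)
    T = np.column_stack([phenotypes.values_for(t, genotypes.families)
                         for t in trait_ids])
    complete = np.isfinite(T).all(axis=1)
    col = genotypes.column(marker)
    rows_co = complete & (col == CO)
    rows_mt = complete & (col == MT)
    n_co, n_mt = int(rows_co.sum()), int(rows_mt.sum())
    if min(n_co, n_mt) < min_class:
        raise ValueError(
            f"marker {marker!r}: class sizes {n_co}/{n_mt} below "
            f"minimum {min_class} complete families")
    g_co = np.cov(T[rows_co], rowvar=False, ddof=1)
    g_mt = np.cov(T[rows_mt], rowvar=False, ddof=1)
    return GMatrixPair(np.atleast_2d(g_co), np.atleast_2d(g_mt),
                       n_co - 1, n_mt - 1, trait_ids)


def boxs_m(pair: GMatrixPair, form: str = "trace") -> float:
    """Box's M comparing the size of the two G matrices.

    The default trace form is ``N*ln(S) - V_CO*ln(S_CO) - V_MT*ln(S_MT)``
    with S_i = trace(G_i) and S their df-weighted mean; it is non-negative,
    zero iff the traces are equal, and invariant to rescaling both matrices
    by a common factor. ``form="det"`` gives the classical determinant-based
    statistic on the pooled matrix instead.
    """
    v1, v2 = pair.V_CO, pair.V_MT
    n = v1 + v2
    if form == "trace":
        s1 = float(np.trace(pair.G_CO))
        s2 = float(np.trace(pair.G_MT))
        if s1 <= 0 or s2 <= 0:
            raise ValueError("Box's M (trace form) requires positive traces")
        s = (v1 * s1 + v2 * s2) / n
        return n * np.log(s) - v1 * np.log(s1) - v2 * np.log(s2)
    if form == "det":
        pooled = (v1 * pair.G_CO + v2 * pair.G_MT) / n
        sign, logdet_p = np.linalg.slogdet(pooled)
        s1, l1 = np.linalg.slogdet(pair.G_CO)
        s2, l2 = np.linalg.slogdet(pair.G_MT)
        if min(sign, s1, s2) <= 0:
            raise ValueError("Box's M (det form) requires positive-definite "
                             "matrices")
        return n * logdet_p - v1 * l1 - v2 * l2
    raise ValueError(f"unknown Box's M form {form!r}")


def leading_eigenvector(g: np.ndarray) -> np.ndarray:
    """Unit leading eigenvector with its largest-magnitude component positive."""
    vals, vecs = np.linalg.eigh(np.atleast_2d(g))
    v = vecs[:, -1]
    pivot = np.argmax(np.abs(v))
    return v * np.sign(v[pivot]) if v[pivot] != 0 else v


def gmax_angle(pair: GMatrixPair) -> float:
    """Radian angle in [0, pi/2] between the two leading eigenvectors.

    The raw arccos angle between directed eigenvectors lies in [0, pi];
    because eigenvectors are axes, angles past pi/2 are reflected to
    pi - theta. The result is invariant to sign flips of either eigenvector.
    """
    if not (np.any(pair.G_CO) and np.any(pair.G_MT)):
        raise ValueError("G_max angle undefined for a zero matrix")
    u = leading_eigenvector(pair.G_CO)
    v = leading_eigenvector(pair.G_MT)
    cos = float(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    theta = float(np.arccos(np.clip(cos, -1.0, 1.0)))
    return np.pi - theta if theta > np.pi / 2 else theta


def _top_k_basis(g: np.ndarray, k: int) -> np.ndarray:
    """First k eigenvectors (descending eigenvalue), each scaled to unit norm."""
    _, vecs = np.linalg.eigh(g)
    basis = vecs[:, ::-1][:, :k]
    return basis / np.linalg.norm(basis, axis=0, keepdims=True)


def krzanowski_index(pair: GMatrixPair, k: int) -> float:
    """Subspace-overlap index between the first-k-eigenvector subspaces.

    With A and B the matrices of the first k (unit-normalized) eigenvectors
    of each G matrix, the index is the sum of eigenvalues of the similarity
    matrix S = A^T B B^T A, which equals trace(S) = ||B^T A||_F^2; it ranges
    from 0 (orthogonal subspaces) to k (identical subspaces) and depends only
    on the subspaces, not the bases chosen within them.
    """
    p = pair.n_traits
    if not 1 <= k <= p // 2:
        raise ValueError(f"k must satisfy 1 <= k <= floor(p/2) = {p // 2}, "
                         f"got {k}")
    a = _top_k_basis(pair.G_CO, k)
    b = _top_k_basis(pair.G_MT, k)
    return float(np.sum((a.T @ b) ** 2))


def _class_moments(T3: np.ndarray, idx: np.ndarray, full: bool):
    """Mean-centred second moments for one class across a permutation batch.

    T3: (n_fam, B, p) permuted trait arrays; idx: class row indices.
    Returns per-trait variances (B, p) and, if ``full``, covariance
    matrices (B, p, p), both with ddof=1.
    """
    x = T3[idx]                               # (ni, B, p)
    ni = idx.size
    mu = x.mean(axis=0)
    xc = x - mu
    var = (xc ** 2).sum(axis=0) / (ni - 1)
    if not full:
        return var, None
    cov = np.einsum("nbp,nbq->bpq", xc, xc) / (ni - 1)
    return var, cov


def _fold_angle(delta: np.ndarray) -> np.ndarray:
    d = np.mod(delta, np.pi)
    return np.minimum(d, np.pi - d)


def _cov_stats_batch(codes: np.ndarray, T3: np.ndarray, method: str,
                     k: int | None, min_class: int) -> np.ndarray:
    """Per-marker covariance-comparison statistics for a batch of trait arrays.

    Returns (n_mark, B); markers with a class below min_class are NaN.
    Krzanowski statistics are returned as the NEGATIVE index (dissimilarity).
    """
    n_fam, n_mark = codes.shape
    B, p = T3.shape[1], T3.shape[2]
    full = method != "boxm" and not (method == "gmax_angle" and p == 2)
    out = np.full((n_mark, B), np.nan)
    for j in range(n_mark):
        col = codes[:, j]
        i0 = np.flatnonzero(col == CO)
        i1 = np.flatnonzero(col == MT)
        n0, n1 = i0.size, i1.size
        if min(n0, n1) < min_class:
            continue
        var0, cov0 = _class_moments(T3, i0, full)
        var1, cov1 = _class_moments(T3, i1, full)
        v0, v1 = n0 - 1, n1 - 1
        if method == "boxm":
            s0 = var0.sum(axis=1)
            s1 = var1.sum(axis=1)
            s = (v0 * s0 + v1 * s1) / (v0 + v1)
            out[j] = (v0 + v1) * np.log(s) - v0 * np.log(s0) - v1 * np.log(s1)
        elif method == "gmax_angle" and p == 2:
            # closed-form major-axis orientation of a 2x2 covariance matrix
            def orient(var, t3, idx, nloc):
                x = t3[idx]
                xc = x - x.mean(axis=0)
                cxy = (xc[..., 0] * xc[..., 1]).sum(axis=0) / (nloc - 1)
                return 0.5 * np.arctan2(2.0 * cxy, var[:, 0] - var[:, 1])
            phi0 = orient(var0, T3, i0, n0)
            phi1 = orient(var1, T3, i1, n1)
            out[j] = _fold_angle(phi0 - phi1)
        else:
            vals0, vecs0 = np.linalg.eigh(cov0)
            vals1, vecs1 = np.linalg.eigh(cov1)
            if method == "gmax_angle":
                u = vecs0[:, :, -1]
                v = vecs1[:, :, -1]
                cos = np.abs(np.sum(u * v, axis=1))
                out[j] = np.arccos(np.clip(cos, 0.0, 1.0))
            elif method == "krzanowski":
                a = vecs0[:, :, ::-1][:, :, :k]     # (B, p, k)
                b = vecs1[:, :, ::-1][:, :, :k]
                cross = np.einsum("bpi,bpj->bij", a, b)
                out[j] = -np.sum(cross ** 2, axis=(1, 2))
            else:
                raise ValueError(f"unknown method {method!r}")
    return out


def scan_covariance(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait_set,
    method: str = "boxm",
    k: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
    min_class: int = 3,
    perm_chunk: int = 250,
) -> pd.DataFrame:
    """Genome-wide covariance-structure scan for one trait set.

    The permutation null shuffles whole family trait vectors against the
    genotype matrix (inter-trait correlation preserved) and records each
    permutation's genome-wide maximum statistic; for the Krzanowski method
    the scanned statistic is the negative index, so larger always means more
    dissimilar G matrices. Returns marker, linkage_group, cM, method,
    statistic, perm_p, n_CO, n_MT.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    trait_set = list(trait_set)
    p = len(trait_set)
    if method == "krzanowski":
        if p < 4:
            raise ValueError(
                "the Krzanowski method needs at least 4 traits (for 2-trait "
                "sets the G_max angle captures all orientation difference)")
        if k is None:
            k = p // 2
        if not 1 <= k <= p // 2:
            raise ValueError(f"k must satisfy 1 <= k <= floor(p/2) = {p // 2}")
    T = np.column_stack([phenotypes.values_for(t, genotypes.families)
                         for t in trait_set])
    complete = np.isfinite(T).all(axis=1)
    if (~complete).any():
        logger.info("scan_covariance: dropping %d families with incomplete "
                    "trait vectors", int((~complete).sum()))
    T = T[complete]
    codes = genotypes.codes[complete]
    n = T.shape[0]
    if n < 2 * min_class:
        raise ValueError("too few complete-case families for a scan")

    logger.info("scan_covariance(%s, p=%d): %d families, %d markers, "
                "%d permutations, seed=%s", method, p, n, codes.shape[1],
                n_perm, seed)
    observed = _cov_stats_batch(codes, T[:, None, :], method, k,
                                min_class)[:, 0]
    skipped = ~np.isfinite(observed)
    if skipped.any():
        warnings.warn(
            f"scan_covariance: {int(skipped.sum())} marker(s) skipped "
            f"(a class had fewer than {min_class} complete families)",
            UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        bc = min(perm_chunk, n_perm - done)
        perm = permutation_indices(n, bc, rng)
        T3 = T[perm]                       # (n, bc, p)
        stats = _cov_stats_batch(codes, T3, method, k, min_class)
        maxima[done:done + bc] = np.nanmax(stats, axis=0)
        done += bc
    pvals = perm_pvalues(observed, maxima, add_one=add_one)

    res = genotypes.map.table.copy()
    res["method"] = method
    res["statistic"] = observed
    res["perm_p"] = pvals
    res["n_CO"] = (codes == CO).sum(axis=0)
    res["n_MT"] = (codes == MT).sum(axis=0)
    return res[~skipped].reset_index(drop=True)


def confidence_ellipse(g: np.ndarray, mean=None, level: float = 0.95):
    """Parameters of the 2-D confidence ellipse of a 2x2 covariance matrix.

    Returns (center, semi_axes, angle_rad) using the chi-square(2) quantile;
    presentation helper only, not used by any statistic.
    """
    from scipy.stats import chi2

    g = np.atleast_2d(np.asarray(g, float))
    if g.shape != (2, 2):
        raise ValueError("confidence_ellipse needs a 2x2 covariance matrix")
    if mean is None:
        mean = np.zeros(2)
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    radius2 = chi2.ppf(level, df=2)
    semi = np.sqrt(np.maximum(vals, 0.0) * radius2)
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return np.asarray(mean, float), semi, angle
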