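"""Single-trait variance-QTL mapping.

At every marker the families are split into the two homozygote classes and
the Brown-Forsythe statistic (Levene's test centred on the class medians)
measures the difference in trait spread between the classes. Genome-wide
significance comes from the maximum-statistic permutation null; significant
markers can be decomposed into the share of total trait variance explained
by the class mean difference (Vm) versus the class variance difference (Vv).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._perm import perm_pvalues, permutation_indices
from .dataio import CO, MT, MISSING, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger("vcqtl")


class DegenerateGroupsError(ValueError):
    """Within-group median deviations are all zero: statistic undefined."""


def standardize(phenotypes: PhenotypeTable) -> PhenotypeTable:
    """Scale every trait column to mean 0, SD 1 over non-missing families.

    Uses the sample SD (ddof=1). Missing values are preserved. A trait with
    fewer than two non-missing values or zero spread is an error.
    """
    table = phenotypes.table.copy()
    for trait in table.columns:
        vals = table[trait].to_numpy(float)
        obs = np.isfinite(vals)
        if obs.sum() < 2:
            raise ValueError(f"trait {trait!r}: fewer than 2 non-missing values")
        sd = np.std(vals[obs], ddof=1)
        if sd == 0:
            raise ValueError(f"trait {trait!r}: zero standard deviation")
        table[trait] = (vals - vals[obs].mean()) / sd
    return PhenotypeTable(table, standardized=True,
                          parental_lines=list(phenotypes.parental_lines))


def filter_maf(genotypes: GenotypeMatrix,
               maf_min: float = 0.33) -> GenotypeMatrix:
    """Drop markers whose minor homozygote-class frequency is below maf_min.

    Frequencies are computed over non-missing calls; segregation-distorted
    markers yield unbalanced class sizes and unstable (co)variance estimates.
    """
    freq_mt = genotypes.allele_frequency(MT)
    maf = np.minimum(freq_mt, 1.0 - freq_mt)
    keep = maf >= maf_min
    dropped = [m for m, k in zip(genotypes.markers, keep) if not k]
    if dropped:
        logger.info("filter_maf: excluded %d/%d markers below MAF %.2f: %s",
                    len(dropped), len(keep), maf_min, dropped)
    if not keep.any():
        warnings.warn("filter_maf: no markers pass the MAF filter",
                      UserWarning, stacklevel=2)
    kept = [m for m, k in zip(genotypes.markers, keep) if k]
    return genotypes.subset_markers(kept)


def _bf_from_groups(z_list):
    """Levene-median F from per-group absolute deviations."""
    k = len(z_list)
    ns = np.array([len(z) for z in z_list], float)
    n_total = ns.sum()
    means = np.array([z.mean() for z in z_list])
    grand = float(sum(z.sum() for z in z_list)) / n_total
    num = (n_total - k) * float(np.sum(ns * (means - grand) ** 2))
    den = (k - 1) * float(sum(((z - m) ** 2).sum()
                              for z, m in zip(z_list, means)))
    if den == 0.0:
        raise DegenerateGroupsError(
            "all within-group median deviations are zero")
    return num / den


def brown_forsythe(group_co, group_mt) -> float:
    """Two-group Brown-Forsythe statistic (Levene's test on median deviations).

    z_ij = |y_ij - median(group i)|; the returned F is the one-way ANOVA F on
    the z values. Location shifts of either group leave it unchanged.
    """
    a = np.asarray(group_co, float)
    b = np.asarray(group_mt, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each genotype class needs at least 2 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    return _bf_from_groups([za, zb])


def _bf_scan_kernel(codes: np.ndarray, y_mat: np.ndarray) -> np.ndarray:
    """Brown-Forsythe F at every marker for a batch of trait vectors.

    codes: (n_fam, n_mark) int8 genotype codes; y_mat: (n_fam, B) trait
    columns (observed scan and/or permutations). Returns (n_mark, B).
    Markers where a class has < 2 non-missing calls yield NaN.
    """
    n_fam, n_mark = codes.shape
    B = y_mat.shape[1]
    out = np.full((n_mark, B), np.nan)
    for j in range(n_mark):
        col = codes[:, j]
        i0 = np.flatnonzero(col == CO)
        i1 = np.flatnonzero(col == MT)
        n0, n1 = i0.size, i1.size
        if n0 < 2 or n1 < 2:
            continue
        y0 = y_mat[i0]                       # (n0, B)
        y1 = y_mat[i1]
        z0 = np.abs(y0 - np.median(y0, axis=0))
        z1 = np.abs(y1 - np.median(y1, axis=0))
        m0 = z0.mean(axis=0)
        m1 = z1.mean(axis=0)
        grand = (n0 * m0 + n1 * m1) / (n0 + n1)
        num = (n0 + n1 - 2) * (n0 * (m0 - grand) ** 2
                               + n1 * (m1 - grand) ** 2)
        den = ((z0 - m0) ** 2).sum(axis=0) + ((z1 - m1) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = num / den
        f[den == 0] = np.where(num[den == 0] > 0, np.inf, 0.0)
        out[j] = f
    return out


def scan_variance(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    n_perm: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> pd.DataFrame:
    """Genome-wide Brown-Forsythe scan with permutation p-values for one trait.

    Families with a missing trait value are dropped from the whole scan;
    missing genotype calls are dropped per marker. The permutation null
    shuffles the trait vector as a whole against the genotype rows and
    records each permutation's genome-wide maximum statistic; p-values are
    exceedance fractions of that null (ties count as exceeding; with
    ``add_one`` the observed scan is counted among the permutations).

    Returns a DataFrame with columns marker, linkage_group, cM, statistic,
    perm_p, n_CO, n_MT; markers with an empty class are skipped with a
    warning.
    """
    y_all = phenotypes.values_for(trait, genotypes.families)
    obs_mask = np.isfinite(y_all)
    if obs_mask.sum() < 4:
        raise ValueError(f"trait {trait!r}: too few non-missing families")
    if (~obs_mask).any():
        logger.info("scan_variance(%s): dropping %d families with missing "
                    "trait values", trait, int((~obs_mask).sum()))
    codes = genotypes.codes[obs_mask]
    y = y_all[obs_mask]

    logger.info("scan_variance(%s): %d families, %d markers, %d permutations,"
                " seed=%s", trait, codes.shape[0], codes.shape[1], n_perm,
                seed)
    observed = _bf_scan_kernel(codes, y[:, None])[:, 0]
    skipped = ~np.isfinite(observed)
    if skipped.any():
        warnings.warn(
            f"scan_variance: {int(skipped.sum())} marker(s) skipped "
            "(a genotype class had fewer than 2 values)",
            UserWarning, stacklevel=2)

    rng = np.random.default_rng(seed)
    perm = permutation_indices(codes.shape[0], n_perm, rng)
    perm_stats = _bf_scan_kernel(codes, y[perm])
    maxima = np.nanmax(perm_stats, axis=0)
    pvals = perm_pvalues(observed, maxima, add_one=add_one)

    n_co = (codes == CO).sum(axis=0)
    n_mt = (codes == MT).sum(axis=0)
    res = genotypes.map.table.copy()
    res["statistic"] = observed
    res["perm_p"] = pvals
    res["n_CO"] = n_co
    res["n_MT"] = n_mt
    return res[~skipped].reset_index(drop=True)


@dataclass
class VarianceDecomposition:
    """Share of total trait variance at a biallelic homozygous locus.

    Total variance pooling both classes splits exactly into the part due to
    the class-mean difference (Vm = p*q*(mu1-mu2)^2), the part due to the
    class-SD difference (Vv = p*q*(sigma1-sigma2)^2), and a remainder
    (Vr = (p*sigma1 + q*sigma2)^2), with p + q = 1 the class frequencies.
    """

    p: float
    q: float
    mu_CO: float
    mu_MT: float
    sigma_CO: float
    sigma_MT: float
    Vm: float
    Vv: float
    Vr: float
    Vp: float

    @property
    def Vm_over_Vp(self) -> float:
        return self.Vm / self.Vp

    @property
    def Vv_over_Vp(self) -> float:
        return self.Vv / self.Vp


def decompose_variance(group_co, group_mt) -> VarianceDecomposition:
    """Decompose pooled trait variance at a locus into Vm, Vv and Vr shares."""
    a = np.asarray(group_co, float)
    b = np.asarray(group_mt, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each genotype class needs at least 2 values")
    n = a.size + b.size
    p = a.size / n
    q = b.size / n
    mu1, mu2 = a.mean(), b.mean()
    s1 = a.std(ddof=1)
    s2 = b.std(ddof=1)
    if s1 == 0 and s2 == 0 and mu1 == mu2:
        raise DegenerateGroupsError("both classes are constant and equal")
    vm = p * q * (mu1 - mu2) ** 2
    vv = p * q * (s1 - s2) ** 2
    vr = (p * s1 + q * s2) ** 2
    return VarianceDecomposition(p=p, q=q, mu_CO=mu1, mu_MT=mu2,
                                 sigma_CO=s1, sigma_MT=s2,
                                 Vm=vm, Vv=vv, Vr=vr, Vp=vm + vv + vr)


def decompose_at_marker(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
                        trait: str, marker: str) -> VarianceDecomposition:
    """Vm/Vv decomposition at one marker for one trait."""
    y = phenotypes.values_for(trait, genotypes.families)
    col = genotypes.column(marker)
    ok = np.isfinite(y)
    return decompose_variance(y[ok & (col == CO)], y[ok & (col == MT)])


def pairwise_epistasis(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    focal_marker: str,
    partner_markers,
) -> pd.DataFrame:
    """Two-way fixed-effects interaction ANOVA between a focal locus and partners.

    For each partner marker, fits trait ~ focal + partner + focal:partner on
    family means (complete cases for both calls) and reports the interaction
    F and p. Partners with any empty genotype cell (including the focal
    marker itself) are skipped with a warning.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = phenotypes.values_for(trait, genotypes.families)
    focal = genotypes.column(focal_marker)
    rows = []
    for partner in partner_markers:
        part = genotypes.column(partner)
        ok = np.isfinite(y) & (focal != MISSING) & (part != MISSING)
        cells = {(f, p) for f, p in zip(focal[ok], part[ok])}
        if len(cells) < 4:
            warnings.warn(
                f"pairwise_epistasis: partner {partner!r} skipped "
                "(empty or confounded genotype cell)",
                UserWarning, stacklevel=2)
            continue
        df = pd.DataFrame({"y": y[ok],
                           "focal": np.where(focal[ok] == CO, "CO", "MT"),
                           "partner": np.where(part[ok] == CO, "CO", "MT")})
        fit = ols("y ~ C(focal) * C(partner)", data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        inter = anova.loc["C(focal):C(partner)"]
        rows.append((partner, float(inter["F"]), float(inter["PR(>F)"])))
    return pd.DataFrame(rows, columns=["partner", "interaction_F",
                                       "interaction_p"])
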