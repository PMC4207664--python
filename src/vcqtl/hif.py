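"""Heterogeneous-inbred-family (HIF) analyses.

A HIF panel contrasts the two homozygotes of one focal locus against a set
of otherwise (nearly) constant genomic backgrounds, so a focal-genotype by
HIF interaction is a direct test of locus-by-background epistasis. The
module fits REML linear mixed models of the form

    response ~ genotype + HIF + genotype:HIF   (fixed)
             + family + block                  (independent random intercepts)

reporting marginal (Type III) F statistics for the fixed terms with
containment denominator degrees of freedom, and likelihood-ratio chi-square
tests (1 df, comparing restricted likelihoods of fits with and without the
term) for the random terms. The same machinery drives the qPCR expression
model on ΔCt and the visible-bud/expression association.

The REML fit maximises the restricted likelihood profiled over the error
variance, working on the variance ratios gamma_t = sigma_t^2/sigma_e^2 in a
low-rank (Woodbury) form, with explicit boundary candidates so variance
components estimated at zero are handled exactly. Full and reduced models
for the LRTs are evaluated on the one likelihood scale of ``reml_loglike``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "delta_ct", "relative_expression", "fit_mixed_anova",
    "fit_hif_mixed_model", "fit_expression_model", "test_bud_association",
    "holm_bonferroni", "reml_loglike",
]


def delta_ct(ct_act2, ct_ft):
    """ΔCt = reference-gene Ct minus target Ct.

    In the qPCR convention used here the reference amplifies earlier, so ΔCt
    is negative and a larger (less negative) ΔCt means higher target
    expression. ΔCt itself, not 2**ΔCt, is the analysis response (2**ΔCt is
    log-skewed across samples).
    """
    return np.asarray(ct_act2, float) - np.asarray(ct_ft, float)


def relative_expression(dct):
    """Relative target/reference signal, 2**ΔCt."""
    return 2.0 ** np.asarray(dct, float)


def holm_bonferroni(pvalues) -> np.ndarray:
    """Sequential-Bonferroni (Holm) adjusted p-values."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def reml_loglike(y, X, Z_list, variances, sigma2) -> float:
    """Restricted log-likelihood of a Gaussian mixed model.

    V = sigma2*I + sum(var_t * Z_t Z_t'); the value is
    -0.5*[log|V| + log|X'V^-1 X| + r'V^-1 r + (n-p)*log(2*pi)] with r the
    GLS residual.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    V = sigma2 * np.eye(n)
    for Z, var in zip(Z_list, variances):
        if var > 0:
            V += var * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    xvx = X.T @ Vi_X
    sign, logdet_xvx = np.linalg.slogdet(xvx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(xvx, X.T @ Vi_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    return -0.5 * (logdet_v + logdet_xvx + quad
                   + (n - p) * np.log(2.0 * np.pi))


def _random_design(data: pd.DataFrame, factor: str) -> np.ndarray:
    return pd.get_dummies(data[factor]).to_numpy(float)


class _RemlProblem:
    """Profiled restricted likelihood of y = Xb + sum(u_t) + e in low-rank form.

    With gamma_t = sigma_t^2/sigma_e^2 and Z the concatenated random-effect
    indicator columns, V = sigma_e^2 * W, W = I + Z diag(gamma) Z'. All W
    solves reduce to a q x q system (q = total random levels), and the error
    variance profiles out as sigma_e^2 = r'W^-1 r / (n - p).
    """

    def __init__(self, y, X, Z_list):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        self.Z_list = [np.asarray(Z, float) for Z in Z_list]
        self.sizes = [Z.shape[1] for Z in self.Z_list]
        Z = np.hstack(self.Z_list) if self.Z_list else np.zeros((self.n, 0))
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ self.X
        self.Zty = Z.T @ self.y
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _w_pieces(self, gammas):
        g = np.concatenate([np.full(m, gam)
                            for m, gam in zip(self.sizes, gammas)]) \
            if self.sizes else np.zeros(0)
        active = g > 0
        if not active.any():
            return (self.XtX, self.Xty, self.yty, 0.0)
        s = np.sqrt(g[active])
        M = np.eye(active.sum()) + (s[:, None] * self.ZtZ[np.ix_(active, active)]
                                    * s[None, :])
        L = np.linalg.cholesky(M)
        logdet_w = 2.0 * np.sum(np.log(np.diag(L)))
        SX = s[:, None] * self.ZtX[active]
        Sy = s * self.Zty[active]
        AX = np.linalg.solve(M, SX)
        Ay = np.linalg.solve(M, Sy)
        xwx = self.XtX - SX.T @ AX
        xwy = self.Xty - SX.T @ Ay
        ywy = self.yty - float(Sy @ Ay)
        return (xwx, xwy, ywy, logdet_w)

    def profile(self, gammas):
        """(restricted llf, sigma_e^2, beta, cov_beta) at given variance ratios."""
        xwx, xwy, ywy, logdet_w = self._w_pieces(gammas)
        sign, logdet_xwx = np.linalg.slogdet(xwx)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'W^-1X not positive definite")
        beta = np.linalg.solve(xwx, xwy)
        rss_w = max(ywy - float(beta @ xwy), 1e-300)
        df = self.n - self.p
        sigma2 = rss_w / df
        llf = -0.5 * (self.n * np.log(sigma2) + logdet_w
                      + logdet_xwx - self.p * np.log(sigma2)
                      + df + df * np.log(2.0 * np.pi))
        cov_beta = np.linalg.inv(xwx) * sigma2
        return llf, sigma2, beta, cov_beta

    def fit(self):
        """Maximise over the gamma vector, checking every zero-boundary subset."""
        k = len(self.Z_list)
        if k == 0:
            llf, sigma2, beta, cov = self.profile(())
            return np.zeros(0), sigma2, llf, beta, cov

        def negll(log_g, mask):
            g = np.zeros(k)
            g[mask] = np.exp(np.clip(log_g, -30.0, 30.0))
            try:
                return -self.profile(g)[0]
            except np.linalg.LinAlgError:
                return np.inf

        best = (-np.inf, np.zeros(k))
        for mask_bits in range(2 ** k):
            mask = np.array([(mask_bits >> i) & 1 for i in range(k)],
                            dtype=bool)
            if not mask.any():
                cand = np.zeros(k)
                val = -negll(np.zeros(0), mask)
                if val > best[0]:
                    best = (val, cand)
                continue
            for start in (-2.0, 0.0, 2.0):
                x0 = np.full(int(mask.sum()), start)
                res = minimize(negll, x0, args=(mask,), method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 4000})
                if -res.fun > best[0]:
                    g = np.zeros(k)
                    g[mask] = np.exp(np.clip(res.x, -30.0, 30.0))
                    best = (-res.fun, g)
        llf, sigma2, beta, cov = self.profile(best[1])
        variances = best[1] * sigma2
        # ratios driven to the clip floor are boundary zeros
        variances[best[1] < 1e-12] = 0.0
        return variances, sigma2, llf, beta, cov


def _rank(mat: np.ndarray) -> int:
    return int(np.linalg.matrix_rank(mat))


def _containment_df(term_factors: set, random_specs: dict, X, Z_map,
                    resid_df: int) -> int:
    """SAS-style containment denominator df.

    A fixed term is tested against the first random effect whose declared
    factor set contains the term's factors (its df being that random
    effect's rank contribution beyond the fixed design); otherwise against
    the residual.
    """
    for name, spec in random_specs.items():
        if term_factors <= spec["factors"]:
            Z = Z_map[name]
            return _rank(np.hstack([X, Z])) - _rank(X)
    return resid_df


def _term_factors(patsy_term_name: str) -> set:
    """Factor columns in a patsy term name like 'C(a, Sum):C(b, Sum)'."""
    factors = set()
    for part in patsy_term_name.split(":"):
        part = part.strip()
        if part.startswith("C("):
            factors.add(part[2:].split(",")[0].split(")")[0].strip())
        elif part and part != "Intercept":
            factors.add(part)
    return factors


def fit_mixed_anova(data: pd.DataFrame, response: str, fixed_formula: str,
                    term_map: dict, random_specs: dict) -> pd.DataFrame:
    """REML mixed-model ANOVA with Type III fixed tests and random-term LRTs.

    Parameters
    ----------
    data, response
        Long-format table and the response column name.
    fixed_formula
        patsy right-hand side for the fixed effects, in sum-to-zero coding
        so the marginal (Type III) tests are meaningful.
    term_map
        fixed term label -> set of factor names it involves.
    random_specs
        random term label -> {"factor": grouping column, "factors": factor
        set used by the containment rule}.

    Returns a DataFrame with one row per fixed term (F, num_df, den_df, p)
    and one per random term (chi2 with 1 df from the REML likelihood-ratio
    test; a variance on the zero boundary gives chi2 = 0 and p = 1). The
    fitted variance components are attached in ``.attrs``.
    """
    data = data.reset_index(drop=True)
    y = np.asarray(data[response], float)
    design = patsy.dmatrix(fixed_formula, data, return_type="dataframe")
    X = design.to_numpy(float)
    term_slices = design.design_info.term_name_slices

    names = list(random_specs)
    Z_map = {name: _random_design(data, random_specs[name]["factor"])
             for name in names}
    Z_list = [Z_map[name] for name in names]

    var_arr, sigma2, llf_full, beta, cov_beta = \
        _RemlProblem(y, X, Z_list).fit()
    variances = dict(zip(names, var_arr))

    resid_df = len(y) - _rank(np.hstack([X] + Z_list) if Z_list else X)

    rows = []
    for label, factors in term_map.items():
        patsy_name = next(t for t in term_slices if _term_factors(t) == factors)
        idx = np.arange(X.shape[1])[term_slices[patsy_name]]
        b = beta[idx]
        c = cov_beta[np.ix_(idx, idx)]
        q = len(idx)
        if np.var(y) == 0:
            fstat = 0.0   # constant response carries no effect
        else:
            fstat = float(b @ np.linalg.solve(c, b)) / q
        den_df = _containment_df(factors, random_specs, X, Z_map, resid_df)
        pval = float(stats.f.sf(fstat, q, den_df))
        rows.append({"term": label, "kind": "fixed", "F": fstat,
                     "num_df": q, "den_df": den_df, "p": pval,
                     "chi2": np.nan, "chi2_df": np.nan})

    for name in names:
        reduced = [Z_map[k] for k in names if k != name]
        _, _, llf_red, _, _ = _RemlProblem(y, X, reduced).fit()
        chi2 = max(0.0, 2.0 * (llf_full - llf_red))
        pval = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
        rows.append({"term": f"{name} (random)", "kind": "random",
                     "F": np.nan, "num_df": np.nan, "den_df": np.nan,
                     "p": pval, "chi2": chi2, "chi2_df": 1})

    out = pd.DataFrame(rows)
    out.attrs["variance_components"] = variances
    out.attrs["residual_variance"] = sigma2
    out.attrs["reml_loglike"] = llf_full
    return out


def fit_hif_mixed_model(data: pd.DataFrame, response: str) -> pd.DataFrame:
    """Mixed-model ANOVA of one HIF phenotype.

    Fixed: focal genotype, HIF background, and their interaction (the
    epistasis test). Random: family and experimental block. Family is
    declared nested in HIF for the containment rule, so the HIF main effect
    is tested at the family level and the genotype terms at the residual
    level. A boundary variance of zero is reported (chi2 = 0), not an error.
    """
    hifs = data["HIF"].unique()
    if len(hifs) < 2:
        raise ValueError("need at least 2 HIFs for the interaction test")
    for h in hifs:
        genos = data.loc[data["HIF"] == h, "nFT_genotype"].unique()
        if len(genos) < 2:
            raise ValueError(f"HIF {h!r} lacks one of the genotype classes")
    return fit_mixed_anova(
        data, response,
        "C(nFT_genotype, Sum) * C(HIF, Sum)",
        term_map={"nFT": {"nFT_genotype"},
                  "HIF": {"HIF"},
                  "nFT x HIF": {"nFT_genotype", "HIF"}},
        random_specs={
            "Family": {"factor": "Family", "factors": {"Family", "HIF"}},
            "Block": {"factor": "Block", "factors": {"Block"}},
        })


def fit_expression_model(data: pd.DataFrame) -> pd.DataFrame:
    """Mixed-model ANOVA of qPCR ΔCt: genotype * HIF fixed, family random.

    All plants share one block, so there is no block term. Family is
    declared nested within genotype-by-HIF, so every fixed term is tested at
    the family level under containment.
    """
    hifs = data["HIF"].unique()
    if len(hifs) < 2:
        raise ValueError("need at least 2 HIFs for the interaction test")
    return fit_mixed_anova(
        data, "delta_Ct",
        "C(nFT_genotype, Sum) * C(HIF, Sum)",
        term_map={"nFT": {"nFT_genotype"},
                  "HIF": {"HIF"},
                  "nFT x HIF": {"nFT_genotype", "HIF"}},
        random_specs={
            "Family": {"factor": "Family",
                       "factors": {"Family", "HIF", "nFT_genotype"}},
        })


def test_bud_association(data: pd.DataFrame) -> pd.DataFrame:
    """Association between visible flowering buds and ΔCt (family random)."""
    states = data["Visible_bud"].unique()
    if len(states) < 2:
        raise ValueError("both bud states must be present")
    work = data.copy()
    work["Visible_bud"] = work["Visible_bud"].map({True: "yes", False: "no"})
    return fit_mixed_anova(
        work, "delta_Ct",
        "C(Visible_bud, Sum)",
        term_map={"Visible_bud": {"Visible_bud"}},
        random_specs={
            "Family": {"factor": "Family", "factors": {"Family"}},
        })
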