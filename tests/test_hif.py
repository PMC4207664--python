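import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import vcqtl as v
from vcqtl.hif import fit_mixed_anova, reml_loglike


class TestDeltaCt:
    def test_direct_formula(self):
        assert v.delta_ct(20, 25) == pytest.approx(-5.0)
        assert v.relative_expression(v.delta_ct(20, 25)) == pytest.approx(1 / 32)

    def test_equal_cts_zero(self):
        assert v.delta_ct(21.3, 21.3) == pytest.approx(0.0)

    def test_later_target_amplification_is_negative(self, rng):
        ct_ref = rng.uniform(18, 22, 20)
        ct_tgt = ct_ref + rng.uniform(0.5, 8, 20)
        assert (v.delta_ct(ct_ref, ct_tgt) < 0).all()


def test_holm_adjustment_hand_case():
    adj = v.holm_bonferroni([0.01, 0.04, 0.03])
    assert adj == pytest.approx([0.03, 0.06, 0.06])


def _fixed_effects_data(seed, fam_sd=0.0, block_sd=0.0, noise_sd=1.0,
                        n_hifs=2, fams=6, sibs=8, n_blocks=4):
    """Balanced HIF layout with configurable random-effect variances."""
    rng = np.random.default_rng(seed)
    cell_means = {("CO", i): 10.0 + 3 * i for i in range(n_hifs)}
    cell_means.update({("MT", i): 8.0 + 1.5 * i for i in range(n_hifs)})
    blocks = rng.normal(0, block_sd, n_blocks)
    rows = []
    for h in range(n_hifs):
        for f in range(fams):
            geno = "CO" if f % 2 == 0 else "MT"
            fam_dev = rng.normal(0, fam_sd)
            for s in range(sibs):
                b = s % n_blocks
                y = (cell_means[(geno, h)] + fam_dev + blocks[b]
                     + rng.normal(0, noise_sd))
                rows.append((f"B{b}", y, 1.0, 1.0 + y, geno, f"H{h}",
                             f"H{h}F{f}"))
    return pd.DataFrame(rows, columns=[
        "Block", "Flowering_time", "Leaf_number_at_flowering",
        "Height_at_flowering", "nFT_genotype", "HIF", "Family"])


class TestRemlFit:
    def test_reduces_to_ols_anova_when_variances_hit_zero(self):
        # pure fixed-effect data: both variance components estimate to the
        # boundary and the mixed F must equal ordinary Type III ANOVA F
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        data = _fixed_effects_data(seed=1)
        tab = v.fit_hif_mixed_model(data, "Flowering_time")
        vc = tab.attrs["variance_components"]
        assert vc["Family"] == 0.0 and vc["Block"] == 0.0
        fit = ols("Flowering_time ~ C(nFT_genotype, Sum) * C(HIF, Sum)",
                  data=data).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        ours = tab.set_index("term")
        assert ours.loc["nFT", "F"] == pytest.approx(
            ref.loc["C(nFT_genotype, Sum)", "F"], abs=1e-6)
        assert ours.loc["HIF", "F"] == pytest.approx(
            ref.loc["C(HIF, Sum)", "F"], abs=1e-6)
        assert ours.loc["nFT x HIF", "F"] == pytest.approx(
            ref.loc["C(nFT_genotype, Sum):C(HIF, Sum)", "F"], abs=1e-6)

    def test_components_match_grid_search_oracle(self):
        # brute-force maximizer of an independently coded restricted
        # likelihood on a tiny balanced one-way design
        rng = np.random.default_rng(8)
        n_fam, sibs = 6, 6
        fam = np.repeat(np.arange(n_fam), sibs)
        y = rng.normal(0, 1.5, n_fam)[fam] + rng.normal(0, 1.0, n_fam * sibs)
        data = pd.DataFrame({"y": y, "Family": [f"F{i}" for i in fam]})
        tab = fit_mixed_anova(data, "y", "1", term_map={},
                              random_specs={"Family": {
                                  "factor": "Family", "factors": {"Family"}}})
        est_vf = tab.attrs["variance_components"]["Family"]
        est_s2 = tab.attrs["residual_variance"]

        X = np.ones((len(y), 1))
        Z = np.zeros((len(y), n_fam))
        Z[np.arange(len(y)), fam] = 1.0

        def restricted_ll(vf, s2):
            V = s2 * np.eye(len(y)) + vf * Z @ Z.T
            Vi = np.linalg.inv(V)
            xvx = X.T @ Vi @ X
            beta = np.linalg.solve(xvx, X.T @ Vi @ y)
            r = y - X @ beta
            return -0.5 * (np.linalg.slogdet(V)[1]
                           + np.linalg.slogdet(xvx)[1]
                           + r @ Vi @ r
                           + (len(y) - 1) * np.log(2 * np.pi))

        # two-stage grid around the plausible range
        vf_grid = np.linspace(1e-6, 8, 60)
        s2_grid = np.linspace(0.05, 4, 60)
        lls = [[restricted_ll(a, b) for b in s2_grid] for a in vf_grid]
        i, j = np.unravel_index(np.argmax(lls), (60, 60))
        vf0, s20 = vf_grid[i], s2_grid[j]
        vf_grid = np.linspace(max(vf0 - 0.3, 1e-8), vf0 + 0.3, 60)
        s2_grid = np.linspace(max(s20 - 0.2, 1e-8), s20 + 0.2, 60)
        lls = [[restricted_ll(a, b) for b in s2_grid] for a in vf_grid]
        i, j = np.unravel_index(np.argmax(lls), (60, 60))
        assert est_vf == pytest.approx(vf_grid[i], rel=0.01, abs=0.01)
        assert est_s2 == pytest.approx(s2_grid[j], rel=0.01)

    def test_loglike_evaluator_matches_profiled_fit(self):
        # the dense-V evaluator and the low-rank profiled path agree
        data = _fixed_effects_data(seed=5, fam_sd=2.0)
        tab = v.fit_hif_mixed_model(data, "Flowering_time")
        import patsy
        from vcqtl.hif import _random_design
        y = data["Flowering_time"].to_numpy(float)
        X = patsy.dmatrix("C(nFT_genotype, Sum) * C(HIF, Sum)", data,
                          return_type="dataframe").to_numpy(float)
        Zf = _random_design(data, "Family")
        Zb = _random_design(data, "Block")
        vc = tab.attrs["variance_components"]
        dense = reml_loglike(y, X, [Zf, Zb], [vc["Family"], vc["Block"]],
                             tab.attrs["residual_variance"])
        assert dense == pytest.approx(tab.attrs["reml_loglike"], abs=1e-6)


class TestAgainstLmer:
    def test_f_statistics_match_lmertest(self, tmp_path):
        # independent oracle: R lme4/lmerTest REML fit with Type III tests
        assert shutil.which("Rscript"), "Rscript not on PATH"
        model = v.default_model(v.default_map())
        data = v.simulate_hif(model, n_hifs=3, families_per_hif=8,
                              sibs_per_family=6, n_blocks=4, seed=17,
                              hif_backgrounds=(1.0, 3.3, 0.6))
        csv = tmp_path / "hif.csv"
        data.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(Flowering_time ~ nFT_genotype*HIF + (1|Family) + (1|Block),
          data=d, REML=TRUE,
          control=lmerControl(check.conv.singular="ignore"))
a <- anova(m, type=3, ddf="Satterthwaite")
vc <- as.data.frame(VarCorr(m))
cat(jsonlite::toJSON(list(F=a$`F value`, vc=vc$vcov), digits=12))
""")
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        tab = v.fit_hif_mixed_model(data, "Flowering_time").set_index("term")
        # lmerTest rows: nFT_genotype, HIF, interaction
        assert tab.loc["nFT", "F"] == pytest.approx(ref["F"][0], rel=1e-4)
        assert tab.loc["HIF", "F"] == pytest.approx(ref["F"][1], rel=1e-4)
        assert tab.loc["nFT x HIF", "F"] == pytest.approx(ref["F"][2],
                                                          rel=1e-4)
        # variance components: Family, Block, residual (order per VarCorr)
        vc = tab.attrs["variance_components"]
        ours = sorted([vc["Family"], vc["Block"],
                       tab.attrs["residual_variance"]])
        assert ours == pytest.approx(sorted(ref["vc"]), rel=1e-3, abs=1e-6)


class TestLikelihoodRatioTests:
    def test_boundary_variance_gives_zero_chi2(self):
        data = _fixed_effects_data(seed=1)
        tab = v.fit_hif_mixed_model(data, "Flowering_time").set_index("term")
        assert tab.loc["Family (random)", "chi2"] == pytest.approx(0.0,
                                                                   abs=1e-6)
        assert tab.loc["Family (random)", "p"] == pytest.approx(1.0, abs=1e-4)

    def test_planted_family_variance_detected(self):
        data = _fixed_effects_data(seed=9, fam_sd=5.0, noise_sd=1.0)
        tab = v.fit_hif_mixed_model(data, "Flowering_time").set_index("term")
        assert tab.loc["Family (random)", "chi2"] > 10
        assert tab.loc["Family (random)", "p"] < 0.001


class TestModelContracts:
    def test_relabeling_invariance(self):
        data = _fixed_effects_data(seed=4, fam_sd=1.0, block_sd=1.0)
        base = v.fit_hif_mixed_model(data, "Flowering_time").set_index("term")
        relab = data.copy()
        relab["HIF"] = relab["HIF"].map({"H0": "zebra", "H1": "aardvark"})
        relab["nFT_genotype"] = relab["nFT_genotype"].map(
            {"CO": "MT", "MT": "CO"})
        out = v.fit_hif_mixed_model(relab, "Flowering_time").set_index("term")
        for term in ("nFT", "HIF", "nFT x HIF"):
            assert out.loc[term, "F"] == pytest.approx(base.loc[term, "F"],
                                                       rel=1e-6)

    def test_single_hif_error(self):
        data = _fixed_effects_data(seed=0, n_hifs=2)
        with pytest.raises(ValueError, match="2 HIF"):
            v.fit_hif_mixed_model(data[data["HIF"] == "H0"], "Flowering_time")

    def test_interaction_recovered_when_one_threshold_straddled(self,
                                                                full_map):
        # one background between the thresholds, one above both: the focal
        # genotype matters in the first HIF only -> detectable epistasis
        model = v.default_model(full_map)
        hits = 0
        n_seeds = 15
        for seed in range(n_seeds):
            data = v.simulate_hif(model, n_hifs=2, families_per_hif=10,
                                  sibs_per_family=6, n_blocks=3, seed=seed,
                                  hif_backgrounds=(1.1, 3.3))
            tab = v.fit_hif_mixed_model(data, "Flowering_time")
            hits += tab.set_index("term").loc["nFT x HIF", "p"] < 0.05
        assert hits >= n_seeds - 1


class TestExpressionModel:
    def test_null_interaction_p_roughly_uniform(self, full_map):
        # both backgrounds saturate the sigmoid: no true interaction
        model = v.default_model(full_map)
        pvals = []
        for seed in range(40):
            expr = v.simulate_expression(model, seed=seed,
                                         hif_backgrounds=(3.4, 4.2))
            tab = v.fit_expression_model(expr).set_index("term")
            pvals.append(tab.loc["nFT x HIF", "p"])
        assert 0.25 < np.mean(pvals) < 0.75
        assert sps.kstest(pvals, "uniform").pvalue > 0.005

    def test_straddling_background_gives_interaction(self, full_map):
        model = v.default_model(full_map)
        expr = v.simulate_expression(model, seed=6,
                                     hif_backgrounds=(0.9, 3.1),
                                     families_per_genotype=6)
        tab = v.fit_expression_model(expr).set_index("term")
        assert tab.loc["nFT x HIF", "p"] < 0.01


class TestBudAssociation:
    def test_null_bud_status_p_roughly_uniform(self):
        pvals = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            fam = np.repeat([f"F{i}" for i in range(10)], 4)
            dct = (np.repeat(rng.normal(0, 0.5, 10), 4)
                   + rng.normal(-6, 0.6, 40))
            bud = rng.random(40) < 0.5
            if bud.all() or not bud.any():
                continue
            data = pd.DataFrame({"Family": fam, "delta_Ct": dct,
                                 "Visible_bud": bud})
            tab = v.test_bud_association(data).set_index("term")
            pvals.append(tab.loc["Visible_bud", "p"])
        assert 0.25 < np.mean(pvals) < 0.75

    def test_true_association_detected(self, full_map):
        model = v.default_model(full_map)
        expr = v.simulate_expression(model, seed=13,
                                     hif_backgrounds=(0.9, 3.1))
        tab = v.test_bud_association(expr).set_index("term")
        assert tab.loc["Visible_bud", "p"] < 0.01

    def test_constant_response_zero_f(self):
        data = pd.DataFrame({
            "Family": ["F1", "F1", "F2", "F2"],
            "delta_Ct": [-5.0, -5.0, -5.0, -5.0],
            "Visible_bud": [True, False, True, False]})
        tab = v.test_bud_association(data).set_index("term")
        assert tab.loc["Visible_bud", "F"] == 0.0

    def test_single_bud_state_error(self):
        data = pd.DataFrame({"Family": ["F1", "F2"],
                             "delta_Ct": [-5.0, -6.0],
                             "Visible_bud": [True, True]})
        with pytest.raises(ValueError, match="bud"):
            v.test_bud_association(data)
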