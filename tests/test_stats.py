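"""Normalisation, assumption checks, REML mixed model, BIC comparison."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import symbiolipo.stats as st
from symbiolipo import (
    check_assumptions,
    compare_models_bic,
    fit_mixed_model,
    normalise_to_endosymbiont_mean,
    transform,
)


def two_group_data(seed=0, n_colonies=6, n_per=5, delta=0.0, colony_sd=0.5, resid_sd=1.0):
    """Balanced paired design: every colony contributes both cell types."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_colonies):
        eff = rng.normal(0, colony_sd)
        for ct, shift in (("endosymbiotic", 0.0), ("ex-symbiotic", delta)):
            for _ in range(n_per):
                rows.append(
                    {"colony": f"c{c}", "cell_type": ct, "y": eff + shift + rng.normal(0, resid_sd)}
                )
    return pd.DataFrame(rows)


class TestNormalisation:
    def test_hand_arithmetic(self):
        table = pd.DataFrame(
            {
                "species": ["s"] * 3,
                "cell_type": ["endosymbiotic", "endosymbiotic", "ex-symbiotic"],
                "lpo_ratio": [2.0, 4.0, 6.0],
                "lipid_volume_um3": [1.0, 1.0, 1.0],
            }
        )
        out = normalise_to_endosymbiont_mean(table)
        np.testing.assert_allclose(out["rel_lpo_ratio"], [2 / 3, 4 / 3, 2.0])

    def test_endosymbiont_rel_mean_is_one(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "species": np.repeat(["a", "b"], 20),
                "cell_type": "endosymbiotic",
                "lpo_ratio": rng.uniform(0.5, 3.0, 40),
                "lipid_volume_um3": rng.uniform(1, 50, 40),
            }
        )
        out = normalise_to_endosymbiont_mean(table)
        for _, grp in out.groupby("species"):
            assert grp["rel_lpo_ratio"].mean() == pytest.approx(1.0, abs=1e-9)
            assert grp["rel_lipid_volume_um3"].mean() == pytest.approx(1.0, abs=1e-9)

    def test_species_normalised_independently(self):
        rng = np.random.default_rng(2)
        base = pd.DataFrame(
            {
                "species": np.repeat(["a", "b"], 10),
                "cell_type": ["endosymbiotic", "ex-symbiotic"] * 10,
                "lpo_ratio": rng.uniform(0.5, 2, 20),
                "lipid_volume_um3": rng.uniform(1, 9, 20),
            }
        )
        out1 = normalise_to_endosymbiont_mean(base)
        scaled = base.copy()
        scaled.loc[scaled.species == "a", ["lpo_ratio", "lipid_volume_um3"]] *= 7.5
        out2 = normalise_to_endosymbiont_mean(scaled)
        sel = out1.species == "b"
        np.testing.assert_allclose(
            out1.loc[sel, "rel_lpo_ratio"], out2.loc[sel, "rel_lpo_ratio"]
        )

    def test_species_without_endosymbionts_named_in_error(self):
        table = pd.DataFrame(
            {
                "species": ["lonely"],
                "cell_type": ["ex-symbiotic"],
                "lpo_ratio": [1.0],
                "lipid_volume_um3": [1.0],
            }
        )
        with pytest.raises(ValueError, match="lonely"):
            normalise_to_endosymbiont_mean(table)


class TestAssumptions:
    def test_equal_dispersion_levene_near_one(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, 2000)
        groups = np.repeat(["a", "b"], 1000)
        rep = check_assumptions(values, groups)
        assert rep.levene_p > 0.2
        assert rep.normal

    def test_heavy_tails_rejected_by_shapiro(self):
        rejections = 0
        for seed in range(20):
            values = np.random.default_rng(seed).standard_cauchy(500)
            rep = check_assumptions(values, np.repeat(["a", "b"], 250))
            rejections += rep.shapiro_p < 0.05
        assert rejections >= 19  # >= 95% of seeds

    def test_levene_type_one_error_calibrated(self):
        # equal variances: rejection rate close to the nominal 5%
        hits = 0
        n_sim = 400
        for seed in range(n_sim):
            rng = np.random.default_rng(seed)
            values = rng.normal(0, 1, 60)
            rep = check_assumptions(values, np.repeat(["a", "b", "c"], 20))
            hits += rep.levene_p < 0.05
        assert abs(hits / n_sim - 0.05) < 0.03

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            check_assumptions(np.ones(10), np.repeat(["a", "b"], 5))


class TestTransform:
    def test_closed_forms(self):
        np.testing.assert_allclose(transform([1.0, np.e], "log"), [0.0, 1.0])
        np.testing.assert_allclose(transform([0.0, 4.0], "sqrt"), [0.0, 2.0])
        np.testing.assert_allclose(transform([3.0, -1.0], "none"), [3.0, -1.0])

    def test_log_rejects_nonpositive_and_lists_rows(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            transform([1.0, -2.0, 3.0], "log")

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown"):
            transform([1.0], "boxcox")


class TestMixedModel:
    def test_boundary_fit_matches_ols(self):
        # no colony structure at all -> variance at the zero boundary -> OLS
        data = two_group_data(seed=4, colony_sd=0.0, delta=1.0)
        fit = fit_mixed_model(data, "y", ["cell_type"])
        assert fit.boundary
        x = (data.cell_type == "ex-symbiotic").astype(float)
        ols = sps.linregress(x, data["y"])
        t_ols = ols.slope / ols.stderr
        got = fit.coef("cell_type[ex-symbiotic]")
        assert got["t"] == pytest.approx(t_ols, rel=1e-9)
        assert got["df"] == len(data) - 2
        assert got["p"] == pytest.approx(ols.pvalue, rel=1e-9)

    def test_variance_components_match_grid_search(self):
        data = two_group_data(seed=5, delta=0.8)
        fit = fit_mixed_model(data, "y", ["cell_type"])

        # independent oracle: dense REML loglik on a lambda grid
        X = np.column_stack([np.ones(len(data)), (data.cell_type == "ex-symbiotic").astype(float)])
        y = data["y"].to_numpy()
        Z = pd.get_dummies(data["colony"]).to_numpy(float)
        n, p = X.shape

        def reml(lam):
            V0 = np.eye(n) + lam * Z @ Z.T
            Vi = np.linalg.inv(V0)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            s2e = r @ Vi @ r / (n - p)
            return (
                -0.5
                * (
                    np.linalg.slogdet(V0)[1]
                    + np.linalg.slogdet(XtViX)[1]
                    + (n - p) * (np.log(s2e) + 1)
                ),
                s2e,
            )

        lams = np.linspace(1e-4, 10.0, 20001)
        lls = [reml(l)[0] for l in lams]
        best = lams[int(np.argmax(lls))]
        s2e = reml(best)[1]
        assert fit.sigma2_residual == pytest.approx(s2e, abs=1e-4)
        assert fit.sigma2_colony == pytest.approx(best * s2e, abs=1e-3)

    def test_satterthwaite_df_bounded_by_residual_df(self):
        data = two_group_data(seed=6, delta=0.5)
        fit = fit_mixed_model(data, "y", ["cell_type"])
        assert np.all(fit.dfs <= len(data) - 2 + 1e-9)
        assert np.all(fit.dfs > 0)

    def test_fixed_effect_recovery_unbiased(self):
        delta = 0.7
        estimates = [
            fit_mixed_model(two_group_data(seed=s, delta=delta), "y", ["cell_type"])
            .coef("cell_type[ex-symbiotic]")["estimate"]
            for s in range(60)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - delta) < 2 * se

    def test_colony_mean_mode_reduces_df(self):
        data = two_group_data(seed=7, n_colonies=4, n_per=8, delta=1.0)
        fit = fit_mixed_model(data, "y", ["cell_type"], mode="colony_mean")
        assert fit.n_obs == 8  # 4 colonies x 2 cell types
        assert fit.coef("cell_type[ex-symbiotic]")["df"] < 7

    def test_too_few_colonies_rejected(self):
        data = two_group_data(n_colonies=1)
        with pytest.raises(ValueError, match="colonies"):
            fit_mixed_model(data, "y", ["cell_type"])

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lmerTest_reference(self, tmp_path):
        """Estimates, SEs, Satterthwaite df and p must match R's lmerTest."""
        data = two_group_data(seed=8, delta=0.6)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = f"""
        suppressMessages(library(lmerTest))
        d <- read.csv("{csv}")
        m <- lmer(y ~ cell_type + (1|colony), data=d, REML=TRUE)
        co <- summary(m)$coefficients["cell_typeex-symbiotic", ]
        vc <- as.data.frame(VarCorr(m))$vcov
        cat(co[["Estimate"]], co[["Std. Error"]], co[["df"]], co[["t value"]],
            co[["Pr(>|t|)"]], vc[1], vc[2], sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        est, se, df, t, p, s2c, s2e = map(float, out.stdout.strip().split("\n"))
        fit = fit_mixed_model(data, "y", ["cell_type"])
        got = fit.coef("cell_type[ex-symbiotic]")
        assert got["estimate"] == pytest.approx(est, rel=1e-6)
        assert got["se"] == pytest.approx(se, rel=1e-6)
        assert got["df"] == pytest.approx(df, rel=1e-4)
        assert got["t"] == pytest.approx(t, rel=1e-6)
        assert got["p"] == pytest.approx(p, rel=1e-4)
        assert fit.sigma2_colony == pytest.approx(s2c, rel=1e-5)
        assert fit.sigma2_residual == pytest.approx(s2e, rel=1e-5)


class TestBICComparison:
    def make_data(self, seed=0, n=300, vol_beta=0.5, type_beta=0.8):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(1, 5, n)
        is_ex = rng.random(n) < 0.5
        y = 1.0 + vol_beta * vol + type_beta * is_ex + rng.normal(0, 0.3, n)
        return pd.DataFrame(
            {
                "lpo": y,
                "lipid_volume": vol,
                "cell_type": np.where(is_ex, "ex-symbiotic", "endosymbiotic"),
            }
        )

    def test_single_candidate_is_best(self):
        data = self.make_data()
        comp = compare_models_bic(data, "lpo", [("lipid_volume",)])
        assert comp.best_model == ("lipid_volume",)

    def test_bic_formula(self):
        data = self.make_data(n=50)
        comp = compare_models_bic(data, "lpo", [("lipid_volume",)])
        assert comp.bics[0] == pytest.approx(
            -2 * comp.logliks[0] + 3 * np.log(50)
        )  # intercept + slope + error variance

    def test_smaller_model_wins_when_extra_term_null(self):
        wins = 0
        n_sim = 40
        for seed in range(n_sim):
            data = self.make_data(seed=seed, type_beta=0.0, n=400)
            comp = compare_models_bic(
                data, "lpo", [("lipid_volume",), ("lipid_volume", "cell_type")]
            )
            wins += comp.best_model == ("lipid_volume",)
        assert wins / n_sim >= 0.8

    def test_both_effects_selects_full_model(self):
        wins = 0
        n_sim = 20
        for seed in range(n_sim):
            data = self.make_data(seed=seed, vol_beta=0.5, type_beta=0.8)
            comp = compare_models_bic(
                data,
                "lpo",
                [("lipid_volume",), ("cell_type",), ("lipid_volume", "cell_type")],
            )
            wins += comp.best_model == ("lipid_volume", "cell_type")
        assert wins / n_sim > 0.5

    def test_row_count_guard(self):
        data = self.make_data(n=30)
        data.loc[0, "lipid_volume"] = np.nan
        comp = compare_models_bic(data, "lpo", [("lipid_volume",), ("cell_type",)])
        assert comp.n_obs == 29  # shared complete-case rows for all candidates
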