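"""Mixed-model endpoint: estimation, sequential ANOVA, Satterthwaite df."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from smrnf.lmm import (
    PowerTrendModel,
    anova_type1,
    fit_lmm,
    partial_eta_squared,
    post_test_per_group,
    simulate_power_table,
)

FULL_TERMS = ["group", "condition", "runs", "group:condition", "group:runs",
              "condition:runs", "group:condition:runs"]


class TestPartialEtaSquared:
    def test_zero_f_gives_zero(self):
        assert partial_eta_squared(0.0, 1, 100) == 0.0

    def test_symmetric_point(self):
        assert partial_eta_squared(1.0, 1, 1) == pytest.approx(0.5)

    def test_f_conversion_arithmetic(self):
        # F(1,166) = 29.29 -> 29.29 / (29.29 + 166) = 0.15 to 2 dp
        assert partial_eta_squared(29.29, 1, 166) == pytest.approx(0.15, abs=0.005)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            partial_eta_squared(-1.0, 1, 10)


class TestNoiselessRecovery:
    def test_exact_fixed_effects_without_noise(self):
        """Pure fixed-effect data: estimates are exact to machine precision."""
        table = simulate_power_table(n_per_cell=4, group_slopes={"3D": 0.3, "2D": 0.3},
                                     sigma_intercept=0.0, sigma_slope=0.0,
                                     sigma_res=0.0, mu=5.0, seed=0)
        res = PowerTrendModel.from_power_table(table).fit(force_zero_variances=True)
        fe = res.fixed_effects
        # slope 0.3 on raw run = 0.3 on centred run; intercept absorbs 3.5*0.3
        assert fe["runs"] == pytest.approx(0.3, abs=1e-10)
        assert fe["Intercept"] == pytest.approx(5.0 + 0.3 * 3.5, abs=1e-10)
        assert fe["group:runs"] == pytest.approx(0.0, abs=1e-10)


class TestOLSOracle:
    def test_matches_closed_form_sequential_anova(self):
        """With variances forced to zero, Type I F equals statsmodels' OLS
        sequential ANOVA to 6 decimals and df equals n - p."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        table = simulate_power_table(n_per_cell=6, group_slopes={"3D": 0.2, "2D": 0.0},
                                     seed=11)
        res = PowerTrendModel.from_power_table(table).fit(force_zero_variances=True)
        ours = res.anova(ddf_method="residual")

        df = table.copy()
        df["g"] = df["group"].map({"3D": 1.0, "2D": -1.0})
        df["c"] = df["condition"].map({"real": 1.0, "sham": -1.0})
        df["r"] = df["run"] - 3.5
        ols = smf.ols("mean_power ~ g + c + r + g:c + g:r + c:r + g:c:r", df).fit()
        ref = anova_lm(ols, typ=1)
        ref_map = {"g": "group", "c": "condition", "r": "runs",
                   "g:c": "group:condition", "g:r": "group:runs",
                   "c:r": "condition:runs", "g:c:r": "group:condition:runs"}
        for r_name, name in ref_map.items():
            assert ours.loc[name, "F"] == pytest.approx(ref.loc[r_name, "F"], abs=1e-6)
            assert ours.loc[name, "df_den"] == ref.loc["Residual", "df"]

    def test_satterthwaite_df_reduces_to_residual_df_in_ols(self):
        table = simulate_power_table(n_per_cell=4, seed=5)
        res = PowerTrendModel.from_power_table(table).fit(force_zero_variances=True)
        an = res.anova()
        n_p = res.model.n_obs - res.model.n_fixed
        assert np.allclose(an["df_den"], n_p, rtol=1e-3)


class TestLmerTestOracle:
    def test_matches_lmertest_f_and_df(self, tmp_path):
        """Full REML + Type I Satterthwaite ANOVA agrees with lmerTest."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        table = simulate_power_table(n_per_cell=5, group_slopes={"3D": 0.2, "2D": 0.0},
                                     seed=3)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
d$g <- ifelse(d$group=="3D", 1, -1)
d$c <- ifelse(d$condition=="real", 1, -1)
d$r <- d$run - 3.5
m <- lmer(mean_power ~ g + c + r + g:c + g:r + c:r + g:c:r
          + (1|subject_id) + (0+r|subject_id), data=d, REML=TRUE)
a <- anova(m, type=1)
write.csv(data.frame(term=rownames(a), F=a[,"F value"], ddf=a[,"DenDF"]),
          "{tmp_path / 'ref.csv'}", row.names=FALSE)
""")
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.csv").set_index("term")
        ours = PowerTrendModel.from_power_table(table).fit().anova()
        name_map = {"g": "group", "c": "condition", "r": "runs",
                    "g:c": "group:condition", "g:r": "group:runs",
                    "c:r": "condition:runs", "g:c:r": "group:condition:runs"}
        for r_name, name in name_map.items():
            assert ours.loc[name, "F"] == pytest.approx(ref.loc[r_name, "F"], rel=1e-3)
            assert ours.loc[name, "df_den"] == pytest.approx(ref.loc[r_name, "ddf"], rel=0.02)


@pytest.fixture(scope="module")
def base_anova():
    table = simulate_power_table(n_per_cell=5, group_slopes={"3D": 0.15, "2D": 0.0},
                                 seed=21)
    return table, fit_lmm(table).anova()


class TestInvariances:

    def test_location_shift_leaves_f_unchanged(self, base_anova):
        table, an = base_anova
        shifted = table.copy()
        shifted["mean_power"] += 100.0
        an2 = fit_lmm(shifted).anova()
        # boundary fits leave a numerically flat REML surface; agreement is
        # limited by optimizer resolution rather than the invariance itself
        assert np.allclose(an["F"], an2["F"], rtol=1e-3)

    def test_positive_rescaling_leaves_f_unchanged(self, base_anova):
        table, an = base_anova
        scaled = table.copy()
        scaled["mean_power"] *= 7.3
        an2 = fit_lmm(scaled).anova()
        assert np.allclose(an["F"], an2["F"], rtol=1e-4)

    def test_satterthwaite_df_bounded_by_residual_df(self):
        for seed in range(3):
            table = simulate_power_table(n_per_cell=5, seed=seed)
            res = fit_lmm(table)
            an = res.anova()
            assert (an["df_den"] <= res.model.n_obs - res.model.n_fixed + 1e-9).all()
            assert (an["df_den"] > 0).all()


class TestParameterRecovery:
    def test_run_slope_estimates_unbiased(self):
        """Mean fixed-effect estimates over replicates track the generative
        values (3D amplitude-power slope 0.2, 2D 0.0 -> runs effect 0.1,
        group:runs effect 0.1)."""
        reps = 30
        runs_eff, gxr_eff = [], []
        for s in range(reps):
            table = simulate_power_table(n_per_cell=8,
                                         group_slopes={"3D": 0.2, "2D": 0.0},
                                         seed=1000 + s)
            fe = fit_lmm(table).fixed_effects
            runs_eff.append(fe["runs"])
            gxr_eff.append(fe["group:runs"])
        # effect coding: runs main = mean slope 0.1, group:runs = half diff 0.1
        assert np.mean(runs_eff) == pytest.approx(0.1, abs=0.02)
        assert np.mean(gxr_eff) == pytest.approx(0.1, abs=0.02)

    def test_variance_components_recovered(self):
        ests = []
        for s in range(20):
            table = simulate_power_table(n_per_cell=10, sigma_intercept=2.0,
                                         sigma_slope=0.3, sigma_res=0.5,
                                         seed=2000 + s)
            ests.append(fit_lmm(table).variance_components.values)
        mean = np.vstack(ests).mean(axis=0)
        assert mean[0] == pytest.approx(4.0, rel=0.35)  # sigma_intercept^2
        assert mean[1] == pytest.approx(0.09, rel=0.35)  # sigma_slope^2
        assert mean[2] == pytest.approx(0.25, rel=0.20)  # sigma_res^2


class TestPostTests:
    def test_constant_subjects_give_zero_runs_f(self):
        table = simulate_power_table(n_per_cell=5, sigma_intercept=1.0,
                                     sigma_slope=0.0, sigma_res=0.0, seed=2)
        res = post_test_per_group(table, "3D")
        assert res.anova().loc["runs", "F"] == pytest.approx(0.0, abs=1e-6)

    def test_groups_partition_subjects(self):
        table = simulate_power_table(n_per_cell=4, seed=9)
        a = post_test_per_group(table, "3D").model
        b = post_test_per_group(table, "2D").model
        all_ids = set(pd.unique(table["subject_id"]))
        seen = set(a.subject_ids) | set(b.subject_ids)
        assert seen == all_ids
        assert not (set(a.subject_ids) & set(b.subject_ids))

    def test_single_condition_subset_drops_condition_terms(self):
        table = simulate_power_table(n_per_cell=4, seed=13)
        sub = table[table["condition"] == "real"]
        res = PowerTrendModel.from_group_subset(sub, "3D").fit()
        assert res.model.term_names == ("runs",)

    def test_positive_slope_detected_in_effect_group(self):
        table = simulate_power_table(n_per_cell=14,
                                     group_slopes={"3D": 0.23, "2D": 0.0}, seed=31)
        res = post_test_per_group(table, "3D")
        assert res.fixed_effects["runs"] > 0
        assert res.anova().loc["runs", "p"] < 0.05


class TestEdgeCases:
    def test_boundary_slope_variance_flagged_singular_not_crash(self):
        table = simulate_power_table(n_per_cell=6, sigma_slope=0.0,
                                     sigma_res=0.3, seed=4)
        res = fit_lmm(table)
        assert res.converged
        an = res.anova()
        assert np.isfinite(an["F"]).all()

    def test_too_few_subjects_per_cell_rejected(self):
        table = simulate_power_table(n_per_cell=1, seed=0)
        with pytest.raises(ValueError):
            PowerTrendModel.from_power_table(table)

    def test_missing_runs_tolerated(self):
        table = simulate_power_table(n_per_cell=5, seed=8)
        thinned = table[~((table["subject_id"] == "S001") & (table["run"] > 4))]
        res = fit_lmm(thinned)
        assert np.isfinite(anova_type1(res)["F"]).all()

    def test_anova_wrapper_matches_results_method(self):
        table = simulate_power_table(n_per_cell=4, seed=6)
        res = fit_lmm(table)
        assert anova_type1(res).equals(res.anova())

    def test_summary_renders(self):
        table = simulate_power_table(n_per_cell=4, seed=6)
        text = fit_lmm(table).summary()
        assert "Type I ANOVA" in text and "group:runs" in text
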