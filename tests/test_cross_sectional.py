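"""Z-scoring, adjusted baseline models, group comparisons, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import braakadl as ba
from braakadl.regression import fit_adjusted_ols, zscore


def _frame(n, rng, groups=("0", "I-II", "III-IV", "V-VI")):
    df = pd.DataFrame(
        {
            "stage_group": rng.choice(groups, size=n),
            "age": rng.normal(70, 7, n),
            "sex": rng.choice(["female", "male"], size=n),
            "abeta_suvr": rng.normal(1.8, 0.5, n),
        }
    )
    return df


class TestZscore:
    def test_unit_spacing(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1], atol=1e-12)

    def test_two_values_hand_arithmetic(self):
        np.testing.assert_allclose(
            zscore([10, 20]), [-0.7071068, 0.7071068], atol=1e-6
        )

    def test_output_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore(rng.normal(5, 3, 100))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)

    def test_missing_propagates(self):
        z = zscore([1.0, np.nan, 3.0])
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2]]).all()

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])


class TestStageModel:
    def test_outcome_equal_to_age_gives_unit_beta(self):
        rng = np.random.default_rng(1)
        df = _frame(80, rng)
        df["y"] = df["age"]
        res = fit_adjusted_ols(df, "y", predictors={})
        assert res.term("age")["beta"] == pytest.approx(1.0, abs=1e-8)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-8)

    def test_two_group_closed_form(self):
        """Without covariates, a stage dummy's beta is the z-scored group
        mean difference."""
        rng = np.random.default_rng(2)
        df = _frame(60, rng, groups=("0", "V-VI"))
        df["y"] = rng.normal(0, 1, 60) + 2.0 * (df["stage_group"] == "V-VI")
        res = fit_adjusted_ols(df, "y", predictors={"stage_group": "group"},
                               covariates=())
        z = zscore(df["y"])
        expected = z[df["stage_group"] == "V-VI"].mean() - z[df["stage_group"] == "0"].mean()
        assert res.term("stage V-VI")["beta"] == pytest.approx(expected, abs=1e-10)

    def test_betas_invariant_to_affine_covariate_rescale(self):
        rng = np.random.default_rng(3)
        df = _frame(120, rng)
        df["y"] = rng.normal(0, 1, 120) + 0.8 * (df["stage_group"] == "V-VI")
        r1 = ba.fit_stage_model(df, "y")
        df2 = df.assign(age=12 * df["age"] + 7, abeta_suvr=0.1 * df["abeta_suvr"] - 3)
        r2 = ba.fit_stage_model(df2, "y")
        np.testing.assert_allclose(
            r1.terms["beta"].abs(), r2.terms["beta"].abs(), atol=1e-8
        )

    def test_missing_reference_level_errors(self):
        rng = np.random.default_rng(4)
        df = _frame(50, rng, groups=("I-II", "V-VI"))
        df["y"] = rng.normal(size=50)
        with pytest.raises(ValueError, match="reference"):
            ba.fit_stage_model(df, "y")

    def test_rank_deficiency_reports_collinear_terms(self):
        rng = np.random.default_rng(5)
        df = _frame(50, rng)
        df["y"] = rng.normal(size=50)
        df["abeta_suvr"] = df["age"]  # exact collinearity after z-scoring
        with pytest.raises(ValueError, match="collinear"):
            ba.fit_stage_model(df, "y")

    def test_ci_brackets_beta(self, default_cohort):
        res = ba.fit_stage_model(default_cohort.baseline(), "faq")
        t = res.terms
        assert (t["ci_low"] <= t["beta"]).all() and (t["beta"] <= t["ci_high"]).all()
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()
        assert res.n_used <= len(default_cohort.baseline())


class TestRoiModel:
    def test_outcome_equal_to_predictor_unit_slope(self):
        rng = np.random.default_rng(6)
        df = _frame(80, rng)
        df["suvr_braak_2"] = rng.normal(1.2, 0.3, 80)
        df["y"] = df["suvr_braak_2"]
        res = ba.fit_roi_suvr_model(df, "y", "suvr_braak_2", covariates=())
        assert res.term("suvr_braak_2")["beta"] == pytest.approx(1.0, abs=1e-10)

    def test_slope_recovery_and_null(self):
        rng = np.random.default_rng(7)
        betas, nulls = [], []
        for _ in range(200):
            n = 290
            x = rng.normal(size=n)
            df = pd.DataFrame(
                {
                    "suvr": x,
                    "age": rng.normal(70, 7, n),
                    "sex": rng.choice(["female", "male"], n),
                    "abeta_suvr": rng.normal(1.8, 0.5, n),
                    "y": 0.6 * x + 0.8 * rng.normal(size=n),
                    "y0": rng.normal(size=n),
                }
            )
            betas.append(
                ba.fit_roi_suvr_model(df, "y", "suvr").term("suvr")["beta"]
            )
            nulls.append(
                abs(ba.fit_roi_suvr_model(df, "y0", "suvr").term("suvr")["beta"])
            )
        assert np.mean(betas) == pytest.approx(0.6, abs=0.05)
        assert np.mean(np.asarray(nulls) < 0.2) >= 0.95


class TestGroupComparison:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame(
            {"stage_group": ["0"] * 3 + ["V-VI"] * 3, "y": [1, 2, 3, 1, 2, 3]}
        )
        gc = ba.compare_groups(df, "y")
        assert gc.anova_f == pytest.approx(0.0, abs=1e-12)
        assert (gc.pairwise["p_adj"] > 0.99).all()

    def test_pairwise_covers_all_six_pairs(self, default_cohort):
        gc = ba.compare_groups(default_cohort.baseline(), "faq")
        assert len(gc.pairwise) == 6

    def test_tiny_group_errors_with_name(self):
        df = pd.DataFrame({"stage_group": ["0", "0", "V-VI"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="V-VI"):
            ba.compare_groups(df, "y")

    def test_graded_means_power(self):
        """Means 0/0/0.5/1.5 (SD 1, n=50): ANOVA p<1e-4 and Tukey separates
        V-VI from 0 in nearly all replicates."""
        rng = np.random.default_rng(8)
        hits_p, hits_tk = 0, 0
        for _ in range(200):
            df = pd.DataFrame(
                {
                    "stage_group": np.repeat(["0", "I-II", "III-IV", "V-VI"], 50),
                    "y": np.concatenate(
                        [rng.normal(m, 1, 50) for m in (0, 0, 0.5, 1.5)]
                    ),
                }
            )
            gc = ba.compare_groups(df, "y")
            hits_p += gc.anova_p < 1e-4
            pw = gc.pairwise.set_index(["group1", "group2"])
            hits_tk += pw.loc[("0", "V-VI"), "p_adj"] < 0.05
        assert hits_p / 200 >= 0.99
        assert hits_tk / 200 >= 0.99


class TestDescribe:
    def test_constant_variable_skipped_with_reason(self, default_cohort):
        df = default_cohort.baseline().copy()
        df["education"] = 16.0
        desc = ba.describe_cohort(df)
        row = desc[desc["variable"] == "education"].iloc[0]
        assert np.isnan(row["p"]) and "skipped" in row["note"]

    def test_identical_sex_proportions_give_p_one(self):
        df = pd.DataFrame(
            {
                "stage_group": ["0"] * 50 + ["V-VI"] * 50,
                "sex": (["female"] * 30 + ["male"] * 20) * 2,
                "age": np.tile(np.linspace(60, 80, 50), 2),
            }
        )
        desc = ba.describe_cohort(df).set_index("variable")
        assert desc.loc["sex", "p"] == pytest.approx(1.0)

    def test_kruskal_p_uniform_under_null(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(300):
            df = pd.DataFrame(
                {
                    "stage_group": np.repeat(["0", "I-II", "III-IV", "V-VI"], 20),
                    "age": rng.normal(70, 7, 80),
                }
            )
            ps.append(ba.describe_cohort(df).set_index("variable").loc["age", "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_reports_missing_counts(self, default_cohort):
        df = default_cohort.baseline().copy()
        df.loc[df.index[:7], "mmse"] = np.nan
        desc = ba.describe_cohort(df).set_index("variable")
        assert desc.loc["mmse", "n_missing"] == 7
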