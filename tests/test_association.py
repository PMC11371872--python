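"""Region association models, information criteria, and model comparison."""

import numpy as np
import pandas as pd
import pytest

from mtlpath.association import (ComparisonResult, RegionAssociationModel,
                                 bonferroni_threshold, compare_models,
                                 information_criteria, prediction_error_l1,
                                 run_cohort_analyses)
from mtlpath.simulate import EffectSpec, generate_cohort

PATHOLOGY = ["tangles_q", "threads_q", "mtl_ptdp_rating"]


def compose_cohort(n_total, n_in, stage_col, stage_min, seed):
    """Cohort with an exact subgroup size, drawn from a large simulation."""
    pool = generate_cohort(1200, seed=seed)
    members = pool[pool[stage_col] >= stage_min].head(n_in)
    others = pool[pool[stage_col] < stage_min].head(n_total - n_in)
    assert len(members) == n_in and len(others) == n_total - n_in
    return pd.concat([members, others]).reset_index(drop=True)


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 6, 0.05 / 6), (0.05, 1, 0.05), (0.01, 10, 1e-3),
    ])
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 6)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRegionModel:
    def test_degrees_of_freedom_by_cohort_size(self, cohort140):
        # 3 pathology predictors + 4 nuisance (+ ICV for volumes) + intercept
        assert RegionAssociationModel(
            cohort140, "ERC", PATHOLOGY).fit().df_resid == 132
        assert RegionAssociationModel(
            cohort140, "AH", PATHOLOGY).fit().df_resid == 131

    def test_noiseless_fit_saturates(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        z = (x - x.mean()) / x.std(ddof=1)
        d = pd.DataFrame({"tangles_q": x, "thk_ERC": -0.5 * z})
        fit = RegionAssociationModel(d, "ERC", ["tangles_q"],
                                     covariates=[]).fit()
        # z-scored outcome: standardized beta is the correlation (-1);
        # the raw-scale slope recovers the planted -0.5
        assert fit.params["tangles_q"] == pytest.approx(-1.0)
        assert fit.pvalues_one_sided["tangles_q"] < 1e-12
        assert np.isfinite(fit.tvalues["tangles_q"])
        raw_slope = fit.params["tangles_q"] * d["thk_ERC"].std(ddof=1)
        assert raw_slope == pytest.approx(-0.5)

    def test_single_predictor_beta_is_pearson_correlation(self, cohort140):
        fit = RegionAssociationModel(cohort140, "ERC", ["tangles_q"],
                                     covariates=[]).fit()
        r = np.corrcoef(cohort140["tangles_q"], cohort140["thk_ERC"])[0, 1]
        assert fit.params["tangles_q"] == pytest.approx(r, abs=1e-10)

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        n = 18
        d = pd.DataFrame({
            "tangles_q": rng.uniform(0, 5, n),
            "age_at_death": rng.normal(75, 8, n),
            "thk_ERC": rng.normal(2.5, 0.5, n),
        })
        fit = RegionAssociationModel(d, "ERC", ["tangles_q"],
                                     covariates=["age_at_death"]).fit()
        z = lambda v: (v - v.mean()) / v.std(ddof=1)  # noqa: E731
        X = np.column_stack([np.ones(n), z(d["tangles_q"]),
                             z(d["age_at_death"])])
        y = z(d["thk_ERC"]).to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_rank_deficient_design_names_columns(self, cohort140):
        d = cohort140.copy()
        d["tangles_copy"] = d["tangles_q"]
        with pytest.raises(ValueError, match="tangles_copy"):
            RegionAssociationModel(d, "ERC", ["tangles_q", "tangles_copy"])

    def test_one_sided_type_one_error_near_nominal(self):
        # beta = 0, no confounding: p < 0.05 rate within the binomial band
        null = [EffectSpec(region="ERC", beta={"tangles_q": 0.0})]
        hits = 0
        for rep in range(500):
            c = generate_cohort(60, effects=null, seed=30_000 + rep)
            fit = RegionAssociationModel(c, "ERC", ["tangles_q"]).fit()
            hits += fit.pvalues_one_sided["tangles_q"] < 0.05
        assert 0.03 <= hits / 500 <= 0.07


class TestInformationCriteria:
    def test_identical_models_have_zero_deltas(self, cohort140):
        f1 = RegionAssociationModel(cohort140, "ERC", PATHOLOGY).fit()
        f2 = RegionAssociationModel(cohort140, "ERC", PATHOLOGY).fit()
        cmp = compare_models(f1, f2)
        assert cmp.delta_aicc == 0 and cmp.delta_bic == 0
        assert cmp.evidence_label == "none"

    def test_pure_noise_predictor_bic_penalty_is_log_n(self):
        # with RSS held equal, one extra coefficient costs ln(n) in BIC
        aicc_small, bic_small = information_criteria(50.0, 100, 3)
        aicc_big, bic_big = information_criteria(50.0, 100, 4)
        assert bic_big - bic_small == pytest.approx(np.log(100))
        assert aicc_big - aicc_small > 2.0  # 2 + small-sample correction

    def test_bic_matches_brute_force_formula(self, cohort140):
        fit = RegionAssociationModel(cohort140, "ERC", PATHOLOGY).fit()
        rss = float(fit.resid @ fit.resid)
        k = len(fit.predictor_names) + 1
        n = fit.n
        assert fit.bic == pytest.approx(
            n * np.log(rss / n) + k * np.log(n), abs=1e-10)
        aic = n * np.log(rss / n) + 2 * k
        assert fit.aicc == pytest.approx(
            aic + 2 * k * (k + 1) / (n - k - 1), abs=1e-10)

    def test_aicc_undefined_for_tiny_n(self):
        with pytest.raises(ValueError, match="AICc"):
            information_criteria(1.0, 5, 4)

    def test_l1_prediction_error(self, cohort140):
        fit = RegionAssociationModel(cohort140, "ERC", PATHOLOGY).fit()
        assert prediction_error_l1(fit) == pytest.approx(
            np.abs(fit.resid).sum(), abs=1e-10)
        fit.resid = np.array([1.0, -2.0, 0.5])
        assert prediction_error_l1(fit) == 3.5


class TestModelComparison:
    @pytest.mark.parametrize("dbic,label", [
        (0.0, "none"), (1.9, "none"), (2.5, "positive"), (7.0, "strong"),
        (-7.0, "strong"), (11.0, "very_strong"),
    ])
    def test_evidence_labels_from_bic_thresholds(self, dbic, label):
        cmp = ComparisonResult("ERC", 0.0, 0.0, 0.0, dbic)
        assert cmp.evidence_label == label

    def test_negative_bic_delta_favors_quantitative(self):
        assert ComparisonResult("ERC", 0.1, -1, -5, -7).favors == "quantitative"
        assert ComparisonResult("ERC", -0.1, 1, 5, 7).favors == "semiquantitative"

    def test_differing_subject_sets_rejected(self, cohort140):
        d = cohort140.copy()
        d.loc[d.index[0], "mtl_ptau_rating"] = np.nan
        fq = RegionAssociationModel(d, "ERC", ["tangles_q"]).fit()
        fs = RegionAssociationModel(d, "ERC", ["mtl_ptau_rating"]).fit()
        with pytest.raises(ValueError, match="subject"):
            compare_models(fq, fs)

    def test_deltas_invariant_to_affine_outcome_rescaling(self, cohort140):
        d = cohort140.copy()
        fq1 = RegionAssociationModel(d, "ERC", ["tangles_q"]).fit()
        fs1 = RegionAssociationModel(d, "ERC", ["mtl_ptau_rating"]).fit()
        d["thk_ERC"] = 3.0 * d["thk_ERC"] + 10.0
        fq2 = RegionAssociationModel(d, "ERC", ["tangles_q"]).fit()
        fs2 = RegionAssociationModel(d, "ERC", ["mtl_ptau_rating"]).fit()
        c1, c2 = compare_models(fq1, fs1), compare_models(fq2, fs2)
        assert c2.delta_aicc == pytest.approx(c1.delta_aicc, abs=1e-9)
        assert c2.delta_bic == pytest.approx(c1.delta_bic, abs=1e-9)


class TestCohortAnalyses:
    def test_subgroup_sizes_match_counting_oracle(self, cohort140):
        n_adv = int((cohort140["braak_stage"] >= 5).sum())
        tab = run_cohort_analyses(cohort140, "advanced_adnc")
        assert set(tab["n"]) == {n_adv}
        n_late = int((cohort140["late_stage"] >= 1).sum())
        tab = run_cohort_analyses(cohort140, "late")
        assert tab.empty or set(tab["n"]) == {n_late}

    def test_whole_cohort_partitions_into_subgroup_and_rest(self, cohort140):
        in_adv = cohort140["braak_stage"] >= 5
        assert in_adv.sum() + (~in_adv).sum() == len(cohort140)

    def test_late_subgroup_of_31_has_reported_dfs(self):
        d = compose_cohort(140, 31, "late_stage", 1, seed=21)
        tab = run_cohort_analyses(d, "late")
        by_region = tab.groupby("region")["df_resid"].first()
        assert by_region["AH"] == 22 and by_region["PH"] == 22
        assert all(by_region[r] == 23 for r in ("ERC", "BA35", "BA36", "PHC"))

    def test_too_small_subgroup_skipped_with_warning(self):
        d = compose_cohort(60, 3, "late_stage", 1, seed=22)
        with pytest.warns(UserWarning, match="skipped"):
            tab = run_cohort_analyses(d, "late")
        assert tab.empty

    def test_significance_flags_consistent(self, cohort140):
        tab = run_cohort_analyses(cohort140, "whole")
        assert (tab["sig_bonferroni"] <= tab["sig_uncorrected"]).all()
        assert ((tab["p_one_sided"] < 0.05) == tab["sig_uncorrected"]).all()
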