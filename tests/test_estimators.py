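"""Per-CpG estimators: exact cases, truth recovery, convergence accounting."""

import numpy as np
import pandas as pd
import pytest

from methylestimand import (
    InvalidInputError,
    MethylationMatrix,
    SimulationConfig,
    adjust_pvalues,
    fit_beta_regression,
    fit_gaussian_beta,
    fit_m_with_intercept,
    m_to_beta,
    raw_beta_diff,
    simulate_beta_outcome,
    simulate_cohort,
)


class TestGaussianBeta:
    def test_noiseless_two_group_exact(self, constant_matrix, two_group_meta):
        res = fit_gaussian_beta(constant_matrix, two_group_meta)
        assert res["coef_treatment"].to_numpy() == pytest.approx([0.1, 0.1], abs=1e-12)
        assert res["intercept"].to_numpy() == pytest.approx([0.2, 0.45], abs=1e-12)
        assert res["estimand_kind"].eq("difference").all()
        assert res["converged"].all()

    def test_recovers_simulated_effect_mid_range(self):
        cfg = SimulationConfig(
            n_per_group=500, beta0_placebo=0.5, delta_beta=0.1, n_cpg=50, seed=21
        )
        matrix, meta, _ = simulate_cohort(cfg)
        res = fit_gaussian_beta(matrix.to_scale("beta"), meta)
        assert res["estimand"].mean() == pytest.approx(0.1, abs=0.01)

    def test_boundary_bias_exceeds_mid_range_bias(self):
        # same noise, same effect: linear-on-Beta is more biased near 0
        common = dict(n_per_group=1000, delta_beta=0.05, n_cpg=100, noise_sd_m=0.5, seed=22)
        mat_b, meta_b, _ = simulate_cohort(SimulationConfig(beta0_placebo=0.05, **common))
        mat_m, meta_m, _ = simulate_cohort(SimulationConfig(beta0_placebo=0.5, **common))
        bias_b = fit_gaussian_beta(mat_b.to_scale("beta"), meta_b)["estimand"].mean() - 0.05
        bias_m = fit_gaussian_beta(mat_m.to_scale("beta"), meta_m)["estimand"].mean() - 0.05
        assert abs(bias_b) > abs(bias_m)

    def test_out_of_range_predictions_flagged_not_fatal(self, two_group_meta):
        values = pd.DataFrame(
            [[0.01, 0.02, 0.01, 0.9, 0.95, 0.99]],
            index=["cg1"],
            columns=two_group_meta["sample_id"],
        )
        meta = two_group_meta.assign(age=[20.0, 80.0, 50.0, 30.0, 70.0, 55.0])
        res = fit_gaussian_beta(MethylationMatrix(values, "beta"), meta, adjust=("age",))
        assert "pred_out_of_range" in res.columns
        assert res["converged"].all()

    def test_wrong_scale_rejected(self, constant_matrix, two_group_meta):
        with pytest.raises(InvalidInputError):
            fit_gaussian_beta(constant_matrix.to_scale("m"), two_group_meta)

    def test_matches_statsmodels_ols(self):
        # independent route: statsmodels OLS per CpG on the same design
        import statsmodels.api as sm

        from methylestimand.estimators import build_design

        cfg = SimulationConfig(n_per_group=40, n_cpg=5, confounder_fraction=0.1, seed=30)
        matrix, meta, _ = simulate_cohort(cfg)
        beta_mat = matrix.to_scale("beta")
        res = fit_gaussian_beta(beta_mat, meta, adjust=("age", "sex"))
        X, _ = build_design(meta, ("age", "sex"))
        for i, cpg in enumerate(beta_mat.cpg_ids):
            ref = sm.OLS(beta_mat.values.loc[cpg].to_numpy(), X).fit()
            assert res["coef_treatment"].iloc[i] == pytest.approx(ref.params[1], abs=1e-10)
            assert res["p_value"].iloc[i] == pytest.approx(ref.pvalues[1], abs=1e-10)


class TestRawBetaDiff:
    def test_exact_group_means(self, constant_matrix, two_group_meta):
        res = raw_beta_diff(constant_matrix, two_group_meta)
        assert res["estimand"].to_numpy() == pytest.approx([0.1, 0.1], abs=1e-12)
        assert res["p_value"].notna().all()  # p comes from the companion M fit

    def test_empty_group_rejected(self, constant_matrix, two_group_meta):
        meta = two_group_meta.assign(group="Placebo")
        with pytest.raises(InvalidInputError):
            raw_beta_diff(constant_matrix, meta)

    def test_unconfounded_cohort_mean_deviation_small(self):
        # at c=0 the raw difference tracks the predefined effect up to the
        # O(sd²) back-transform curvature of noisy M draws
        cfg = SimulationConfig(
            n_per_group=1000, beta0_placebo=0.3, delta_beta=0.1, n_cpg=200, seed=31
        )
        matrix, meta, _ = simulate_cohort(cfg)
        res = raw_beta_diff(matrix.to_scale("beta"), meta)
        assert res["estimand"].mean() == pytest.approx(0.1, rel=0.04)

    def test_confounded_cohort_overstates_treatment_effect(self, confounded_cohort):
        _, matrix, meta, truth = confounded_cohort
        res = raw_beta_diff(matrix.to_scale("beta"), meta)
        target = truth.delta_beta_treatment
        # raw difference absorbs the confounder share: systematic excess
        assert res["estimand"].mean() > target * 1.1


class TestMWithIntercept:
    def test_noiseless_worked_example(self, two_group_meta):
        values = pd.DataFrame(
            [[-3.15, -3.15, -3.15, -1.99, -1.99, -1.99]],
            index=["cg1"],
            columns=two_group_meta["sample_id"],
        )
        res = fit_m_with_intercept(MethylationMatrix(values, "m"), two_group_meta, adjust=())
        assert res["intercept"].iloc[0] == pytest.approx(-3.15, abs=1e-12)
        assert res["coef_treatment"].iloc[0] == pytest.approx(1.16, abs=1e-12)
        assert round(res["estimand"].iloc[0], 2) == pytest.approx(0.10)

    def test_zero_effect_zero_estimand(self, two_group_meta):
        values = pd.DataFrame(
            [[0.7] * 6], index=["cg1"], columns=two_group_meta["sample_id"]
        )
        res = fit_m_with_intercept(MethylationMatrix(values, "m"), two_group_meta, adjust=())
        assert res["estimand"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_unadjusted_coef_equals_group_mean_difference(self):
        cfg = SimulationConfig(n_per_group=100, n_cpg=10, seed=33)
        matrix, meta, _ = simulate_cohort(cfg)
        res = fit_m_with_intercept(matrix, meta, adjust=())
        m = matrix.values.to_numpy()
        grp = (meta["group"] == "Treatment").to_numpy()
        diffs = m[:, grp].mean(axis=1) - m[:, ~grp].mean(axis=1)
        assert res["coef_treatment"].to_numpy() == pytest.approx(diffs, abs=1e-10)

    def test_adjusted_fit_recovers_attributable_delta_beta(self, confounded_cohort):
        _, matrix, meta, truth = confounded_cohort
        res = fit_m_with_intercept(matrix, meta, adjust=("age", "sex"))
        target = truth.delta_beta_treatment
        assert res["estimand"].mean() == pytest.approx(target, rel=0.05)
        # and the M coefficient targets (1-c)·ΔM_total, not the total
        assert res["coef_treatment"].mean() == pytest.approx(
            truth.delta_m_treatment, rel=0.05
        )

    def test_null_p_values_uniform(self):
        from scipy import stats

        cfg = SimulationConfig(
            n_per_group=200, beta0_placebo=0.4, delta_beta=0.0, n_cpg=500, seed=34
        )
        matrix, meta, _ = simulate_cohort(cfg)
        res = fit_m_with_intercept(matrix, meta, adjust=("age", "sex"))
        ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01


class TestBetaRegression:
    def test_symmetric_groups_logit_difference(self):
        # means 1/3 vs 2/3 → treatment coefficient ln 4 on the logit scale
        cfg = SimulationConfig(
            n_per_group=10_000, beta0_placebo=1 / 3, delta_beta=1 / 3,
            beta_precision=50, seed=35,
        )
        matrix, meta = simulate_beta_outcome(cfg)
        res = fit_beta_regression(matrix, meta)
        assert res["converged"].iloc[0]
        assert res["coef_treatment"].iloc[0] == pytest.approx(np.log(4.0), abs=0.05)
        assert res["estimand"].iloc[0] == pytest.approx(4.0, rel=0.06)
        assert res["estimand_kind"].iloc[0] == "odds_ratio"

    def test_mid_range_converges_boundary_fails(self):
        results = {}
        for b0 in (0.01, 0.5):
            cfg = SimulationConfig(
                n_per_group=500, beta0_placebo=b0, delta_beta=0.1, n_cpg=5, seed=36
            )
            matrix, meta = simulate_beta_outcome(cfg)
            res = fit_beta_regression(matrix, meta)
            results[b0] = res["converged"].mean()
        assert results[0.5] == 1.0
        assert results[0.01] < results[0.5]

    def test_failures_reported_not_dropped(self):
        cfg = SimulationConfig(
            n_per_group=300, beta0_placebo=0.005, delta_beta=0.1, n_cpg=4, seed=37
        )
        matrix, meta = simulate_beta_outcome(cfg)
        res = fit_beta_regression(matrix, meta)
        assert len(res) == 4
        failed = res[~res["converged"]]
        assert failed["estimand"].isna().all()

    def test_null_type_one_error_near_nominal(self):
        cfg = SimulationConfig(
            n_per_group=500, beta0_placebo=0.4, delta_beta=0.0,
            beta_precision=30, n_cpg=300, seed=38,
        )
        matrix, meta = simulate_beta_outcome(cfg)
        res = fit_beta_regression(matrix, meta)
        rate = (res.loc[res["converged"], "p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.035)


class TestAdjustPvalues:
    def test_bh_adjustment_appended(self, constant_matrix, two_group_meta):
        res = adjust_pvalues(raw_beta_diff(constant_matrix, two_group_meta))
        assert "p_adj" in res.columns
        assert (res["p_adj"] >= res["p_value"] - 1e-15).all()
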