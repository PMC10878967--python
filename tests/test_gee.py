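import numpy as np
import pandas as pd
import pytest

from sweptrial import (
    ModifiedPoissonGEE,
    effect_estimate,
    estimate_icc,
    fit_trial_gee,
    mean_difference,
)
from sweptrial.exceptions import (
    AliasingError,
    InferenceInfeasibleError,
    ValidationError,
)

from _oracles import dense_gee


def _clustered_binary(seed, n_clusters=6, per_cluster=40, beta_trt=-0.2):
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        u = rng.normal(0, 0.2)
        for t in (1, 2, 3):
            x = int(t > 1 + c % 3)
            p = np.clip(np.exp(-0.9 + beta_trt * x + 0.05 * t + u), 0, 1)
            y = rng.random(per_cluster) < p
            for yi in y:
                rows.append((f"c{c}", t, x, int(yi)))
    return pd.DataFrame(rows, columns=["cluster", "period", "treatment", "y"])


class TestFitAgainstDenseOracle:
    @pytest.mark.parametrize("correlation", ["independence", "exchangeable"])
    @pytest.mark.parametrize("family", ["poisson", "gaussian"])
    def test_small_fixture_matches_dense_solve(
        self, toy_gee_data, correlation, family
    ):
        """Coefficients, working correlation and all three covariance
        kinds must agree with a full-matrix computation to 1e-8."""
        df, X = toy_gee_data
        Xi = np.column_stack([np.ones(len(df)), X.to_numpy()])
        beta_o, alpha_o, phi_o, cov_m, cov_sw, cov_md = dense_gee(
            Xi, df["y"], df["cluster"], family=family,
            correlation=correlation,
        )
        est = ModifiedPoissonGEE(
            family=family, correlation=correlation
        ).fit(X, df["y"], df["cluster"])
        assert est.converged_
        np.testing.assert_allclose(est.coef_, beta_o, atol=1e-8)
        assert est.alpha_ == pytest.approx(alpha_o, abs=1e-8)
        assert est.scale_ == pytest.approx(phi_o, abs=1e-8)
        np.testing.assert_allclose(
            est.robust_covariance("model_based"), cov_m, atol=1e-8
        )
        np.testing.assert_allclose(
            est.robust_covariance("sandwich"), cov_sw, atol=1e-8
        )
        np.testing.assert_allclose(
            est.robust_covariance("mancl_derouen"), cov_md, atol=1e-8
        )

    def test_five_cluster_fixture_matches_dense_solve(self):
        df = _clustered_binary(11, n_clusters=5, per_cluster=25)
        fit = fit_trial_gee(df, "y")
        X = pd.get_dummies(df["period"], prefix="period", drop_first=True)
        Xi = np.column_stack(
            [np.ones(len(df)), df["treatment"], X.to_numpy(float)]
        )
        beta_o, *_, cov_sw, cov_md = dense_gee(
            Xi, df["y"], df["cluster"]
        )
        np.testing.assert_allclose(fit.coef_, beta_o, atol=1e-8)
        np.testing.assert_allclose(
            fit.robust_covariance("sandwich"), cov_sw, atol=1e-8
        )
        np.testing.assert_allclose(
            fit.robust_covariance("mancl_derouen"), cov_md, atol=1e-8
        )


class TestAgainstStatsmodels:
    """statsmodels is the independent cross-check, never the engine."""

    def test_independence_equals_poisson_glm(self):
        import statsmodels.api as smapi

        df = _clustered_binary(3)
        fit = fit_trial_gee(df, "y", correlation="independence")
        X = pd.get_dummies(df["period"], prefix="period", drop_first=True)
        X = X.astype(float)
        X.insert(0, "treatment", df["treatment"].astype(float))
        X.insert(0, "const", 1.0)
        glm = smapi.GLM(
            df["y"], X, family=smapi.families.Poisson()
        ).fit()
        np.testing.assert_allclose(
            fit.coef_, glm.params.to_numpy(), atol=1e-8
        )

    def test_exchangeable_and_variances_match_statsmodels(self):
        from statsmodels.genmod.cov_struct import Exchangeable
        from statsmodels.genmod.families import Poisson
        from statsmodels.genmod.generalized_estimating_equations import GEE

        df = _clustered_binary(5, n_clusters=8, per_cluster=60)
        X = pd.get_dummies(df["period"], prefix="period", drop_first=True)
        X = X.astype(float)
        X.insert(0, "treatment", df["treatment"].astype(float))
        X.insert(0, "const", 1.0)

        fit = fit_trial_gee(df, "y")
        sm_fit = GEE(
            df["y"], X, groups=df["cluster"], family=Poisson(),
            cov_struct=Exchangeable(),
        ).fit()
        # correlation-parameter estimators differ by O(p/n) finite-
        # sample corrections, so coefficients agree only to ~1e-3
        np.testing.assert_allclose(
            fit.coef_, sm_fit.params.to_numpy(), atol=1e-3
        )

        fit_ind = fit_trial_gee(df, "y", correlation="independence")
        sm_ind = GEE(
            df["y"], X, groups=df["cluster"], family=Poisson()
        ).fit(cov_type="bias_reduced")
        np.testing.assert_allclose(
            fit_ind.robust_covariance("sandwich"),
            np.asarray(sm_ind.cov_robust), rtol=1e-8,
        )
        np.testing.assert_allclose(
            fit_ind.robust_covariance("mancl_derouen"),
            np.asarray(sm_ind.cov_robust_bc), rtol=1e-8,
        )


class TestDegenerateAndInvalidInputs:
    def test_constant_outcome(self):
        df = pd.DataFrame(
            {
                "cluster": list("AABBCC"),
                "period": [1, 2] * 3,
                "treatment": [0, 1, 1, 0, 0, 1],
                "y": 1,
            }
        )
        fit = fit_trial_gee(df, "y")
        j = fit.term_names_.index("treatment")
        assert fit.coef_[j] == pytest.approx(0.0, abs=1e-10)
        assert fit.coef_[0] == pytest.approx(np.log(1.0), abs=1e-10)
        # perfect fit: both robust variances are the zero matrix
        assert np.allclose(fit.robust_covariance("sandwich"), 0.0)
        assert np.allclose(fit.robust_covariance("mancl_derouen"), 0.0)

    def test_rank_deficiency_names_aliased_column(self, toy_gee_data):
        df, X = toy_gee_data
        X = X.copy()
        X["treatment_dup"] = X["treatment"]
        with pytest.raises(AliasingError) as err:
            ModifiedPoissonGEE().fit(X, df["y"], df["cluster"])
        assert any("treatment" in c for c in err.value.columns)

    def test_nonbinary_outcome_rejected_for_poisson(self, toy_gee_data):
        df, X = toy_gee_data
        with pytest.raises(ValidationError):
            ModifiedPoissonGEE().fit(X, df["y"] + 0.5, df["cluster"])

    def test_nonconvergence_is_flagged_never_silent(self, toy_gee_data):
        df, X = toy_gee_data
        est = ModifiedPoissonGEE(max_iter=1).fit(X, df["y"], df["cluster"])
        assert not est.converged_
        with pytest.raises(ValidationError):
            est.robust_covariance("mancl_derouen")
        est.robust_covariance("mancl_derouen", allow_unconverged=True)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            ModifiedPoissonGEE().fit(
                np.ones((4, 1)), [0, 1, 0, 1], ["A"] * 4
            )


class TestManclDeRouenAsymptotics:
    def test_correction_vanishes_as_clusters_grow(self):
        """Cluster leverage shrinks with many clusters, so the
        corrected and uncorrected sandwiches converge (relative
        Frobenius difference decreasing over N = 4, 16, 64)."""
        diffs = []
        for n_clusters in (4, 16, 64):
            df = _clustered_binary(
                13, n_clusters=n_clusters, per_cluster=12
            )
            fit = fit_trial_gee(df, "y")
            sw = fit.robust_covariance("sandwich")
            md = fit.robust_covariance("mancl_derouen")
            diffs.append(
                np.linalg.norm(md - sw) / np.linalg.norm(sw)
            )
        assert diffs[0] > diffs[1] > diffs[2]
        assert diffs[2] < diffs[0] / 5


class TestEffectEstimate:
    def test_null_coefficient_gives_unit_rr_symmetric_ci(self):
        df = pd.DataFrame(
            {
                "cluster": np.repeat(list("ABCD"), 40),
                "period": np.tile([1, 1, 2, 2], 40),
                "treatment": np.tile([0, 1], 80),
                "y": np.tile([0, 1, 1, 0], 40),
            }
        )
        # outcome prevalence identical in both arms: beta_trt ~ 0
        fit = fit_trial_gee(df, "y")
        est = effect_estimate(fit)
        assert est.rr == pytest.approx(1.0, abs=1e-6)
        assert np.log(est.ci_high) == pytest.approx(
            -np.log(est.ci_low), abs=1e-6
        )

    def test_small_df_widens_interval(self, toy_gee_data):
        df, X = toy_gee_data
        fit = fit_trial_gee(df, "y")
        narrow = effect_estimate(fit, df=1000)
        wide = effect_estimate(fit, df=1)
        assert wide.ci_low < narrow.ci_low
        assert wide.ci_high > narrow.ci_high

    def test_toy_fixture_interval_matches_scalar_arithmetic(
        self, toy_gee_data
    ):
        from scipy import stats

        df, X = toy_gee_data
        fit = fit_trial_gee(df, "y")
        est = effect_estimate(fit)
        j = fit.term_names_.index("treatment")
        se = np.sqrt(fit.robust_covariance("mancl_derouen")[j, j])
        tq = stats.t.ppf(0.975, 1)
        assert est.df == 1
        assert est.ci_low == pytest.approx(
            np.exp(fit.coef_[j] - tq * se), rel=1e-12
        )
        assert est.ci_high == pytest.approx(
            np.exp(fit.coef_[j] + tq * se), rel=1e-12
        )

    def test_two_clusters_infeasible(self):
        df = pd.DataFrame(
            {
                "cluster": list("AABB"),
                "period": [1, 2, 1, 2],
                "treatment": [0, 1, 0, 0],
                "y": [0, 1, 1, 0],
            }
        )
        fit = fit_trial_gee(df, "y")
        with pytest.raises(InferenceInfeasibleError):
            effect_estimate(fit)


class TestInvariance:
    def test_cluster_relabeling_and_row_order(self):
        df = _clustered_binary(21, n_clusters=5, per_cluster=30)
        fit = fit_trial_gee(df, "y")
        relabeled = df.assign(
            cluster=df["cluster"].map(
                {"c0": "z9", "c1": "m5", "c2": "a1", "c3": "q7", "c4": "b2"}
            )
        ).sample(frac=1.0, random_state=0)
        fit2 = fit_trial_gee(relabeled, "y")
        np.testing.assert_allclose(fit.coef_, fit2.coef_, atol=1e-10)
        np.testing.assert_allclose(
            fit.robust_covariance("mancl_derouen"),
            fit2.robust_covariance("mancl_derouen"),
            atol=1e-10,
        )


class TestICC:
    def test_independent_observations_estimate_near_zero(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "cluster": np.repeat([f"c{i}" for i in range(6)], 300),
                "period": np.tile([1, 2, 3], 600),
                "y": rng.integers(0, 2, 1800),
            }
        )
        est = estimate_icc(df, "y", n_boot=60, seed=9)
        assert abs(est.icc) < 0.02
        assert est.ci_low == 0.0

    def test_too_few_clusters(self):
        df = pd.DataFrame(
            {"cluster": list("AABB"), "period": 1, "y": [0, 1, 0, 1]}
        )
        with pytest.raises(InferenceInfeasibleError):
            estimate_icc(df, "y")

    def test_single_member_clusters_undefined(self):
        df = pd.DataFrame(
            {
                "cluster": list("ABCDE"),
                "period": 1,
                "y": [0, 1, 0, 1, 0],
            }
        )
        with pytest.raises(InferenceInfeasibleError):
            estimate_icc(df, "y")


class TestMeanDifference:
    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "cluster": np.repeat(list("ABCD"), 200),
                "period": np.tile([1, 1, 2, 2], 200),
                "treatment": np.tile([0, 1], 400),
                "days": rng.lognormal(0, 0.5, 800),
            }
        )
        md = mean_difference(df, "days")
        assert abs(md.difference) < 0.15
        assert md.ci_low < 0 < md.ci_high

    def test_injected_shift_recovered(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {
                "cluster": np.repeat(list("ABCD"), 400),
                "period": np.tile([1, 1, 2, 2], 400),
                "treatment": np.tile([0, 1], 800),
                "days": rng.lognormal(0, 0.4, 1600),
            }
        )
        df.loc[df["treatment"] == 1, "days"] += 0.5
        md = mean_difference(df, "days")
        assert md.difference == pytest.approx(0.5, abs=0.1)

    def test_all_missing_rejected(self):
        df = pd.DataFrame(
            {
                "cluster": list("AB"),
                "period": 1,
                "treatment": [0, 1],
                "days": [np.nan, np.nan],
            }
        )
        with pytest.raises(ValidationError):
            mean_difference(df, "days")
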