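import numpy as np
import pytest

from swgee.binary_simulator import ClusterSizeSpec, simulate_trial
from swgee.correlation_structures import CorrelationSpec
from swgee.gee_fit import exchangeable_alpha, fit_gee, fit_gee_matrix
from swgee.marginal_model import MarginalSpec
from swgee.trial_design import build_design


class TestIndependenceEquivalence:
    def test_matches_ml_logistic(self, small_trial):
        """Independence-working GEE point estimates are ML logistic estimates."""
        import statsmodels.api as sm

        fit = fit_gee(small_trial, "independence")
        assert fit.converged
        x = np.zeros((len(small_trial), 4))
        for j, t in enumerate(sorted(small_trial["period"].unique())):
            x[small_trial["period"].to_numpy() == t, j] = 1.0
        x[:, -1] = small_trial["treated"]
        ref = sm.GLM(small_trial["outcome"].to_numpy(), x, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)

    def test_order_invariance(self, small_trial, rng):
        fit = fit_gee(small_trial, "independence")
        shuffled = small_trial.sample(frac=1.0, random_state=3)
        fit2 = fit_gee(shuffled, "independence")
        np.testing.assert_allclose(fit.beta, fit2.beta, atol=1e-10)
        fe = fit_gee(small_trial, "exchangeable")
        fe2 = fit_gee(shuffled, "exchangeable")
        np.testing.assert_allclose(fe.beta, fe2.beta, atol=1e-10)
        assert fe.alpha == pytest.approx(fe2.alpha, abs=1e-12)


class TestExchangeable:
    def test_close_to_statsmodels_gee(self, small_trial):
        """Same estimating equations as the reference GEE implementation.

        Moment-estimator conventions for alpha differ slightly between
        implementations, so the comparison is loose but diagnostic.
        """
        import statsmodels.api as sm

        fit = fit_gee(small_trial, "exchangeable")
        assert fit.converged
        x = np.zeros((len(small_trial), 4))
        for j, t in enumerate(sorted(small_trial["period"].unique())):
            x[small_trial["period"].to_numpy() == t, j] = 1.0
        x[:, -1] = small_trial["treated"]
        ref = sm.GEE(
            small_trial["outcome"].to_numpy(),
            x,
            groups=small_trial["cluster"].to_numpy(),
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        ).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=5e-3)

    def test_alpha_small_when_data_independent(self):
        design = build_design(3, 30)
        corr = CorrelationSpec.from_name("exchangeable", 0.0)
        df = simulate_trial(design, MarginalSpec(), corr, ClusterSizeSpec(60, 0.0), seed=5)
        fit = fit_gee(df, "exchangeable")
        assert abs(fit.alpha) < 0.02

    def test_alpha_near_one_for_duplicated_observations(self, rng):
        # every cluster is one individual repeated: within-cluster correlation -> 1
        y = np.repeat(rng.integers(0, 2, size=30), 4).astype(float)
        x = np.ones((120, 1))
        fit = fit_gee_matrix(y, x, np.repeat(np.arange(30), 4), "exchangeable")
        assert fit.alpha > 0.95

    def test_moment_estimator_hand_computed(self):
        # 2 clusters x 3 observations with known residuals
        pearson = np.array([1.0, -0.5, 0.5, 2.0, 0.0, -1.0])
        offsets = np.array([0, 3, 6])
        p = 1
        # hand arithmetic: sum of within-cluster products of distinct pairs
        cross = (1 * -0.5 + 1 * 0.5 + -0.5 * 0.5) + (2 * 0 + 2 * -1 + 0 * -1)
        pairs = 6.0
        scale = (pearson**2).sum() / (6 - p)
        expected = cross / (pairs - p) / scale
        assert exchangeable_alpha(pearson, offsets, p) == pytest.approx(expected, abs=1e-12)


class TestDegenerate:
    def test_separated_period_flagged_not_raised(self, rng):
        """An all-zero period cell sends that cell-mean to -inf; flagged as non-converged."""
        design = build_design(3, 6)
        corr = CorrelationSpec.from_name("exchangeable", 0.0)
        df = simulate_trial(design, MarginalSpec(), corr, ClusterSizeSpec(24, 0.0), seed=11)
        df.loc[df.period == 1, "outcome"] = 0
        fit = fit_gee(df, "independence")
        assert not fit.converged

    def test_single_cluster_rejected(self):
        y = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            fit_gee_matrix(y, np.ones((2, 1)), np.zeros(2), "independence")

    def test_nonbinary_outcome_rejected(self, small_trial):
        bad = small_trial.copy()
        bad.loc[bad.index[0], "outcome"] = 2
        with pytest.raises(ValueError):
            fit_gee(bad)


class TestCellMeansSolution:
    def test_saturated_period_model_reproduces_cell_proportions(self, rng):
        """Without a treatment column the period cell-means are exact logit proportions."""
        n = 40
        y = np.concatenate([rng.binomial(1, 0.3, n), rng.binomial(1, 0.6, n)]).astype(float)
        x = np.zeros((2 * n, 2))
        x[:n, 0] = 1.0
        x[n:, 1] = 1.0
        clusters = np.tile(np.arange(8), 10)
        fit = fit_gee_matrix(y, x, clusters, "independence")
        p1, p2 = y[:n].mean(), y[n:].mean()
        np.testing.assert_allclose(
            fit.beta, [np.log(p1 / (1 - p1)), np.log(p2 / (1 - p2))], atol=1e-8
        )

    def test_estimating_equation_residual_small(self, small_trial):
        fit = fit_gee(small_trial, "exchangeable")
        assert np.max(np.abs(fit.g.sum(axis=0))) < 1e-6 * fit.n_obs
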