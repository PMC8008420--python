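import numpy as np
import pytest
from scipy import stats

from swgee.binary_simulator import (
    ClusterSizeSpec,
    achieved_phi,
    build_latent_covariance,
    bvn_cdf,
    phi_bounds,
    sample_cluster_sizes,
    simulate_trial,
    solve_latent_correlation,
)
from swgee.correlation_structures import CorrelationSpec
from swgee.marginal_model import MarginalSpec, marginal_probability
from swgee.trial_design import build_design


class TestBvnCdf:
    @pytest.mark.parametrize("h", [-1.5, -0.3, 0.0, 0.52, 2.1])
    @pytest.mark.parametrize("k", [-2.0, 0.0, 0.8])
    @pytest.mark.parametrize("rho", [-0.95, -0.4, 0.0, 0.3, 0.9])
    def test_against_scipy_mvn(self, h, k, rho):
        # independent numerical-integration oracle
        ref = stats.multivariate_normal(cov=[[1, rho], [rho, 1]]).cdf([h, k])
        assert bvn_cdf(h, k, rho) == pytest.approx(ref, abs=5e-8)


class TestLatentSolver:
    def test_zero_phi_maps_to_zero(self):
        assert solve_latent_correlation(0.3, 0.42, 0.0) == 0.0

    def test_half_probability_closed_form(self):
        # at p1 = p2 = 1/2 the phi/latent link is phi = (2/pi) arcsin(delta)
        delta = solve_latent_correlation(0.5, 0.5, 0.5)
        assert delta == pytest.approx(np.sin(np.pi * 0.25), abs=1e-9)

    @pytest.mark.parametrize("p1", [0.1, 0.3, 0.46])
    @pytest.mark.parametrize("p2", [0.3, 0.55])
    @pytest.mark.parametrize("phi", [-0.05, 0.01, 0.1, 0.3])
    def test_round_trip(self, p1, p2, phi):
        delta = solve_latent_correlation(p1, p2, phi)
        assert achieved_phi(p1, p2, delta) == pytest.approx(phi, abs=1e-8)

    def test_infeasible_phi_names_interval(self):
        lo, hi = phi_bounds(0.05, 0.9)
        with pytest.raises(ValueError, match="feasible interval"):
            solve_latent_correlation(0.05, 0.9, hi + 0.05)

    def test_invalid_marginals(self):
        with pytest.raises(ValueError):
            solve_latent_correlation(0.0, 0.5, 0.1)


class TestLatentCovariance:
    def test_zero_icc_gives_identity(self, design3):
        corr = CorrelationSpec.from_name("exchangeable", 0.0)
        sigma, thr = build_latent_covariance(design3, MarginalSpec(), corr, [4] * 6, sequence=1)
        assert np.allclose(sigma, np.eye(24))
        assert thr.shape == (24,)

    def test_dimension_and_thresholds(self, design6):
        corr = CorrelationSpec.from_name("ar1_0.8", 0.1)
        sigma, thr = build_latent_covariance(design6, MarginalSpec(), corr, [4] * 6, sequence=6)
        assert sigma.shape == (24, 24)
        # sequence 6 is control until the final occasion
        p1 = marginal_probability(MarginalSpec(), 1, 0)
        assert thr[0] == pytest.approx(stats.norm.ppf(1 - p1))

    def test_exchangeable_pair_classes(self, design6):
        """Always-treated cluster, exchangeable: one latent value per (p_i, p_j) pair."""
        corr = CorrelationSpec.from_name("exchangeable", 0.1)
        sigma, _ = build_latent_covariance(design6, MarginalSpec(), corr, [2] * 6, sequence=1)
        off = sigma[~np.eye(12, dtype=bool)]
        # 6 distinct marginals -> at most 6*(6+1)/2 = 21 distinct latent entries
        assert len(np.unique(np.round(off, 12))) <= 21


class TestClusterSizes:
    def test_constant_when_cv_zero(self, rng):
        assert (sample_cluster_sizes(ClusterSizeSpec(24, 0.0), 6, rng) == 4).all()
        assert (sample_cluster_sizes(ClusterSizeSpec(60, 0.0), 6, rng) == 10).all()

    def test_truncated_nb_calibration(self, rng):
        """Post-truncation totals hit mean 60 and CV 0.4 within Monte-Carlo error."""
        sizes = sample_cluster_sizes(ClusterSizeSpec(60, 0.4), 6, rng, n_clusters=10_000)
        totals = sizes.sum(axis=1)
        cv = totals.std() / totals.mean()
        assert totals.mean() == pytest.approx(60, rel=0.02)
        assert cv == pytest.approx(0.4, rel=0.10)
        assert sizes.min() >= 2

    def test_infeasible_mean_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_cluster_sizes(ClusterSizeSpec(6, 0.0), 6, rng)


class TestSimulateTrial:
    def test_same_seed_identical(self, design3):
        args = (design3, MarginalSpec(), CorrelationSpec.from_name("ar1_0.6", 0.1), ClusterSizeSpec(24, 0.4))
        a = simulate_trial(*args, seed=42)
        b = simulate_trial(*args, seed=42)
        assert a.equals(b)
        c = simulate_trial(*args, seed=43)
        assert not a["outcome"].equals(c["outcome"])

    def test_schema_and_invariants(self, small_trial, design3):
        df = small_trial
        assert set(df.columns) == {"cluster", "sequence", "occasion", "period", "treated", "outcome"}
        assert df["outcome"].isin([0, 1]).all()
        # treated constant within cluster-occasion; >= 2 rows per cell
        cell = df.groupby(["cluster", "occasion"])
        assert (cell["treated"].nunique() == 1).all()
        assert (cell.size() >= 2).all()

    def test_zero_icc_matches_marginal_probabilities(self):
        """With rho=0 the generator reduces to independent Bernoulli draws."""
        design = build_design(3, 18)
        corr = CorrelationSpec.from_name("exchangeable", 0.0)
        df = simulate_trial(design, MarginalSpec(), corr, ClusterSizeSpec(300, 0.0), seed=7)
        for occ, trt in [(1, 0), (6, 1)]:
            sub = df[(df.occasion == occ) & (df.treated == trt)]
            if len(sub) < 500:
                continue
            p = marginal_probability(MarginalSpec(), occ, trt)
            mcse = np.sqrt(p * (1 - p) / len(sub))
            assert abs(sub.outcome.mean() - p) < 3.5 * mcse
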