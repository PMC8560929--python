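"""Priors, latent prediction, likelihood, posterior, and its gradient."""

import numpy as np
import pytest
from scipy.stats import norm

from epimap.dynamics import fixed_point_2d
from epimap.features import DataFeatures
from epimap.forward import Connectome, GainMatrix
from epimap.model import (
    Observation,
    ThetaParameters,
    log_likelihood,
    log_posterior,
    log_posterior_with_grad,
    log_prior,
    make_priors,
    pack_theta,
    predict_latent_states,
    unpack_theta,
)

_LOG_2PI = np.log(2 * np.pi)


class TestThetaPacking:
    @pytest.mark.parametrize("n,expected", [(164, 498), (10, 36), (1, 9)])
    def test_flat_length_is_3n_plus_6(self, n, expected):
        priors = make_priors([], n)
        assert priors.mean.shape == (expected,)
        assert pack_theta(unpack_theta(priors.mean, n)).shape == (expected,)

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(0)
        vec = rng.standard_normal(3 * 7 + 6)
        np.testing.assert_array_equal(pack_theta(unpack_theta(vec, 7)), vec)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            unpack_theta(np.zeros(20), 7)

    def test_block_ordering(self):
        n = 3
        vec = np.arange(3 * n + 6, dtype=float)
        tp = unpack_theta(vec, n)
        np.testing.assert_array_equal(tp.x0, [0, 1, 2])
        np.testing.assert_array_equal(tp.x_init, [3, 4, 5])
        np.testing.assert_array_equal(tp.z_init, [6, 7, 8])
        assert (tp.K, tp.tau0, tp.alpha, tp.beta, tp.eps1, tp.eps2) == \
            (9.0, 10.0, 11.0, 12.0, 13.0, 14.0)


class TestPriors:
    def test_hypothesis_conditioning_of_x0(self):
        priors = make_priors([1, 3], 5)
        np.testing.assert_array_equal(priors.mean[:5],
                                      [-3.0, -1.5, -3.0, -1.5, -3.0])
        np.testing.assert_array_equal(priors.sd[:5], np.ones(5))

    def test_scalar_prior_table(self):
        n = 4
        priors = make_priors([], n)
        tail_mean = priors.mean[3 * n:]
        tail_sd = priors.sd[3 * n:]
        np.testing.assert_array_equal(tail_mean, [1, 20, 1, 0, 1, 1])
        np.testing.assert_array_equal(tail_sd, [10] * 6)
        # initial-state blocks
        assert set(priors.mean[n:2 * n]) == {-2.0}
        assert set(priors.mean[2 * n:3 * n]) == {3.5}
        assert set(priors.sd[n:3 * n]) == {10.0}

    def test_truncation_set_is_the_positive_parameters(self):
        n = 4
        priors = make_priors([], n)
        idx = np.flatnonzero(priors.truncated)
        assert idx.tolist() == [3 * n, 3 * n + 1, 3 * n + 4, 3 * n + 5]

    def test_out_of_range_hypothesis_rejected(self):
        with pytest.raises(ValueError):
            make_priors([7], 5)


class TestLogPrior:
    def test_untruncated_parameter_at_mean(self):
        """A parameter at its prior mean contributes -ln(sigma sqrt(2 pi))."""
        n = 1
        priors = make_priors([], n)
        lp_mean = log_prior(priors.mean, priors)
        moved = priors.mean.copy()
        moved[0] += priors.sd[0]  # x0, untruncated, one SD away
        assert log_prior(moved, priors) == pytest.approx(lp_mean - 0.5)

    def test_truncated_normal_renormalizer(self):
        """K truncated at 0 with mean 1, SD 10: density at the mean is the
        normal density divided by Phi(0.1)."""
        n = 1
        priors = make_priors([], n)
        base = log_prior(priors.mean, priors)
        # recompute with the closed-form for every block
        expected = 0.0
        for mu, sd, trunc in zip(priors.mean, priors.sd, priors.truncated):
            expected += norm.logpdf(mu, mu, sd)
            if trunc:
                expected -= np.log(norm.cdf(mu / sd))
        assert base == pytest.approx(expected, rel=1e-12)

    def test_violating_truncation_gives_neg_inf(self):
        n = 2
        priors = make_priors([], n)
        bad = priors.mean.copy()
        bad[3 * n] = -0.5  # K <= 0
        assert log_prior(bad, priors) == -np.inf
        with pytest.raises(ValueError):
            log_prior(bad, priors, on_violation="raise")


class TestPredictLatentStates:
    def test_background_network_stays_quiescent(self):
        """All regions at x0 = -3 starting at the fixed point never cross
        the onset threshold over 300 samples."""
        n = 6
        rng = np.random.default_rng(2)
        C = rng.uniform(0, 0.3, (n, n))
        np.fill_diagonal(C, 0)
        x_star, z_star = fixed_point_2d(-3.0)
        theta = ThetaParameters(
            x0=np.full(n, -3.0), x_init=np.full(n, x_star),
            z_init=np.full(n, z_star), K=1.0, tau0=20.0,
            alpha=1.0, beta=0.0, eps1=1.0, eps2=1.0)
        latent = predict_latent_states(theta, Connectome(weights=C), T=300)
        assert latent.x.max() < 0.0

    def test_deterministic(self, small_problem):
        connectome, priors, obs, theta_vec = small_problem
        tp = unpack_theta(theta_vec, priors.n_regions)
        a = predict_latent_states(tp, connectome, T=50)
        b = predict_latent_states(tp, connectome, T=50)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.z, b.z)

    def test_epileptogenic_regions_show_depolarization_shift(self):
        """Two regions at x0=-1.8 with connected neighbours at -2.3 move
        from the interictal to the ictal branch within the window."""
        n = 4
        C = np.array([
            [0, 1.0, 0.8, 0.8],
            [1.0, 0, 0.8, 0.8],
            [0.8, 0.8, 0, 0.1],
            [0.8, 0.8, 0.1, 0],
        ])
        theta = ThetaParameters(
            x0=np.array([-1.8, -1.8, -2.3, -2.3]),
            x_init=np.full(n, -2.0), z_init=np.full(n, 3.5),
            K=1.0, tau0=20.0, alpha=1.0, beta=0.0, eps1=1.0, eps2=1.0)
        latent = predict_latent_states(theta, Connectome(weights=C), T=300)
        assert latent.x[0].max() > 0.0
        assert latent.x[1].max() > 0.0

    def test_y_matrix_interleaves_x_and_z(self, small_problem):
        connectome, priors, obs, theta_vec = small_problem
        tp = unpack_theta(theta_vec, priors.n_regions)
        latent = predict_latent_states(tp, connectome, T=20)
        Y = latent.Y
        np.testing.assert_array_equal(Y[0], latent.x[0])
        np.testing.assert_array_equal(Y[1], latent.z[0])
        assert Y.shape == (2 * priors.n_regions, 20)


class TestLogLikelihood:
    def _perfect_obs(self):
        """Single region, single sensor, observations equal to the model
        prediction with alpha=1, beta=0."""
        n, T = 1, 40
        C = np.zeros((1, 1))
        theta = ThetaParameters(
            x0=np.array([-3.0]), x_init=np.array([-2.0]),
            z_init=np.array([3.5]), K=0.0, tau0=20.0,
            alpha=1.0, beta=0.0, eps1=1.0, eps2=1.0)
        latent = predict_latent_states(theta, C, T=T)
        S = np.log(np.exp(latent.x)).T  # G = [1]
        feats = DataFeatures(S=S, rho=np.mean(S ** 2, axis=0),
                             times=np.arange(T, dtype=float))
        obs = Observation(features=feats, gain=GainMatrix(G=np.eye(1)))
        return theta, latent, obs, T

    def test_zero_residuals_give_normalization_terms(self):
        theta, latent, obs, T = self._perfect_obs()
        ll = log_likelihood(theta, latent, obs)
        # S term: T samples at the mean; rho term: model-predicted moment
        # equals the observed moment because predictions are exact
        expected = -T * (0.0 + 0.5 * _LOG_2PI) - 1 * (0.0 + 0.5 * _LOG_2PI)
        assert ll == pytest.approx(expected)

    def test_beta_offset_degeneracy(self, small_problem):
        """Adding kappa to beta and subtracting it from every observed
        sample leaves the S-likelihood unchanged (checked with the rho
        term neutralized by a huge eps2)."""
        connectome, priors, obs, theta_vec = small_problem
        n = priors.n_regions
        kappa = 0.7
        tp = unpack_theta(theta_vec, n)
        tp.eps2 = 1e8  # neutralize the total-power term
        latent = predict_latent_states(tp, connectome, T=obs.n_times)
        base = log_likelihood(tp, latent, obs)

        shifted = unpack_theta(theta_vec, n)
        shifted.eps2 = 1e8
        shifted.beta += kappa
        feats = obs.features
        feats_shift = DataFeatures(
            S=feats.S + kappa, rho=feats.rho, times=feats.times)
        obs_shift = Observation(features=feats_shift, gain=obs.gain)
        shifted_ll = log_likelihood(shifted, latent, obs_shift)
        assert shifted_ll == pytest.approx(base, abs=1e-6)

    def test_residual_scaling_follows_gaussian_quadratic(self):
        theta, latent, obs, T = self._perfect_obs()
        S = obs.features.S + 0.5  # uniform residual 0.5
        feats = DataFeatures(S=S, rho=obs.features.rho,
                             times=obs.features.times)
        # keep rho unchanged -> rho residual changes too; neutralize it
        theta.eps2 = 1e8
        obs2 = Observation(features=feats, gain=obs.gain)
        ll1 = log_likelihood(theta, latent, obs2)
        feats4 = DataFeatures(S=obs.features.S + 1.0, rho=obs.features.rho,
                              times=obs.features.times)
        obs4 = Observation(features=feats4, gain=obs.gain)
        ll2 = log_likelihood(theta, latent, obs4)
        base = log_likelihood(theta, latent,
                              Observation(features=DataFeatures(
                                  S=obs.features.S, rho=obs.features.rho,
                                  times=obs.features.times), gain=obs.gain))
        # doubling every residual quadruples the quadratic penalty
        assert (ll2 - base) == pytest.approx(4.0 * (ll1 - base), rel=1e-6)


class TestLogPosterior:
    def test_additivity(self, small_problem):
        connectome, priors, obs, theta_vec = small_problem
        tp = unpack_theta(theta_vec, priors.n_regions)
        latent = predict_latent_states(tp, connectome, T=obs.n_times)
        lp = log_posterior(theta_vec, obs, priors, connectome)
        assert lp == pytest.approx(
            log_prior(theta_vec, priors) + log_likelihood(tp, latent, obs))

    def test_gradient_matches_finite_differences(self, small_problem):
        """Central finite differences at several random draws near the
        prior means (rtol 1e-4, step 1e-5)."""
        connectome, priors, obs, _ = small_problem
        rng = np.random.default_rng(42)
        dim = priors.mean.shape[0]
        step = 1e-5
        for _ in range(10):
            vec = priors.mean + 0.2 * rng.standard_normal(dim)
            vec[priors.truncated] = np.abs(vec[priors.truncated]) + 0.5
            _, grad = log_posterior_with_grad(vec, obs, priors, connectome)
            fd = np.empty(dim)
            for i in range(dim):
                up, dn = vec.copy(), vec.copy()
                up[i] += step
                dn[i] -= step
                fd[i] = (log_posterior(up, obs, priors, connectome)
                         - log_posterior(dn, obs, priors, connectome)) \
                    / (2 * step)
            np.testing.assert_allclose(grad, fd, rtol=1e-4, atol=1e-6)

    def test_ground_truth_beats_random_prior_draws(self):
        """With identity-like gain and noiseless model-generated features
        the generating parameters attain a higher posterior than 100 draws
        from the prior."""
        n, T = 4, 60
        rng = np.random.default_rng(13)
        C = rng.uniform(0, 0.5, (n, n))
        C = 0.5 * (C + C.T)
        np.fill_diagonal(C, 0)
        connectome = Connectome(weights=C)
        priors = make_priors([0], n)
        truth = priors.mean + 0.05 * rng.standard_normal(3 * n + 6)
        truth[priors.truncated] = np.abs(truth[priors.truncated])
        tp = unpack_theta(truth, n)
        G = np.eye(n) + 0.05
        latent = predict_latent_states(tp, connectome, T=T)
        S = (tp.alpha * np.log(G @ np.exp(latent.x)) + tp.beta).T
        feats = DataFeatures(S=S, rho=np.mean(S ** 2, axis=0),
                             times=np.arange(T, dtype=float))
        obs = Observation(features=feats, gain=GainMatrix(G=G))
        lp_truth = log_posterior(truth, obs, priors, connectome)
        n_better = 0
        for _ in range(100):
            draw = priors.mean + priors.sd * rng.standard_normal(3 * n + 6)
            bad = priors.truncated & (draw <= 0)
            draw[bad] = np.abs(draw[bad]) + 1e-6
            if log_posterior(draw, obs, priors, connectome) > lp_truth:
                n_better += 1
        assert n_better == 0

    def test_divergent_theta_maps_to_neg_inf(self, small_problem):
        connectome, priors, obs, theta_vec = small_problem
        bad = theta_vec.copy()
        bad[priors.n_regions:2 * priors.n_regions] = 500.0  # x_init huge
        assert log_posterior(bad, obs, priors, connectome) == -np.inf
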