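"""Generative-model densities against independent per-term oracles."""

import numpy as np
import pytest
from scipy import stats

import sociomort as sm
from sociomort.model import ModelError, ModelSpec

from conftest import random_design


def oracle_log_prior(state, spec):
    """Independent per-term sum of elementary log-densities."""
    s = np.asarray(state.s_beta)
    Sigma = np.outer(s, s) * state.corr_beta
    lp = stats.multivariate_normal.logpdf(state.beta[0], np.zeros(spec.k), Sigma)
    for t in range(1, spec.T + 1):
        lp += stats.multivariate_normal.logpdf(
            state.beta[t] - state.beta[t - 1] - state.mu_beta,
            np.zeros(spec.k), Sigma)
    lp += stats.norm.logpdf(state.log_sigma[0], scale=state.ell)
    for t in range(1, spec.T + 1):
        lp += stats.norm.logpdf(
            state.log_sigma[t] - state.log_sigma[t - 1] - state.mu_sigma,
            scale=state.ell)
    for v in state.mu_beta:
        lp += stats.norm.logpdf(v)
    lp += stats.norm.logpdf(state.mu_sigma)
    for v in s:
        lp += stats.lognorm.logpdf(v, 1.0)
    lp += stats.lognorm.logpdf(state.ell, 1.0)
    if spec.variant != "baseline":
        sg = np.asarray(state.s_gamma)
        Lam = np.outer(sg, sg) * state.corr_gamma
        lp += stats.multivariate_normal.logpdf(state.gamma[0], np.zeros(spec.g), Lam)
        for t in range(1, spec.T + 1):
            lp += stats.multivariate_normal.logpdf(
                state.gamma[t] - state.gamma[t - 1] - state.mu_gamma,
                np.zeros(spec.g), Lam)
        for v in state.mu_gamma:
            lp += stats.norm.logpdf(v)
        for v in sg:
            lp += stats.lognorm.logpdf(v, 1.0)
    return float(lp)


def oracle_log_likelihood(state, spec, X, Y, F):
    lp = 0.0
    for t in range(1, spec.T + 1):
        for n in range(spec.N):
            mean = X[t - 1][n] @ state.beta[t]
            if spec.variant != "baseline":
                mean += F[t - 1][n] @ state.gamma[t]
            lp += stats.norm.logpdf(Y[n, t - 1], mean, np.exp(state.log_sigma[t]))
    return float(lp)


class TestLogPrior:
    @pytest.mark.parametrize("variant", ["baseline", "sp", "wsp"])
    def test_matches_per_term_oracle(self, variant, rng):
        for trial in range(25):
            spec = ModelSpec(variant=variant, p=int(rng.integers(1, 4)),
                             N=int(rng.integers(2, 6)), T=int(rng.integers(1, 4)))
            state = sm.sample_prior(spec, int(rng.integers(1 << 30)))
            assert sm.log_prior(state, spec) == pytest.approx(
                oracle_log_prior(state, spec), abs=1e-8, rel=1e-9)

    def test_lkj_flat_over_correlations(self, rng):
        """Two states differing only in their correlation matrices have prior
        log-densities that differ only through the walk terms, not an LKJ
        normalizer; with identity walks removed, contributions are equal."""
        spec = ModelSpec(variant="baseline", p=2, N=3, T=1)
        a = sm.sample_prior(spec, 1)
        b = sm.sample_prior(spec, 2)
        b2 = sm.sample_prior(spec, 2)
        b2.corr_beta = a.corr_beta.copy()
        # oracle contains no correlation-dependent term beyond the MVNs
        diff_model = sm.log_prior(b, spec) - sm.log_prior(b2, spec)
        diff_oracle = oracle_log_prior(b, spec) - oracle_log_prior(b2, spec)
        assert diff_model == pytest.approx(diff_oracle, abs=1e-8)

    def test_initial_condition_standard_mvn(self):
        """beta_0 = 0 with Sigma = I contributes -(k/2) log(2 pi)."""
        spec = ModelSpec(variant="baseline", p=2, N=3, T=1)
        state = sm.sample_prior(spec, 0)
        state.beta = np.zeros_like(state.beta)
        state.s_beta = np.ones(spec.k)
        state.corr_beta = np.eye(spec.k)
        state.mu_beta = np.zeros(spec.k)
        lp = sm.log_prior(state, spec)
        # isolate the beta_0 term by comparing against the oracle's remainder
        rest = oracle_log_prior(state, spec) - stats.multivariate_normal.logpdf(
            np.zeros(spec.k), np.zeros(spec.k), np.eye(spec.k))
        assert lp - rest == pytest.approx(-(spec.k / 2) * np.log(2 * np.pi), abs=1e-9)

    def test_invalid_states_error(self):
        spec = ModelSpec(variant="baseline", p=2, N=3, T=1)
        state = sm.sample_prior(spec, 0)
        state.s_beta = -np.abs(state.s_beta)
        with pytest.raises(ModelError):
            sm.log_prior(state, spec)
        state = sm.sample_prior(spec, 0)
        state.corr_beta = np.array([[1.0, 2.0, 0], [2.0, 1, 0], [0, 0, 1.0]])
        with pytest.raises(ModelError):
            sm.log_prior(state, spec)


class TestLogLikelihood:
    def test_zero_residual_unit_sigma(self):
        spec = ModelSpec(variant="baseline", p=1, N=2, T=1)
        state = sm.sample_prior(spec, 3)
        state.log_sigma = np.zeros(spec.T + 1)
        X = np.ones((1, 2, 2))
        Y = (X[0] @ state.beta[1]).reshape(2, 1)
        ll = sm.log_likelihood(state, spec, X, Y)
        assert ll == pytest.approx(2 * -0.5 * np.log(2 * np.pi), abs=1e-10)

    def test_doubling_sigma_costs_log2_per_obs(self):
        spec = ModelSpec(variant="baseline", p=1, N=3, T=2)
        state = sm.sample_prior(spec, 4)
        X = np.random.default_rng(0).standard_normal((2, 3, 2))
        X[:, :, 0] = 1.0
        Y = np.stack([X[t] @ state.beta[t + 1] for t in range(2)], axis=1)
        base = sm.log_likelihood(state, spec, X, Y)
        state.log_sigma = state.log_sigma + np.log(2)
        assert sm.log_likelihood(state, spec, X, Y) == pytest.approx(
            base - 6 * np.log(2), abs=1e-9)

    @pytest.mark.parametrize("variant", ["baseline", "sp"])
    def test_matches_per_obs_oracle(self, variant, rng):
        for trial in range(20):
            spec = ModelSpec(variant=variant, p=1, N=3, T=2)
            X, F, Y = random_design(spec, rng)
            # moderate states: keep magnitudes where 1e-8 is meaningful
            state = sm.constrain(rng.standard_normal(sm.latent_dim(spec)), spec)
            assert sm.log_likelihood(state, spec, X, Y, F) == pytest.approx(
                oracle_log_likelihood(state, spec, X, Y, F), abs=1e-8)
            wild = sm.sample_prior(spec, int(rng.integers(1 << 30)))
            assert sm.log_likelihood(wild, spec, X, Y, F) == pytest.approx(
                oracle_log_likelihood(wild, spec, X, Y, F), abs=1e-8, rel=1e-9)

    def test_spatial_nests_baseline(self, rng):
        """sp/wsp likelihood with gamma = 0 equals the baseline likelihood."""
        spec_sp = ModelSpec(variant="sp", p=2, N=4, T=2)
        spec_b = ModelSpec(variant="baseline", p=2, N=4, T=2)
        X, F, Y = random_design(spec_sp, rng)
        state = sm.sample_prior(spec_sp, 9)
        state.gamma = np.zeros_like(state.gamma)
        base_state = sm.sample_prior(spec_b, 9)
        for f in ("beta", "log_sigma", "mu_beta", "mu_sigma", "s_beta",
                  "corr_beta", "ell"):
            setattr(base_state, f, getattr(state, f))
        assert sm.log_likelihood(state, spec_sp, X, Y, F) == pytest.approx(
            sm.log_likelihood(base_state, spec_b, X, Y), abs=1e-12)

    def test_missing_neighbor_design_errors(self, rng):
        spec = ModelSpec(variant="sp", p=2, N=4, T=2)
        X, F, Y = random_design(spec, rng)
        state = sm.sample_prior(spec, 1)
        with pytest.raises(ModelError):
            sm.log_likelihood(state, spec, X, Y, None)


class TestSamplePrior:
    def test_beta0_zero_centered(self):
        means = np.array([sm.sample_prior(ModelSpec(p=2, N=3, T=1), s).beta[0]
                          for s in range(5000)])
        se = means.std(axis=0) / np.sqrt(len(means))
        assert np.all(np.abs(means.mean(axis=0)) < 3 * se + 1e-12)

    def test_log_sigma_increment_scale(self):
        """Var of (log sigma_t - log sigma_{t-1} - mu) given ell equals ell^2."""
        spec = ModelSpec(p=1, N=2, T=3)
        ratios = []
        for s in range(5000):
            st = sm.sample_prior(spec, s)
            inc = np.diff(st.log_sigma) - st.mu_sigma
            ratios.extend(inc / st.ell)  # should be iid standard normal
        assert np.var(ratios) == pytest.approx(1.0, abs=0.05)

    def test_correlations_valid(self):
        for s in range(200):
            st = sm.sample_prior(ModelSpec(variant="sp", p=3, N=3, T=1), s)
            for C in (st.corr_beta, st.corr_gamma):
                np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
                assert np.all(np.linalg.eigvalsh(C) > 0)

    def test_deterministic_given_seed(self):
        a = sm.sample_prior(ModelSpec(p=2, N=3, T=2), 42)
        b = sm.sample_prior(ModelSpec(p=2, N=3, T=2), 42)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_walk_reconstructs_from_innovations(self):
        st = sm.sample_prior(ModelSpec(p=2, N=3, T=2), 7)
        L = st.chol_beta()
        beta = np.empty_like(st.beta)
        beta[0] = L @ st.v_beta[0]
        for t in range(1, 3):
            beta[t] = beta[t - 1] + st.mu_beta + L @ st.v_beta[t]
        np.testing.assert_allclose(beta, st.beta, atol=1e-12)


class TestPredict:
    def test_zero_coefficients(self, rng):
        spec = ModelSpec(variant="sp", p=2, N=4, T=2)
        X, F, _ = random_design(spec, rng)
        st = sm.sample_prior(spec, 1)
        st.beta = np.zeros_like(st.beta)
        st.gamma = np.zeros_like(st.gamma)
        np.testing.assert_array_equal(sm.predict(st, spec, X, F), 0.0)

    def test_intercept_only(self, rng):
        spec = ModelSpec(variant="baseline", p=2, N=4, T=2)
        X, _, _ = random_design(spec, rng)
        st = sm.sample_prior(spec, 1)
        st.beta = np.zeros_like(st.beta)
        st.beta[:, 0] = 3.5
        np.testing.assert_allclose(sm.predict(st, spec, X), 3.5, atol=1e-12)

    def test_identical_covariates_fold_gamma_into_beta(self, rng):
        """With every district identical, the sp prediction equals a baseline
        prediction whose non-intercept coefficients are beta + gamma."""
        spec = ModelSpec(variant="sp", p=2, N=4, T=2)
        row = rng.standard_normal(spec.p)
        X = np.tile(np.concatenate([[1.0], row]), (spec.T, spec.N, 1))
        F = np.tile(row, (spec.T, spec.N, 1))
        st = sm.sample_prior(spec, 5)
        spec_b = ModelSpec(variant="baseline", p=2, N=4, T=2)
        st_b = sm.sample_prior(spec_b, 5)
        st_b.beta = st.beta.copy()
        st_b.beta[:, 1:] += st.gamma
        for f in ("log_sigma", "mu_beta", "mu_sigma", "s_beta", "corr_beta", "ell"):
            setattr(st_b, f, getattr(st, f))
        np.testing.assert_allclose(sm.predict(st, spec, X, F),
                                   sm.predict(st_b, spec_b, X), atol=1e-10)

    def test_noise_deterministic_given_seed(self, rng):
        spec = ModelSpec(variant="baseline", p=2, N=4, T=2)
        X, _, _ = random_design(spec, rng)
        st = sm.sample_prior(spec, 1)
        a = sm.predict(st, spec, X, noise=True, seed=3)
        b = sm.predict(st, spec, X, noise=True, seed=3)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, sm.predict(st, spec, X))


class TestLogJoint:
    def test_finite_for_prior_draws(self, rng):
        spec = ModelSpec(variant="wsp", p=2, N=4, T=2)
        X, F, Y = random_design(spec, rng)
        vals = [sm.log_joint(sm.sample_prior(spec, s), spec, X, Y, F)
                for s in range(50)]
        assert np.all(np.isfinite(vals))

    def test_decreases_with_residual_growth(self, rng):
        spec = ModelSpec(variant="baseline", p=2, N=4, T=2)
        X, _, Y = random_design(spec, rng)
        st = sm.sample_prior(spec, 2)
        base = sm.log_likelihood(st, spec, X, Y)
        worse = sm.log_likelihood(st, spec, X, Y + 10.0)
        assert worse < base
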