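"""Unconstrained-space bijection, Jacobians and the autodiff core."""

import numpy as np
import pytest

import sociomort as sm
from sociomort import _autodiff as ad
from sociomort.model import ModelSpec
from sociomort.transforms import (LatentLayout, corr_chol_to_theta,
                                  make_logdensity, theta_to_corr_chol,
                                  _tri_size)

from conftest import random_design


class TestBijection:
    @pytest.mark.parametrize("variant", ["baseline", "sp"])
    def test_round_trip(self, variant, rng):
        spec = ModelSpec(variant=variant, p=2, N=4, T=2)
        for s in range(10):
            state = sm.sample_prior(spec, s)
            z = sm.unconstrain(state, spec)
            z2 = sm.unconstrain(sm.constrain(z, spec), spec)
            assert np.max(np.abs(z - z2)) < 1e-9

    def test_unit_ell_maps_to_zero(self):
        spec = ModelSpec(variant="baseline", p=1, N=2, T=1)
        state = sm.sample_prior(spec, 0)
        state.ell = 1.0
        z = sm.unconstrain(state, spec)
        assert z[LatentLayout(spec).slices["log_ell"]][0] == 0.0

    def test_zero_theta_gives_identity_correlation(self):
        spec = ModelSpec(variant="baseline", p=3, N=4, T=1)
        lay = LatentLayout(spec)
        z = np.zeros(lay.dim)
        state = sm.constrain(z, spec)
        np.testing.assert_allclose(state.corr_beta, np.eye(spec.k), atol=1e-12)

    def test_constrain_total_on_reals(self, rng):
        """Any real vector, including extreme ones, maps to a valid state."""
        spec = ModelSpec(variant="sp", p=2, N=4, T=2)
        lay = LatentLayout(spec)
        for scale in (1.0, 10.0, 30.0):
            state = sm.constrain(rng.standard_normal(lay.dim) * scale, spec)
            state.validate(spec)

    @pytest.mark.parametrize("variant", ["baseline", "sp", "wsp"])
    def test_unconstrained_density_identity(self, variant, rng):
        """The differentiated density equals
        log_prior(constrain(z)) + log_likelihood + log_jacobian(z)."""
        spec = ModelSpec(variant=variant, p=2, N=4, T=2)
        X, F, Y = random_design(spec, rng)
        logdens = make_logdensity(spec, X, Y, F)
        lay = LatentLayout(spec)
        z = rng.standard_normal((5, lay.dim)) * 0.8
        vals = logdens(ad.Var(z)).value
        for b in range(5):
            st = sm.constrain(z[b], spec)
            ref = (sm.log_prior(st, spec) + sm.log_likelihood(st, spec, X, Y, F)
                   + sm.log_jacobian(z[b], spec))
            assert vals[b] == pytest.approx(ref, abs=1e-8)


class TestCorrelationTransform:
    @pytest.mark.parametrize("K", [2, 3, 5])
    def test_jacobian_matches_finite_differences(self, K, rng):
        m = _tri_size(K)
        theta = rng.standard_normal(m) * 0.7
        il = np.tril_indices(K, k=-1)

        def corr_vec(t):
            L, _ = theta_to_corr_chol(t, K)
            return (L @ L.T)[il]

        J = np.empty((m, m))
        for i in range(m):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            J[:, i] = (corr_vec(tp) - corr_vec(tm)) / 2e-6
        _, logjac = theta_to_corr_chol(theta, K)
        assert logjac == pytest.approx(np.linalg.slogdet(J)[1], abs=1e-5)

    def test_inverse(self, rng):
        for K in (2, 4, 6):
            theta = rng.standard_normal(_tri_size(K)) * 0.8
            L, _ = theta_to_corr_chol(theta, K)
            np.testing.assert_allclose(corr_chol_to_theta(L), theta, atol=1e-9)

    def test_produces_valid_cholesky(self, rng):
        for K in (2, 5):
            L, _ = theta_to_corr_chol(rng.standard_normal(_tri_size(K)) * 3, K)
            C = L @ L.T
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-10)
            assert np.all(np.linalg.eigvalsh(C) > 0)


def _fd_grad(f, x, h=1e-6):
    g = np.empty_like(x)
    for i in np.ndindex(x.shape):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2 * h)
    return g


class TestAutodiff:
    @pytest.mark.parametrize("op", [
        lambda v: (v * v + 2.0 * v).sum(),
        lambda v: (v.exp() + (v * v + 1.0).log()).sum(),
        lambda v: v.tanh().sum(),
        lambda v: ((v * v + 0.5).sqrt()).sum(),
        lambda v: (v ** 3.0).sum(),
        lambda v: (v / (v * v + 2.0)).sum(),
        lambda v: v.cumsum(axis=1).sum(),
        lambda v: (v * v + 0.1).cumprod(axis=1).sum(),
        lambda v: v[:, 1:].sum() + 2.0 * v[0, 0],
        lambda v: v.reshape(6).sum(axis=0),
        lambda v: v.transpose((1, 0)).cumsum(axis=0).sum(),
    ])
    def test_elementwise_ops_match_finite_differences(self, op, rng):
        x = rng.standard_normal((2, 3))
        xv = ad.Var(x)
        (g,) = ad.grad(op(xv), [xv])
        fd = _fd_grad(lambda a: float(op(ad.Var(a)).value), x)
        np.testing.assert_allclose(g, fd, atol=1e-6)

    def test_matmul_batched(self, rng):
        a = rng.standard_normal((3, 2, 4))
        b = rng.standard_normal((3, 4, 2))
        av, bv = ad.Var(a), ad.Var(b)
        out = (ad.matmul(av, bv) ** 2.0).sum()
        ga, gb = ad.grad(out, [av, bv])
        fd_a = _fd_grad(lambda x: float(((ad.matmul(ad.Var(x), bv)) ** 2.0).sum().value), a)
        fd_b = _fd_grad(lambda x: float(((ad.matmul(av, ad.Var(x))) ** 2.0).sum().value), b)
        np.testing.assert_allclose(ga, fd_a, atol=1e-5)
        np.testing.assert_allclose(gb, fd_b, atol=1e-5)

    def test_matmul_broadcast_const(self, rng):
        c = rng.standard_normal((3, 4, 2))  # constant with batch dim
        b = rng.standard_normal((5, 3, 2, 1))
        bv = ad.Var(b)
        out = (ad.matmul(c, bv) ** 2.0).sum()
        (gb,) = ad.grad(out, [bv])
        fd = _fd_grad(lambda x: float(((ad.matmul(c, ad.Var(x))) ** 2.0).sum().value), b)
        np.testing.assert_allclose(gb, fd, atol=1e-5)

    def test_solve(self, rng):
        a = rng.standard_normal((2, 3, 3)) + 3 * np.eye(3)
        b = rng.standard_normal((2, 3, 2))
        av, bv = ad.Var(a), ad.Var(b)
        out = (ad.solve(av, bv) ** 2.0).sum()
        ga, gb = ad.grad(out, [av, bv])
        fd_a = _fd_grad(lambda x: float(((ad.solve(ad.Var(x), bv)) ** 2.0).sum().value), a)
        fd_b = _fd_grad(lambda x: float(((ad.solve(av, ad.Var(x))) ** 2.0).sum().value), b)
        np.testing.assert_allclose(ga, fd_a, atol=1e-5)
        np.testing.assert_allclose(gb, fd_b, atol=1e-5)

    def test_logdet_psd(self, rng):
        a = rng.standard_normal((4, 4))
        m = a @ a.T + 4 * np.eye(4)
        mv = ad.Var(m)
        (g,) = ad.grad(ad.logdet_psd(mv), [mv])
        np.testing.assert_allclose(g, np.linalg.inv(m), atol=1e-8)

    def test_concatenate(self, rng):
        x = rng.standard_normal((2, 2))
        y = rng.standard_normal((2, 3))
        xv, yv = ad.Var(x), ad.Var(y)
        out = (ad.concatenate([xv, yv], axis=1) ** 2.0).sum()
        gx, gy = ad.grad(out, [xv, yv])
        np.testing.assert_allclose(gx, 2 * x, atol=1e-12)
        np.testing.assert_allclose(gy, 2 * y, atol=1e-12)

    def test_broadcast_unbroadcast(self, rng):
        x = rng.standard_normal((3, 1))
        y = rng.standard_normal((1, 4))
        xv, yv = ad.Var(x), ad.Var(y)
        out = (xv * yv + xv - yv).sum()
        gx, gy = ad.grad(out, [xv, yv])
        fd_x = _fd_grad(lambda a: float(((ad.Var(a) * yv + ad.Var(a) - yv)).sum().value), x)
        fd_y = _fd_grad(lambda a: float(((xv * ad.Var(a) + xv - ad.Var(a))).sum().value), y)
        np.testing.assert_allclose(gx, fd_x, atol=1e-6)
        np.testing.assert_allclose(gy, fd_y, atol=1e-6)

    def test_diamond_graph_accumulates(self):
        x = ad.Var(np.array(2.0))
        y = x * x + x * x  # two paths to the same leaf
        (g,) = ad.grad(y, [x])
        assert g == pytest.approx(8.0)

    def test_full_model_gradient(self, rng):
        """End-to-end gradient of the model density vs finite differences."""
        spec = ModelSpec(variant="sp", p=2, N=3, T=2)
        X, F, Y = random_design(spec, rng)
        ld = make_logdensity(spec, X, Y, F)
        d = sm.latent_dim(spec)
        z0 = rng.standard_normal(d) * 0.5
        zv = ad.Var(z0[None, :])
        (g,) = ad.grad(ld(zv).sum(), [zv])
        idx = rng.choice(d, size=15, replace=False)
        for i in idx:
            zp, zm = z0.copy(), z0.copy()
            zp[i] += 1e-6
            zm[i] -= 1e-6
            fd = (ld(ad.Var(zp[None, :])).value[0]
                  - ld(ad.Var(zm[None, :])).value[0]) / 2e-6
            assert g[0, i] == pytest.approx(fd, abs=1e-5, rel=1e-4)
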