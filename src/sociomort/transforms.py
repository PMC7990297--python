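"""Bijection between latent states and an unconstrained vector space.

Variational inference operates on a flat real vector ``z`` holding the
latents in *centered* form: the coefficient and log-volatility paths enter
as their actual values (they are already unconstrained, and conditional on
the hyperparameters their posterior is Gaussian, which suits a Gaussian
guide), positive scalars enter through ``log``, and correlation matrices
through the canonical partial-correlation (CPC) parameterization of their
Cholesky factor (tanh of unconstrained coordinates). The only non-identity
Jacobians are the log maps and the CPC-to-correlation transform, whose
log-determinant has the closed form (checked numerically in the tests)

    log|J| = sum_{i>j} log(1 - z_ij^2) + sum_{i>j} log W_ij
             + sum_j (K-1-j) log Lc[j, j]

with ``W_ij = prod_{m<j} sqrt(1 - z_im^2)`` the residual norm before entry
``(i, j)`` and ``Lc`` the Cholesky factor of the correlation matrix.

:func:`make_logdensity` builds the differentiable unconstrained-space log
joint used by the ELBO; it equals
``log_prior(constrain(z)) + log_likelihood(...) + log_jacobian(z)``, an
identity asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .model import LOG2PI, LatentState, ModelSpec

__all__ = [
    "LatentLayout", "latent_dim", "unconstrain", "constrain", "log_jacobian",
    "theta_to_corr_chol", "corr_chol_to_theta", "make_logdensity",
]


# ---------------------------------------------------------------------------
# correlation-matrix transform (numpy side)
# ---------------------------------------------------------------------------

def _tri_size(K: int) -> int:
    return K * (K - 1) // 2


def _strict_lower_indices(K: int):
    return np.tril_indices(K, k=-1)


def theta_to_corr_chol(theta: np.ndarray, K: int):
    """Map unconstrained CPC coordinates to (Cholesky factor, log-Jacobian)."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (_tri_size(K),):
        raise ValueError(f"theta must have length {_tri_size(K)}")
    if K == 1:
        return np.ones((1, 1)), 0.0
    zmat = np.zeros((K, K))
    # keep |z| strictly below 1 so the Cholesky factor stays nonsingular
    zmat[_strict_lower_indices(K)] = np.tanh(theta) * (1.0 - 1e-8)
    s2 = 1.0 - zmat ** 2          # equals 1 outside the strict lower triangle
    P = np.ones((K, K))
    P[:, 1:] = np.cumprod(np.sqrt(s2[:, :-1]), axis=1)
    L = (zmat + np.eye(K)) * P
    il = _strict_lower_indices(K)
    logjac = (np.log(s2[il]).sum() + np.log(P[il]).sum()
              + ((K - 1 - np.arange(K)) * np.log(np.diag(P))).sum())
    return L, float(logjac)


def corr_chol_to_theta(L: np.ndarray) -> np.ndarray:
    """Inverse of :func:`theta_to_corr_chol` (ignoring the Jacobian)."""
    L = np.asarray(L, dtype=float)
    K = L.shape[0]
    if K == 1:
        return np.zeros(0)
    cums = np.concatenate([np.zeros((K, 1)), np.cumsum(L ** 2, axis=1)[:, :-1]], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        zmat = L / np.sqrt(np.clip(1.0 - cums, 1e-300, None))
    return np.arctanh(np.clip(zmat[_strict_lower_indices(K)] / (1.0 - 1e-8),
                              -1.0 + 1e-15, 1.0 - 1e-15))


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatentLayout:
    """Slices of the flat unconstrained vector for one model variant."""

    spec: ModelSpec

    def _segments(self):
        k, g, T = self.spec.k, self.spec.g, self.spec.T
        segs = [
            ("beta", (T + 1) * k),
            ("log_sigma", T + 1),
            ("mu_beta", k),
            ("mu_sigma", 1),
            ("log_s_beta", k),
            ("theta_beta", _tri_size(k)),
            ("log_ell", 1),
        ]
        if self.spec.variant != "baseline":
            segs += [
                ("gamma", (T + 1) * g),
                ("mu_gamma", g),
                ("log_s_gamma", g),
                ("theta_gamma", _tri_size(g)),
            ]
        return segs

    @property
    def slices(self) -> dict:
        out, off = {}, 0
        for name, size in self._segments():
            out[name] = slice(off, off + size)
            off += size
        return out

    @property
    def dim(self) -> int:
        return sum(size for _, size in self._segments())

    def names(self) -> list:
        """Flat coordinate names (for serialized guide/state vectors)."""
        out = []
        for name, size in self._segments():
            out.extend(f"{name}[{i}]" for i in range(size))
        return out


def latent_dim(spec: ModelSpec) -> int:
    return LatentLayout(spec).dim


# ---------------------------------------------------------------------------
# constrain / unconstrain (numpy)
# ---------------------------------------------------------------------------

def constrain(z: np.ndarray, spec: ModelSpec) -> LatentState:
    """Map any real vector to a valid latent state (total on R^d)."""
    z = np.asarray(z, dtype=float)
    lay = LatentLayout(spec)
    if z.shape != (lay.dim,):
        raise ValueError(f"z must have length {lay.dim}")
    sl = lay.slices
    k, g, T = spec.k, spec.g, spec.T

    Lc, _ = theta_to_corr_chol(z[sl["theta_beta"]], k)
    state = LatentState(
        beta=z[sl["beta"]].reshape(T + 1, k),
        log_sigma=z[sl["log_sigma"]].copy(),
        mu_beta=z[sl["mu_beta"]].copy(),
        mu_sigma=float(z[sl["mu_sigma"]][0]),
        s_beta=np.exp(z[sl["log_s_beta"]]),
        corr_beta=Lc @ Lc.T,
        ell=float(np.exp(z[sl["log_ell"]][0])),
    )
    if spec.variant != "baseline":
        Lcg, _ = theta_to_corr_chol(z[sl["theta_gamma"]], g)
        state.gamma = z[sl["gamma"]].reshape(T + 1, g)
        state.mu_gamma = z[sl["mu_gamma"]].copy()
        state.s_gamma = np.exp(z[sl["log_s_gamma"]])
        state.corr_gamma = Lcg @ Lcg.T
    return state


def unconstrain(state: LatentState, spec: ModelSpec) -> np.ndarray:
    """Inverse of :func:`constrain`; errors on invalid states."""
    state.validate(spec)
    lay = LatentLayout(spec)
    sl = lay.slices
    z = np.empty(lay.dim)
    z[sl["beta"]] = np.asarray(state.beta).ravel()
    z[sl["log_sigma"]] = state.log_sigma
    z[sl["mu_beta"]] = state.mu_beta
    z[sl["mu_sigma"]] = state.mu_sigma
    z[sl["log_s_beta"]] = np.log(state.s_beta)
    z[sl["theta_beta"]] = corr_chol_to_theta(np.linalg.cholesky(state.corr_beta))
    z[sl["log_ell"]] = np.log(state.ell)
    if spec.variant != "baseline":
        z[sl["gamma"]] = np.asarray(state.gamma).ravel()
        z[sl["mu_gamma"]] = state.mu_gamma
        z[sl["log_s_gamma"]] = np.log(state.s_gamma)
        z[sl["theta_gamma"]] = corr_chol_to_theta(np.linalg.cholesky(state.corr_gamma))
    return z


def log_jacobian(z: np.ndarray, spec: ModelSpec) -> float:
    """log |d constrain / dz| at ``z`` (log maps plus the CPC transform)."""
    z = np.asarray(z, dtype=float)
    lay = LatentLayout(spec)
    sl = lay.slices
    _, corr_jac = theta_to_corr_chol(z[sl["theta_beta"]], spec.k)
    total = z[sl["log_s_beta"]].sum() + float(z[sl["log_ell"]][0]) + corr_jac
    if spec.variant != "baseline":
        _, corr_jac_g = theta_to_corr_chol(z[sl["theta_gamma"]], spec.g)
        total += z[sl["log_s_gamma"]].sum() + corr_jac_g
    return float(total)


# ---------------------------------------------------------------------------
# differentiable unconstrained-space log density
# ---------------------------------------------------------------------------

def _corr_block(th: "ad.Var", K: int):
    """Batched CPC transform.

    Returns the Cholesky factor (B, K, K), the transform's log-Jacobian (B,)
    and ``sum_j log Lc[j, j]`` (B,) needed by the walk log-determinants.
    """
    m = _tri_size(K)
    il = _strict_lower_indices(K)
    E = np.zeros((m, K * K))
    for idx, (i, j) in enumerate(zip(*il)):
        E[idx, i * K + j] = 1.0
    Bn = th.shape[0]
    zmat = (ad.matmul(th.tanh(), E) * (1.0 - 1e-8)).reshape(Bn, K, K)
    s2 = 1.0 - zmat * zmat
    srt = s2 ** 0.5
    P = ad.concatenate([ad.Var(np.ones((Bn, K, 1))), srt[:, :, : K - 1]],
                       axis=2).cumprod(axis=2)
    L = (zmat + np.eye(K)) * P
    ML = np.zeros((K, K))
    ML[il] = 1.0
    MW = ML + np.diag(K - 1.0 - np.arange(K))
    jac = (s2.log() * ML + P.log() * MW).sum(axis=(1, 2))
    logdiag = (P.log() * np.eye(K)).sum(axis=(1, 2))
    return L, jac, logdiag


def _walk_terms(path, mu, log_s, theta, K, T, Bn):
    """Log density of a Gaussian random-walk block plus its hyperpriors.

    ``path`` is (B, T+1, K): x_0 ~ N(0, Sigma), x_t ~ N(x_{t-1} + mu, Sigma)
    with Sigma = diag(s) C diag(s); adds the CPC Jacobian (flat LKJ(1) prior
    on C) and iid standard-normal terms for mu and log s.
    """
    drift_mask = np.ones((T + 1, 1))
    drift_mask[0, 0] = 0.0
    resid = ad.concatenate([path[:, :1, :], path[:, 1:, :] - path[:, : T, :]],
                           axis=1) - mu.reshape(Bn, 1, K) * drift_mask
    s = log_s.exp()
    scaled = resid / s.reshape(Bn, 1, K)
    if K > 1:
        Lc, jac, logdiag_c = _corr_block(theta, K)
        white = ad.solve(Lc, scaled.transpose((0, 2, 1)))   # (B, K, T+1)
        quad = (white * white).sum(axis=(1, 2))
        extra = jac
    else:
        quad = (scaled * scaled).sum(axis=(1, 2))
        logdiag_c = ad.Var(np.zeros(Bn))
        extra = ad.Var(np.zeros(Bn))
    half_logdet = log_s.sum(axis=1) + logdiag_c
    dens = (quad * (-0.5) - (T + 1.0) * half_logdet
            - 0.5 * (T + 1.0) * K * LOG2PI)
    hyper = ((mu * mu).sum(axis=1) + (log_s * log_s).sum(axis=1)) * (-0.5) \
        - 0.5 * 2 * K * LOG2PI
    return dens + hyper + extra


def make_logdensity(spec: ModelSpec, design: np.ndarray, Y: np.ndarray,
                    neighbor: np.ndarray | None = None):
    """Return ``f(zVar) -> Var`` giving the unconstrained log joint per draw.

    ``zVar`` is a batched ``(B, d)`` autodiff variable; the result is ``(B,)``.
    """
    lay = LatentLayout(spec)
    sl = lay.slices
    k, g, T, N = spec.k, spec.g, spec.T, spec.N
    X = np.asarray(design, dtype=float)          # (T, N, k)
    Yt = np.asarray(Y, dtype=float).T            # (T, N)
    if X.shape != (T, N, k):
        raise ValueError(f"design shape {X.shape} does not match spec")
    F = None
    if spec.variant != "baseline":
        F = np.asarray(neighbor, dtype=float)    # (T, N, g)
        if F.shape != (T, N, g):
            raise ValueError(f"neighbor design shape {F.shape} does not match spec")
    sigma_mask = np.ones(T + 1)
    sigma_mask[0] = 0.0

    def logdensity(z: "ad.Var") -> "ad.Var":
        Bn = z.shape[0]
        col = lambda name: z[:, sl[name]]

        beta = col("beta").reshape(Bn, T + 1, k)
        logdens = _walk_terms(beta, col("mu_beta"), col("log_s_beta"),
                              col("theta_beta"), k, T, Bn)

        # log-volatility walk and its hyperpriors
        ls = col("log_sigma")                              # (B, T+1)
        mus = col("mu_sigma")                              # (B, 1)
        log_ell = col("log_ell")
        ell = log_ell.exp()
        sres = (ad.concatenate([ls[:, :1], ls[:, 1:] - ls[:, :T]], axis=1)
                - mus * sigma_mask) / ell
        logdens = logdens + (sres * sres).sum(axis=1) * (-0.5) \
            - (T + 1.0) * log_ell[:, 0] - 0.5 * (T + 1.0) * LOG2PI
        logdens = logdens + (mus * mus + log_ell * log_ell).sum(axis=1) * (-0.5) \
            - 0.5 * 2 * LOG2PI

        # likelihood
        mean = ad.matmul(X, beta[:, 1:, :].reshape(Bn, T, k, 1)).reshape(Bn, T, N)
        if F is not None:
            gamma = col("gamma").reshape(Bn, T + 1, g)
            logdens = logdens + _walk_terms(gamma, col("mu_gamma"),
                                            col("log_s_gamma"),
                                            col("theta_gamma"), g, T, Bn)
            mean = mean + ad.matmul(F, gamma[:, 1:, :].reshape(Bn, T, g, 1)
                                    ).reshape(Bn, T, N)
        ls_obs = ls[:, 1:].reshape(Bn, T, 1)
        resid = (Yt - mean) / ls_obs.exp()
        loglik = ((resid * resid) * (-0.5) - ls_obs).sum(axis=(1, 2)) \
            - 0.5 * T * N * LOG2PI
        return logdens + loglik

    return logdensity
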