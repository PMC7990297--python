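"""Bayesian state-space regression models for district crude death rates.

Three variants share one backbone. The response for year ``t`` is

    y_t = X_t beta_t (+ F_t gamma_t) + sigma_t u_t,      u_t ~ N(0, I_N)

where ``X_t`` is the (N, p+1) standardized design matrix and ``F_t`` the
(N, p) neighbor-averaged design (absent for the baseline variant, binary
neighbor means for SP, distance-decay weighted means for WSP). Coefficients
follow biased Gaussian random walks,

    beta_t  = beta_{t-1} + mu_beta  + L_beta  v_t,   v_t ~ N(0, I)
    gamma_t = gamma_{t-1} + mu_gamma + L_gamma q_t,
    log sigma_t = log sigma_{t-1} + mu_sigma + ell w_t,

initialised with zero-mean Gaussians (beta_0 ~ N(0, Sigma_beta),
log sigma_0 ~ N(0, ell^2)). The innovation covariance decomposes as
Sigma = diag(s) C diag(s) with s ~ LogNormal(0, 1) elementwise and
C ~ LKJ(1), i.e. uniform over valid correlation matrices (its log-density is
taken as 0 on valid matrices; the omitted normalization constant shifts every
log-joint equally and is irrelevant to inference). Drifts are standard
normal, ell ~ LogNormal(0, 1).

beta_0 (and gamma_0, log sigma_0) are pre-sample initial conditions;
observations use indices 1..T aligned to the census years in order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

LOG2PI = float(np.log(2.0 * np.pi))

VARIANTS = ("baseline", "sp", "wsp")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    variant: str = "baseline"
    p: int = 7
    N: int = 18
    T: int = 3
    response_scale: float = 1000.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ModelError(f"unknown variant {self.variant!r}")
        if self.p < 1 or self.N < 2 or self.T < 1:
            raise ModelError("need p >= 1, N >= 2, T >= 1")

    @property
    def k(self) -> int:
        """Coefficient dimension including the intercept."""
        return self.p + 1

    @property
    def g(self) -> int:
        """Spatial coefficient dimension (0 for the baseline)."""
        return 0 if self.variant == "baseline" else self.p


def _check_corr(C: np.ndarray, what: str) -> None:
    C = np.asarray(C)
    if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ModelError(f"{what} is not a correlation matrix")
    try:
        # tiny jitter: valid matrices can brush singularity in float
        np.linalg.cholesky(C + 1e-12 * np.eye(C.shape[0]))
    except np.linalg.LinAlgError:
        raise ModelError(f"{what} is not positive-definite") from None


@dataclass
class LatentState:
    """One full draw of all model latents."""

    beta: np.ndarray                     # (T+1, p+1)
    log_sigma: np.ndarray                # (T+1,)
    mu_beta: np.ndarray                  # (p+1,)
    mu_sigma: float
    s_beta: np.ndarray                   # (p+1,)
    corr_beta: np.ndarray                # (p+1, p+1)
    ell: float
    gamma: Optional[np.ndarray] = None   # (T+1, p) for sp/wsp
    mu_gamma: Optional[np.ndarray] = None
    s_gamma: Optional[np.ndarray] = None
    corr_gamma: Optional[np.ndarray] = None
    # innovations as stored by the forward sampler (optional)
    v_beta: Optional[np.ndarray] = None
    w_sigma: Optional[np.ndarray] = None
    v_gamma: Optional[np.ndarray] = None

    def validate(self, spec: ModelSpec) -> None:
        k, g, T = spec.k, spec.g, spec.T
        if self.beta.shape != (T + 1, k):
            raise ModelError(f"beta has shape {self.beta.shape}, expected {(T + 1, k)}")
        if self.log_sigma.shape != (T + 1,):
            raise ModelError("log_sigma has wrong shape")
        if np.any(np.asarray(self.s_beta) <= 0) or self.ell <= 0:
            raise ModelError("scales must be strictly positive")
        _check_corr(self.corr_beta, "corr_beta")
        if spec.variant == "baseline":
            if self.gamma is not None:
                raise ModelError("baseline state must not carry gamma")
        else:
            if self.gamma is None or self.gamma.shape != (T + 1, g):
                raise ModelError("sp/wsp state needs gamma of shape (T+1, p)")
            if np.any(np.asarray(self.s_gamma) <= 0):
                raise ModelError("scales must be strictly positive")
            _check_corr(self.corr_gamma, "corr_gamma")

    # -- derived quantities -------------------------------------------
    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)

    def chol_beta(self) -> np.ndarray:
        """Lower Cholesky factor of Sigma_beta = diag(s) C diag(s)."""
        s = np.asarray(self.s_beta)
        return s[:, None] * np.linalg.cholesky(self.corr_beta)

    def chol_gamma(self) -> np.ndarray:
        s = np.asarray(self.s_gamma)
        return s[:, None] * np.linalg.cholesky(self.corr_gamma)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for name in ("beta", "log_sigma", "mu_beta", "s_beta", "corr_beta",
                     "gamma", "mu_gamma", "s_gamma", "corr_gamma",
                     "v_beta", "w_sigma", "v_gamma"):
            arr = getattr(self, name)
            if arr is not None:
                out[name] = np.asarray(arr).tolist()
        out["mu_sigma"] = float(self.mu_sigma)
        out["ell"] = float(self.ell)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "LatentState":
        kw = {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**kw)


def _mvn_logpdf(x, mean, cov):
    return stats.multivariate_normal.logpdf(x, mean=mean, cov=cov)


def log_prior(state: LatentState, spec: ModelSpec) -> float:
    """Log prior density of a latent state (LKJ terms contribute 0)."""
    state.validate(spec)
    k, T = spec.k, spec.T
    s = np.asarray(state.s_beta)
    Sigma = s[:, None] * state.corr_beta * s[None, :]

    lp = _mvn_logpdf(state.beta[0], np.zeros(k), Sigma)
    for t in range(1, T + 1):
        lp += _mvn_logpdf(state.beta[t], state.beta[t - 1] + state.mu_beta, Sigma)
    lp += stats.norm.logpdf(state.log_sigma[0], 0.0, state.ell)
    for t in range(1, T + 1):
        lp += stats.norm.logpdf(state.log_sigma[t],
                                state.log_sigma[t - 1] + state.mu_sigma, state.ell)
    lp += stats.norm.logpdf(state.mu_beta, 0.0, 1.0).sum()
    lp += stats.norm.logpdf(state.mu_sigma, 0.0, 1.0)
    lp += stats.lognorm.logpdf(s, 1.0).sum()
    lp += stats.lognorm.logpdf(state.ell, 1.0)
    if spec.variant != "baseline":
        sg = np.asarray(state.s_gamma)
        Lam = sg[:, None] * state.corr_gamma * sg[None, :]
        g = spec.g
        lp += _mvn_logpdf(state.gamma[0], np.zeros(g), Lam)
        for t in range(1, T + 1):
            lp += _mvn_logpdf(state.gamma[t], state.gamma[t - 1] + state.mu_gamma, Lam)
        lp += stats.norm.logpdf(state.mu_gamma, 0.0, 1.0).sum()
        lp += stats.lognorm.logpdf(sg, 1.0).sum()
    return float(lp)


def _mean_matrix(state: LatentState, spec: ModelSpec, design: np.ndarray,
                 neighbor: Optional[np.ndarray]) -> np.ndarray:
    """Noiseless linear predictor, shape (N, T)."""
    T, N, k = design.shape
    if (T, k) != (spec.T, spec.k) or N != spec.N:
        raise ModelError(f"design shape {design.shape} does not match spec")
    if spec.variant != "baseline":
        if neighbor is None:
            raise ModelError("sp/wsp likelihood needs the neighbor design")
        if neighbor.shape != (spec.T, spec.N, spec.g):
            raise ModelError(f"neighbor design shape {neighbor.shape} is wrong")
    mean = np.empty((N, T))
    for t in range(1, T + 1):
        m = design[t - 1] @ state.beta[t]
        if spec.variant != "baseline":
            m = m + neighbor[t - 1] @ state.gamma[t]
        mean[:, t - 1] = m
    return mean


def log_likelihood(state: LatentState, spec: ModelSpec, design: np.ndarray,
                   Y: np.ndarray, neighbor: Optional[np.ndarray] = None) -> float:
    """Gaussian log-likelihood of the (N, T) response under a latent state."""
    state.validate(spec)
    Y = np.asarray(Y, dtype=float)
    if Y.shape != (spec.N, spec.T):
        raise ModelError(f"Y has shape {Y.shape}, expected {(spec.N, spec.T)}")
    mean = _mean_matrix(state, spec, np.asarray(design, float),
                        None if neighbor is None else np.asarray(neighbor, float))
    sigma = state.sigma[1:]  # observation years use sigma_1..sigma_T
    return float(stats.norm.logpdf(Y, mean, sigma[None, :]).sum())


def log_joint(state: LatentState, spec: ModelSpec, design, Y, neighbor=None) -> float:
    return log_prior(state, spec) + log_likelihood(state, spec, design, Y, neighbor)


def sample_correlation(K: int, rng: np.random.Generator) -> np.ndarray:
    """Draw C ~ LKJ(1) via independent canonical partial correlations."""
    if K == 1:
        return np.ones((1, 1))
    L = np.zeros((K, K))
    L[0, 0] = 1.0
    for i in range(1, K):
        acc = 1.0
        for j in range(i):
            b = 1.0 + (K - 2 - j) / 2.0
            z = 2.0 * rng.beta(b, b) - 1.0
            L[i, j] = z * np.sqrt(acc)
            acc *= 1.0 - z * z
        L[i, i] = np.sqrt(acc)
    return L @ L.T


def sample_prior(spec: ModelSpec, seed) -> LatentState:
    """Forward-sample all latents (hyperparameters, then the walks)."""
    rng = np.random.default_rng(seed)
    k, g, T = spec.k, spec.g, spec.T

    s_beta = np.exp(rng.standard_normal(k))
    corr_beta = sample_correlation(k, rng)
    mu_beta = rng.standard_normal(k)
    mu_sigma = float(rng.standard_normal())
    ell = float(np.exp(rng.standard_normal()))

    L = s_beta[:, None] * np.linalg.cholesky(corr_beta)
    v = rng.standard_normal((T + 1, k))
    beta = np.empty((T + 1, k))
    beta[0] = L @ v[0]
    for t in range(1, T + 1):
        beta[t] = beta[t - 1] + mu_beta + L @ v[t]

    w = rng.standard_normal(T + 1)
    log_sigma = np.empty(T + 1)
    log_sigma[0] = ell * w[0]
    for t in range(1, T + 1):
        log_sigma[t] = log_sigma[t - 1] + mu_sigma + ell * w[t]

    state = LatentState(beta=beta, log_sigma=log_sigma, mu_beta=mu_beta,
                        mu_sigma=mu_sigma, s_beta=s_beta, corr_beta=corr_beta,
                        ell=ell, v_beta=v, w_sigma=w)
    if spec.variant != "baseline":
        s_gamma = np.exp(rng.standard_normal(g))
        corr_gamma = sample_correlation(g, rng)
        mu_gamma = rng.standard_normal(g)
        Lg = s_gamma[:, None] * np.linalg.cholesky(corr_gamma)
        q = rng.standard_normal((T + 1, g))
        gamma = np.empty((T + 1, g))
        gamma[0] = Lg @ q[0]
        for t in range(1, T + 1):
            gamma[t] = gamma[t - 1] + mu_gamma + Lg @ q[t]
        state.gamma, state.mu_gamma = gamma, mu_gamma
        state.s_gamma, state.corr_gamma = s_gamma, corr_gamma
        state.v_gamma = q
    return state


def predict(state: LatentState, spec: ModelSpec, design, neighbor=None,
            noise: bool = False, seed=None) -> np.ndarray:
    """Linear predictor per (district, year); optionally add sigma_t noise."""
    state.validate(spec)
    mean = _mean_matrix(state, spec, np.asarray(design, float),
                        None if neighbor is None else np.asarray(neighbor, float))
    if noise:
        rng = np.random.default_rng(seed)
        mean = mean + state.sigma[1:][None, :] * rng.standard_normal(mean.shape)
    return mean
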