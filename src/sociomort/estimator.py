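"""Scikit-learn style estimator wrapping the variational mortality models.

``SpatialMortalityRegression`` is the main entry point of the package: it
fits one model variant (baseline, SP or WSP) to a district panel by
stochastic ELBO ascent and predicts crude death rates as posterior-mean
linear predictors. Hyperparameters follow sklearn conventions
(``get_params``/``set_params``, fitted attributes with a trailing
underscore); the module-level functions in :mod:`sociomort.vi` are thin
wrappers over this class.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import vi
from .graph import SpatialGraph
from .model import ModelSpec, predict as predict_state
from .panel import DistrictPanel
from .transforms import latent_dim


class SpatialMortalityRegression(BaseEstimator):
    """Bayesian time-varying-coefficient regression of district death rates.

    Parameters
    ----------
    variant : {"baseline", "sp", "wsp"}
        Whether and how neighboring districts' covariates enter the mean:
        not at all, as unweighted neighbor means, or as exponential
        distance-decay weighted means.
    rank : int or None
        Rank of the low-rank guide covariance factor; ``None`` uses the full
        latent dimension.
    n_iter, step_size, n_mc : int, float, int
        Adam iteration budget, step size, and Monte-Carlo draws per ELBO
        gradient estimate.
    n_draws : int
        Default number of posterior draws used by :meth:`predict`.
    seed : int
        Governs guide initialization noise, ELBO sampling and posterior
        draws through named substreams.
    """

    def __init__(self, variant: str = "baseline", rank: Optional[int] = None,
                 n_iter: int = 10_000, step_size: float = 0.02,
                 step_size_final: float = 5e-4, n_mc: int = 8,
                 n_draws: int = 1000, seed: int = 0, init_diag: float = 0.1,
                 tol: float = 1e-4, tol_window: int = 500):
        self.variant = variant
        self.rank = rank
        self.n_iter = n_iter
        self.step_size = step_size
        self.step_size_final = step_size_final
        self.n_mc = n_mc
        self.n_draws = n_draws
        self.seed = seed
        self.init_diag = init_diag
        self.tol = tol
        self.tol_window = tol_window

    # ------------------------------------------------------------------
    def _vi_config(self) -> vi.VIConfig:
        return vi.VIConfig(rank=self.rank, n_iter=self.n_iter,
                           step_size=self.step_size,
                           step_size_final=self.step_size_final,
                           n_mc=self.n_mc, seed=self.seed,
                           init_diag=self.init_diag, tol=self.tol,
                           tol_window=self.tol_window)

    def fit(self, panel: DistrictPanel, graph: Optional[SpatialGraph] = None
            ) -> "SpatialMortalityRegression":
        """Fit the model to a district panel (graph required for sp/wsp)."""
        spec, design, neighbor, Y = vi.assemble_data(panel, graph, self.variant)
        from .transforms import make_logdensity
        logdensity = make_logdensity(spec, design, Y, neighbor)
        result = vi.fit_guide(logdensity, latent_dim(spec), self._vi_config())
        result.spec = spec
        self.spec_: ModelSpec = spec
        self.design_: np.ndarray = design
        self.neighbor_: Optional[np.ndarray] = neighbor
        self.guide_ = result.guide
        self.elbo_trace_: np.ndarray = result.elbo_trace
        self.result_: vi.FitResult = result
        self.districts_ = list(panel.districts)
        self.years_ = list(panel.years)
        self.feature_names_ = list(panel.feature_names)
        return self

    def _check_fitted(self):
        if not hasattr(self, "guide_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def posterior_draws(self, n: Optional[int] = None, seed: Optional[int] = None
                        ) -> list:
        """Draw latent states from the fitted guide (constrained space)."""
        self._check_fitted()
        return vi.posterior_draws(self.guide_, self.spec_,
                                  n=n or self.n_draws,
                                  seed=self.seed if seed is None else seed)

    def predict_draws(self, n: Optional[int] = None, seed: Optional[int] = None,
                      noise: bool = False) -> np.ndarray:
        """Per-draw predictions, shape (n_draws, N, T).

        By default the noiseless linear predictor of each posterior draw;
        with ``noise=True``, observation noise sigma_t is added per draw.
        """
        self._check_fitted()
        states = self.posterior_draws(n=n, seed=seed)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.seed if seed is None else seed), 0xAD0]))
        out = np.empty((len(states), self.spec_.N, self.spec_.T))
        for i, st in enumerate(states):
            out[i] = predict_state(st, self.spec_, self.design_, self.neighbor_,
                                   noise=noise,
                                   seed=int(rng.integers(2 ** 31)) if noise else None)
        return out

    def predict(self, n: Optional[int] = None, seed: Optional[int] = None
                ) -> np.ndarray:
        """Posterior-mean crude death rate per (district, year), shape (N, T)."""
        return self.predict_draws(n=n, seed=seed).mean(axis=0)

    def score(self, Y: np.ndarray) -> float:
        """Negative mean absolute error over all districts and years."""
        self._check_fitted()
        return -float(np.abs(self.predict() - np.asarray(Y)).mean())
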