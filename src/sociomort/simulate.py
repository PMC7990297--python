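"""Synthetic district panels with the structure the models assume.

The generator emulates the study setting — 18 districts observed at three
census snapshots (2006/2011/2016), 16 socioeconomic covariates, crude death
rates on a per-1,000 scale, and a sparse connected road-adjacency graph —
without reproducing any real marginal distribution. Covariates are drawn
from per-feature families (log-normal for incomes and density, logit-normal
for proportions and rates) on top of a latent Gaussian field with AR(1)
persistence across census years and mild spatial autocorrelation from mixing
each district with its neighbor mean. Responses come from the model's own
forward equations at a stored ground-truth latent state, so parameter
recovery is testable end to end.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy.special import expit, logit

from .graph import SpatialGraph, build_graph, hk_graph, write_edge_list
from .model import LatentState, ModelSpec, predict as predict_state, sample_prior
from .panel import DEFAULT_RESPONSE_SCALE, DistrictPanel
from .schema import DEFAULT_SCHEMA, FEATURE_FAMILIES, FeatureSchema
from .vi import assemble_data


class SimulationError(RuntimeError):
    pass


#: latent-scale location/spread per feature family; values chosen to give
#: plausible magnitudes (densities in the thousands per km^2, incomes in the
#: ten-thousands HKD, proportions well inside (0, 1))
_FAMILY_PARAMS = {
    "population_density": (8.5, 0.8),
    "median_income": (9.6, 0.35),
    "median_household_income": (10.1, 0.35),
    "aux_sociodemographic_index": (0.0, 0.5),
    "unemployment_rate": (logit(0.045), 0.35),
    "household_unemployment_rate": (logit(0.06), 0.35),
    "prop_homeless": (logit(0.002), 0.5),
    "prop_mobile_residents": (logit(0.03), 0.4),
    "prop_single_parent": (logit(0.035), 0.3),
    "prop_children_in_school": (logit(0.25), 0.3),
    "median_rent_to_income": (logit(0.3), 0.25),
    "insurance_coverage": (logit(0.08), 0.4),
    "minority_unemployment_rate": (logit(0.05), 0.4),
    "prop_minorities": (logit(0.06), 0.6),
    "prop_children_under_15": (logit(0.12), 0.25),
    "prop_elderly": (logit(0.13), 0.3),
}

#: nonzero generating coefficients used by default. Direct effects act on
#: unit-sd standardized covariates; the spatial coefficient is larger because
#: neighbor averaging shrinks its regressor's spread well below 1 (about 0.4
#: for binary neighbor means on the 18-district graph, less for the weighted
#: version), and the spatial signal is meant to be strong, i.e. comparable to
#: the direct effects on the response scale.
DEFAULT_BETA_EFFECTS = {"unemployment_rate": 1.0, "prop_homeless": 0.8}
DEFAULT_GAMMA_EFFECTS = {"household_unemployment_rate": 2.5}


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    n_districts: int = 18
    years: tuple = (2006, 2011, 2016)
    graph_kind: str = "hk_fixture"     # hk_fixture | chain | grid | random_geometric
    rho: float = 0.6                   # AR(1) persistence of covariates
    spatial_mix: float = 0.3           # weight on neighbor mean of latent field
    sigma: float = 0.5                 # observation noise (model scale)
    intercept: float = 0.5             # model-scale intercept (prior-compatible)
    affine_offset: float = 5.5         # shifts rates into a per-1,000 range
    affine_scale: float = 1.0
    beta_effects: dict = field(default_factory=lambda: dict(DEFAULT_BETA_EFFECTS))
    gamma_effects: dict = field(default_factory=lambda: dict(DEFAULT_GAMMA_EFFECTS))
    variant: str = "baseline"
    category: str = "all"
    seed: int = 0

    def __post_init__(self):
        if self.n_districts < 2 or len(self.years) < 1:
            raise SimulationError("need at least 2 districts and 1 year")
        if not 0.0 <= self.rho < 1.0:
            raise SimulationError("rho must lie in [0, 1)")
        if self.sigma <= 0:
            raise SimulationError("sigma must be positive")

    @property
    def n_years(self) -> int:
        return len(self.years)


def generate_graph(config: SimConfig) -> SpatialGraph:
    """Connected district graph of the configured kind (seed-deterministic)."""
    n = config.n_districts
    labels = [f"D{i:02d}" for i in range(n)]
    if config.graph_kind == "hk_fixture":
        g = hk_graph()
        if n != g.n:
            raise SimulationError("hk_fixture graph has exactly 18 districts")
        return g
    if config.graph_kind == "chain":
        return build_graph([(labels[i], labels[i + 1]) for i in range(n - 1)], labels)
    if config.graph_kind == "grid":
        cols = int(np.ceil(np.sqrt(n)))
        edges = []
        for i in range(n):
            r, c = divmod(i, cols)
            if c + 1 < cols and i + 1 < n:
                edges.append((labels[i], labels[i + 1]))
            if i + cols < n:
                edges.append((labels[i], labels[i + cols]))
        return build_graph(edges, labels)
    if config.graph_kind == "random_geometric":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6E0]))
        for _ in range(100):
            pos = rng.random((n, 2))
            g = nx.random_geometric_graph(n, radius=1.8 / np.sqrt(n), pos=dict(enumerate(pos)))
            if nx.is_connected(g):
                return build_graph([(labels[a], labels[b]) for a, b in g.edges],
                                   labels)
        raise SimulationError("random geometric graph not connected in 100 tries")
    raise SimulationError(f"unknown graph kind {config.graph_kind!r}")


def generate_covariates(config: SimConfig, graph: SpatialGraph,
                        schema: FeatureSchema = DEFAULT_SCHEMA) -> DistrictPanel:
    """Covariate panel (all 16 features); the response is a zero placeholder."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F]))
    N, T = graph.n, config.n_years
    names = schema.names("all")
    deg = graph.A - np.eye(N)
    nbr_mean = deg / deg.sum(axis=1, keepdims=True)
    lam = config.spatial_mix
    X = np.empty((N, T, len(names)))
    for j, name in enumerate(names):
        e = rng.standard_normal(N)
        field_ = np.empty((N, T))
        for t in range(T):
            if t > 0:
                e = config.rho * e + np.sqrt(1 - config.rho ** 2) * rng.standard_normal(N)
            field_[:, t] = (1 - lam) * e + lam * (nbr_mean @ e)
        loc, scale = _FAMILY_PARAMS[name]
        latent = loc + scale * field_
        if FEATURE_FAMILIES[name] == "lognormal":
            X[:, :, j] = np.exp(latent)
        else:
            X[:, :, j] = expit(latent)
    return DistrictPanel(districts=list(graph.labels), years=list(config.years),
                         feature_names=names, X=X, Y=np.zeros((N, T)),
                         response_scale=DEFAULT_RESPONSE_SCALE)


def make_truth(spec: ModelSpec, config: SimConfig,
               feature_names: list) -> LatentState:
    """Ground-truth latent state with the configured effect sizes.

    Coefficients are constant over time (zero drift, zero innovations in the
    walk), observation noise is config.sigma in every year, and the
    hyperparameters are fixed at moderate values.
    """
    k, g, T = spec.k, spec.g, spec.T
    beta_row = np.zeros(k)
    beta_row[0] = config.intercept
    for name, effect in config.beta_effects.items():
        if name in feature_names:
            beta_row[1 + feature_names.index(name)] = effect
    state = LatentState(
        beta=np.tile(beta_row, (T + 1, 1)),
        log_sigma=np.full(T + 1, np.log(config.sigma)),
        mu_beta=np.zeros(k), mu_sigma=0.0,
        s_beta=np.full(k, 0.3), corr_beta=np.eye(k), ell=0.3,
    )
    if spec.variant != "baseline":
        gamma_row = np.zeros(g)
        for name, effect in config.gamma_effects.items():
            if name in feature_names:
                gamma_row[feature_names.index(name)] = effect
        state.gamma = np.tile(gamma_row, (T + 1, 1))
        state.mu_gamma = np.zeros(g)
        state.s_gamma = np.full(g, 0.3)
        state.corr_gamma = np.eye(g)
    return state


def generate_response(covariates: DistrictPanel, graph: Optional[SpatialGraph],
                      config: SimConfig, truth=None, seed: Optional[int] = None):
    """Simulate Y from the forward model; returns (panel, truth state).

    ``truth`` may be a LatentState, ``None`` (a fixed-effect truth from the
    config) or ``"sample_prior"`` (a full draw from the model prior). The
    model-scale response (zero-centered priors) is mapped into a plausible
    per-1,000 crude-rate range by the recorded affine map
    ``Y = affine_offset + affine_scale * (linear predictor + noise)``;
    :func:`to_model_scale` inverts it for recovery tests.
    """
    panel = covariates.restrict(DEFAULT_SCHEMA, config.category)
    spec, design, neighbor, _ = assemble_data(panel, graph, config.variant)
    if truth is None:
        truth = make_truth(spec, config, panel.feature_names)
    elif isinstance(truth, str) and truth == "sample_prior":
        truth = sample_prior(spec, np.random.SeedSequence([config.seed, 0x70]))
    truth.validate(spec)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else seed, 0x4E5]))
    mean = predict_state(truth, spec, design, neighbor, noise=False)
    Y = mean + truth.sigma[1:][None, :] * rng.standard_normal(mean.shape)
    Y = config.affine_offset + config.affine_scale * Y
    out = DistrictPanel(districts=list(panel.districts), years=list(panel.years),
                        feature_names=list(panel.feature_names), X=panel.X.copy(),
                        Y=Y, response_scale=panel.response_scale)
    return out, truth


def to_model_scale(panel: DistrictPanel, config: SimConfig) -> DistrictPanel:
    """Invert the recorded affine response map (for recovery tests)."""
    return DistrictPanel(
        districts=list(panel.districts), years=list(panel.years),
        feature_names=list(panel.feature_names), X=panel.X.copy(),
        Y=(panel.Y - config.affine_offset) / config.affine_scale,
        response_scale=panel.response_scale)


def simulate_dataset(config: SimConfig):
    """Graph + covariates + response in one call; returns (panel, graph, truth)."""
    graph = generate_graph(config)
    cov = generate_covariates(config, graph)
    panel, truth = generate_response(cov, graph, config)
    return panel, graph, truth


def make_fixture_csv(config: SimConfig, outdir) -> dict:
    """Write panel CSV, edge list and ground-truth JSON; returns the paths.

    The CSV stores integer death counts and populations, so a reloaded
    panel's rates differ from the exact simulated rates by count rounding
    (well under 0.002 per 1,000); the exact rates live in the truth file.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel, graph, truth = simulate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF0B]))
    population = np.round(np.exp(rng.normal(12.6, 0.5, size=(panel.n_districts, 1)))
                          * np.ones((1, panel.n_years)))
    deaths = np.round(np.clip(panel.Y, 0.0, None) * population
                      / panel.response_scale)
    csv_panel = DistrictPanel(
        districts=list(panel.districts), years=list(panel.years),
        feature_names=list(panel.feature_names), X=panel.X,
        Y=panel.response_scale * deaths / population,
        deaths=deaths, population=population,
        response_scale=panel.response_scale)
    paths = {"panel": out / "panel.csv", "edges": out / "edges.csv",
             "truth": out / "truth.json"}
    frame = csv_panel.to_frame().drop(columns="rate")
    frame.to_csv(paths["panel"], index=False)
    write_edge_list(graph, paths["edges"])
    with open(paths["truth"], "w") as fh:
        json.dump({
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(config).items()},
            "affine_map": {"offset": config.affine_offset,
                           "scale": config.affine_scale},
            "exact_rate": panel.Y.tolist(),
            "truth": truth.to_dict(),
        }, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
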