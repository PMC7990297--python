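"""Model evaluation: MAE, signed deviations, credible intervals, flags.

Predictions are compared to observed crude death rates per year via the
mean absolute error e_t = (1/N) sum_i |Yhat_it - Y_it|, averaged over
posterior draws (draws use the noiseless linear predictor, so the MAE
measures model-mean error). Systematic bias is diagnosed from the signed
deviation Yhat - Y: a centered Q% credible interval (empirical quantiles
leaving (1 - Q/100)/2 tail mass on each side) entirely above zero flags
systematic overestimation, entirely below zero systematic underestimation.
The same interval machinery summarizes regression coefficients, and an
ego-network report localizes errors in each district's neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .estimator import SpatialMortalityRegression
from .graph import SpatialGraph, ego_network
from .model import VARIANTS, LatentState
from .panel import DistrictPanel
from .schema import CATEGORY_TAGS, DEFAULT_SCHEMA, FeatureSchema


class EvaluationError(ValueError):
    pass


def mae(pred_draws: np.ndarray, Y: np.ndarray) -> float:
    """Per-draw mean absolute error over districts, averaged over draws."""
    pred_draws = np.atleast_2d(np.asarray(pred_draws, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if pred_draws.shape[1] != Y.shape[0]:
        raise EvaluationError(
            f"draws have {pred_draws.shape[1]} districts, Y has {Y.shape[0]}")
    return float(np.abs(pred_draws - Y[None, :]).mean(axis=1).mean())


def signed_deviation(pred_draws: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Elementwise Yhat - Y per draw, shape (n_draws, N); positive = over."""
    pred_draws = np.atleast_2d(np.asarray(pred_draws, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if pred_draws.shape[1] != Y.shape[0]:
        raise EvaluationError("dimension mismatch between draws and Y")
    return pred_draws - Y[None, :]


def credible_interval(samples: np.ndarray, Q: float = 80.0) -> tuple:
    """Centered Q% interval: empirical quantiles with (1-Q/100)/2 per tail."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise EvaluationError("cannot form a credible interval of no samples")
    if not 0.0 < Q < 100.0:
        raise EvaluationError(f"Q must be in (0, 100), got {Q}")
    tail = 0.5 * (1.0 - Q / 100.0)
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


def significance_flag(samples: np.ndarray, Q: float = 80.0) -> str:
    """'over' if the whole CI is above 0, 'under' if below, else 'none'."""
    a, b = credible_interval(samples, Q)
    if a > 0:
        return "over"
    if b < 0:
        return "under"
    return "none"


def coefficient_summary(draws: list, Q: float = 80.0,
                        feature_names: Optional[list] = None,
                        years: Optional[list] = None) -> pd.DataFrame:
    """Per-predictor, per-year CI and flag for beta (and gamma) entries."""
    if len(draws) < 2:
        raise EvaluationError("need at least 2 posterior draws")
    first: LatentState = draws[0]
    T = first.beta.shape[0] - 1
    k = first.beta.shape[1]
    names = ["intercept"] + list(feature_names or
                                 [f"x{j}" for j in range(1, k)])
    yrs = list(years) if years is not None else list(range(1, T + 1))
    rows = []
    beta = np.stack([d.beta for d in draws])          # (n, T+1, k)
    for t in range(1, T + 1):
        for j in range(k):
            samples = beta[:, t, j]
            a, b = credible_interval(samples, Q)
            rows.append({"param": "beta", "feature": names[j], "year": yrs[t - 1],
                         "mean": samples.mean(), "lo": a, "hi": b,
                         "flag": significance_flag(samples, Q)})
    if first.gamma is not None:
        gamma = np.stack([d.gamma for d in draws])
        g = gamma.shape[2]
        gnames = list(feature_names or [f"x{j}" for j in range(1, g + 1)])
        for t in range(1, T + 1):
            for j in range(g):
                samples = gamma[:, t, j]
                a, b = credible_interval(samples, Q)
                rows.append({"param": "gamma", "feature": gnames[j],
                             "year": yrs[t - 1], "mean": samples.mean(),
                             "lo": a, "hi": b,
                             "flag": significance_flag(samples, Q)})
    return pd.DataFrame(rows)


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def ego_error_report(graph: SpatialGraph, Y: np.ndarray,
                     pred_mean: np.ndarray) -> pd.DataFrame:
    """Neighborhood view of model error for one year.

    For every ego district, lists its neighbors with the across-district
    standardized mortality rate (node shading of the ego-network figure) and
    the standardized signed deviation of the model (edge shading).
    """
    Y = np.asarray(Y, dtype=float)
    pred_mean = np.asarray(pred_mean, dtype=float)
    if Y.shape != (graph.n,) or pred_mean.shape != (graph.n,):
        raise EvaluationError("Y and predictions must be one value per district")
    mort_z = _zscore(Y)
    err_z = _zscore(pred_mean - Y)
    rows = []
    for i, ego in enumerate(graph.labels):
        sub = ego_network(graph, ego)
        for lab in sub.labels:
            if lab == ego:
                continue
            j = graph.index(lab)
            rows.append({"ego": ego, "neighbor": lab,
                         "ego_mortality_z": mort_z[i],
                         "neighbor_mortality_z": mort_z[j],
                         "neighbor_error_z": err_z[j],
                         "ego_degree": sub.n - 1})
    return pd.DataFrame(rows)


def plot_ego_network(graph: SpatialGraph, Y: np.ndarray, pred_mean: np.ndarray,
                     ego, path=None):
    """Draw one district's ego network, nodes shaded by standardized
    mortality and edges by standardized signed error (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    sub = ego_network(graph, ego)
    mort_z = _zscore(np.asarray(Y, dtype=float))
    err_z = _zscore(np.asarray(pred_mean, dtype=float) - np.asarray(Y, dtype=float))
    g = sub.to_networkx()
    pos = nx.spring_layout(g, seed=7)
    nodes = list(g.nodes)
    ncol = [mort_z[graph.index(n)] for n in nodes]
    ecol = [0.5 * (err_z[graph.index(a)] + err_z[graph.index(b)])
            for a, b in g.edges]
    fig, ax = plt.subplots(figsize=(5, 4))
    nx.draw_networkx(g, pos=pos, ax=ax, node_color=ncol, cmap="coolwarm",
                     edge_color=ecol, edge_cmap=plt.cm.PiYG, width=2.5,
                     font_size=7)
    ax.set_title(f"Ego network: {ego}")
    ax.axis("off")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# full evaluation grid
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    variants: tuple = VARIANTS
    categories: tuple = tuple(CATEGORY_TAGS)
    n_draws: int = 1000
    Q: float = 80.0
    seed: int = 0
    estimator_kwargs: dict = field(default_factory=dict)


@dataclass
class EvalReport:
    """Evaluation-grid output: MAE tables, bias flags, coefficient tables."""

    mae_by_year: pd.DataFrame          # years x (category, variant)
    mae_by_district: pd.DataFrame      # districts x (category, variant), last year
    best_by_year: pd.DataFrame         # per (category, year): variant with min MAE
    msd_summary: pd.DataFrame          # per district/model: signed-dev CI + flag
    coefficient_tables: dict           # (variant, category) -> DataFrame
    config: ExperimentConfig = None
    n_reduced: bool = False

    def save(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mae_by_year.to_csv(out / "mae_by_year.csv")
        self.mae_by_district.to_csv(out / "mae_by_district.csv")
        self.best_by_year.to_csv(out / "best_by_year.csv", index=False)
        self.msd_summary.to_csv(out / "msd_summary.csv", index=False)
        for (variant, category), table in self.coefficient_tables.items():
            table.to_csv(out / f"coefficients_{variant}_{category}.csv", index=False)
        with open(out / "mae_by_year.md", "w") as fh:
            fh.write(self.mae_by_year.round(3).to_markdown())
            if self.n_reduced:
                fh.write("\n\n*reduced draw count*\n")


def run_experiment(panel_all: DistrictPanel, graph: SpatialGraph,
                   config: ExperimentConfig = None,
                   schema: FeatureSchema = DEFAULT_SCHEMA) -> EvalReport:
    """Fit every variant x predictor-category combination and tabulate MAE.

    ``panel_all`` must carry all 16 schema features; each grid cell restricts
    it to one category, fits one variant, and reports the draw-averaged MAE
    per year plus the per-district breakdown for the final year.
    """
    config = config or ExperimentConfig()
    years = list(panel_all.years)
    districts = list(panel_all.districts)
    cols = pd.MultiIndex.from_product([config.categories, config.variants],
                                      names=["category", "variant"])
    mae_year = pd.DataFrame(index=pd.Index(years, name="year"), columns=cols,
                            dtype=float)
    mae_dist = pd.DataFrame(index=pd.Index(districts, name="district"),
                            columns=cols, dtype=float)
    msd_rows, coef_tables = [], {}
    for category in config.categories:
        panel = panel_all.restrict(schema, category)
        for variant in config.variants:
            est = SpatialMortalityRegression(variant=variant, seed=config.seed,
                                             n_draws=config.n_draws,
                                             **config.estimator_kwargs)
            est.fit(panel, graph)
            draws = est.predict_draws()                     # (n, N, T)
            for t, year in enumerate(years):
                mae_year.loc[year, (category, variant)] = mae(draws[:, :, t],
                                                              panel.Y[:, t])
            last = len(years) - 1
            dev = signed_deviation(draws[:, :, last], panel.Y[:, last])
            mae_dist[(category, variant)] = np.abs(dev).mean(axis=0)
            for i, d in enumerate(districts):
                a, b = credible_interval(dev[:, i], config.Q)
                msd_rows.append({"district": d, "category": category,
                                 "variant": variant, "year": years[last],
                                 "mean_dev": dev[:, i].mean(), "lo": a, "hi": b,
                                 "flag": significance_flag(dev[:, i], config.Q)})
            coef_tables[(variant, category)] = coefficient_summary(
                est.posterior_draws(), Q=config.Q,
                feature_names=panel.feature_names, years=years)
    best = (mae_year.T.groupby(level="category")
            .apply(lambda df: df.idxmin(axis=0).map(lambda c: c[1]))
            .T.reset_index().melt(id_vars="year", var_name="category",
                                  value_name="best_variant"))
    return EvalReport(mae_by_year=mae_year, mae_by_district=mae_dist,
                      best_by_year=best, msd_summary=pd.DataFrame(msd_rows),
                      coefficient_tables=coef_tables, config=config,
                      n_reduced=config.n_draws < 1000)
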