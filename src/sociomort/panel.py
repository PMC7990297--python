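"""District-by-census-year panels and per-year standardized design tensors.

A :class:`DistrictPanel` stores the covariate tensor ``X`` (districts x years
x features), the response ``Y`` (crude death rate per 1,000 residents) and,
when available, the raw death and population counts it was derived from:
``Y[i, t] = scale * deaths[i, t] / population[i, t]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .schema import DEFAULT_SCHEMA, FeatureSchema, SchemaError

DEFAULT_RESPONSE_SCALE = 1000.0


class PanelValidationError(ValueError):
    """Raised when a panel violates its invariants (missing/invalid cells)."""


@dataclass
class DistrictPanel:
    districts: list
    years: list
    feature_names: list
    X: np.ndarray  # (N, T, p)
    Y: np.ndarray  # (N, T)
    deaths: Optional[np.ndarray] = None      # (N, T)
    population: Optional[np.ndarray] = None  # (N, T)
    response_scale: float = DEFAULT_RESPONSE_SCALE

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        N, T = len(self.districts), len(self.years)
        if N < 2 or T < 1:
            raise PanelValidationError(f"need N >= 2 districts and T >= 1 years, got {N}, {T}")
        if self.X.shape != (N, T, len(self.feature_names)):
            raise PanelValidationError(
                f"X has shape {self.X.shape}, expected {(N, T, len(self.feature_names))}")
        if self.Y.shape != (N, T):
            raise PanelValidationError(f"Y has shape {self.Y.shape}, expected {(N, T)}")
        for name, arr in (("X", self.X), ("Y", self.Y)):
            if not np.all(np.isfinite(arr)):
                i, t = np.argwhere(~np.isfinite(arr).reshape(N, T, -1).all(axis=2))[0]
                raise PanelValidationError(
                    f"missing/non-finite value in {name} at "
                    f"(district={self.districts[i]}, year={self.years[t]})")
        if self.population is not None:
            self.population = np.asarray(self.population, dtype=float)
            if np.any(self.population <= 0):
                i, t = np.argwhere(self.population <= 0)[0]
                raise PanelValidationError(
                    f"nonpositive population at (district={self.districts[i]}, "
                    f"year={self.years[t]})")
        if self.deaths is not None:
            self.deaths = np.asarray(self.deaths, dtype=float)
            if np.any(self.deaths < 0):
                raise PanelValidationError("negative death counts")
        if self.deaths is not None and self.population is not None:
            expected = self.response_scale * self.deaths / self.population
            if not np.allclose(self.Y, expected, atol=1e-9, rtol=0):
                raise PanelValidationError(
                    "stored Y does not match scale * deaths / population")

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def restrict(self, schema: FeatureSchema, category: str) -> "DistrictPanel":
        """Panel with only the features of ``category``, in schema order."""
        wanted = schema.names(category)
        missing = [n for n in wanted if n not in self.feature_names]
        if missing:
            raise SchemaError(f"panel lacks feature column(s): {missing}")
        idx = [self.feature_names.index(n) for n in wanted]
        return DistrictPanel(
            districts=list(self.districts), years=list(self.years),
            feature_names=wanted, X=self.X[:, :, idx], Y=self.Y.copy(),
            deaths=None if self.deaths is None else self.deaths.copy(),
            population=None if self.population is None else self.population.copy(),
            response_scale=self.response_scale,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.districts):
            for t, y in enumerate(self.years):
                row = {"district": d, "year": y}
                if self.population is not None:
                    row["population"] = self.population[i, t]
                if self.deaths is not None:
                    row["deaths"] = self.deaths[i, t]
                row["rate"] = self.Y[i, t]
                row.update({n: self.X[i, t, j] for j, n in enumerate(self.feature_names)})
                rows.append(row)
        return pd.DataFrame(rows)


def load_panel(path, schema: FeatureSchema = DEFAULT_SCHEMA, category: str = "all",
               response_scale: float = DEFAULT_RESPONSE_SCALE) -> DistrictPanel:
    """Read a panel CSV and return the features of the selected category.

    The CSV must contain ``district``, ``year``, the schema's feature columns
    and either ``deaths`` + ``population`` (the crude rate is then computed as
    ``response_scale * deaths / population``) or a precomputed ``rate``.
    """
    df = pd.read_csv(path)
    wanted = schema.names(category)
    required = ["district", "year"] + wanted
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"panel file is missing required column {col!r}")
    has_counts = "deaths" in df.columns and "population" in df.columns
    if not has_counts and "rate" not in df.columns:
        raise SchemaError("panel file needs either 'deaths'+'population' or 'rate'")

    districts = list(dict.fromkeys(df["district"]))
    years = sorted(dict.fromkeys(df["year"]))
    N, T = len(districts), len(years)
    dindex = {d: i for i, d in enumerate(districts)}
    yindex = {y: t for t, y in enumerate(years)}

    X = np.full((N, T, len(wanted)), np.nan)
    Y = np.full((N, T), np.nan)
    deaths = np.full((N, T), np.nan) if has_counts else None
    population = np.full((N, T), np.nan) if has_counts else None
    for _, row in df.iterrows():
        i, t = dindex[row["district"]], yindex[row["year"]]
        X[i, t] = [row[n] for n in wanted]
        if has_counts:
            if not np.isfinite(row["population"]) or row["population"] <= 0:
                raise PanelValidationError(
                    f"nonpositive/missing population at (district={row['district']}, "
                    f"year={row['year']})")
            deaths[i, t] = row["deaths"]
            population[i, t] = row["population"]
            Y[i, t] = response_scale * row["deaths"] / row["population"]
        else:
            Y[i, t] = row["rate"]

    holes = np.argwhere(~np.isfinite(Y))
    if holes.size:
        i, t = holes[0]
        raise PanelValidationError(
            f"missing cell for (district={districts[i]}, year={years[t]})")
    return DistrictPanel(districts, years, wanted, X, Y, deaths=deaths,
                         population=population, response_scale=response_scale)


def write_panel(panel: DistrictPanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)


def standardize_by_year(values: np.ndarray) -> np.ndarray:
    """Z-score each year-column of an (N, T) matrix using the population sd."""
    values = np.asarray(values, dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0)  # ddof=0: population standard deviation
    if np.any(sd <= 0):
        t = int(np.argwhere(sd <= 0)[0][0])
        raise PanelValidationError(f"zero variance in year-column {t}; cannot standardize")
    return (values - mean) / sd


@dataclass
class DesignTensor:
    """T design matrices, each (N, p+1) with an intercept column of ones and
    per-year standardized covariate columns."""

    matrices: np.ndarray  # (T, N, p+1)
    feature_names: list

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)

    @property
    def T(self) -> int:
        return self.matrices.shape[0]

    @property
    def N(self) -> int:
        return self.matrices.shape[1]

    @property
    def p(self) -> int:
        return self.matrices.shape[2] - 1


def build_design(panel: DistrictPanel) -> DesignTensor:
    """Standardize covariates within each year and prepend the intercept."""
    N, T, p = panel.X.shape
    mats = np.empty((T, N, p + 1))
    mats[:, :, 0] = 1.0
    for j, name in enumerate(panel.feature_names):
        col = panel.X[:, :, j]  # (N, T)
        sd = col.std(axis=0)
        if np.any(sd <= 0):
            t = int(np.argwhere(sd <= 0)[0][0])
            raise PanelValidationError(
                f"feature {name!r} is constant in year {panel.years[t]}")
        mats[:, :, j + 1] = standardize_by_year(col).T
    return DesignTensor(mats, list(panel.feature_names))
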