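"""Canonical socioeconomic covariate schema for the district panel.

Districts are described by 16 covariates organised into three nested
predictor categories: ``base`` (7 deprivation-style indicators), ``wealth``
(base plus 4 wealth indicators, 11 total) and ``all`` (wealth plus 5
age/ethnicity-sensitive indicators, 16 total). The nesting and the counts
7/11/16 are enforced; the exact membership can be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

CATEGORY_ORDER = ("base", "wealth", "sensitive")

#: category selector -> tags included
CATEGORY_TAGS = {
    "base": ("base",),
    "wealth": ("base", "wealth"),
    "all": ("base", "wealth", "sensitive"),
}

#: expected number of features per selector
CATEGORY_SIZES = {"base": 7, "wealth": 11, "all": 16}

# name -> (tag, distribution family used by the synthetic generator)
DEFAULT_FEATURES = [
    ("population_density", "base", "lognormal"),
    ("unemployment_rate", "base", "proportion"),
    ("household_unemployment_rate", "base", "proportion"),
    ("prop_homeless", "base", "proportion"),
    ("prop_mobile_residents", "base", "proportion"),
    ("prop_single_parent", "base", "proportion"),
    ("prop_children_in_school", "base", "proportion"),
    ("median_income", "wealth", "lognormal"),
    ("median_rent_to_income", "wealth", "proportion"),
    ("median_household_income", "wealth", "lognormal"),
    ("insurance_coverage", "wealth", "proportion"),
    ("minority_unemployment_rate", "sensitive", "proportion"),
    ("prop_minorities", "sensitive", "proportion"),
    ("prop_children_under_15", "sensitive", "proportion"),
    ("prop_elderly", "sensitive", "proportion"),
    # the census tables name 15 concrete indicators; the 16th slot is a
    # configurable auxiliary sociodemographic indicator
    ("aux_sociodemographic_index", "sensitive", "lognormal"),
]


class SchemaError(ValueError):
    """Raised when a feature schema or a panel file violates the schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered list of named covariates with category tags."""

    features: tuple = field(
        default_factory=lambda: tuple((n, t) for n, t, _ in DEFAULT_FEATURES)
    )

    def __post_init__(self):
        names = [n for n, _ in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        counts = {tag: sum(1 for _, t in self.features if t == tag)
                  for tag in CATEGORY_ORDER}
        bad = [t for t in self.features if t[1] not in CATEGORY_ORDER]
        if bad:
            raise SchemaError(f"unknown category tags: {bad}")
        if counts["base"] != 7 or counts["wealth"] != 4 or counts["sensitive"] != 5:
            raise SchemaError(
                "schema must have 7 base + 4 wealth + 5 sensitive features, got "
                f"{counts['base']}/{counts['wealth']}/{counts['sensitive']}"
            )

    def names(self, category: str = "all") -> list:
        """Feature names in the given category, in schema order."""
        tags = self._tags(category)
        return [n for n, t in self.features if t in tags]

    def _tags(self, category):
        try:
            return CATEGORY_TAGS[category]
        except KeyError:
            raise SchemaError(
                f"unknown category {category!r}; expected one of {sorted(CATEGORY_TAGS)}"
            ) from None

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(features=tuple((f["name"], f["category"]) for f in cfg["features"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"features": [{"name": n, "category": t} for n, t in self.features]},
                fh, sort_keys=False,
            )


DEFAULT_SCHEMA = FeatureSchema()

#: name -> synthetic distribution family
FEATURE_FAMILIES = {n: fam for n, _, fam in DEFAULT_FEATURES}
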