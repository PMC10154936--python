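"""Table schemas, validation and standardization utilities.

Three CSV schemas flow through the pipeline:

``trait``
    Replicate-level greenhouse measurements: one row per genotype x block,
    with ecotype and population-cluster labels and the eight life-history
    traits (seed mass, germination time/percentage, shoot/root length,
    flowering time, seed number, aboveground biomass).
``climate``
    Climate-of-origin covariates, one row per genotype (elevation, latitude,
    longitude, mean annual temperature, temperature seasonality, annual
    precipitation, precipitation seasonality).
``plot``
    Field seed-addition design: one row per plot with site, genotype,
    seedling and adult counts, and a control flag.

All readers return plain :class:`pandas.DataFrame` objects with typed
columns; validation failures raise :class:`SchemaError` or
:class:`ValidationError` naming the offending column/rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ecosel")

ECOTYPES = ("lowland", "sympatric", "upland")
SITES = ("xeric", "mesic")

TRAIT_COLUMNS = (
    "seed_mass",
    "germination_time",
    "germination_pct",
    "shoot_length",
    "root_length",
    "flowering_time",
    "seed_number",
    "aboveground_biomass",
)

TRAIT_SCHEMA = ("genotype_id", "ecotype", "population_cluster", "block") + TRAIT_COLUMNS

CLIMATE_PREDICTORS = (
    "elevation",
    "latitude",
    "longitude",
    "mat",
    "temp_seasonality",
    "annual_precip",
    "precip_seasonality",
)

CLIMATE_SCHEMA = ("genotype_id",) + CLIMATE_PREDICTORS

PLOT_SCHEMA = (
    "plot_id",
    "site",
    "genotype_id",
    "ecotype",
    "population_cluster",
    "seeds_added",
    "seedling_count",
    "adult_count",
    "is_control",
)

_SCHEMAS = {"trait": TRAIT_SCHEMA, "climate": CLIMATE_SCHEMA, "plot": PLOT_SCHEMA}


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Schema invariants are violated by the data values."""


class DegenerateScaleError(ValueError):
    """A column with zero variance cannot be standardized."""


def _require_columns(df: pd.DataFrame, schema: str) -> None:
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema} table is missing required column(s): {', '.join(missing)}"
        )


def validate_trait(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "trait")
    df = df.copy()
    for col in TRAIT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    bad_eco = set(df["ecotype"].dropna()) - set(ECOTYPES)
    if bad_eco:
        raise ValidationError(f"unknown ecotype level(s): {sorted(bad_eco)}")

    # each genotype maps to exactly one ecotype and one population cluster
    for label in ("ecotype", "population_cluster"):
        n_labels = df.groupby("genotype_id")[label].nunique()
        conflicts = n_labels[n_labels > 1]
        if len(conflicts):
            raise ValidationError(
                f"genotype(s) with conflicting {label} labels: "
                f"{', '.join(map(str, conflicts.index[:5]))}"
            )

    gp = df["germination_pct"]
    if gp.dropna().gt(1).any():
        # percent-scale input: auto-rescale to proportion
        if gp.dropna().gt(100).any():
            raise ValidationError("germination_pct exceeds 100")
        logger.info("germination_pct appears percent-scaled; dividing by 100")
        df["germination_pct"] = gp / 100.0
    if df["germination_pct"].dropna().lt(0).any():
        raise ValidationError("germination_pct below 0")

    nonneg = ("seed_mass", "germination_time", "shoot_length", "root_length",
              "flowering_time", "seed_number", "aboveground_biomass")
    for col in nonneg:
        bad = df.index[df[col].dropna().lt(0).reindex(df.index, fill_value=False)]
        if len(bad):
            raise ValidationError(f"negative values in {col} at rows {list(bad[:5])}")
    return df


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "climate")
    df = df.copy()
    for col in CLIMATE_PREDICTORS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df["genotype_id"].duplicated().any():
        dups = df.loc[df["genotype_id"].duplicated(), "genotype_id"]
        raise ValidationError(f"duplicated genotype rows: {list(dups[:5])}")
    if df["latitude"].abs().gt(90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if df["longitude"].abs().gt(180).any():
        raise ValidationError("longitude outside [-180, 180]")
    return df


def validate_plot(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, "plot")
    df = df.copy()
    for col in ("seeds_added", "seedling_count", "adult_count"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
    df["is_control"] = df["is_control"].astype(bool)
    for col in ("genotype_id", "ecotype", "population_cluster"):
        df[col] = df[col].fillna("")  # control plots carry no genotype

    bad_site = set(df["site"]) - set(SITES)
    if bad_site:
        raise ValidationError(f"unknown site level(s): {sorted(bad_site)}")
    for col in ("seeds_added", "seedling_count", "adult_count"):
        if (df[col] < 0).any():
            raise ValidationError(f"negative counts in {col}")
    bad = df.index[df["adult_count"] > df["seedling_count"]]
    if len(bad):
        raise ValidationError(
            f"adult_count exceeds seedling_count at rows {list(bad[:5])}"
        )
    return df


_VALIDATORS = {"trait": validate_trait, "climate": validate_climate, "plot": validate_plot}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against one of the three schemas."""
    if schema not in _VALIDATORS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(_VALIDATORS)}")
    df = pd.read_csv(path)
    return _VALIDATORS[schema](df)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class ZScore:
    """A standardized vector together with its back-transform parameters."""

    values: np.ndarray
    mean: float
    sd: float

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z) * self.sd + self.mean


def zscore(column) -> ZScore:
    """Standardize to mean 0, sample SD 1 (n-1 denominator).

    Raises :class:`DegenerateScaleError` for constant input; requires n >= 2.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise ValueError("zscore requires at least 2 observations")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateScaleError("column has zero variance; cannot standardize")
    return ZScore(values=(x - mean) / sd, mean=mean, sd=sd)


def genotype_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a replicate-level trait table to one row per genotype.

    Trait values are averaged across blocks (missing cells ignored);
    ecotype/population labels are carried through unchanged. Label
    conflicts within a genotype raise :class:`ValidationError`.
    """
    for label in ("ecotype", "population_cluster"):
        n_labels = table.groupby("genotype_id")[label].nunique()
        if (n_labels > 1).any():
            raise ValidationError(
                f"conflicting {label} labels within genotype(s): "
                f"{list(n_labels.index[n_labels > 1][:5])}"
            )
    traits = [c for c in TRAIT_COLUMNS if c in table.columns]
    agg = {label: "first" for label in ("ecotype", "population_cluster") if label in table}
    agg.update({t: "mean" for t in traits})
    out = table.groupby("genotype_id", sort=True).agg(agg).reset_index()
    return out


def collapse_lowland_clusters(table: pd.DataFrame) -> pd.DataFrame:
    """Relabel the three lowland population clusters as a single group.

    The lowland ecotype contributes few genotypes, so its clusters are
    condensed before the nested variance decomposition.
    """
    out = table.copy()
    mask = out["ecotype"] == "lowland"
    n = out.loc[mask, "population_cluster"].nunique()
    if n > 1:
        logger.info("collapsing %d lowland clusters into one", n)
    out.loc[mask, "population_cluster"] = "lowland_all"
    return out


DEFAULT_CONFIG = {
    "reference_levels": {"site": "xeric", "ecotype": "lowland"},
    "seed": 0,
    "varcomp": {"n_boot": 1000},
    "climate": {"delta_max": 7.0},
    "selection": {"chains": 3, "iterations": 4000},
}


def load_config(path=None) -> dict:
    """Load a YAML config, filling unspecified keys from the defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
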