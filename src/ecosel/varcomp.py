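"""Nested variance decomposition of life-history traits.

Each trait is modelled as an intercept plus nested Gaussian random
intercepts for ecotype, population cluster within ecotype, and genotype
within cluster, with a block-level residual; the REML variance estimates
are converted to proportions of total variance and given nonparametric
bootstrap percentile confidence intervals (genotypes resampled with
replacement within their population clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import collapse_lowland_clusters
from .mixed import ConvergenceError, fit_nested_lmm

logger = logging.getLogger("ecosel")

LEVELS = ("ecotype", "population", "genotype", "residual")


@dataclass
class VarianceDecomposition:
    trait: str
    sigma2: dict  # level -> variance
    proportions: dict  # level -> share of total
    ci: dict | None = None  # level -> (lo, hi) percentile bounds
    n_boot: int = 0
    n_failed: int = 0

    def as_row(self) -> dict:
        row = {"trait": self.trait}
        for lev in LEVELS:
            row[f"sigma2_{lev}"] = self.sigma2[lev]
            row[f"prop_{lev}"] = self.proportions[lev]
            if self.ci is not None:
                row[f"ci_lo_{lev}"], row[f"ci_hi_{lev}"] = self.ci[lev]
        return row


def _complete_cases(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[["ecotype", "population_cluster", "genotype_id", "block", trait]]
    out = sub.dropna(subset=[trait])
    dropped = len(sub) - len(out)
    if dropped:
        logger.info("%s: dropped %d incomplete rows", trait, dropped)
    return out


def fit_nested_ranef(table: pd.DataFrame, trait: str, method: str = "reml", **fit_kw) -> dict:
    """REML variance estimates for the four nested levels of one trait.

    Expects replicate-level rows; the three lowland clusters are collapsed
    into one group before fitting (the lowland ecotype contributes too few
    genotypes to support three cluster levels).
    """
    data = collapse_lowland_clusters(_complete_cases(table, trait))
    if data["ecotype"].nunique() < 2:
        raise ValueError("ecotype variance is unidentifiable with a single ecotype level")
    y = data[trait].to_numpy(float)
    X = np.ones((len(y), 1))
    # cluster/genotype labels made globally unique to guarantee nesting
    cluster = data["ecotype"].astype(str) + "/" + data["population_cluster"].astype(str)
    geno = cluster + "/" + data["genotype_id"].astype(str)
    fit = fit_nested_lmm(y, X, [data["ecotype"], cluster, geno], method=method, **fit_kw)
    if not fit.converged:
        raise ConvergenceError(f"variance-component fit for {trait} did not converge")
    return dict(zip(LEVELS, fit.variances))


def variance_proportions(sigma2: dict) -> VarianceDecomposition:
    """Convert level variances to shares of the total (all four levels)."""
    total = sum(sigma2[lev] for lev in LEVELS)
    if total <= 0:
        raise ValueError("all variance components are zero; proportions undefined")
    props = {lev: sigma2[lev] / total for lev in LEVELS}
    return VarianceDecomposition(trait="", sigma2=dict(sigma2), proportions=props)


def decompose_trait(table: pd.DataFrame, trait: str, **fit_kw) -> VarianceDecomposition:
    out = variance_proportions(fit_nested_ranef(table, trait, **fit_kw))
    out.trait = trait
    return out


def bootstrap_proportions(
    table: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    unit: str = "genotype",
    strict: bool = False,
) -> VarianceDecomposition:
    """Percentile bootstrap CIs for the four variance proportions.

    Case bootstrap: genotypes are resampled with replacement within their
    population cluster (clusters and ecotypes fixed), the model refit on
    each replicate, and the 2.5/97.5 percentiles of each proportion taken.
    ``unit='row'`` switches to plain row resampling.  Replicates whose
    refit fails are dropped; more than 20% failures is a warning, or an
    error under ``strict``.
    """
    if unit not in ("genotype", "row"):
        raise ValueError("unit must be 'genotype' or 'row'")
    base = decompose_trait(table, trait)
    base.trait = trait
    total_var = max(sum(base.sigma2.values()), 1e-12)
    # floor boundary components: starting exactly at sigma2 = 0 strands the
    # optimizer on the log-variance cliff
    x0_warm = np.log(np.clip([base.sigma2[lev] for lev in LEVELS], 1e-3 * total_var, None))
    data = _complete_cases(table, trait)
    rng = np.random.default_rng(seed)

    by_cluster = {
        cl: sub["genotype_id"].unique()
        for cl, sub in data.groupby(data["ecotype"].astype(str) + "/" + data["population_cluster"].astype(str))
    }
    rows_by_geno = {g: sub for g, sub in data.groupby("genotype_id")}

    draws = np.full((n_boot, 4), np.nan)
    n_failed = 0
    for b in range(n_boot):
        if unit == "genotype":
            parts = []
            copy_idx = 0
            for cl, genos in by_cluster.items():
                take = rng.choice(genos, size=len(genos), replace=True)
                for g in take:
                    copy_idx += 1
                    part = rows_by_geno[g].copy()
                    # resampled copies of one genotype stay distinct genotypes
                    part["genotype_id"] = f"{g}*{copy_idx}"
                    parts.append(part)
            rep = pd.concat(parts, ignore_index=True)
        else:
            rep = data.sample(n=len(data), replace=True, random_state=rng.integers(2**31 - 1))
        try:
            # warm-started, unpolished refits: percentile CIs do not need
            # the base fit's tight optimum
            dec = decompose_trait(rep, trait, n_restarts=2, polish=False, x0=x0_warm)
            draws[b] = [dec.proportions[lev] for lev in LEVELS]
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    ok = draws[~np.isnan(draws).any(axis=1)]
    if n_failed:
        msg = f"{trait}: {n_failed}/{n_boot} bootstrap replicates failed"
        if strict and n_failed > 0.2 * n_boot:
            raise ConvergenceError(msg)
        logger.warning(msg)
    if not len(ok):
        raise ConvergenceError(f"{trait}: all bootstrap replicates failed")

    a = (1.0 - level) / 2.0
    lo = np.percentile(ok, 100 * a, axis=0)
    hi = np.percentile(ok, 100 * (1 - a), axis=0)
    base.ci = {lev: (float(lo[k]), float(hi[k])) for k, lev in enumerate(LEVELS)}
    base.n_boot = n_boot
    base.n_failed = n_failed
    return base


def decompose_all(table: pd.DataFrame, traits, n_boot: int = 0, seed: int = 0) -> pd.DataFrame:
    """One decomposition row per trait; bootstrap CIs when n_boot > 0."""
    rows = []
    for t in traits:
        if n_boot > 0:
            dec = bootstrap_proportions(table, t, n_boot=n_boot, seed=seed)
        else:
            dec = decompose_trait(table, t)
        rows.append(dec.as_row())
    return pd.DataFrame(rows)
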