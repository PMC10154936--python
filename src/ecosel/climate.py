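"""Climate-of-origin effects on seed mass: AICc all-subsets model averaging.

A Gaussian mixed model regresses genotype-level seed mass (mg) on seven
standardized climate/geography predictors with random intercepts for
ecotype and population cluster.  All 2^7 additive predictor subsets are
fit by maximum likelihood on the identical row set, ranked by AICc, and
full (zero-substituted) model averaging is applied over the candidate set
with delta AICc below a cutoff (default 7).  The global model's marginal
R^2 (fixed-effect variance share) summarizes goodness of fit.

Because seed mass is a single genotype-level measurement, the genotype
random intercept is exactly aliased with the residual and is absorbed
into it; AICc's parameter count k = intercept + predictors + 2 random
variances + residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats

from .io import CLIMATE_PREDICTORS, genotype_means, zscore
from .mixed import NestedLMMFit, fit_nested_lmm

N_VARCOMP = 3  # ecotype + cluster + residual variances counted in k


@dataclass
class CandidateModel:
    predictor_set: tuple
    coefficients: dict  # predictor -> estimate on SD scale (plus intercept)
    se: dict
    loglik: float
    k: int
    aicc: float
    delta: float = np.nan
    weight: float = np.nan


@dataclass
class AveragedModel:
    averaged_coef: dict
    unconditional_se: dict
    z: dict
    p: dict
    importance: dict
    n_models: int
    delta_max: float
    marginal_r2: float | None = None


@dataclass
class GlobalFitData:
    """Prepared modelling frame shared by all candidate fits."""

    y: np.ndarray
    Z: pd.DataFrame  # standardized predictors
    groups: list
    predictors: tuple
    scale: dict  # predictor -> (mean, sd)


def prepare_climate_frame(traits: pd.DataFrame, climate: pd.DataFrame, predictors=CLIMATE_PREDICTORS) -> GlobalFitData:
    """Join genotype-mean seed mass to climate and z-standardize predictors.

    Rows are fixed to the global complete-case set so every candidate
    model is fit on identical data.
    """
    gm = genotype_means(traits)[["genotype_id", "ecotype", "population_cluster", "seed_mass"]]
    df = gm.merge(climate, on="genotype_id", how="inner")
    df = df.dropna(subset=["seed_mass", *predictors]).reset_index(drop=True)
    Z = pd.DataFrame(index=df.index)
    scale = {}
    for pcol in predictors:
        zs = zscore(df[pcol])
        Z[pcol] = zs.values
        scale[pcol] = (zs.mean, zs.sd)
    cluster = df["ecotype"].astype(str) + "/" + df["population_cluster"].astype(str)
    return GlobalFitData(
        y=df["seed_mass"].to_numpy(float),
        Z=Z,
        groups=[df["ecotype"], cluster],
        predictors=tuple(predictors),
        scale=scale,
    )


def _fit_subset(data: GlobalFitData, subset: tuple, method: str = "ml", **fit_kw) -> tuple[CandidateModel, NestedLMMFit]:
    X = np.column_stack([np.ones(len(data.y))] + [data.Z[p].to_numpy() for p in subset])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient predictor matrix for subset {subset}")
    fit = fit_nested_lmm(data.y, X, data.groups, method=method, **fit_kw)
    names = ("intercept", *subset)
    se = np.sqrt(np.diag(fit.cov_beta))
    k = X.shape[1] + N_VARCOMP
    cand = CandidateModel(
        predictor_set=tuple(subset),
        coefficients=dict(zip(names, fit.beta)),
        se=dict(zip(names, se)),
        loglik=fit.loglik,
        k=k,
        aicc=aicc(fit.loglik, k, len(data.y)),
    )
    return cand, fit


def fit_global_lmm(traits: pd.DataFrame, climate: pd.DataFrame, predictors=CLIMATE_PREDICTORS, method: str = "ml"):
    """ML fit of the global (all-predictor) model; coefficients on SD scale."""
    data = prepare_climate_frame(traits, climate, predictors)
    cand, fit = _fit_subset(data, data.predictors, method=method)
    return cand, fit, data


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values):
    """Delta AICc and normalized Akaike weights exp(-delta/2)/sum."""
    a = np.asarray(aicc_values, float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def all_subsets(traits: pd.DataFrame, climate: pd.DataFrame, predictors=CLIMATE_PREDICTORS) -> list[CandidateModel]:
    """Fit every additive predictor subset (including intercept-only) by ML
    on the identical row set; returns candidates ranked by AICc."""
    data = prepare_climate_frame(traits, climate, predictors)
    # the variance structure is shared across subsets: warm-start every
    # candidate from the global model's (floored) variance estimates
    _, gfit = _fit_subset(data, tuple(predictors))
    floor = 1e-3 * max(gfit.variances.sum(), 1e-12)
    x0 = np.log(np.clip(gfit.variances, floor, None))
    cands = []
    for r in range(len(data.predictors) + 1):
        for subset in combinations(data.predictors, r):
            cand, _ = _fit_subset(data, subset, x0=x0, n_restarts=2, polish=False)
            cands.append(cand)
    cands.sort(key=lambda c: c.aicc)
    delta, w = akaike_weights([c.aicc for c in cands])
    for c, d, wi in zip(cands, delta, w):
        c.delta, c.weight = float(d), float(wi)
    return cands


def model_average(candidates: list[CandidateModel], delta_max: float = 7.0, conditional: bool = False) -> AveragedModel:
    """Full (zero-substituted) model averaging over the delta < delta_max set.

    Weights are renormalized over the retained set.  The unconditional SE
    follows the usual multimodel formula
    se_j = sum_i w_i sqrt(se_ij^2 + (b_ij - bbar_j)^2) with absent
    predictors contributing b = 0, se = 0 (unless ``conditional``, which
    averages only over models containing the predictor).
    """
    kept = [c for c in candidates if (c.aicc - min(x.aicc for x in candidates)) < delta_max]
    if not kept:
        raise ValueError("no candidate models within delta_max")
    _, w = akaike_weights([c.aicc for c in kept])

    predictors = sorted({p for c in kept for p in c.predictor_set})
    avg, use, zval, pval, imp = {}, {}, {}, {}, {}
    for pname in predictors:
        beta = np.array([c.coefficients.get(pname, 0.0) for c in kept])
        se = np.array([c.se.get(pname, 0.0) for c in kept])
        present = np.array([pname in c.predictor_set for c in kept])
        imp[pname] = float(w[present].sum())
        if conditional:
            wc = w[present] / w[present].sum()
            bbar = float(wc @ beta[present])
            sbar = float(wc @ np.sqrt(se[present] ** 2 + (beta[present] - bbar) ** 2))
        else:
            bbar = float(w @ beta)
            sbar = float(w @ np.sqrt(se**2 + (beta - bbar) ** 2))
        avg[pname], use[pname] = bbar, sbar
        z = bbar / sbar if sbar > 0 else np.nan
        zval[pname] = z
        pval[pname] = float(2 * scipy.stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
    return AveragedModel(
        averaged_coef=avg,
        unconditional_se=use,
        z=zval,
        p=pval,
        importance=imp,
        n_models=len(kept),
        delta_max=delta_max,
    )


def marginal_r2(fit: NestedLMMFit, X: np.ndarray) -> float:
    """Fixed-effect variance share: var(X b) / (var(X b) + sum s2_random + s2_res).

    ``X`` must include the intercept column used in the fit.
    """
    eta = X @ fit.beta
    var_f = float(np.var(eta))
    denom = var_f + float(np.sum(fit.variances))
    return var_f / denom if denom > 0 else 0.0


def climate_analysis(traits: pd.DataFrame, climate: pd.DataFrame, delta_max: float = 7.0):
    """End-to-end stage: ranked candidate table, averaged model, marginal R^2."""
    data = prepare_climate_frame(traits, climate)
    cands = all_subsets(traits, climate)
    avg = model_average(cands, delta_max=delta_max)
    gcand, gfit, _ = fit_global_lmm(traits, climate)
    Xg = np.column_stack([np.ones(len(data.y))] + [data.Z[p].to_numpy() for p in data.predictors])
    avg.marginal_r2 = marginal_r2(gfit, Xg)
    return cands, avg


def candidates_to_frame(cands: list[CandidateModel]) -> pd.DataFrame:
    rows = []
    for c in cands:
        row = {"predictors": "+".join(c.predictor_set) or "(intercept)", "k": c.k,
               "loglik": c.loglik, "aicc": c.aicc, "delta": c.delta, "weight": c.weight}
        row.update({p: c.coefficients.get(p, np.nan) for p in CLIMATE_PREDICTORS})
        rows.append(row)
    return pd.DataFrame(rows)
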