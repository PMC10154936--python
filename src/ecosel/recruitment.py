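"""Poisson GLMs of field recruitment: ecotype x site effects on counts.

Seedling and adult counts per plot are modelled with a log link and
ecotype, site and their interaction as categorical predictors.  Each term
is tested by a likelihood-ratio chi-square against the model with the
term removed; fit adequacy is judged by the Pearson statistic, and
within-ecotype site contrasts are reported as cell means with delta-method
standard errors and directional percent differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger("ecosel")


@dataclass
class GLMFit:
    response: str
    result: object  # statsmodels GLMResults for the full interaction model
    data: pd.DataFrame
    ref_site: str
    ref_ecotype: str

    @property
    def coefficients(self):
        return self.result.params

    @property
    def cov(self):
        return self.result.cov_params()

    @property
    def deviance(self):
        return float(self.result.deviance)

    @property
    def df_resid(self):
        return int(self.result.df_resid)

    @property
    def fitted(self):
        return np.asarray(self.result.fittedvalues)


@dataclass
class TermTest:
    term: str
    chisq: float
    df: int
    p: float


@dataclass
class SiteContrast:
    ecotype: str
    mean_xeric: float
    mean_mesic: float
    se_xeric: float
    se_mesic: float
    pct_difference: float
    favoured_site: str
    p: float


def _formula(response, ref_ecotype, ref_site, terms="full"):
    eco = f"C(ecotype, Treatment(reference='{ref_ecotype}'))"
    site = f"C(site, Treatment(reference='{ref_site}'))"
    if terms == "full":
        return f"{response} ~ {eco} * {site}"
    if terms == "main":
        return f"{response} ~ {eco} + {site}"
    if terms == "no_ecotype":
        return f"{response} ~ {site}"
    if terms == "no_site":
        return f"{response} ~ {eco}"
    raise ValueError(terms)


def fit_poisson_glm(plots: pd.DataFrame, response: str = "seedling_count",
                    ref_site: str = "xeric", ref_ecotype: str = "lowland") -> GLMFit:
    """Fit the full ecotype * site Poisson model on non-control plots."""
    data = plots.loc[~plots["is_control"].astype(bool)].copy()
    if data["site"].nunique() < 2 or data["ecotype"].nunique() < 2:
        raise ValueError("need both sites and >= 2 ecotypes in non-control plots")
    zero_cells = (
        data.groupby(["ecotype", "site"])[response].sum().pipe(lambda s: s[s == 0])
    )
    if len(zero_cells):
        logger.warning(
            "all-zero %s cell(s) %s: the cell MLE diverges to -inf on the log scale",
            response, list(zero_cells.index),
        )
    res = smf.glm(
        _formula(response, ref_ecotype, ref_site), data=data, family=sm.families.Poisson()
    ).fit()
    return GLMFit(response=response, result=res, data=data,
                  ref_site=ref_site, ref_ecotype=ref_ecotype)


def term_tests(fit: GLMFit) -> list[TermTest]:
    """Likelihood-ratio chi-square per term.

    The interaction is tested against the main-effects model; each main
    effect is tested by removing it from the main-effects model.
    """
    kw = dict(data=fit.data, family=sm.families.Poisson())
    full = fit.result
    main = smf.glm(_formula(fit.response, fit.ref_ecotype, fit.ref_site, "main"), **kw).fit()
    no_eco = smf.glm(_formula(fit.response, fit.ref_ecotype, fit.ref_site, "no_ecotype"), **kw).fit()
    no_site = smf.glm(_formula(fit.response, fit.ref_ecotype, fit.ref_site, "no_site"), **kw).fit()

    n_eco = fit.data["ecotype"].nunique()
    n_site = fit.data["site"].nunique()
    tests = []
    for term, big, small, df in (
        ("ecotype", main, no_eco, n_eco - 1),
        ("site", main, no_site, n_site - 1),
        ("site x ecotype", full, main, (n_eco - 1) * (n_site - 1)),
    ):
        chisq = max(0.0, 2.0 * (big.llf - small.llf))
        tests.append(TermTest(term=term, chisq=float(chisq), df=df,
                              p=float(scipy.stats.chi2.sf(chisq, df))))
    return tests


def pearson_gof(fit: GLMFit):
    """Pearson X^2, residual df and the dispersion ratio X^2/df."""
    obs = fit.data[fit.response].to_numpy(float)
    mu = fit.fitted
    x2 = float(np.sum((obs - mu) ** 2 / mu))
    df = fit.df_resid
    return x2, df, x2 / df


def site_contrasts(fit: GLMFit) -> list[SiteContrast]:
    """Per-ecotype cell means by site with delta-method SEs and the Wald
    test of the within-ecotype site difference on the log scale.

    Percent difference is (favoured - other) / other * 100, where the
    favoured site is the one with the larger mean.
    """
    res = fit.result
    params = res.params.to_numpy()
    cov = res.cov_params().to_numpy()
    exog_names = res.model.exog_names

    out = []
    for eco in sorted(fit.data["ecotype"].unique()):
        row = {}
        logmean = {}
        grad = {}
        for site in ("xeric", "mesic"):
            # design row for this cell via patsy on a one-row frame
            one = pd.DataFrame({"ecotype": [eco], "site": [site], fit.response: [0]})
            X = np.asarray(patsy.dmatrix(res.model.data.design_info, one))[0]
            eta = float(X @ params)
            var_eta = float(X @ cov @ X)
            logmean[site] = (eta, var_eta)
            grad[site] = X
            row[site] = (np.exp(eta), np.exp(eta) * np.sqrt(var_eta))  # delta method
        d = grad["mesic"] - grad["xeric"]
        diff = float(d @ params)
        se_diff = float(np.sqrt(d @ cov @ d))
        z = diff / se_diff if se_diff > 0 else np.nan
        p = float(2 * scipy.stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan

        mx, sx = row["xeric"]
        mm, sm_ = row["mesic"]
        if mm >= mx:
            fav, pct = "mesic", (np.inf if mx == 0 else (mm - mx) / mx * 100.0)
        else:
            fav, pct = "xeric", (np.inf if mm == 0 else (mx - mm) / mm * 100.0)
        if not np.isfinite(pct):
            logger.warning("zero cell mean for %s; percent difference unbounded", eco)
        out.append(SiteContrast(ecotype=str(eco), mean_xeric=mx, mean_mesic=mm,
                                se_xeric=sx, se_mesic=sm_, pct_difference=float(pct),
                                favoured_site=fav, p=p))
    return out


def control_summary(plots: pd.DataFrame) -> pd.DataFrame:
    """Seed-bank background: count summaries of the control plots per site."""
    ctrl = plots.loc[plots["is_control"].astype(bool)]
    return ctrl.groupby("site")[["seedling_count", "adult_count"]].agg(["count", "mean", "sum"])


def recruitment_analysis(plots: pd.DataFrame, response: str = "seedling_count"):
    """Fit + term tests + GOF + site contrasts for one response."""
    fit = fit_poisson_glm(plots, response=response)
    return fit, term_tests(fit), pearson_gof(fit), site_contrasts(fit)
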