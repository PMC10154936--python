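"""Standardized major axis (SMA) allometry of seed mass against other traits.

The SMA slope is sign(r) * s_y / s_x — the line-fitting choice when both
variables carry error.  Per-group fits report the slope with its exact
F-based confidence interval and the correlation test of H0: r = 0; slope
heterogeneity among ecotypes is tested with the likelihood-ratio
common-slope statistic (chi-square, groups - 1 df) based on the
residual-versus-axis correlation r_uv(beta) with u = y - beta x,
v = y + beta x.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .io import genotype_means

logger = logging.getLogger("ecosel")


@dataclass
class SMAGroupFit:
    group: str
    n: int
    slope: float
    intercept: float
    r: float
    slope_ci: tuple
    p_corr: float
    trait_pair: tuple


@dataclass
class CommonSlopeTest:
    groups: list
    lr_stat: float
    df: int
    p: float
    common_slope: float


def sma_fit(x, y, group: str = "", trait_pair=("x", "y")) -> SMAGroupFit:
    """Single-group SMA fit with exact slope CI and correlation test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"SMA needs n >= 3 (got {n})")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0.0:
        warnings.warn("r is exactly 0; SMA slope sign taken positive")
        sign = 1.0
    else:
        sign = np.sign(r)
    b = float(sign * sy / sx)
    a = float(np.mean(y) - b * np.mean(x))

    if abs(r) == 1.0:
        p_corr, ci = 0.0, (b, b)
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p_corr = float(2 * scipy.stats.t.sf(abs(t), n - 2))
        B = scipy.stats.f.ppf(0.95, 1, n - 2) * (1 - r * r) / (n - 2)
        bounds = (b * (np.sqrt(B + 1) + np.sqrt(B)), b * (np.sqrt(B + 1) - np.sqrt(B)))
        ci = (float(min(bounds)), float(max(bounds)))
    return SMAGroupFit(group=group, n=n, slope=b, intercept=a, r=r,
                       slope_ci=ci, p_corr=p_corr, trait_pair=tuple(trait_pair))


def _r2_uv(x, y, beta):
    """Squared correlation of residual u = y - beta x and axis v = y + beta x."""
    u = y - beta * x
    v = y + beta * x
    su, sv = np.std(u), np.std(v)
    if su == 0 or sv == 0:
        return 0.0
    r = np.mean((u - u.mean()) * (v - v.mean())) / (su * sv)
    return min(r * r, 1.0 - 1e-15)


def _profile_objective(groups_xy, beta):
    return -sum((len(x) - 2) * np.log1p(-_r2_uv(x, y, beta)) for x, y in groups_xy)


def common_slope_test(groups_xy, labels=None) -> CommonSlopeTest:
    """Likelihood-ratio test that all groups share one SMA slope.

    ``groups_xy`` is a list of (x, y) sample pairs.  The objective
    -sum_i (n_i - 2) log(1 - r_uv,i^2(beta)) is zero at each group's own
    slope and is minimized over a common beta; the minimum is the LR
    statistic, chi-square with groups - 1 df under H0.
    """
    clean = []
    labels = list(labels) if labels is not None else [f"group{i}" for i in range(len(groups_xy))]
    for lab, (x, y) in zip(labels, groups_xy):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"degenerate group {lab!r} (n < 3 or zero variance)")
        clean.append((x, y))
    if len(clean) < 2:
        raise ValueError("common-slope test needs >= 2 groups (df >= 1)")

    own = [sma_fit(x, y).slope for x, y in clean]
    lo, hi = min(own), max(own)
    span = max(hi - lo, 1e-6)
    grid = np.linspace(lo - 0.5 * span, hi + 0.5 * span, 512)
    vals = [_profile_objective(clean, b) for b in grid]
    b0 = grid[int(np.argmin(vals))]
    res = scipy.optimize.minimize_scalar(
        lambda b: _profile_objective(clean, b),
        bracket=(b0 - span / 256, b0, b0 + span / 256) if lo < hi else None,
        bounds=(grid[0], grid[-1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lr = max(float(res.fun), 0.0)
    df = len(clean) - 1
    return CommonSlopeTest(groups=labels, lr_stat=lr, df=df,
                           p=float(scipy.stats.chi2.sf(lr, df)), common_slope=float(res.x))


def sma_by_ecotype(traits: pd.DataFrame, y: str, x: str = "seed_mass", log_scale: bool = False):
    """Per-ecotype SMA of trait ``y`` on seed mass, plus the common-slope test.

    Works on genotype means.  Ecotypes with fewer than 3 usable genotypes
    are skipped with a warning (the test df shrinks accordingly).
    Returns ``(list of SMAGroupFit, CommonSlopeTest or None)``.
    """
    gm = genotype_means(traits)
    fits, pairs, labels = [], [], []
    for eco, sub in gm.groupby("ecotype"):
        xv = sub[x].to_numpy(float)
        yv = sub[y].to_numpy(float)
        if log_scale:
            xv, yv = np.log(xv), np.log(yv)
        ok = ~(np.isnan(xv) | np.isnan(yv))
        if ok.sum() < 3:
            logger.warning("ecotype %s has n=%d (<3) for %s~%s; skipped", eco, ok.sum(), y, x)
            continue
        fits.append(sma_fit(xv[ok], yv[ok], group=str(eco), trait_pair=(x, y)))
        pairs.append((xv[ok], yv[ok]))
        labels.append(str(eco))
    test = common_slope_test(pairs, labels) if len(pairs) >= 2 else None
    return fits, test


def pairwise_slope_tests(traits: pd.DataFrame, y: str, x: str = "seed_mass", log_scale: bool = False) -> pd.DataFrame:
    """Post-hoc pairwise common-slope tests with Bonferroni correction."""
    gm = genotype_means(traits)
    groups = {}
    for eco, sub in gm.groupby("ecotype"):
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if log_scale:
            xv, yv = np.log(xv), np.log(yv)
        ok = ~(np.isnan(xv) | np.isnan(yv))
        if ok.sum() >= 3:
            groups[str(eco)] = (xv[ok], yv[ok])
    names = sorted(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t = common_slope_test([groups[a], groups[b]], [a, b])
            rows.append({"pair": f"{a}-{b}", "lr_stat": t.lr_stat, "df": t.df,
                         "p": t.p, "p_bonferroni": min(1.0, t.p * m)})
    return pd.DataFrame(rows)


def fits_to_frame(fits, test=None) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({"group": f.group, "n": f.n, "x": f.trait_pair[0], "y": f.trait_pair[1],
                     "slope": f.slope, "intercept": f.intercept, "r": f.r,
                     "slope_lo": f.slope_ci[0], "slope_hi": f.slope_ci[1], "p_corr": f.p_corr,
                     "common_slope_p": test.p if test else np.nan})
    return pd.DataFrame(rows)
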