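"""Hierarchical Bayesian two-stage Poisson model of seed-mass selection.

Seedling counts per plot are Poisson with a log link; the linear predictor
carries an intercept, a site effect, the genotype's standardized seed
mass, a seed-mass x site interaction, a Gaussian genotype intercept and a
plot effect.  Adult counts are Poisson with the same structure plus the
realized seedling count (scaled by its sample SD) and its site
interaction.  The two plot effects of a plot are jointly Gaussian with
correlation rho, capturing the dependence between a plot's seedling and
adult outcomes.  Priors are weakly informative: N(0, 25 sd) on slopes,
N(0, 10 sd) on intercepts, half-student-t(3, 0, 10) on random-effect SDs,
uniform on rho.

The posterior is explored with Hamiltonian Monte Carlo on an
unconstrained, non-centered parameterization (plot/genotype effects as
scaled standard normals, log SDs, atanh rho) with analytic gradients; the
site-specific selection gradient on each response is the posterior of the
seed-mass slope at that site (base slope, plus interaction at the mesic
site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import gammaln

from .hmc import hmc_chain

logger = logging.getLogger("ecosel")

_HALF_T_DF = 3.0
_HALF_T_SCALE = 10.0


@dataclass
class SelectionModelSpec:
    prior_sd_slope: float = 25.0
    prior_sd_intercept: float = 10.0
    prior_sd_scale: float = _HALF_T_SCALE
    prior_sd_df: float = _HALF_T_DF
    scale_seedling: bool = True  # adult seedling covariate divided by its SD
    three_way: bool = False  # add seed-mass x seedling (x site) terms to the adult stage
    standardize_mass: bool = True
    chains: int = 3
    iterations: int = 4000  # per chain; first half discarded as warm-up
    target_accept: float = 0.8
    leapfrog_range: tuple = (16, 64)

    def __post_init__(self):
        if min(self.prior_sd_slope, self.prior_sd_intercept, self.prior_sd_scale) <= 0:
            raise ValueError("prior scales must be positive")


SEEDLING_TERMS = ("alpha_seedling", "site_seedling", "mass_seedling", "mass_x_site_seedling")
ADULT_TERMS = ("alpha_adult", "site_adult", "mass_adult", "mass_x_site_adult",
               "seedling_adult", "seedling_x_site_adult")
ADULT_TERMS_3WAY = ADULT_TERMS + ("mass_x_seedling_adult", "mass_x_seedling_x_site_adult")
SD_NAMES = ("sd_plot_seedling", "sd_plot_adult", "sd_geno_seedling", "sd_geno_adult")


class SelectionModel:
    """Model + data container: builds design matrices and evaluates the
    log posterior (and its gradient) in both parameterizations."""

    def __init__(self, plots: pd.DataFrame, seed_mass, spec: SelectionModelSpec | None = None):
        self.spec = spec or SelectionModelSpec()
        data = plots.loc[~plots["is_control"].astype(bool)].reset_index(drop=True)
        sm = pd.Series(seed_mass)
        missing = set(data["genotype_id"]) - set(sm.index)
        if missing:
            raise ValueError(f"seed mass missing for genotype(s): {sorted(missing)[:5]}")
        self.n_plots = len(data)
        self.geno_levels = sorted(data["genotype_id"].unique())
        self.n_geno = len(self.geno_levels)
        self.geno_idx = data["genotype_id"].map({g: i for i, g in enumerate(self.geno_levels)}).to_numpy()

        mass = sm.loc[self.geno_levels].to_numpy(float)
        if self.spec.standardize_mass:
            self.mass_mean, self.mass_sd = float(mass.mean()), float(mass.std(ddof=1))
        else:
            self.mass_mean, self.mass_sd = 0.0, 1.0
        z_by_geno = (mass - self.mass_mean) / self.mass_sd
        z = z_by_geno[self.geno_idx]

        m = (data["site"] == "mesic").to_numpy(float)
        self.site = m
        self.y_seedling = data["seedling_count"].to_numpy(float)
        self.y_adult = data["adult_count"].to_numpy(float)

        s_raw = self.y_seedling
        self.seedling_scale = float(s_raw.std(ddof=1)) if self.spec.scale_seedling else 1.0
        if self.seedling_scale == 0:
            self.seedling_scale = 1.0
        s_cov = s_raw / self.seedling_scale

        self.X_seedling = np.column_stack([np.ones(self.n_plots), m, z, z * m])
        cols_a = [np.ones(self.n_plots), m, z, z * m, s_cov, s_cov * m]
        self.adult_terms = ADULT_TERMS
        if self.spec.three_way:
            cols_a += [z * s_cov, z * s_cov * m]
            self.adult_terms = ADULT_TERMS_3WAY
        self.X_adult = np.column_stack(cols_a)
        self.data = data

        self.n_fs = self.X_seedling.shape[1]
        self.n_fa = self.X_adult.shape[1]
        # unconstrained layout: fixed_S, fixed_A, e1, e2, f_S, f_A, 4 log sds, atanh rho
        n, g = self.n_plots, self.n_geno
        o = self.n_fs + self.n_fa
        self.sl_e1 = slice(o, o + n)
        self.sl_e2 = slice(o + n, o + 2 * n)
        self.sl_fs = slice(o + 2 * n, o + 2 * n + g)
        self.sl_fa = slice(o + 2 * n + g, o + 2 * n + 2 * g)
        self.sl_ls = slice(o + 2 * n + 2 * g, o + 2 * n + 2 * g + 4)
        self.i_rho = o + 2 * n + 2 * g + 4
        self.dim = self.i_rho + 1

        self._slope_prior_mask_s = np.array([0.0, 1.0, 1.0, 1.0])
        self._slope_prior_mask_a = np.array([0.0] + [1.0] * (self.n_fa - 1))

    # ---------------- natural-parameterization posterior (oracle surface) --

    def log_posterior(self, params: dict, include_likelihood: bool = True) -> float:
        """Log posterior density at a natural-parameterization point.

        ``params`` holds ``fixed_seedling`` (length 4), ``fixed_adult``,
        ``u_seedling``/``u_adult`` (per plot), ``v_seedling``/``v_adult``
        (per genotype), ``sd`` (the four random-effect SDs) and ``rho``.
        """
        b_s = np.asarray(params["fixed_seedling"], float)
        b_a = np.asarray(params["fixed_adult"], float)
        u_s = np.asarray(params["u_seedling"], float)
        u_a = np.asarray(params["u_adult"], float)
        v_s = np.asarray(params["v_seedling"], float)
        v_a = np.asarray(params["v_adult"], float)
        sd = np.asarray(params["sd"], float)
        rho = float(params["rho"])
        if b_s.size != self.n_fs or b_a.size != self.n_fa:
            raise ValueError("fixed-effect vector dimension mismatch")
        if u_s.size != self.n_plots or v_s.size != self.n_geno:
            raise ValueError("random-effect vector dimension mismatch")
        if not all(np.all(np.isfinite(np.atleast_1d(v))) for v in (b_s, b_a, u_s, u_a, v_s, v_a, sd, [rho])):
            raise ValueError("non-finite parameter value")
        if np.any(sd <= 0) or abs(rho) >= 1:
            return -np.inf

        lp = 0.0
        if include_likelihood:
            eta_s = self.X_seedling @ b_s + v_s[self.geno_idx] + u_s
            eta_a = self.X_adult @ b_a + v_a[self.geno_idx] + u_a
            lp += np.sum(self.y_seedling * eta_s - np.exp(eta_s) - gammaln(self.y_seedling + 1))
            lp += np.sum(self.y_adult * eta_a - np.exp(eta_a) - gammaln(self.y_adult + 1))

        # bivariate normal plot effects
        n = self.n_plots
        s1, s2 = sd[0], sd[1]
        q = ((u_s / s1) ** 2 - 2 * rho * (u_s / s1) * (u_a / s2) + (u_a / s2) ** 2) / (1 - rho**2)
        lp += -n * np.log(2 * np.pi) - n * np.log(s1 * s2) - 0.5 * n * np.log(1 - rho**2) - 0.5 * np.sum(q)
        # genotype intercepts
        for v, s in ((v_s, sd[2]), (v_a, sd[3])):
            lp += np.sum(-0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (v / s) ** 2)
        lp += self._log_prior(b_s, b_a, sd, rho)
        return float(lp)

    def _log_prior(self, b_s, b_a, sd, rho):
        sp = self.spec
        lp = 0.0
        for b, mask in ((b_s, self._slope_prior_mask_s), (b_a, self._slope_prior_mask_a)):
            sds = np.where(mask > 0, sp.prior_sd_slope, sp.prior_sd_intercept)
            lp += np.sum(-0.5 * np.log(2 * np.pi) - np.log(sds) - 0.5 * (b / sds) ** 2)
        # half-student-t(df, 0, scale) on each SD
        df, A = sp.prior_sd_df, sp.prior_sd_scale
        c = (gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi * A**2) + np.log(2.0))
        lp += np.sum(c - (df + 1) / 2 * np.log1p(sd**2 / (df * A**2)))
        lp += -np.log(2.0)  # uniform(-1, 1) on rho
        return lp

    # ---------------- unconstrained non-centered target --------------------

    def _unpack(self, theta):
        b_s = theta[: self.n_fs]
        b_a = theta[self.n_fs: self.n_fs + self.n_fa]
        e1, e2 = theta[self.sl_e1], theta[self.sl_e2]
        f_s, f_a = theta[self.sl_fs], theta[self.sl_fa]
        ls = theta[self.sl_ls]
        r = theta[self.i_rho]
        return b_s, b_a, e1, e2, f_s, f_a, ls, r

    def natural_from_unconstrained(self, theta):
        b_s, b_a, e1, e2, f_s, f_a, ls, r = self._unpack(theta)
        sd = np.exp(ls)
        rho = np.tanh(r)
        u_s = sd[0] * e1
        u_a = sd[1] * (rho * e1 + np.sqrt(1 - rho**2) * e2)
        return {
            "fixed_seedling": b_s, "fixed_adult": b_a,
            "u_seedling": u_s, "u_adult": u_a,
            "v_seedling": sd[2] * f_s, "v_adult": sd[3] * f_a,
            "sd": sd, "rho": rho,
        }

    def logp_grad(self, theta, likelihood_weight: float = 1.0):
        """Log density and gradient of the non-centered unconstrained target.

        The pushforward of this density is the model posterior; it differs
        from :meth:`log_posterior` by the change-of-variables Jacobian.
        ``likelihood_weight=0`` ablates the likelihood for prior-only runs.
        """
        sp = self.spec
        w = likelihood_weight
        b_s, b_a, e1, e2, f_s, f_a, ls, r = self._unpack(theta)
        sd = np.exp(ls)
        rho = np.tanh(r)
        c = np.sqrt(1 - rho**2)
        u_s = sd[0] * e1
        u_a = sd[1] * (rho * e1 + c * e2)
        v_s, v_a = sd[2] * f_s, sd[3] * f_a

        grad = np.zeros_like(theta)
        lp = 0.0
        if w != 0.0:
            with np.errstate(over="ignore", invalid="ignore"):
                eta_s = self.X_seedling @ b_s + v_s[self.geno_idx] + u_s
                eta_a = self.X_adult @ b_a + v_a[self.geno_idx] + u_a
            lim_s, lim_a = np.max(eta_s), np.max(eta_a)
            if not (lim_s < 60 and lim_a < 60):  # also catches NaN
                return -np.inf, grad
            mu_s, mu_a = np.exp(eta_s), np.exp(eta_a)
            lp += w * float(
                np.sum(self.y_seedling * eta_s - mu_s - gammaln(self.y_seedling + 1))
                + np.sum(self.y_adult * eta_a - mu_a - gammaln(self.y_adult + 1))
            )
            d_s = self.y_seedling - mu_s
            d_a = self.y_adult - mu_a
        else:
            d_s = d_a = np.zeros(self.n_plots)

        grad[: self.n_fs] = w * (self.X_seedling.T @ d_s)
        grad[self.n_fs: self.n_fs + self.n_fa] = w * (self.X_adult.T @ d_a)
        grad[self.sl_e1] = w * (d_s * sd[0] + d_a * sd[1] * rho) - e1
        grad[self.sl_e2] = w * d_a * sd[1] * c - e2
        agg_s = np.bincount(self.geno_idx, weights=d_s, minlength=self.n_geno)
        agg_a = np.bincount(self.geno_idx, weights=d_a, minlength=self.n_geno)
        grad[self.sl_fs] = w * sd[2] * agg_s - f_s
        grad[self.sl_fa] = w * sd[3] * agg_a - f_a

        # standard-normal densities of the non-centered effects
        for e in (e1, e2, f_s, f_a):
            lp += float(np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * e * e))

        # fixed-effect priors
        for b, mask, sl in (
            (b_s, self._slope_prior_mask_s, slice(0, self.n_fs)),
            (b_a, self._slope_prior_mask_a, slice(self.n_fs, self.n_fs + self.n_fa)),
        ):
            sds = np.where(mask > 0, sp.prior_sd_slope, sp.prior_sd_intercept)
            lp += float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sds) - 0.5 * (b / sds) ** 2))
            grad[sl] += -b / sds**2

        # half-t priors on sds, with the exp-transform Jacobian (+ls)
        df, A = sp.prior_sd_df, sp.prior_sd_scale
        t2 = sd**2 / (df * A**2)
        lp += float(np.sum(-(df + 1) / 2 * np.log1p(t2) + ls))
        dls_prior = -(df + 1) * t2 / (1 + t2) + 1.0
        # likelihood pull on the log sds via the scaled effects
        dls_lik = w * np.array([
            np.sum(d_s * u_s),
            np.sum(d_a * u_a),
            np.sum(d_s * v_s[self.geno_idx]),
            np.sum(d_a * v_a[self.geno_idx]),
        ])
        grad[self.sl_ls] = dls_lik + dls_prior

        # uniform rho with tanh Jacobian: log(1 - rho^2)
        lp += float(np.log1p(-rho**2))
        du_dr = sd[1] * (e1 - rho / c * e2) * (1 - rho**2)
        grad[self.i_rho] = w * float(np.sum(d_a * du_dr)) - 2.0 * rho
        return lp, grad


@dataclass
class SelectionPosterior:
    draws: dict  # parameter name -> (chains, draws) or (chains, draws, k)
    rhat: dict
    ess: dict
    converged: bool
    model: SelectionModel
    accept_rate: list = field(default_factory=list)

    def stacked(self, name):
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])


def _initial_point(model: SelectionModel, rng) -> np.ndarray:
    x = np.zeros(model.dim)
    x[0] = np.log(model.y_seedling.mean() + 0.5)
    x[model.n_fs] = np.log(model.y_adult.mean() + 0.5)
    x[model.sl_ls] = np.log(0.3)
    x += 0.1 * rng.standard_normal(model.dim)
    return x


_SCALAR_PARAMS = SEEDLING_TERMS  # expanded at runtime with adult terms etc.


def sample_posterior(
    model: SelectionModel,
    seed: int = 0,
    chains: int | None = None,
    iterations: int | None = None,
    likelihood_weight: float = 1.0,
) -> SelectionPosterior:
    """Run HMC chains and collect draws with convergence diagnostics.

    Half of each chain is discarded as warm-up.  Split-Rhat and bulk ESS
    are computed for the interpretable parameters (fixed effects, SDs,
    rho); any Rhat above 1.05 flags the run as non-converged (the result
    is still returned, with ``converged=False``).
    """
    sp = model.spec
    chains = chains or sp.chains
    iterations = iterations or sp.iterations
    if chains < 2:
        logger.warning("fewer than 2 chains: Rhat is not meaningful")
    warmup = iterations // 2
    kept = iterations - warmup

    raw = np.empty((chains, kept, model.dim))
    accepts = []
    for ch in range(chains):
        rng = np.random.default_rng((int(seed) + 1000003 * ch) % (2**31 - 1))
        x0 = _initial_point(model, rng)
        lg = lambda th: model.logp_grad(th, likelihood_weight=likelihood_weight)
        draws, info = hmc_chain(
            lg, x0, n_iter=iterations, warmup=warmup, rng=rng,
            target_accept=sp.target_accept, leapfrog_range=sp.leapfrog_range,
        )
        raw[ch] = draws
        accepts.append(info["accept_rate"])
        logger.info("chain %d: accept %.2f step %.3g", ch, info["accept_rate"], info["step_size"])

    names_s = list(SEEDLING_TERMS)
    names_a = list(model.adult_terms)
    out = {}
    for j, nm in enumerate(names_s):
        out[nm] = raw[:, :, j]
    for j, nm in enumerate(names_a):
        out[nm] = raw[:, :, model.n_fs + j]
    sds = np.exp(raw[:, :, model.sl_ls])
    for j, nm in enumerate(SD_NAMES):
        out[nm] = sds[:, :, j]
    out["cor_plot"] = np.tanh(raw[:, :, model.i_rho])
    # scaled random effects, needed for posterior predictive replication
    rho = out["cor_plot"][..., None]
    out["u_seedling"] = sds[:, :, 0:1] * raw[:, :, model.sl_e1]
    out["u_adult"] = sds[:, :, 1:2] * (
        rho * raw[:, :, model.sl_e1] + np.sqrt(1 - rho**2) * raw[:, :, model.sl_e2]
    )
    out["v_seedling"] = sds[:, :, 2:3] * raw[:, :, model.sl_fs]
    out["v_adult"] = sds[:, :, 3:4] * raw[:, :, model.sl_fa]

    scalar_names = names_s + names_a + list(SD_NAMES) + ["cor_plot"]
    idata = az.from_dict({k: out[k] for k in scalar_names})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in scalar_names}
    ess = {k: float(ess_ds[k].values) for k in scalar_names}
    converged = all(np.isfinite(v) and v <= 1.05 for v in rhat.values()) if chains >= 2 else True
    if not converged:
        worst = max(rhat, key=rhat.get)
        logger.warning("convergence failure: max Rhat %.3f (%s)", rhat[worst], worst)
    return SelectionPosterior(draws=out, rhat=rhat, ess=ess, converged=converged,
                              model=model, accept_rate=accepts)


def selection_gradients(posterior: SelectionPosterior, site: str, response: str = "seedling"):
    """Posterior summary of the seed-mass selection gradient at one site.

    Returns ``{"mean", "ci95", "ci80", "prob_negative"}`` of the
    site-specific slope (xeric: base slope; mesic: base + interaction).
    """
    if site not in ("xeric", "mesic"):
        raise ValueError(f"unknown site {site!r}")
    if response not in ("seedling", "adult"):
        raise ValueError(f"unknown response {response!r}")
    base = posterior.stacked(f"mass_{response}")
    inter = posterior.stacked(f"mass_x_site_{response}")
    g = base + inter if site == "mesic" else base
    return {
        "mean": float(g.mean()),
        "ci95": (float(np.quantile(g, 0.025)), float(np.quantile(g, 0.975))),
        "ci80": (float(np.quantile(g, 0.10)), float(np.quantile(g, 0.90))),
        "prob_negative": float(np.mean(g < 0)),
    }


def gradient_difference(posterior: SelectionPosterior, response: str = "seedling"):
    """Posterior of the mesic-minus-xeric slope difference (the interaction)."""
    d = posterior.stacked(f"mass_x_site_{response}")
    return {
        "mean": float(d.mean()),
        "ci95": (float(np.quantile(d, 0.025)), float(np.quantile(d, 0.975))),
        "prob_negative": float(np.mean(d < 0)),
    }


def posterior_predictive_check(posterior: SelectionPosterior, n_rep: int = 200, seed: int = 0):
    """Replicate count datasets from posterior draws and compare summary
    statistics (mean, variance, zero fraction) with the observed data.

    Replication is conditional on the sampled plot and genotype effects;
    the adult stage uses the observed seedling covariate, mirroring how
    the model was fit.  Predictive p-values are the fraction of replicates
    with statistic >= observed.
    """
    m = posterior.model
    rng = np.random.default_rng(seed)
    names_s = list(SEEDLING_TERMS)
    names_a = list(m.adult_terms)
    b_s = np.column_stack([posterior.stacked(n) for n in names_s])
    b_a = np.column_stack([posterior.stacked(n) for n in names_a])
    u_s, u_a = posterior.stacked("u_seedling"), posterior.stacked("u_adult")
    v_s, v_a = posterior.stacked("v_seedling"), posterior.stacked("v_adult")
    total = b_s.shape[0]
    take = rng.choice(total, size=min(n_rep, total), replace=False)

    stats = {"seedling": {"mean": [], "var": [], "zero_frac": []},
             "adult": {"mean": [], "var": [], "zero_frac": []}}
    for t in take:
        eta_s = m.X_seedling @ b_s[t] + v_s[t][m.geno_idx] + u_s[t]
        eta_a = m.X_adult @ b_a[t] + v_a[t][m.geno_idx] + u_a[t]
        rep_s = rng.poisson(np.exp(np.clip(eta_s, None, 30)))
        rep_a = rng.poisson(np.exp(np.clip(eta_a, None, 30)))
        for nm, rep in (("seedling", rep_s), ("adult", rep_a)):
            stats[nm]["mean"].append(rep.mean())
            stats[nm]["var"].append(rep.var(ddof=1))
            stats[nm]["zero_frac"].append(np.mean(rep == 0))

    obs = {"seedling": m.y_seedling, "adult": m.y_adult}
    result = {}
    for nm in ("seedling", "adult"):
        o = obs[nm]
        observed = {"mean": o.mean(), "var": o.var(ddof=1), "zero_frac": np.mean(o == 0)}
        result[nm] = {
            stat: {
                "observed": float(observed[stat]),
                "replicated_mean": float(np.mean(vals)),
                "p_value": float(np.mean(np.asarray(vals) >= observed[stat])),
            }
            for stat, vals in stats[nm].items()
        }
    return result


def map_estimate(model: SelectionModel, include_random: bool = False):
    """Posterior mode of the fixed effects with random-effect SDs pinned
    near zero (used to cross-check against the Poisson GLM MLE)."""
    if include_random:
        raise NotImplementedError("MAP is provided for the fixed-effects-only check")
    n_f = model.n_fs + model.n_fa
    template = np.zeros(model.dim)
    template[model.sl_ls] = -12.0  # sds ~ exp(-12): effectively no random effects

    def nll(bf):
        th = template.copy()
        th[:n_f] = bf
        lp, g = model.logp_grad(th)
        return -lp, -g[:n_f]

    x0 = np.zeros(n_f)
    x0[0] = np.log(model.y_seedling.mean() + 0.5)
    x0[model.n_fs] = np.log(model.y_adult.mean() + 0.5)
    res = scipy.optimize.minimize(nll, x0, jac=True, method="L-BFGS-B",
                                  options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000})
    names = list(SEEDLING_TERMS) + list(model.adult_terms)
    return dict(zip(names, res.x)), res
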