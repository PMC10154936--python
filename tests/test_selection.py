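import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ecosel.selection import (
    SelectionModel,
    SelectionModelSpec,
    gradient_difference,
    map_estimate,
    posterior_predictive_check,
    sample_posterior,
    selection_gradients,
)
from ecosel.simulate import FieldConfig, simulate_field


def _toy_plots(n=5):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(n):
        site = "mesic" if i % 2 else "xeric"
        rows.append((f"P{i}", site, f"g{i % 3}", "upland", "upland_1", 100,
                     int(rng.poisson(8)), int(rng.poisson(1)), False))
    df = pd.DataFrame(rows, columns=["plot_id", "site", "genotype_id", "ecotype",
                                     "population_cluster", "seeds_added",
                                     "seedling_count", "adult_count", "is_control"])
    df["adult_count"] = np.minimum(df["adult_count"], df["seedling_count"])
    mass = pd.Series([0.6, 1.0, 1.4], index=["g0", "g1", "g2"])
    return df, mass


def _brute_force_log_posterior(model, params):
    """Naive loops re-implementation of the joint log density."""
    spec = model.spec
    d = model.data
    z_geno = {}
    mass = {g: model.mass_mean + 0.0 for g in model.geno_levels}
    # recover z per genotype from the design matrix column
    for i, g in enumerate(model.geno_idx):
        z_geno[g] = model.X_seedling[i, 2]

    total = 0.0
    for i in range(model.n_plots):
        g = model.geno_idx[i]
        m = model.site[i]
        z = model.X_seedling[i, 2]
        s_cov = model.X_adult[i, 4]
        eta_s = (params["fixed_seedling"][0] + params["fixed_seedling"][1] * m
                 + params["fixed_seedling"][2] * z + params["fixed_seedling"][3] * z * m
                 + params["v_seedling"][g] + params["u_seedling"][i])
        eta_a = (params["fixed_adult"][0] + params["fixed_adult"][1] * m
                 + params["fixed_adult"][2] * z + params["fixed_adult"][3] * z * m
                 + params["fixed_adult"][4] * s_cov + params["fixed_adult"][5] * s_cov * m
                 + params["v_adult"][g] + params["u_adult"][i])
        total += scipy.stats.poisson.logpmf(model.y_seedling[i], math.exp(eta_s))
        total += scipy.stats.poisson.logpmf(model.y_adult[i], math.exp(eta_a))

    sd = params["sd"]
    rho = params["rho"]
    cov = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]])
    for i in range(model.n_plots):
        total += scipy.stats.multivariate_normal.logpdf(
            [params["u_seedling"][i], params["u_adult"][i]], mean=[0, 0], cov=cov
        )
    for g in range(model.n_geno):
        total += scipy.stats.norm.logpdf(params["v_seedling"][g], 0, sd[2])
        total += scipy.stats.norm.logpdf(params["v_adult"][g], 0, sd[3])

    for j, b in enumerate(params["fixed_seedling"]):
        total += scipy.stats.norm.logpdf(b, 0, spec.prior_sd_intercept if j == 0 else spec.prior_sd_slope)
    for j, b in enumerate(params["fixed_adult"]):
        total += scipy.stats.norm.logpdf(b, 0, spec.prior_sd_intercept if j == 0 else spec.prior_sd_slope)
    for s in sd:
        total += np.log(2.0) + scipy.stats.t.logpdf(s, spec.prior_sd_df, 0, spec.prior_sd_scale)
    total += np.log(0.5)  # uniform rho on (-1, 1)
    return total


@pytest.fixture(scope="module")
def toy_model():
    plots, mass = _toy_plots()
    return SelectionModel(plots, mass)


def _random_params(model, seed=0):
    rng = np.random.default_rng(seed)
    return {
        "fixed_seedling": rng.normal(0, 0.5, model.n_fs),
        "fixed_adult": rng.normal(0, 0.5, model.n_fa),
        "u_seedling": rng.normal(0, 0.3, model.n_plots),
        "u_adult": rng.normal(0, 0.3, model.n_plots),
        "v_seedling": rng.normal(0, 0.2, model.n_geno),
        "v_adult": rng.normal(0, 0.2, model.n_geno),
        "sd": np.abs(rng.normal(0.5, 0.2, 4)) + 0.05,
        "rho": float(np.tanh(rng.normal(0, 0.5))),
    }


def test_log_posterior_matches_brute_force_oracle(toy_model):
    for seed in range(3):
        params = _random_params(toy_model, seed)
        assert toy_model.log_posterior(params) == pytest.approx(
            _brute_force_log_posterior(toy_model, params), abs=1e-8
        )


def test_poisson_contributions(toy_model):
    """Likelihood term isolated by differencing against the ablated density."""
    params = _random_params(toy_model, 1)
    for key in ("u_seedling", "u_adult", "v_seedling", "v_adult"):
        params[key] = np.zeros_like(params[key])
    params["fixed_seedling"] = np.zeros(toy_model.n_fs)
    params["fixed_adult"] = np.zeros(toy_model.n_fa)
    lik = toy_model.log_posterior(params) - toy_model.log_posterior(params, include_likelihood=False)
    # all linear predictors are 0 -> every count contributes logpmf(y; 1)
    expected = sum(scipy.stats.poisson.logpmf(y, 1.0)
                   for y in np.concatenate([toy_model.y_seedling, toy_model.y_adult]))
    assert lik == pytest.approx(expected, abs=1e-10)
    # frozen single-count values: logP(0;1) = -1, logP(2;2) = 2 log 2 - 2 - log 2
    assert scipy.stats.poisson.logpmf(0, 1.0) == pytest.approx(-1.0)
    assert scipy.stats.poisson.logpmf(2, 2.0) == pytest.approx(2 * np.log(2) - 2 - np.log(2))


def test_plot_effect_density_factorizes_at_zero_correlation(toy_model):
    params = _random_params(toy_model, 2)
    params["rho"] = 0.0
    joint = toy_model.log_posterior(params, include_likelihood=False)
    indep = (
        np.sum(scipy.stats.norm.logpdf(params["u_seedling"], 0, params["sd"][0]))
        + np.sum(scipy.stats.norm.logpdf(params["u_adult"], 0, params["sd"][1]))
    )
    params_zero_u = dict(params, u_seedling=np.zeros(toy_model.n_plots),
                         u_adult=np.zeros(toy_model.n_plots))
    base = toy_model.log_posterior(params_zero_u, include_likelihood=False)
    base_u = (np.sum(scipy.stats.norm.logpdf(0.0, 0, params["sd"][0])) * toy_model.n_plots
              + np.sum(scipy.stats.norm.logpdf(0.0, 0, params["sd"][1])) * toy_model.n_plots)
    assert (joint - base) == pytest.approx(indep - base_u, abs=1e-12)


def test_log_posterior_guards(toy_model):
    params = _random_params(toy_model, 3)
    bad = dict(params, fixed_seedling=np.zeros(2))
    with pytest.raises(ValueError, match="dimension"):
        toy_model.log_posterior(bad)
    nan = dict(params, rho=float("nan"))
    with pytest.raises(ValueError, match="finite"):
        toy_model.log_posterior(nan)


def test_gradient_matches_finite_differences(toy_model):
    rng = np.random.default_rng(4)
    th = 0.2 * rng.standard_normal(toy_model.dim)
    _, g = toy_model.logp_grad(th)
    h = 1e-6
    for i in rng.choice(toy_model.dim, 25, replace=False):
        tp, tm = th.copy(), th.copy()
        tp[i] += h
        tm[i] -= h
        fd = (toy_model.logp_grad(tp)[0] - toy_model.logp_grad(tm)[0]) / (2 * h)
        assert g[i] == pytest.approx(fd, abs=1e-4, rel=1e-4)


def test_sampling_deterministic_under_seed():
    plots, mass = _toy_plots(12)
    spec = SelectionModelSpec(chains=2, iterations=200)
    model = SelectionModel(plots, mass, spec)
    a = sample_posterior(model, seed=9)
    b = sample_posterior(model, seed=9)
    for k in ("mass_seedling", "sd_plot_adult", "cor_plot"):
        np.testing.assert_array_equal(a.draws[k], b.draws[k])


class _FakePosterior:
    """Posterior stand-in with hand-set draws for summary-identity tests."""

    def __init__(self, draws, model):
        self.draws = draws
        self.model = model
        self.converged = True

    def stacked(self, name):
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:])


def test_gradient_summaries_identities(toy_model):
    rng = np.random.default_rng(5)
    base = rng.normal(-0.5, 0.1, (2, 100))
    post = _FakePosterior({"mass_seedling": base,
                           "mass_x_site_seedling": np.zeros((2, 100))}, toy_model)
    gx = selection_gradients(post, "xeric", "seedling")
    gm = selection_gradients(post, "mesic", "seedling")
    assert gx == gm  # no interaction -> identical gradients at both sites
    assert gx["prob_negative"] == 1.0  # all draws negative
    assert gx["ci95"][0] <= gx["mean"] <= gx["ci95"][1]
    assert gx["ci80"][0] >= gx["ci95"][0] and gx["ci80"][1] <= gx["ci95"][1]
    diff = gradient_difference(post, "seedling")
    assert diff["mean"] == pytest.approx(0.0)
    with pytest.raises(ValueError):
        selection_gradients(post, "alpine", "seedling")
    with pytest.raises(ValueError):
        selection_gradients(post, "xeric", "larvae")


def test_map_matches_poisson_glm_mle():
    import statsmodels.api as sm
    plots, truth = simulate_field(FieldConfig(rng_seed=3))
    spec = SelectionModelSpec(prior_sd_slope=1e3, prior_sd_intercept=1e3)
    model = SelectionModel(plots, truth["seed_mass"], spec)
    est, _ = map_estimate(model)
    d = plots[~plots["is_control"]]
    glm = sm.GLM(d["seedling_count"].to_numpy(), model.X_seedling,
                 family=sm.families.Poisson()).fit()
    names = ("alpha_seedling", "site_seedling", "mass_seedling", "mass_x_site_seedling")
    for name, ref in zip(names, glm.params):
        assert est[name] == pytest.approx(ref, abs=0.02)


def test_posterior_predictive_support_and_misfit_detection():
    plots, truth = simulate_field(FieldConfig(rng_seed=7))
    spec = SelectionModelSpec(chains=2, iterations=500)
    model = SelectionModel(plots, truth["seed_mass"], spec)
    post = sample_posterior(model, seed=21)
    ppc = posterior_predictive_check(post, n_rep=80, seed=1)
    for resp in ("seedling", "adult"):
        for stat in ("mean", "var", "zero_frac"):
            assert 0.0 <= ppc[resp][stat]["p_value"] <= 1.0

    # gross misfit: same posterior confronted with 10x-inflated counts
    inflated = plots.copy()
    inflated["seedling_count"] *= 10
    inflated["adult_count"] *= 10
    model10 = SelectionModel(inflated, truth["seed_mass"], spec)
    post10 = _FakePosterior(post.draws, model10)
    ppc10 = posterior_predictive_check(post10, n_rep=80, seed=2)
    assert ppc10["seedling"]["mean"]["p_value"] == pytest.approx(0.0, abs=0.02)


def test_missing_seed_mass_rejected(field):
    plots, truth = field
    mass = truth["seed_mass"].iloc[:-1]
    with pytest.raises(ValueError, match="seed mass missing"):
        SelectionModel(plots, mass)
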