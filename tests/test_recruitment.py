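import numpy as np
import pandas as pd
import pytest
import scipy.stats

from ecosel.recruitment import (
    control_summary,
    fit_poisson_glm,
    pearson_gof,
    site_contrasts,
    term_tests,
)
from ecosel.simulate import FieldConfig, simulate_field


def _plots_from_counts(cell_counts):
    """Build a plot table from {(ecotype, site): [counts]}."""
    rows = []
    i = 0
    for (eco, site), counts in cell_counts.items():
        for c in counts:
            i += 1
            rows.append((f"P{i}", site, f"g{eco}", eco, f"{eco}_1", 100, c, 0, False))
    return pd.DataFrame(rows, columns=["plot_id", "site", "genotype_id", "ecotype",
                                       "population_cluster", "seeds_added",
                                       "seedling_count", "adult_count", "is_control"])


@pytest.fixture()
def toy_plots():
    rng = np.random.default_rng(0)
    cells = {}
    means = {("lowland", "xeric"): 5, ("lowland", "mesic"): 9,
             ("sympatric", "xeric"): 7, ("sympatric", "mesic"): 7,
             ("upland", "xeric"): 11, ("upland", "mesic"): 4}
    for cell, mu in means.items():
        cells[cell] = rng.poisson(mu, 40)
    return _plots_from_counts(cells)


def test_saturated_model_fits_cell_means_exactly(toy_plots):
    fit = fit_poisson_glm(toy_plots, "seedling_count")
    obs = toy_plots.groupby(["ecotype", "site"])["seedling_count"].mean()
    fitted = toy_plots.assign(mu=fit.fitted).groupby(["ecotype", "site"])["mu"].mean()
    np.testing.assert_allclose(fitted, obs, rtol=1e-8)


def test_canonical_link_cell_total_identity(toy_plots):
    fit = fit_poisson_glm(toy_plots, "seedling_count")
    df = toy_plots.assign(mu=fit.fitted)
    for _, cell in df.groupby(["ecotype", "site"]):
        assert cell["mu"].sum() == pytest.approx(cell["seedling_count"].sum(), abs=1e-8)


def test_homogeneous_counts_give_zero_effects():
    cells = {(e, s): [6] * 10 for e in ("lowland", "upland") for s in ("xeric", "mesic")}
    fit = fit_poisson_glm(_plots_from_counts(cells), "seedling_count")
    params = fit.coefficients
    assert params.iloc[0] == pytest.approx(np.log(6), abs=1e-8)
    np.testing.assert_allclose(params.iloc[1:], 0.0, atol=1e-8)
    for t in term_tests(fit):
        assert t.chisq == pytest.approx(0.0, abs=1e-6)


def test_term_df_bookkeeping(toy_plots):
    tests = {t.term: t for t in term_tests(fit_poisson_glm(toy_plots, "seedling_count"))}
    assert tests["ecotype"].df == 2
    assert tests["site"].df == 1
    assert tests["site x ecotype"].df == 2


def test_lr_chisq_invariant_to_reference_levels(toy_plots):
    a = term_tests(fit_poisson_glm(toy_plots, "seedling_count",
                                   ref_site="xeric", ref_ecotype="lowland"))
    b = term_tests(fit_poisson_glm(toy_plots, "seedling_count",
                                   ref_site="mesic", ref_ecotype="upland"))
    for ta, tb in zip(a, b):
        assert ta.chisq == pytest.approx(tb.chisq, rel=1e-8)


def test_lr_chisq_equals_explicit_deviance_difference(toy_plots):
    """Oracle: interaction chi2 from two explicit deviances."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    fit = fit_poisson_glm(toy_plots, "seedling_count")
    full = smf.glm("seedling_count ~ C(ecotype) * C(site)", data=toy_plots,
                   family=sm.families.Poisson()).fit()
    main = smf.glm("seedling_count ~ C(ecotype) + C(site)", data=toy_plots,
                   family=sm.families.Poisson()).fit()
    inter = [t for t in term_tests(fit) if t.term == "site x ecotype"][0]
    assert inter.chisq == pytest.approx(main.deviance - full.deviance, rel=1e-8)


def test_duplicating_data_doubles_chisq(toy_plots):
    doubled = pd.concat([toy_plots, toy_plots], ignore_index=True)
    a = term_tests(fit_poisson_glm(toy_plots, "seedling_count"))
    b = term_tests(fit_poisson_glm(doubled, "seedling_count"))
    for ta, tb in zip(a, b):
        assert tb.chisq == pytest.approx(2 * ta.chisq, rel=0.01)


def test_pearson_statistic_matches_direct_sum(toy_plots):
    fit = fit_poisson_glm(toy_plots, "seedling_count")
    x2, df, disp = pearson_gof(fit)
    manual = np.sum((toy_plots["seedling_count"] - fit.fitted) ** 2 / fit.fitted)
    assert x2 == pytest.approx(manual, rel=1e-12)
    assert df == len(toy_plots) - 6
    # true Poisson data: dispersion near 1
    assert abs(disp - 1.0) < 0.25


def test_perfect_fit_has_zero_pearson():
    cells = {(e, s): [int(5 + 3 * i)] * 8 for i, (e, s) in enumerate(
        ((e, s) for e in ("lowland", "upland") for s in ("xeric", "mesic")))}
    fit = fit_poisson_glm(_plots_from_counts(cells), "seedling_count")
    x2, _, _ = pearson_gof(fit)
    assert x2 == pytest.approx(0.0, abs=1e-8)


def test_site_contrast_arithmetic(toy_plots):
    contrasts = {c.ecotype: c for c in site_contrasts(fit_poisson_glm(toy_plots, "seedling_count"))}
    low = contrasts["lowland"]
    expected = (low.mean_mesic - low.mean_xeric) / low.mean_xeric * 100
    assert low.favoured_site == "mesic"
    assert low.pct_difference == pytest.approx(expected)
    up = contrasts["upland"]
    assert up.favoured_site == "xeric"
    assert up.p < 0.001


def test_equal_cell_means_give_null_contrast():
    cells = {(e, s): [6] * 30 for e in ("lowland", "upland") for s in ("xeric", "mesic")}
    for c in site_contrasts(fit_poisson_glm(_plots_from_counts(cells), "seedling_count")):
        assert c.pct_difference == pytest.approx(0.0, abs=1e-8)
        assert c.p > 0.99


def test_interaction_p_uniform_under_additive_null():
    """No true interaction: LR p-values for site x ecotype are U(0,1)."""
    rng = np.random.default_rng(5)
    eco_eff = {"lowland": 0.0, "sympatric": 0.3, "upland": -0.2}
    pvals = []
    for _ in range(300):
        cells = {}
        for eco, e in eco_eff.items():
            for site, s in (("xeric", 0.0), ("mesic", 0.4)):
                cells[(eco, site)] = rng.poisson(np.exp(np.log(8) + e + s), 20)
        tests = term_tests(fit_poisson_glm(_plots_from_counts(cells), "seedling_count"))
        pvals.append([t for t in tests if t.term == "site x ecotype"][0].p)
    assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


def test_local_adaptation_pattern_recovered_from_generator(field):
    plots, truth = field
    fit = fit_poisson_glm(plots, "seedling_count")
    contrasts = {c.ecotype: c for c in site_contrasts(fit)}
    # generator favours small seeds (lowland) at mesic, large (upland) at xeric
    assert contrasts["lowland"].favoured_site == "mesic"
    assert contrasts["upland"].favoured_site == "xeric"
    inter = [t for t in term_tests(fit) if t.term == "site x ecotype"][0]
    assert inter.p < 0.001


def test_contrast_recovery_against_generator_truth():
    """GLM cell contrasts track the generator's expected cell-mean ratios."""
    errs = []
    for s in range(4):
        cfg = FieldConfig(rng_seed=50 + s, sd_plot=(0.1, 0.1))
        plots, truth = simulate_field(cfg)
        z = truth["z_seed_mass"]
        v = pd.Series(truth["genotype_effects"]["seedling"])
        lab = plots[~plots["is_control"]][["genotype_id", "ecotype"]].drop_duplicates()
        fit = fit_poisson_glm(plots, "seedling_count")
        for c in site_contrasts(fit):
            genos = lab.loc[lab["ecotype"] == c.ecotype, "genotype_id"]
            ex = np.sum(np.exp(truth["beta_mass"]["xeric"] * z[genos] + v[genos]))
            em = np.sum(np.exp(truth["beta_mass"]["mesic"] * z[genos] + v[genos]))
            truth_ratio = max(ex, em) / min(ex, em)
            est_ratio = max(c.mean_xeric, c.mean_mesic) / min(c.mean_xeric, c.mean_mesic)
            errs.append(est_ratio - truth_ratio)
    assert abs(np.mean(errs)) < 0.15


def test_control_plots_excluded_and_summarized(field):
    plots, _ = field
    fit = fit_poisson_glm(plots, "seedling_count")
    assert len(fit.data) == 294
    summ = control_summary(plots)
    assert (summ[("seedling_count", "count")] == 7).all()


def test_control_only_or_single_site_rejected(field):
    plots, _ = field
    with pytest.raises(ValueError):
        fit_poisson_glm(plots[plots["site"] == "xeric"], "seedling_count")
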