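# ecosel

Statistical pipeline for studying ecotypic divergence and natural
selection on seed mass in reciprocal-transplant designs, written for
quantitative ecologists working with diversity panels (genotype × block
trait tables), climate-of-origin covariates, and field seed-addition
experiments.

Many grasses and other widespread plants form locally adapted ecotypes —
e.g. a large-seeded upland form in xeric habitat and a small-seeded
lowland form in mesic habitat. `ecosel` packages the analyses needed to
ask, end to end: how is trait variation arrayed across ecotypes,
populations and genotypes; does climate of origin predict seed mass; do
trait covariances differ among ecotypes; are ecotypes locally adapted;
and how strong is selection on seed mass in each habitat?

## The models

- **Ecotype discrimination** — canonical (linear) discriminant analysis
  of genotype-mean traits: axes from the between/within scatter
  eigenproblem, percent discrimination per axis, structure-coefficient
  loadings, and equal-prior classification accuracy.
- **Variance decomposition** — intercept-only REML mixed models with
  nested random intercepts (genotype ⊂ population cluster ⊂ ecotype),
  variance proportions per level, and case-bootstrap percentile CIs
  (genotypes resampled within clusters, 1000 replicates).
- **Climate model averaging** — all 2⁷ additive subsets of seven
  standardized climate predictors of seed mass, fit by ML with nested
  random intercepts, ranked by AICc, and full (zero-substituted)
  model-averaged over the ΔAICc < 7 set; marginal R² of the global model.
- **SMA allometry** — standardized major axis regression of each trait
  on seed mass per ecotype (slope b = sign(r)·s_y/s_x with exact CIs)
  and the likelihood-ratio common-slope test among ecotypes.
- **Recruitment GLMs** — Poisson ecotype × site models of seedling and
  adult counts with likelihood-ratio term tests, Pearson goodness of
  fit, and per-ecotype site contrasts with percent differences.
- **Selection gradients** — a joint hierarchical Bayesian two-stage
  Poisson model: seedling counts driven by site-specific seed-mass
  slopes, adult counts additionally by realized seedling number, with
  correlated plot effects and genotype intercepts, sampled by the
  package's Hamiltonian Monte Carlo with analytic gradients. The
  site-specific selection gradient β is the log-linear effect of a 1 SD
  seed-mass increase on recruitment at that site.

A synthetic-data module generates both experiments (123 genotypes × 3
blocks; 21 genotypes × 7 replicates × 2 sites = 294 plots of 100 seeds)
from known parameters, so every estimator ships with recovery tests.
See `docs/methods.md` for the full model descriptions and caveats.

## Worked example

```python
from ecosel import simulate_panel, simulate_field, genotype_means, PanelConfig, FieldConfig
from ecosel.lda import lda_fit
from ecosel.io import TRAIT_COLUMNS
from ecosel.selection import SelectionModel, sample_posterior, selection_gradients

traits, climate, _ = simulate_panel(PanelConfig(rng_seed=1))
gm = genotype_means(traits)
res = lda_fit(gm, gm["ecotype"], traits=list(TRAIT_COLUMNS))
print(f"axis 1: {100 * res.pct_discrimination[0]:.1f}% of discrimination, "
      f"accuracy {100 * res.accuracy_overall:.1f}%")

plots, truth = simulate_field(FieldConfig(rng_seed=1))
post = sample_posterior(SelectionModel(plots, truth["seed_mass"]), seed=1)
for site in ("xeric", "mesic"):
    g = selection_gradients(post, site, "seedling")
    print(f"{site}: beta = {g['mean']:.2f}, 95% CI "
          f"({g['ci95'][0]:.2f}, {g['ci95'][1]:.2f}), P(beta<0) = {g['prob_negative']:.2f}")
```

prints (a few minutes for the sampler):

```
axis 1: 92.2% of discrimination, accuracy 86.2%
xeric: beta = 0.13, 95% CI (0.03, 0.22), P(beta<0) = 0.01
mesic: beta = -0.60, 95% CI (-0.70, -0.51), P(beta<0) = 1.00
```

The first canonical axis carries nearly all ecotype discrimination (seed
mass and its correlates dominate it). The selection gradients recover
the generating regime — selection favouring larger seeds at the xeric
site and smaller seeds at the mesic site, the genotype-by-environment
signature of local adaptation; the generator's true slopes here are
+0.20 and −0.56 per SD of seed mass.

A `ecosel` command-line interface wraps each stage
(`ecosel simulate panel`, `ecosel lda`, `ecosel varcomp`,
`ecosel climate`, `ecosel sma`, `ecosel recruitment`,
`ecosel selection`, `ecosel validate`); every subcommand reads and
writes the CSV schemas described in `docs/methods.md`.

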