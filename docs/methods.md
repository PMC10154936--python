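# Methods

`ecosel` implements the statistical machinery of a local-adaptation study
design built around two experiments on a perennial grass with divergent
upland (xeric-adapted, large-seeded) and lowland (mesic-adapted,
small-seeded) ecotypes plus an admixed sympatric group: a greenhouse
diversity panel (genotypes measured for seed, seedling and reproductive
traits in replicate blocks) and a reciprocal seed-addition experiment at a
xeric and a mesic field site. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Data model

Three tables flow through the pipeline. The trait table holds one row per
genotype × block with eight traits: seed mass (mg/seed, measured once per
genotype as the mass of 100 seeds ÷ 100 and therefore constant across
blocks), germination time (h), germination percentage (stored as a
proportion; percent-scaled input is auto-detected and divided by 100),
shoot and root length (mm), flowering time (d), seed number and
aboveground biomass (mg). The climate table carries seven genotype-level
climate-of-origin covariates (elevation, latitude, longitude, mean annual
temperature, temperature seasonality, annual precipitation, precipitation
seasonality). The plot table holds the field design: plot × site ×
genotype with seeds added (100), seedling and adult counts, and a control
flag for the no-seed plots used to gauge the seed bank. Missing trait
cells are allowed and dropped listwise per analysis, with the count
logged. Reference levels default to `xeric` (site) and `lowland`
(ecotype) and are configurable.

## Canonical discriminant analysis

Genotype-mean traits are analysed by the generalized eigenproblem of
between-ecotype versus pooled within-ecotype scatter. Traits are scaled
to unit pooled within-group variance before the eigensolve (the ratio
criterion is invariant to this, so reported results are on the raw
scale). An axis's eigenvalue share is its percent discrimination.
Loadings are reported as structure coefficients — pooled within-group
correlations between each trait and the canonical scores — which is the
convention behind statements like "trait X had the highest loading"; raw
coefficients are also available. Classification uses equal priors and
the pooled covariance; the headline accuracy is resubstitution (matching
common point-and-click defaults), with a leave-one-out variant provided.

## Nested variance decomposition

Each trait is fit with an intercept-only Gaussian mixed model with nested
random intercepts: genotype within population cluster within ecotype,
block-level residual. Because the lowland ecotype contributes few
genotypes, its three clusters are collapsed into one before fitting. The
REML criterion is maximized numerically over log-variances (L-BFGS-B with
three starts, simplex polish, tolerance 1e-14 on the objective); the
marginal covariance is assembled block-wise over ecotypes, so likelihood
evaluations scale with the largest ecotype block. Variances that reach
the zero boundary are reported as exact zeros. Proportions divide each
variance by the four-component total (residual included). Confidence
intervals are nonparametric case-bootstrap percentiles: genotypes are
resampled with replacement within their population cluster (clusters and
ecotypes fixed — the inference target is the genotype sample), the model
refit per replicate (warm-started from the base fit, floored away from
the zero boundary), and 2.5/97.5 percentiles taken over 1000 replicates
by default. Failed refits are dropped and counted; more than 20% failures
escalates to an error in strict mode. Row-level resampling is available
by flag. Note that with only three ecotype levels the ecotype variance is
intrinsically noisy and its bootstrap interval is correspondingly wide;
this is a property of the design, not the estimator.

## Climate-of-origin model averaging

Genotype seed mass (mg) is regressed on the seven z-standardized climate
predictors with random intercepts for ecotype and population cluster, fit
by maximum likelihood (not REML) so that AICc is comparable across
fixed-effect sets. Seed mass is a single genotype-level measurement, so a
genotype random intercept would be exactly aliased with the residual; the
genotype level is absorbed into the residual and the AICc parameter count
is k = intercept + predictors + 2 random variances + residual. All 2^7 =
128 additive subsets are fit on the identical complete-case rows
(warm-started from the global model's variance estimates), ranked by
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n = number of genotypes, and
model-averaged over the ΔAICc < 7 set using full (zero-substituted)
averaging: absent predictors contribute β = 0, and the unconditional SE
is Σᵢ wᵢ √(seᵢ² + (βᵢ − β̄)²). Conditional averaging is available by
flag. The global model's marginal R² is the fixed-effect linear
predictor's variance over the total (fixed + random + residual).

## SMA allometry

For each trait against seed mass, per-ecotype standardized major axis
lines are fit on genotype means: slope b = sign(r)·s_y/s_x, intercept
through the centroid, correlation test of H0 r = 0 on n−2 df, and the
exact slope CI b·(√(B+1) ± √B) with B = F(0.95; 1, n−2)(1−r²)/(n−2).
Traits are analysed on the raw scale by default (a log-log option
exists). Slope heterogeneity among ecotypes is the likelihood-ratio
common-slope test: with u = y − βx and v = y + βx, the objective
−Σᵢ (nᵢ−2) log(1 − r²_uv,i(β)) is zero at each group's own slope and its
minimum over a common β is the LR statistic, χ² with groups − 1 df. The
minimization is a dense grid bracket followed by bounded scalar
refinement; ecotypes with fewer than three genotypes are skipped and the
df reduced. Pairwise post-hoc comparisons reuse the statistic with
Bonferroni correction.

A structural caveat: cov(y−βx, y+βx) = s²_y − β²s²_x depends on β only
through β², so this test — like the classical common-slope test it
follows — is blind to the *sign* of the slope and detects heterogeneity
of slope magnitude. Groups whose relationships differ only in sign (equal
|slope|) are not flagged; the per-group correlation tests carry the sign
information.

## Recruitment GLMs

Seedling and adult counts on non-control plots are modelled as Poisson
with log link and ecotype × site factorial predictors. Term tests are
likelihood-ratio χ² (interaction against the main-effects model; each
main effect by removal from the main-effects model); Wald-style tests of
the same contrasts are recoverable from the coefficient covariance. Fit
adequacy is the Pearson X²/df dispersion ratio. Site contrasts per
ecotype report the two cell means (delta-method SEs), a Wald test of the
log-scale site difference, and the percent difference defined
directionally as (favoured − other)/other × 100. Control plots are
excluded from the models and summarized separately as the seed-bank
background. No offset is used since every treatment plot received the
same 100 seeds; an offset option exists for unequal designs. All-zero
cells (which send the cell MLE to −∞ on the log scale) are flagged with a
warning.

## Hierarchical Bayesian selection model

The two-stage recruitment model is the package's centrepiece. Per plot i
with site indicator m (mesic = 1), standardized genotype seed mass z, and
genotype g:

    S_i ~ Poisson(exp(α_S + β_site m + β_mass z + β_mass×site z·m + v_S,g + u_S,i))
    A_i ~ Poisson(exp(α_A + γ_site m + γ_mass z + γ_mass×site z·m
                      + γ_seedling S̃_i + γ_seedling×site S̃_i·m + v_A,g + u_A,i))

where S̃ is the observed seedling count scaled by its sample SD, (u_S,
u_A) are plot effects jointly Gaussian with SDs (σ_uS, σ_uA) and
correlation ρ (capturing the dependence between a plot's two outcomes),
and v are genotype intercepts, independent between responses. Priors are
weakly informative: N(0, sd 25) on slopes, N(0, sd 10) on intercepts,
half-student-t(3, 0, 10) on random-effect SDs, uniform on ρ. The "sd 25"
reading of the slope prior follows the convention of the usual regression
PPLs. The adult stage includes the two two-way interactions with site;
a `three_way` switch adds seed-mass × seedling(× site) terms for users
who read "their interactions" maximally. The site-specific selection
gradient is the posterior of the seed-mass slope at that site (xeric:
base slope; mesic: base + interaction), and the mesic−xeric difference is
the interaction posterior.

Sampling is Hamiltonian Monte Carlo written for this model: the target is
the non-centered, unconstrained parameterization (plot and genotype
effects as scaled standard normals, log SDs, atanh ρ) with analytic
gradients; jittered leapfrog path lengths (uniform 16–64 steps),
dual-averaging step-size adaptation to 0.8 acceptance, and two diagonal
mass-matrix updates during warm-up. Defaults are 3 chains × 4000
iterations with the first half discarded, giving 6000 retained draws;
split-R̂ and bulk ESS (via arviz) are computed for the interpretable
parameters and any R̂ > 1.05 flags the run as non-converged (the result
is returned with the flag set). Runs are exactly reproducible given a
seed. The unconstrained target is verified against the natural-
parameterization log posterior, which in turn is tested against a naive
loop-based re-implementation. Posterior predictive checks replicate
count datasets conditional on the sampled plot/genotype effects (the
adult stage keeps the observed seedling covariate) and compare mean,
variance and zero fraction with tail p-values. A MAP mode with
random-effect SDs pinned near zero reproduces the Poisson GLM MLE and is
used as a cross-check.

## Synthetic data generator

The generator is first-class code that defines the study conditions for
every test. The panel emulates 123 genotypes in 7 population clusters (3
upland, 3 lowland, 1 sympatric; the lowland clusters are genotype-poor)
measured in 3 blocks. Trait values are built hierarchically — ecotype
mean + cluster effect + genotype effect + block residual — on a
transform scale chosen for positivity: log for sizes/masses/counts, raw
for times, logit for germination percentage. Ecotype trait means are
qualitative defaults (upland > sympatric > lowland seed mass, and so on);
no quantitative per-ecotype trait means were available to calibrate
against, so realism is limited to ordering and the design counts. Traits
with configured SMA structure derive their genotype-level variation from
the genotype's log seed-mass deviation within its ecotype, so the
within-ecotype SMA slope and correlation match the configuration in
expectation; block residuals then attenuate the realized genotype-mean
correlations, which is why convergence tests zero the block variance.
Mean annual temperature is drawn independently per genotype (SD 2.34 °C)
and shifts seed mass by −0.28 mg per SD by default, applied on the log
scale via the panel-weighted mean mass so the mg-scale regression slope
matches; the remaining climate covariates are noise, with elevation
mildly anti-correlated with temperature to emulate collinearity.

The field generator mirrors the experimental design (21 genotypes × 7
replicates × 2 sites, 100 seeds per plot, 7 control plots per site) and
draws counts from the selection model itself, with defaults set to the
estimated seedling gradients (+0.20 xeric, −0.56 mesic per SD of seed
mass). Adult gradients default to −0.49 (xeric) and −1.2 (mesic): the
conditional-on-seedling mesic estimate reported for this design is far
more negative, but using it as a generator default would empty the mesic
adult cells and make the parameter unidentifiable in every downstream
demonstration, so the default preserves the sign and ordering at a
moderate magnitude. Draws are truncated at the physical bounds (seeds
added, then seedlings emerged); the fitted model is untruncated, so
recovery studies run in regimes where expected counts (~10 per 100
seeds) make truncation negligible. Control plots emit zero counts — the
generator does not emulate a natural seed bank, spatial autocorrelation
between plots, seed dormancy, or census timing.

What passing tests show, and do not show: parameter recovery and interval
coverage hold when the data-generating process is the model itself (plus
physical truncation). They do not certify behavior under overdispersion
beyond the modelled random effects, zero-inflation, non-random genotype
placement, or trait distributions unlike the generator's.

## Numerical choices and limitations

- REML/ML optimizations run on log-variance scale with bounds
  [−30, 20]; estimates below 1e−8 of the total are snapped to exact 0.
  Warm starts are floored at 1e−3 of the total variance because starting
  on the zero boundary strands the optimizer.
- With zero-noise degenerate inputs the restricted likelihood is
  unbounded; fits stop at the bound and proportions approach (not reach)
  their limits.
- The bootstrap treats non-converged replicates as missing; their count
  is reported.
- AICc requires n > k + 1; candidate sets are always fit on the global
  complete-case rows so likelihoods are comparable.
- The common-slope grid spans the per-group slopes ±50% of their range;
  exactly collinear groups make the profile objective degenerate (the CI
  collapses and the grid dip has measure zero), so perfect-fit toys are
  not meaningful inputs.
- HMC divergence protection caps linear predictors at 60 on the log
  scale (rejecting the trajectory), which is far outside any realistic
  count regime.
- Problem sizes in the test suite are scaled to desk hardware: bootstrap
  and replication counts in tests are smaller than the 1000-replicate
  defaults, and the coverage study for the Bayesian stage uses 30
  simulated datasets with 2 × 800-iteration chains; the acceptance
  script runs the full 3 × 4000 sampler on the full 294-plot design.
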