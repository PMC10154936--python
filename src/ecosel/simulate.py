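"""Synthetic diversity-panel and field-experiment data with known truth.

The generator mirrors the study design the pipeline targets: a diversity
panel of 123 inbred genotypes from 7 population clusters in 3 ecotypes
(upland, lowland, sympatric), measured in 3 replicate blocks; and a
reciprocal seed-addition experiment of 21 genotypes x 7 replicates x 2
sites (294 plots of 100 seeds each) whose Poisson recruitment counts are
drawn from the same selection model the Bayesian stage fits.

Every simulator returns the generating parameters alongside the data so
downstream estimators can be tested for parameter recovery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ECOTYPES, SITES, TRAIT_COLUMNS

__all__ = [
    "PanelConfig",
    "FieldConfig",
    "simulate_panel",
    "simulate_field",
    "simulate_nested_gaussian",
    "stage_rng",
]


def stage_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic substream for a pipeline stage: one global seed + tag."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


# transform scale on which each trait's hierarchical effects act
TRAIT_SCALE = {
    "seed_mass": "log",
    "germination_time": "raw",
    "germination_pct": "logit",
    "shoot_length": "log",
    "root_length": "log",
    "flowering_time": "raw",
    "seed_number": "log",
    "aboveground_biomass": "log",
}


def _to_transformed(trait: str, x):
    scale = TRAIT_SCALE[trait]
    x = np.asarray(x, dtype=float)
    if scale == "log":
        return np.log(x)
    if scale == "logit":
        return np.log(x / (1.0 - x))
    return x


def _from_transformed(trait: str, t):
    scale = TRAIT_SCALE[trait]
    t = np.asarray(t, dtype=float)
    if scale == "log":
        return np.exp(t)
    if scale == "logit":
        return 1.0 / (1.0 + np.exp(-t))
    return t


# per-ecotype trait means on the natural scale; qualitative ordering only
# (large-seeded upland, small-seeded lowland, intermediate sympatric)
DEFAULT_ECOTYPE_MEANS = {
    "seed_mass": {"lowland": 0.60, "sympatric": 0.90, "upland": 1.20},
    "germination_time": {"lowland": 60.0, "sympatric": 72.0, "upland": 84.0},
    "germination_pct": {"lowland": 0.75, "sympatric": 0.70, "upland": 0.65},
    "shoot_length": {"lowland": 35.0, "sympatric": 40.0, "upland": 45.0},
    "root_length": {"lowland": 45.0, "sympatric": 52.0, "upland": 60.0},
    "flowering_time": {"lowland": 95.0, "sympatric": 85.0, "upland": 75.0},
    "seed_number": {"lowland": 600.0, "sympatric": 450.0, "upland": 300.0},
    "aboveground_biomass": {"lowland": 2500.0, "sympatric": 3000.0, "upland": 3500.0},
}

# (sigma2_population, sigma2_genotype, sigma2_residual) on the transformed scale
DEFAULT_VARIANCE_COMPONENTS = {
    "seed_mass": (0.010, 0.020, 0.0),  # one weighing per genotype: no block noise
    "germination_time": (12.0, 36.0, 16.0),
    "germination_pct": (0.04, 0.12, 0.09),
    "shoot_length": (0.008, 0.025, 0.010),
    "root_length": (0.008, 0.025, 0.010),
    "flowering_time": (9.0, 49.0, 25.0),
    "seed_number": (0.02, 0.08, 0.04),
    "aboveground_biomass": (0.02, 0.08, 0.04),
}

# per-ecotype (SMA slope, correlation) of each trait (transformed scale)
# against log seed mass; signs follow the qualitative ecotype-specific
# covariation patterns the pipeline is meant to resolve
DEFAULT_SMA_STRUCTURE = {
    "germination_time": {"upland": (40.0, 0.70), "sympatric": (40.0, 0.70), "lowland": (-20.0, -0.30)},
    "germination_pct": {"upland": (-2.0, -0.60), "sympatric": (-2.0, -0.40), "lowland": (-1.0, -0.15)},
    "shoot_length": {"upland": (0.5, 0.50), "sympatric": (0.5, 0.60), "lowland": (0.2, 0.15)},
    "root_length": {"upland": (0.6, 0.60), "sympatric": (0.6, 0.60), "lowland": (0.6, 0.55)},
    "flowering_time": {"upland": (-5.0, -0.10), "sympatric": (-25.0, -0.35), "lowland": (-35.0, -0.60)},
    "seed_number": {"upland": (-0.8, -0.60), "sympatric": (0.8, 0.45), "lowland": (0.3, 0.20)},
    "aboveground_biomass": {"upland": (0.6, 0.60), "sympatric": (0.6, 0.60), "lowland": (-0.4, -0.40)},
}

DEFAULT_CLUSTER_SIZES = {
    "upland_1": 20, "upland_2": 20, "upland_3": 21,
    "lowland_1": 5, "lowland_2": 5, "lowland_3": 5,
    "sympatric_1": 47,
}


@dataclass
class PanelConfig:
    """Generative parameters for the diversity panel.

    ``cluster_sizes`` maps cluster name (prefixed by its ecotype) to the
    number of genotypes; the default allocation reproduces the 123-genotype
    / 7-cluster / 3-ecotype panel with a genotype-poor lowland ecotype.
    ``climate_effect`` is the regression slope of seed mass (mg) on
    standardized mean annual temperature.
    """

    cluster_sizes: dict = field(default_factory=lambda: dict(DEFAULT_CLUSTER_SIZES))
    n_blocks: int = 3
    ecotype_trait_means: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ECOTYPE_MEANS.items()})
    variance_components: dict = field(default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS))
    sma_structure: dict = field(default_factory=lambda: {k: {e: t for e, t in v.items()} for k, v in DEFAULT_SMA_STRUCTURE.items()})
    climate_effect: float = -0.28
    mat_mean: float = 17.0
    mat_sd: float = 2.34
    rng_seed: int = 0

    def __post_init__(self):
        for name, n in self.cluster_sizes.items():
            if n < 1:
                raise ValueError(f"cluster {name!r} has {n} genotypes; need >= 1")
            if not any(name.startswith(e) for e in ECOTYPES):
                raise ValueError(f"cluster name {name!r} must be prefixed by its ecotype")
        for trait, comps in self.variance_components.items():
            if any(v < 0 for v in comps):
                raise ValueError(f"negative variance component for {trait}")
        for trait, per_eco in self.sma_structure.items():
            for eco, (slope, r) in per_eco.items():
                if abs(r) > 1:
                    raise ValueError(f"|correlation| > 1 for {trait}/{eco}")


def _cluster_ecotype(name: str) -> str:
    for eco in ECOTYPES:
        if name.startswith(eco):
            return eco
    raise ValueError(name)


def simulate_panel(config: PanelConfig | None = None):
    """Draw a replicate-level trait table, a climate table, and the truth.

    Trait values are built hierarchically on each trait's transform scale:
    ecotype mean + cluster effect + genotype effect + block residual, all
    Gaussian with the configured variances.  Traits listed in
    ``sma_structure`` instead derive their genotype-level variation from
    the genotype's log seed-mass deviation within its ecotype, so that the
    within-ecotype SMA slope and correlation against log seed mass equal
    the configured values in expectation.  Mean annual temperature is
    generated so that genotype seed mass regresses on standardized MAT
    with slope ``climate_effect`` (mg per SD).

    Returns ``(trait_table, climate_table, truth)``.
    """
    cfg = config or PanelConfig()
    rng = stage_rng(cfg.rng_seed, "panel")

    clusters = list(cfg.cluster_sizes)
    geno_rows = []
    idx = 0
    for cl in clusters:
        eco = _cluster_ecotype(cl)
        for _ in range(cfg.cluster_sizes[cl]):
            idx += 1
            geno_rows.append((f"G{idx:03d}", eco, cl))
    genotypes = pd.DataFrame(geno_rows, columns=["genotype_id", "ecotype", "population_cluster"])
    n_geno = len(genotypes)
    eco_arr = genotypes["ecotype"].to_numpy()

    # --- seed mass on the log scale ---------------------------------------
    s2_pop, s2_gen, s2_res = cfg.variance_components["seed_mass"]
    mu_log = np.array([_to_transformed("seed_mass", cfg.ecotype_trait_means["seed_mass"][e]) for e in eco_arr])
    cl_eff = {cl: rng.normal(0.0, np.sqrt(s2_pop)) for cl in clusters}
    g_eff = rng.normal(0.0, np.sqrt(s2_gen), n_geno)
    log_sm = mu_log + np.array([cl_eff[c] for c in genotypes["population_cluster"]]) + g_eff

    # MAT as an exogenous genotype covariate whose standardized value
    # shifts seed mass by climate_effect mg per SD (applied on the log
    # scale via the panel-average mass, so the mg-scale slope matches)
    mat = rng.normal(cfg.mat_mean, cfg.mat_sd, n_geno)
    z_mat = (mat - mat.mean()) / mat.std(ddof=1)
    # panel-weighted mean seed mass (with the lognormal mean correction)
    # converts the mg-per-SD climate effect to the log scale
    mean_mass = float(
        np.mean([cfg.ecotype_trait_means["seed_mass"][e] for e in eco_arr])
        * np.exp(0.5 * (s2_pop + s2_gen))
    )
    beta_log = cfg.climate_effect / mean_mass
    log_sm = log_sm + beta_log * z_mat
    seed_mass_geno = np.exp(log_sm)

    # within-ecotype deviations of log seed mass drive trait covariation
    x_dev = np.empty(n_geno)
    x_sd = {}
    for eco in ECOTYPES:
        m = eco_arr == eco
        x_dev[m] = log_sm[m] - log_sm[m].mean()
        x_sd[eco] = log_sm[m].std(ddof=1) if m.sum() > 1 else 1.0

    # --- other traits at the genotype level -------------------------------
    geno_level = {"seed_mass": log_sm}
    for trait in TRAIT_COLUMNS:
        if trait == "seed_mass":
            continue
        mu = np.array([_to_transformed(trait, cfg.ecotype_trait_means[trait][e]) for e in eco_arr])
        if trait in cfg.sma_structure:
            vals = np.empty(n_geno)
            for eco in ECOTYPES:
                m = eco_arr == eco
                slope, r = cfg.sma_structure[trait][eco]
                sd_y = abs(slope) * x_sd[eco]
                beta_ols = r * abs(slope)
                noise_sd = sd_y * np.sqrt(max(0.0, 1.0 - r * r))
                vals[m] = mu[m] + beta_ols * x_dev[m] + rng.normal(0.0, noise_sd, m.sum())
            geno_level[trait] = vals
        else:
            s2_pop, s2_gen, _ = cfg.variance_components[trait]
            cl_eff = {cl: rng.normal(0.0, np.sqrt(s2_pop)) for cl in clusters}
            geno_level[trait] = (
                mu
                + np.array([cl_eff[c] for c in genotypes["population_cluster"]])
                + rng.normal(0.0, np.sqrt(s2_gen), n_geno)
            )

    # --- replicate blocks --------------------------------------------------
    rows = []
    for b in range(1, cfg.n_blocks + 1):
        block = genotypes.copy()
        block["block"] = f"B{b}"
        for trait in TRAIT_COLUMNS:
            s2_res = cfg.variance_components[trait][2]
            noise = rng.normal(0.0, np.sqrt(s2_res), n_geno) if s2_res > 0 else 0.0
            block[trait] = _from_transformed(trait, geno_level[trait] + noise)
        rows.append(block)
    traits = pd.concat(rows, ignore_index=True)
    traits = traits[["genotype_id", "ecotype", "population_cluster", "block", *TRAIT_COLUMNS]]

    climate = pd.DataFrame(
        {
            "genotype_id": genotypes["genotype_id"],
            "elevation": np.clip(1200.0 - 40.0 * mat + rng.normal(0, 250, n_geno), 0, None),
            "latitude": rng.normal(29.0, 2.0, n_geno),
            "longitude": rng.normal(-98.0, 3.0, n_geno),
            "mat": mat,
            "temp_seasonality": rng.normal(800.0, 150.0, n_geno),
            "annual_precip": np.clip(rng.normal(700.0, 250.0, n_geno), 50, None),
            "precip_seasonality": np.clip(rng.normal(50.0, 15.0, n_geno), 5, None),
        }
    )

    truth = {
        "config": cfg,
        "seed_mass_genotype": pd.Series(seed_mass_geno, index=genotypes["genotype_id"]),
        "beta_log_mat": beta_log,
        "climate_effect": cfg.climate_effect,
    }
    return traits, climate, truth


def simulate_nested_gaussian(
    n_top: int,
    n_mid: int,
    n_geno: int,
    n_blocks: int,
    variances,
    mean: float = 0.0,
    seed: int = 0,
    trait: str = "value",
) -> pd.DataFrame:
    """Balanced nested Gaussian panel for variance-component recovery tests.

    ``variances`` = (sigma2_top, sigma2_mid, sigma2_genotype, sigma2_residual);
    the grouping columns follow the trait-table naming (ecotype /
    population_cluster / genotype_id / block) so the decomposition stage can
    consume the output directly.
    """
    s2 = [float(v) for v in variances]
    if len(s2) != 4 or any(v < 0 for v in s2):
        raise ValueError("variances must be 4 non-negative values")
    rng = np.random.default_rng(seed)
    rows = []
    g_index = 0
    for t in range(n_top):
        a = rng.normal(0, np.sqrt(s2[0]))
        for m in range(n_mid):
            b = rng.normal(0, np.sqrt(s2[1]))
            for g in range(n_geno):
                g_index += 1
                c = rng.normal(0, np.sqrt(s2[2]))
                eps = rng.normal(0, np.sqrt(s2[3]), n_blocks)
                for k in range(n_blocks):
                    rows.append(
                        (f"E{t}", f"E{t}_C{m}", f"G{g_index:05d}", f"B{k}", mean + a + b + c + eps[k])
                    )
    return pd.DataFrame(rows, columns=["ecotype", "population_cluster", "genotype_id", "block", trait])


@dataclass
class FieldConfig:
    """Generative parameters for the reciprocal seed-addition experiment.

    The defaults reproduce the experimental design (21 genotypes x 7
    replicates x 2 sites, 100 seeds per plot, 7 empty control plots per
    site) and the estimated site-specific seed-mass selection gradients on
    seedling recruitment (+0.20 at the xeric site, -0.56 at the mesic
    site, per SD of seed mass).
    """

    n_genotypes: int = 21
    n_reps: int = 7
    seeds_added: int = 100
    n_controls_per_site: int = 7
    alpha_seedling: float = float(np.log(10.0))
    alpha_adult: float = -0.5
    site_effect_seedling: float = 0.0  # mesic minus xeric, log scale
    site_effect_adult: float = 0.0
    beta_mass: dict = field(default_factory=lambda: {"xeric": 0.20, "mesic": -0.56})
    gamma_mass: dict = field(default_factory=lambda: {"xeric": -0.49, "mesic": -1.2})
    gamma_seedling: float = 0.08  # per raw seedling
    sd_plot: tuple = (0.30, 0.30)
    cor_plot: float = 0.5
    sd_genotype: tuple = (0.20, 0.20)
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_genotypes, self.n_reps, self.seeds_added) < 1:
            raise ValueError("design counts must be positive")
        if abs(self.cor_plot) > 1:
            raise ValueError("|cor_plot| must be <= 1")
        if min(self.sd_plot) < 0 or min(self.sd_genotype) < 0:
            raise ValueError("standard deviations must be >= 0")


def simulate_field(config: FieldConfig | None = None, seed_mass=None, labels=None):
    """Draw a plot table of Poisson recruitment counts from the selection model.

    ``seed_mass`` maps genotype id -> seed mass (mg); if omitted, 21
    genotypes are drawn spanning the panel's seed-mass range, 3 per
    population cluster.  Seedling counts are Poisson with log-linear
    site-specific seed-mass effects, genotype intercepts, and plot effects
    correlated across the two responses; adult counts additionally depend
    on the realized seedling count.  Draws are truncated at the physical
    bounds (seeds added, then seedlings emerged).

    Returns ``(plot_table, truth)``.
    """
    cfg = config or FieldConfig()
    rng = stage_rng(cfg.rng_seed, "field")

    if seed_mass is None:
        n = cfg.n_genotypes
        clusters = list(DEFAULT_CLUSTER_SIZES)
        geno = []
        for i in range(n):
            cl = clusters[i % len(clusters)]
            geno.append((f"F{i + 1:02d}", _cluster_ecotype(cl), cl))
        labels = pd.DataFrame(geno, columns=["genotype_id", "ecotype", "population_cluster"])
        mass_mu = labels["ecotype"].map(DEFAULT_ECOTYPE_MEANS["seed_mass"]).to_numpy()
        seed_mass = pd.Series(
            np.exp(np.log(mass_mu) + rng.normal(0, 0.17, n)), index=labels["genotype_id"]
        )
    else:
        seed_mass = pd.Series(seed_mass)
        if labels is None:
            labels = pd.DataFrame(
                {
                    "genotype_id": seed_mass.index,
                    "ecotype": "sympatric",
                    "population_cluster": "sympatric_1",
                }
            )
    genos = list(seed_mass.index)
    n_geno = len(genos)
    z = (seed_mass.to_numpy() - seed_mass.mean()) / seed_mass.std(ddof=1)
    z_by_geno = dict(zip(genos, z))

    v_s = rng.normal(0, cfg.sd_genotype[0], n_geno)
    v_a = rng.normal(0, cfg.sd_genotype[1], n_geno)
    v_s_by, v_a_by = dict(zip(genos, v_s)), dict(zip(genos, v_a))

    rows = []
    plot_idx = 0
    lab = labels.set_index("genotype_id")
    for site in SITES:
        m = 1.0 if site == "mesic" else 0.0
        for g in genos:
            for _ in range(cfg.n_reps):
                plot_idx += 1
                # correlated plot effect pair
                e1, e2 = rng.standard_normal(2)
                u_s = cfg.sd_plot[0] * e1
                u_a = cfg.sd_plot[1] * (cfg.cor_plot * e1 + np.sqrt(1 - cfg.cor_plot**2) * e2)
                eta_s = (
                    cfg.alpha_seedling + cfg.site_effect_seedling * m
                    + cfg.beta_mass[site] * z_by_geno[g] + v_s_by[g] + u_s
                )
                s_count = min(int(rng.poisson(np.exp(eta_s))), cfg.seeds_added)
                eta_a = (
                    cfg.alpha_adult + cfg.site_effect_adult * m
                    + cfg.gamma_mass[site] * z_by_geno[g]
                    + cfg.gamma_seedling * s_count + v_a_by[g] + u_a
                )
                a_count = min(int(rng.poisson(np.exp(eta_a))), s_count)
                rows.append(
                    (
                        f"P{plot_idx:04d}", site, g,
                        lab.loc[g, "ecotype"], lab.loc[g, "population_cluster"],
                        cfg.seeds_added, s_count, a_count, False,
                    )
                )
        for _ in range(cfg.n_controls_per_site):
            plot_idx += 1
            rows.append((f"P{plot_idx:04d}", site, "", "", "", 0, 0, 0, True))

    plots = pd.DataFrame(
        rows,
        columns=[
            "plot_id", "site", "genotype_id", "ecotype", "population_cluster",
            "seeds_added", "seedling_count", "adult_count", "is_control",
        ],
    )
    truth = {
        "config": cfg,
        "seed_mass": seed_mass,
        "z_seed_mass": pd.Series(z, index=genos),
        "beta_mass": dict(cfg.beta_mass),
        "gamma_mass": dict(cfg.gamma_mass),
        "genotype_effects": {"seedling": v_s_by, "adult": v_a_by},
    }
    return plots, truth
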