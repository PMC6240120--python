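"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a community-wide plant-frugivore
study — phylogenetically correlated plant traits with brightness-nutrient
couplings of prescribed marginal r-squared, frugivore traits (generalism,
zero-inflated migratory distance), and seasonal site networks in which
fruit choice depends on frugivore traits — so that every pipeline stage
can be tested against a recorded generating truth.

Default dimensions copy the study setting this package targets: 44 plant
species, 43 frugivore species, 3 sites and 4 seasons, with
brightness-nutrient couplings at the published marginal r-squared values
(lipid +0.23, sugar -0.11, protein 0, anthocyanin -0.35) and
frugivore-preference coefficients at the published path scale
(generalism-brightness +0.4, migration-darkness 0.3).  Observation effort
defaults to desk-scale counts (~10^3-10^4 visits), not the field totals.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network_diets import MIGRATION_SEASONS, SEASONS, VisitRecord
from .phylo import Phylogeny, correlation_from_tree, read_newick

__all__ = [
    "SimConfig",
    "SimTruth",
    "sim_tree",
    "sim_plant_traits",
    "sim_frugivores",
    "sim_networks",
    "sim_sem_observations",
    "simulate_study",
]

NUTRIENTS = ("lipid", "sugar", "protein", "anthocyanin")


@dataclass
class SimConfig:
    n_plants: int = 44
    n_frugivores: int = 43
    n_sites: int = 3
    seasons: tuple = SEASONS
    #: signed target marginal r-squared of each ln-nutrient on brightness
    nutrient_r2: dict = field(default_factory=lambda: {
        "lipid": 0.23, "sugar": -0.11, "protein": 0.0, "anthocyanin": -0.35})
    #: share of trait variance attributable to phylogeny (vs iid)
    phylo_share: float = 0.5
    #: preference coefficients: generalism-brightness and migration-darkness
    gamma_generalism: float = 0.4
    gamma_migration: float = 0.3
    resident_fraction: float = 0.5
    effort_hours: float = 50.0
    #: fraction of per-visit consumption rates masked (imputation ladder)
    fpv_missing_frac: float = 0.3
    #: fraction of each trait masked for augmentation tests
    mask_fractions: dict = field(default_factory=lambda: {
        "pulp_mass_g": 0.11, "lipid": 0.07, "sugar": 0.07,
        "protein": 0.09, "anthocyanin": 0.27})
    seed: int = 0

    def __post_init__(self):
        if self.n_plants < 2 or self.n_frugivores < 2 or self.n_sites < 1:
            raise ValueError("counts must be >= 2 (sites >= 1)")
        for k, v in self.nutrient_r2.items():
            if not (0.0 <= abs(v) < 1.0):
                raise ValueError(f"target r2 for {k} must be in [0, 1)")
        if self.effort_hours <= 0:
            raise ValueError("observation effort must be > 0")


@dataclass
class SimTruth:
    """Everything needed to check what the pipeline estimates."""

    plant_tree: Phylogeny | None = None
    bird_tree: Phylogeny | None = None
    plant_traits: pd.DataFrame | None = None   # unmasked values
    frugivores: pd.DataFrame | None = None
    nutrient_slopes: dict = field(default_factory=dict)
    gamma_generalism: float = 0.0
    gamma_migration: float = 0.0
    masked: dict = field(default_factory=dict)  # column -> {species: value}
    expected_rates: pd.DataFrame | None = None  # per network cell
    expected_brightness_profile: pd.DataFrame | None = None
    sem_paths: dict = field(default_factory=dict)
    sem_variances: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trees


def sim_tree(n_tips: int, seed: int, prefix: str = "t") -> Phylogeny:
    """Ultrametric pure-birth-style tree with unit root-to-tip depth."""
    if n_tips < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    # backward in time: merge random lineage pairs at increasing heights
    nodes = [(f"{prefix}{i + 1}", 0.0) for i in range(n_tips)]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        nodes.append(((left, right), t))
    depth = nodes[0][1]

    def emit(node, parent_h):
        sub, h = node
        bl = (parent_h - h) / depth
        if isinstance(sub, str):
            return f"{sub}:{bl:.10f}"
        return f"({emit(sub[0], h)},{emit(sub[1], h)}):{bl:.10f}"

    (lsub, rsub), h = nodes[0]
    newick = f"({emit(lsub, h)},{emit(rsub, h)});"
    return read_newick(newick)


def _phylo_noise(corr_matrix: np.ndarray, phylo_share: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-variance species noise split between tree-structured and iid."""
    n = corr_matrix.shape[0]
    L = np.linalg.cholesky(corr_matrix + 1e-10 * np.eye(n))
    z_phy = L @ rng.normal(size=n)
    z_iid = rng.normal(size=n)
    return np.sqrt(phylo_share) * z_phy + np.sqrt(1 - phylo_share) * z_iid


# ---------------------------------------------------------------------------
# plants


def _random_smooth_spectrum(rng: np.random.Generator):
    """Smooth random reflectance shape (base level plus broad Gaussian
    bumps, fruit-like).  The caller rescales it to a target brightness —
    exact, since brightness is linear in reflectance, unless the scale
    would exceed physical reflectance, in which case the realized
    brightness falls short and the caller records the realized value."""
    from .colour_space import WAVELENGTH_GRID, ReflectanceSpectrum

    wl = WAVELENGTH_GRID
    shape = np.full_like(wl, 0.4)
    for _ in range(rng.integers(2, 5)):
        c = rng.uniform(320, 680)
        w = rng.uniform(40, 120)
        shape = shape + rng.uniform(-0.35, 0.6) * np.exp(
            -0.5 * ((wl - c) / w) ** 2)
    shape = np.clip(shape, 0.02, 1.0)
    return ReflectanceSpectrum(wl, shape)


def sim_plant_traits(tree: Phylogeny, config: SimConfig, seed: int,
                     mask: bool = True, spectra: bool = False):
    """Plant trait table with known brightness-nutrient couplings.

    Returns (masked table, SimTruth-fragment dict).  ln-brightness is a
    standardized latent with phylogenetic signal; each ln-nutrient is
    slope * latent + unit-variance noise with
    slope = sign * sqrt(|r2| / (1 - |r2|)) so the marginal r-squared of
    the coupling equals the target.  Chromatic coordinates are
    independent of the nutrients: by default drawn directly inside the
    tetrahedron; with ``spectra=True`` a smooth random reflectance is
    synthesized per species with the prescribed brightness and the
    colour coordinates are derived from it, so the table's (x, y, z, a)
    round-trip through the colour-space transform by construction (the
    truth fragment carries the spectra under key "spectra").
    """
    rng = np.random.default_rng(seed)
    species = tree.tip_labels
    C = correlation_from_tree(tree, species).matrix
    n = len(species)

    z_a = _phylo_noise(C, config.phylo_share, rng)
    a = np.minimum(np.exp(-1.2 + 0.4 * z_a), 1.0)

    df = pd.DataFrame(index=pd.Index(species, name="species"))
    ln_d = np.log(8.0) + 0.35 * _phylo_noise(C, config.phylo_share, rng)
    df["diameter_mm"] = np.exp(ln_d)
    ln_m = -6.5 + 2.0 * ln_d + 0.3 * _phylo_noise(C, config.phylo_share, rng)
    df["pulp_mass_g"] = np.exp(ln_m)

    slopes = {}
    base_level = {"lipid": -2.8, "sugar": -1.2, "protein": -2.9,
                  "anthocyanin": 0.0}
    for nut in NUTRIENTS:
        r2 = config.nutrient_r2.get(nut, 0.0)
        slope = np.sign(r2) * np.sqrt(abs(r2) / (1 - abs(r2)))
        slopes[nut] = float(slope)
        noise = _phylo_noise(C, config.phylo_share, rng)
        df[nut] = np.exp(base_level[nut] + slope * z_a + noise)

    spectra_map = {}
    if spectra:
        from .colour_space import (ReflectanceSpectrum, make_receptors,
                                   quantum_catches, to_tetra)
        receptors = make_receptors()
        xs, ys, zs, realized_a = [], [], [], []
        for i, sp in enumerate(species):
            base = _random_smooth_spectrum(rng)
            catch = quantum_catches(base, receptors)
            from .colour_space import brightness as _brightness
            scale = min(a[i] / _brightness(catch), 1.0 / base.reflectance.max())
            spec_i = ReflectanceSpectrum(base.wavelengths,
                                         base.reflectance * scale)
            catch = quantum_catches(spec_i, receptors)
            col = to_tetra(catch)
            spectra_map[sp] = spec_i
            xs.append(col.x)
            ys.append(col.y)
            zs.append(col.z)
            realized_a.append(col.a)
        df["x"], df["y"], df["z"] = xs, ys, zs
        df["a"] = realized_a
    else:
        # chroma: mild colours independent of the nutrient axis
        from .colour_space import TETRA_VERTICES
        catches = rng.dirichlet(np.full(4, 5.0), size=n)
        verts = np.stack([TETRA_VERTICES[k]
                          for k in ("uvs", "sws", "mws", "lws")])
        xyz = catches @ verts
        df["x"], df["y"], df["z"] = xyz[:, 0], xyz[:, 1], xyz[:, 2]
        df["a"] = a
    df["brightness_latent"] = z_a

    truth = {"plant_traits": df.copy(), "nutrient_slopes": slopes,
             "spectra": spectra_map}
    masked = {}
    out = df.copy()
    if mask:
        for col, frac in config.mask_fractions.items():
            k = int(round(frac * n))
            if k == 0:
                continue
            hide = rng.choice(species, size=k, replace=False)
            masked[col] = {s: float(df.loc[s, col]) for s in hide}
            out.loc[hide, col] = np.nan
    truth["masked"] = masked
    return out, truth


# ---------------------------------------------------------------------------
# frugivores and networks


def sim_frugivores(config: SimConfig, seed: int) -> pd.DataFrame:
    """Frugivore table: generalism propensity, zero-inflated migratory
    distance (degrees latitude; residents 0) and site memberships."""
    rng = np.random.default_rng(seed)
    n = config.n_frugivores
    names = [f"b{i + 1}" for i in range(n)]
    df = pd.DataFrame(index=pd.Index(names, name="frugivore"))
    df["generalism"] = rng.normal(size=n)
    resident = rng.random(n) < config.resident_fraction
    dist = rng.gamma(4.0, 4.0, size=n)
    df["migratory_distance"] = np.where(resident, 0.0, dist)
    for s in range(config.n_sites):
        present = rng.random(n) < 0.8
        if not present.any():
            present[rng.integers(n)] = True
        df[f"site_s{s + 1}"] = present
    return df


def sim_networks(plants: pd.DataFrame, frugivores: pd.DataFrame,
                 config: SimConfig, seed: int):
    """Seasonal visitation data with planted fruit-choice preferences.

    Expected log visitation rate of frugivore j on plant i is

        base + frugivore effect + gamma_g * generalism_j * b_i
             - gamma_m * migdist_j * b_i * [season in migration period]

    with b_i the standardized brightness latent, so generalists prefer
    bright fruits and migrants prefer dark fruits during the migration
    period.  Visit counts are Poisson(rate * effort); per-visit
    consumption is lognormal with a masked fraction to exercise the
    imputation ladder.  Returns (records, SimTruth).
    """
    rng = np.random.default_rng(seed)
    if config.n_sites < 1 or not config.seasons:
        raise ValueError("empty site/season grid")
    b = plants["brightness_latent"].to_numpy()
    g = frugivores["generalism"].to_numpy()
    md = frugivores["migratory_distance"].to_numpy()
    md_std = (md - md.mean()) / (md.std() or 1.0)

    n_p, n_f = len(plants), len(frugivores)
    # stable fruiting phenology: each plant fruits in two consecutive seasons
    start = rng.integers(0, len(config.seasons), size=n_p)
    fruiting = {
        p: {config.seasons[start[i] % len(config.seasons)],
            config.seasons[(start[i] + 1) % len(config.seasons)]}
        for i, p in enumerate(plants.index)
    }
    frug_eff = rng.normal(0, 0.3, size=n_f)
    base = np.log(0.05)

    records, expected = [], []
    for s in range(config.n_sites):
        site = f"s{s + 1}"
        present = frugivores[f"site_{site}"].to_numpy() \
            if f"site_{site}" in frugivores else np.ones(n_f, bool)
        for season in config.seasons:
            period = 1.0 if season in MIGRATION_SEASONS else 0.0
            avail = [i for i, p in enumerate(plants.index)
                     if season in fruiting[p]]
            if not avail:
                continue
            for j in range(n_f):
                if not present[j]:
                    continue
                for i in avail:
                    pref = (config.gamma_generalism * g[j] * b[i]
                            - config.gamma_migration * md_std[j] * b[i] * period)
                    lam = np.exp(base + frug_eff[j] + pref
                                 + rng.normal(0, 0.3))
                    count = rng.poisson(lam * config.effort_hours)
                    # lam is the realized Poisson intensity per hour, the
                    # quantity visit rates converge to as effort grows
                    expected.append((site, season, frugivores.index[j],
                                     plants.index[i], lam))
                    if count == 0:
                        continue
                    fpv = float(rng.lognormal(np.log(3.0), 0.3))
                    if rng.random() < config.fpv_missing_frac:
                        fpv_rec = None
                    else:
                        fpv_rec = fpv
                    records.append(VisitRecord(
                        site=site, season=season,
                        frugivore=str(frugivores.index[j]),
                        plant=str(plants.index[i]),
                        visits_per_hour=count / config.effort_hours,
                        fruits_per_visit=fpv_rec,
                    ))
    exp_df = pd.DataFrame(expected, columns=["site", "season", "frugivore",
                                             "plant", "rate"])
    # expected brightness profile per (network, frugivore) from exact rates
    prof = []
    bmap = dict(zip(plants.index, b))
    for (site, season, j), grp in exp_df.groupby(["site", "season",
                                                  "frugivore"]):
        w = grp["rate"].to_numpy()
        vals = np.array([bmap[p] for p in grp["plant"]])
        prof.append((site, season, j, float((vals * w).sum() / w.sum())))
    prof_df = pd.DataFrame(prof, columns=["site", "season", "frugivore",
                                          "expected_brightness"])
    truth = SimTruth(
        frugivores=frugivores,
        gamma_generalism=config.gamma_generalism,
        gamma_migration=config.gamma_migration,
        expected_rates=exp_df,
        expected_brightness_profile=prof_df,
    )
    return records, truth


# ---------------------------------------------------------------------------
# direct SEM-level generator


DEFAULT_SEM_PATHS = {
    ("partner_diversity", "diet_a"): 0.4,
    ("migratory_distance", "diet_a"): -0.3,
    ("diet_a", "lipid"): 0.4,
    ("diet_a", "sugar"): -0.4,
    ("diet_a", "anthocyanin"): -0.7,
}

DEFAULT_SEM_VARIANCES = {"phylo": 0.09, "species": 0.09, "site": 0.04,
                         "season": 0.04, "resid": 0.25}


def sim_sem_observations(seed: int, n_species: int = 43, n_sites: int = 3,
                         seasons: tuple = SEASONS,
                         paths: dict | None = None,
                         variances: dict | None = None,
                         presence_prob: float = 0.32):
    """Observation table for the fruit-choice SEM with planted paths.

    Generates one row per realized (species, site, season) combination —
    about 160 rows at the default dimensions — carrying partner diversity,
    interaction strength, seasonally coded migratory distance, a diet
    brightness responding to the planted frugivore-trait paths, null
    chromatic diet coordinates, and nutrient intakes responding to diet
    brightness.  Path coefficients are on the standardized scale the model
    reports.  Returns (table, bird tree, SimTruth).
    """
    rng = np.random.default_rng(seed)
    paths = dict(DEFAULT_SEM_PATHS if paths is None else paths)
    var = dict(DEFAULT_SEM_VARIANCES if variances is None else variances)

    tree = sim_tree(n_species, seed + 104729, prefix="b")
    species = tree.tip_labels
    C = correlation_from_tree(tree, species).matrix

    migdist = np.where(rng.random(n_species) < 0.5, 0.0,
                       rng.gamma(4.0, 4.0, size=n_species))
    rows = []
    for si in range(n_sites):
        for season in seasons:
            for k in range(n_species):
                if rng.random() < presence_prob:
                    rows.append((species[k], k, f"s{si + 1}", season))
    # guarantee a usable minimum
    while len(rows) < 3 * n_species:
        k = int(rng.integers(n_species))
        rows.append((species[k], k, f"s{int(rng.integers(n_sites)) + 1}",
                     seasons[int(rng.integers(len(seasons)))]))
    df = pd.DataFrame(rows, columns=["frugivore", "k", "site", "season"])
    n = len(df)

    def std(v):
        return (v - v.mean()) / v.std(ddof=0)

    # raw-scale covariates whose logs are well behaved
    pd_raw = np.exp(-1.5 + 0.5 * rng.normal(size=n))
    df["partner_diversity"] = np.minimum(pd_raw, 1.0)
    df["interaction_strength"] = np.exp(-2.5 + 0.8 * rng.normal(size=n))
    df["migratory_distance"] = migdist[df["k"]]

    coded = np.where(df["season"].isin(MIGRATION_SEASONS),
                     df["migratory_distance"], 0.0)
    z_pd = std(np.log(df["partner_diversity"].to_numpy()))
    z_is = std(np.log(df["interaction_strength"].to_numpy()))
    z_md = std(coded)

    def ranef(scale_key):
        a_k = np.linalg.cholesky(C + 1e-10 * np.eye(n_species)) @ \
            rng.normal(size=n_species) * np.sqrt(var["phylo"])
        v_k = rng.normal(0, np.sqrt(var["species"]), size=n_species)
        sites = sorted(df["site"].unique())
        s_l = dict(zip(sites, rng.normal(0, np.sqrt(var["site"]),
                                         size=len(sites))))
        t_m = dict(zip(seasons, rng.normal(0, np.sqrt(var["season"]),
                                           size=len(seasons))))
        k = df["k"].to_numpy()
        return (a_k[k] + v_k[k]
                + df["site"].map(s_l).to_numpy()
                + df["season"].map(t_m).to_numpy())

    def equation(response, predictors):
        eta = np.zeros(n)
        for name, zvec in predictors.items():
            eta += paths.get((name, response), 0.0) * zvec
        return eta + ranef(response) + rng.normal(0, np.sqrt(var["resid"]),
                                                  size=n)

    trait_z = {"partner_diversity": z_pd, "interaction_strength": z_is,
               "migratory_distance": z_md}
    ln_a = equation("diet_a", trait_z)
    df["diet_a"] = np.exp(-1.2 + 0.4 * std(ln_a))
    for comp in ("x", "y", "z"):
        df[f"diet_{comp}"] = equation(f"diet_{comp}", trait_z)

    z_a = std(np.log(df["diet_a"].to_numpy()))
    intake_z = dict(trait_z)
    intake_z.update({"diet_a": z_a, "diet_x": std(df["diet_x"].to_numpy()),
                     "diet_y": std(df["diet_y"].to_numpy()),
                     "diet_z": std(df["diet_z"].to_numpy())})
    base = {"lipid": -2.8, "sugar": -1.2, "protein": -2.9, "anthocyanin": 0.0}
    for nut in NUTRIENTS:
        df[f"intake_{nut}"] = np.exp(base[nut]
                                     + 0.5 * equation(nut, intake_z))

    df = df.drop(columns="k")
    truth = SimTruth(bird_tree=tree, sem_paths=paths, sem_variances=var)
    return df, tree, truth


# ---------------------------------------------------------------------------
# whole-study convenience


def simulate_study(config: SimConfig | None = None):
    """Generate a complete synthetic study: trees, plant and frugivore
    tables, visitation records, and the combined SimTruth."""
    cfg = config or SimConfig()
    plant_tree = sim_tree(cfg.n_plants, cfg.seed + 1, prefix="p")
    bird_tree = sim_tree(cfg.n_frugivores, cfg.seed + 2, prefix="b")
    plants, plant_truth = sim_plant_traits(plant_tree, cfg, cfg.seed + 3)
    frugs = sim_frugivores(cfg, cfg.seed + 4)
    records, truth = sim_networks(plant_truth["plant_traits"], frugs, cfg,
                                  cfg.seed + 5)
    truth.plant_tree = plant_tree
    truth.bird_tree = bird_tree
    truth.plant_traits = plant_truth["plant_traits"]
    truth.nutrient_slopes = plant_truth["nutrient_slopes"]
    truth.masked = plant_truth["masked"]
    return {
        "plant_tree": plant_tree, "bird_tree": bird_tree,
        "plants": plants, "frugivores": frugs, "records": records,
        "truth": truth,
    }
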