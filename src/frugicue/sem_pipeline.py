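"""Orchestration of the three-stage hierarchical analysis.

Stage 1 (allometric imputation): ln(pulp dry mass) ~ ln(fruit diameter)
with a phylogenetic random effect; posterior draws of missing pulp masses
feed the diet-profile weighting downstream.

Stage 2 (colour-reward model): each ln-nutrient content regressed on the
colour coordinates (x, y, z) and brightness (a) across plant species,
with indicator variable selection and a phylogenetic random effect;
missing nutrient values are augmented.

Stage 3 (fruit-choice SEM): eight equations — each colour-profile
component of consumed fruits on the frugivore traits (partner diversity,
interaction strength, seasonally coded migratory distance), and each
nutrient intake on those traits plus the colour profile — fitted with
phylogenetic, species, site and season random effects.  Brightness,
intakes, partner diversity and interaction strength enter on the natural
log scale; the chromatic coordinates (which may be negative) stay raw.

The concordance stage regresses the SEM's colour-path inclusion
indicators on each component's marginal selection probability from the
colour-reward model, asking whether the colour component that most
reliably signals rewards is also the one that mediates fruit choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bhm_engine as bhm
from .bhm_engine import FixedTerm, McmcConfig, ModelSpec
from .network_diets import MIGRATION_SEASONS
from .phylo import Phylogeny, correlation_from_tree

logger = logging.getLogger(__name__)

__all__ = [
    "SubmodelResult",
    "SemResult",
    "ConcordanceResult",
    "run_submodel1",
    "run_submodel2",
    "run_submodel3",
    "marginal_selection",
    "concordance",
    "run_pipeline",
]

COLOUR_COMPONENTS = ("x", "y", "z", "a")
NUTRIENTS = ("lipid", "sugar", "protein", "anthocyanin")
TRAIT_TERMS = ("partner_diversity", "interaction_strength",
               "migratory_distance")


@dataclass
class SubmodelResult:
    """Per-response fit summaries for one pipeline stage."""

    summaries: dict          # response -> shrinkage summary DataFrame
    variance: dict           # response -> r_squared dict
    posteriors: dict         # response -> Posterior
    augmented: dict = field(default_factory=dict)  # response -> {row: mean}

    def table(self) -> pd.DataFrame:
        frames = []
        for resp, df in self.summaries.items():
            d = df.copy()
            d.insert(0, "response", resp)
            d["r2_marginal"] = self.variance[resp]["r2_marginal"]
            d["r2_conditional"] = self.variance[resp]["r2_conditional"]
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


@dataclass
class SemResult:
    """Path table and indirect effects of the fruit-choice SEM."""

    submodel: SubmodelResult
    paths: pd.DataFrame          # predictor -> response with P, BF, supported
    indirect: pd.DataFrame       # mediated products along supported paths

    def marginal_colour_selection(self) -> dict:
        return marginal_selection(self, axis="sem")


@dataclass
class ConcordanceResult:
    components: tuple
    colour_reward_marginal: dict
    sem_marginal: dict
    intercept: float
    slope: float
    zvalue: float
    n_samples: int
    quasi_separation: bool = False


def _fit_kwargs(config):
    return config if config is not None else McmcConfig()


# ---------------------------------------------------------------------------
# sub-models


def run_submodel1(plants: pd.DataFrame, tree: Phylogeny,
                  config: McmcConfig | None = None) -> SubmodelResult:
    """Allometric pulp-mass model with phylogenetic augmentation.

    ``plants`` must carry ``diameter_mm`` (complete) and ``pulp_mass_g``
    (may contain NaN); the index is the species label and must be covered
    by the tree.
    """
    if plants["diameter_mm"].isna().any():
        raise ValueError("fruit diameters must be present for all plants")
    if plants["pulp_mass_g"].notna().sum() == 0:
        raise ValueError("no species with observed pulp mass")
    corr = correlation_from_tree(tree, list(plants.index))
    data = plants.reset_index()
    spec = ModelSpec(
        response="pulp_mass_g", log_response=True,
        fixed=[FixedTerm("diameter_mm", selectable=False, log=True)],
        phylo=corr, species_col="species",
    )
    post = bhm.fit(spec, data, _fit_kwargs(config))
    missing = data.loc[post.missing_rows, "species"].tolist()
    aug = dict(zip(missing, post.augmented_means())) if missing else {}
    return SubmodelResult(
        summaries={"pulp_mass_g": bhm.shrinkage_summary(post)},
        variance={"pulp_mass_g": bhm.r_squared(post)},
        posteriors={"pulp_mass_g": post},
        augmented={"pulp_mass_g": aug},
    )


def run_submodel2(plants: pd.DataFrame, tree: Phylogeny,
                  config: McmcConfig | None = None,
                  nutrients: tuple = NUTRIENTS) -> SubmodelResult:
    """Colour-reward model: selection-enabled regressions of each
    ln-nutrient on (x, y, z, a) with a phylogenetic random effect."""
    corr = correlation_from_tree(tree, list(plants.index))
    data = plants.reset_index()
    summaries, variance, posteriors, augmented = {}, {}, {}, {}
    cfg = _fit_kwargs(config)
    for i, nut in enumerate(nutrients):
        if nut not in plants.columns or plants[nut].notna().sum() == 0:
            raise ValueError(f"nutrient {nut!r} entirely missing")
        spec = ModelSpec(
            response=nut, log_response=True,
            fixed=[FixedTerm(c) for c in COLOUR_COMPONENTS],
            phylo=corr, species_col="species",
        )
        sub_cfg = McmcConfig(chains=cfg.chains, iterations=cfg.iterations,
                             burn_in=cfg.burn_in, thin=cfg.thin,
                             seed=cfg.seed + 1000 * (i + 1))
        post = bhm.fit(spec, data, sub_cfg)
        summaries[nut] = bhm.shrinkage_summary(post)
        variance[nut] = bhm.r_squared(post)
        posteriors[nut] = post
        miss = data.loc[post.missing_rows, "species"].tolist()
        augmented[nut] = dict(zip(miss, post.augmented_means())) if miss else {}
    return SubmodelResult(summaries=summaries, variance=variance,
                          posteriors=posteriors, augmented=augmented)


def _sem_specs(mode: str, corr) -> dict:
    trait_terms = {
        "main": [FixedTerm("md_coded")],
        "alt1": [FixedTerm("migratory_distance")],
        "alt2": [FixedTerm("migratory_distance"), FixedTerm("period"),
                 FixedTerm("migdist_x_period")],
    }
    if mode not in trait_terms:
        raise ValueError(f"unknown SEM mode {mode!r}")
    base = [FixedTerm("ln_partner_diversity"),
            FixedTerm("ln_interaction_strength")] + trait_terms[mode]
    colour_preds = [FixedTerm("diet_x"), FixedTerm("diet_y"),
                    FixedTerm("diet_z"), FixedTerm("ln_diet_a")]
    specs = {}
    for comp in ("x", "y", "z"):
        specs[f"diet_{comp}"] = ModelSpec(
            response=f"diet_{comp}", fixed=list(base), phylo=corr,
            species_col="frugivore", species_iid=True,
            site_col="site", season_col="season")
    specs["diet_a"] = ModelSpec(
        response="ln_diet_a", fixed=list(base), phylo=corr,
        species_col="frugivore", species_iid=True,
        site_col="site", season_col="season")
    for nut in NUTRIENTS:
        specs[f"intake_{nut}"] = ModelSpec(
            response=f"intake_{nut}", log_response=True,
            fixed=list(base) + colour_preds, phylo=corr,
            species_col="frugivore", species_iid=True,
            site_col="site", season_col="season")
    return specs


_TERM_ALIASES = {
    "ln_partner_diversity": "partner_diversity",
    "ln_interaction_strength": "interaction_strength",
    "md_coded": "migratory_distance",
    "ln_diet_a": "diet_a",
}


def run_submodel3(observations: pd.DataFrame, bird_tree: Phylogeny,
                  mode: str = "main",
                  config: McmcConfig | None = None) -> SemResult:
    """Fruit-choice SEM over one row per (frugivore, site, season).

    ``observations`` must carry partner_diversity, interaction_strength,
    migratory_distance, season, site, frugivore, diet_{x,y,z,a} and
    intake_{lipid,sugar,protein,anthocyanin}.  mode selects the migratory
    coding: main (zeroed outside the migration period), alt1 (raw), alt2
    (distance + period + interaction).

    The eight equations are run in one deterministic pass with per-equation
    seeds derived from the master seed; with fully observed data they are
    conditionally independent, so this matches equation-wise fitting.
    """
    required = ["frugivore", "site", "season", "diet_a"] + list(TRAIT_TERMS)
    missing_cols = [c for c in required if c not in observations.columns]
    if missing_cols:
        raise ValueError(f"missing role metrics/columns: {missing_cols}")
    df = observations.copy()
    if df[list(TRAIT_TERMS)].isna().any().any():
        raise ValueError("missing role metric values")
    df["ln_partner_diversity"] = np.log(df["partner_diversity"])
    df["ln_interaction_strength"] = np.log(df["interaction_strength"])
    df["ln_diet_a"] = np.log(df["diet_a"])
    df["period"] = df["season"].isin(MIGRATION_SEASONS).astype(float)
    df["md_coded"] = df["migratory_distance"] * df["period"]
    df["migdist_x_period"] = df["md_coded"]

    species = sorted(df["frugivore"].astype(str).unique())
    corr = correlation_from_tree(bird_tree, species)
    specs = _sem_specs(mode, corr)
    cfg = _fit_kwargs(config)

    summaries, variance, posteriors = {}, {}, {}
    for i, (resp, spec) in enumerate(specs.items()):
        sub_cfg = McmcConfig(chains=cfg.chains, iterations=cfg.iterations,
                             burn_in=cfg.burn_in, thin=cfg.thin,
                             seed=cfg.seed + 1000 * (i + 1))
        post = bhm.fit(spec, df, sub_cfg)
        summ = bhm.shrinkage_summary(post)
        summ["term"] = summ["term"].map(lambda t: _TERM_ALIASES.get(t, t))
        summaries[resp] = summ
        variance[resp] = bhm.r_squared(post)
        posteriors[resp] = post
    sub = SubmodelResult(summaries=summaries, variance=variance,
                         posteriors=posteriors)

    paths = sub.table().rename(columns={"term": "predictor"})
    indirect = _indirect_effects(sub, paths)
    return SemResult(submodel=sub, paths=paths, indirect=indirect)


def _indirect_effects(sub: SubmodelResult, paths: pd.DataFrame) -> pd.DataFrame:
    """Products of posterior draws along supported trait -> colour ->
    intake chains (full distributions, summarized by mean and 95% CI)."""
    rows = []
    supported = paths[paths["supported"]]
    colour_resp = {f"diet_{c}" for c in COLOUR_COMPONENTS}
    for _, first in supported.iterrows():
        if first["response"] not in colour_resp:
            continue
        mediator = first["response"]
        med_term = _TERM_ALIASES.get(mediator, mediator)
        for _, second in supported.iterrows():
            if not str(second["response"]).startswith("intake_"):
                continue
            if second["predictor"] != med_term:
                continue
            p1 = sub.posteriors[mediator]
            p2 = sub.posteriors[second["response"]]
            t1 = [_TERM_ALIASES.get(t, t) for t in p1.terms]
            t2 = [_TERM_ALIASES.get(t, t) for t in p2.terms]
            d1 = p1.theta[:, t1.index(first["predictor"])]
            d2 = p2.theta[:, t2.index(med_term)]
            prod = d1 * d2
            lo, hi = np.percentile(prod, [2.5, 97.5])
            rows.append({
                "source": first["predictor"], "mediator": mediator,
                "target": second["response"],
                "estimate": float(prod.mean()),
                "ci_low": float(lo), "ci_high": float(hi),
            })
    return pd.DataFrame(rows, columns=["source", "mediator", "target",
                                       "estimate", "ci_low", "ci_high"])


def diet_intake_draws(net, nutrients: pd.DataFrame, plants: pd.DataFrame,
                      submodel1: SubmodelResult, frugivore: str,
                      max_draws: int = 50) -> pd.DataFrame:
    """Nutrient intake profiles iterated over pulp-mass posterior draws.

    Observed pulp masses are taken from ``plants``; masses of augmented
    species vary draw by draw, so the returned frame (one row per draw)
    carries the full imputation uncertainty into the intake profile.
    The default propagation elsewhere uses posterior means; this is the
    draw-wise alternative.
    """
    from .network_diets import diet_nutrient_intake

    post = submodel1.posteriors["pulp_mass_g"]
    missing = list(submodel1.augmented["pulp_mass_g"])
    draws = post.augmented_draws()
    step = max(1, draws.shape[0] // max_draws)
    observed = plants["pulp_mass_g"].dropna().to_dict()
    rows = []
    for d in range(0, draws.shape[0], step):
        pulp = dict(observed)
        pulp.update(zip(missing, draws[d]))
        rows.append(diet_nutrient_intake(net, nutrients, pulp, frugivore))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marginal selection and concordance


def marginal_selection(result, axis: str = "colour_reward") -> dict:
    """Mean selection probability of each colour component.

    axis="colour_reward": mean P of the component across the nutrient
    responses of the colour-reward model.  axis="sem": mean P of the
    frugivore-trait predictors within the component's colour-profile
    equation of the SEM.  ``result`` may be a SubmodelResult/SemResult or
    a summary table with response/term(P) columns.
    """
    if isinstance(result, SemResult):
        table = result.submodel.table().rename(columns={"term": "predictor"})
        tcol = "predictor"
    elif isinstance(result, SubmodelResult):
        table = result.table()
        tcol = "term"
    else:
        table = result.copy()
        tcol = "term" if "term" in table.columns else "predictor"
    out = {}
    for comp in COLOUR_COMPONENTS:
        if axis == "colour_reward":
            rows = table[(table[tcol] == comp)
                         & table["response"].isin(NUTRIENTS)]
        elif axis == "sem":
            resp = {comp, f"diet_{comp}"}
            rows = table[table["response"].isin(resp)
                         & table[tcol].isin(TRAIT_TERMS)]
        else:
            raise ValueError(f"unknown axis {axis!r}")
        if rows.empty:
            raise KeyError(f"colour component {comp!r} absent from summary")
        out[comp] = float(rows["P"].mean())
    return out


def concordance(m2: dict, m3, n_draws: int = 2000) -> ConcordanceResult:
    """Logistic regression of SEM colour-path inclusion on colour-reward
    marginal selection probability.

    ``m2`` maps colour component -> marginal selection probability from
    the colour-reward model.  ``m3`` is either the matching SEM marginal
    probabilities (converted to pooled indicator counts using ``n_draws``
    retained draws per path, three trait paths per component) or a mapping
    component -> 0/1 indicator draw array.
    """
    import statsmodels.api as sm

    comps = tuple(sorted(m2, key=list(COLOUR_COMPONENTS).index))
    xv, succ, tot = [], [], []
    m3_prob = {}
    for c in comps:
        v = m3[c]
        if np.ndim(v) > 0:
            arr = np.asarray(v, float)
            s, t = arr.sum(), arr.size
        else:
            t = n_draws * len(TRAIT_TERMS)
            s = round(float(v) * t)
        m3_prob[c] = s / t
        xv.append(m2[c])
        succ.append(s)
        tot.append(t)
    if len(set(np.round(xv, 12))) < 2:
        raise ValueError("concordance requires >= 2 distinct probabilities")
    xv = np.asarray(xv, float)
    succ = np.asarray(succ, float)
    tot = np.asarray(tot, float)
    quasi = bool(np.any(succ == 0) or np.any(succ == tot))
    succ_adj = np.clip(succ, 0.5, tot - 0.5)  # continuity guard
    X = sm.add_constant(xv)
    res = sm.GLM(np.column_stack([succ_adj, tot - succ_adj]), X,
                 family=sm.families.Binomial()).fit()
    if quasi:
        logger.warning("concordance fit is quasi-separated; coefficients "
                       "reflect the continuity-corrected counts")
    return ConcordanceResult(
        components=comps, colour_reward_marginal=dict(zip(comps, xv)),
        sem_marginal=m3_prob,
        intercept=float(res.params[0]), slope=float(res.params[1]),
        zvalue=float(res.tvalues[1]), n_samples=int(tot.sum()),
        quasi_separation=quasi,
    )


# ---------------------------------------------------------------------------
# end-to-end run


def run_pipeline(plants: pd.DataFrame, plant_tree: Phylogeny,
                 observations: pd.DataFrame, bird_tree: Phylogeny,
                 mode: str = "main", config: McmcConfig | None = None,
                 out_dir=None) -> dict:
    """Run stages 1-3 and the concordance analysis on prepared tables.

    Returns a dict with the three stage results, the concordance result
    and, when ``out_dir`` is given, writes per-stage CSV summaries plus a
    JSON run manifest.
    """
    cfg = _fit_kwargs(config)
    m1 = run_submodel1(plants, plant_tree,
                       McmcConfig(chains=cfg.chains, iterations=cfg.iterations,
                                  burn_in=cfg.burn_in, thin=cfg.thin,
                                  seed=cfg.seed + 11))
    m2 = run_submodel2(plants, plant_tree,
                       McmcConfig(chains=cfg.chains, iterations=cfg.iterations,
                                  burn_in=cfg.burn_in, thin=cfg.thin,
                                  seed=cfg.seed + 22))
    m3 = run_submodel3(observations, bird_tree, mode=mode,
                       config=McmcConfig(chains=cfg.chains,
                                         iterations=cfg.iterations,
                                         burn_in=cfg.burn_in, thin=cfg.thin,
                                         seed=cfg.seed + 33))
    marg2 = marginal_selection(m2, axis="colour_reward")
    draws = {}
    for comp in COLOUR_COMPONENTS:
        resp = "diet_a" if comp == "a" else f"diet_{comp}"
        post = m3.submodel.posteriors[resp]
        terms = [_TERM_ALIASES.get(t, t) for t in post.terms]
        cols = [terms.index(t) for t in TRAIT_TERMS if t in terms]
        draws[comp] = post.indicator[:, cols].ravel()
    conc = concordance(marg2, draws)

    result = {"submodel1": m1, "submodel2": m2, "submodel3": m3,
              "concordance": conc}
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        m1.table().to_csv(out / "submodel1_summary.csv", index=False,
                          float_format="%.6g")
        m2.table().to_csv(out / "submodel2_summary.csv", index=False,
                          float_format="%.6g")
        m3.paths.to_csv(out / "submodel3_paths.csv", index=False,
                        float_format="%.6g")
        m3.indirect.to_csv(out / "submodel3_indirect.csv", index=False,
                           float_format="%.6g")
        manifest = {
            "seed": cfg.seed, "chains": cfg.chains,
            "iterations": cfg.iterations, "burn_in": cfg.burn_in,
            "thin": cfg.thin, "mode": mode,
            "concordance": {"intercept": conc.intercept, "slope": conc.slope,
                            "n_samples": conc.n_samples},
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
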