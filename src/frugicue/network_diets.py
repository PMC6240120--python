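"""Seasonal plant-frugivore networks and interaction-weighted diet profiles.

A seasonal network holds the fruit consumption rate f_ij (fruits per hour)
of every frugivore j on every plant i observed at one site in one season.
Consumption rates are visitation rates (visits/h) multiplied by per-visit
consumption (fruits/visit); missing per-visit rates are filled by an
imputation ladder (same pair elsewhere -> frugivore mean -> global mean).

From a network the module derives the frugivore role metrics and the
interaction-weighted diet profiles:

* partner diversity: exp(Shannon entropy of a frugivore's interaction
  frequencies) standardized by the number of plants in the network
  (relative niche breadth, in (0, 1]);
* interaction strength: the frugivore's share of total fruit removal;
* mean colour profile of consumed fruits,
  c-bar_j = sum_i c_i f_ij / sum_i f_ij;
* mean nutrient intake per gram dry pulp,
  n-bar_j = sum_i n_i m_i f_ij / sum_i m_i f_ij.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colour_space import TetraColour

logger = logging.getLogger(__name__)

SEASONS = ("spring", "summer", "autumn", "winter")
#: seasons in which migratory distance is active (pre-migration/migration)
MIGRATION_SEASONS = ("summer", "autumn")

__all__ = [
    "SEASONS",
    "MIGRATION_SEASONS",
    "VisitRecord",
    "SeasonalNetwork",
    "FrugivoreRole",
    "DietProfile",
    "build_networks",
    "partner_diversity",
    "interaction_strength",
    "diet_colour_profile",
    "diet_nutrient_intake",
    "migratory_covariate",
    "role_table",
    "read_interactions_csv",
]


@dataclass(frozen=True)
class VisitRecord:
    site: str
    season: str
    frugivore: str
    plant: str
    visits_per_hour: float
    fruits_per_visit: float | None = None

    def __post_init__(self):
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}")
        if not np.isfinite(self.visits_per_hour) or self.visits_per_hour < 0:
            raise ValueError("visitation rate must be finite and >= 0")
        fpv = self.fruits_per_visit
        if fpv is not None and (not np.isfinite(fpv) or fpv < 0):
            raise ValueError("fruits per visit must be finite and >= 0")


@dataclass
class SeasonalNetwork:
    """Consumption matrix f_ij for one (site, season)."""

    site: str
    season: str
    matrix: pd.DataFrame          # rows: plants, columns: frugivores
    provenance: pd.DataFrame      # same shape; imputation flags per cell

    def __post_init__(self):
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise ValueError("network must have at least one plant and frugivore")
        if self.matrix.index.duplicated().any() or self.matrix.columns.duplicated().any():
            raise ValueError("duplicate plant or frugivore labels")
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("consumption rates must be >= 0")

    @property
    def plants(self):
        return list(self.matrix.index)

    @property
    def frugivores(self):
        return list(self.matrix.columns)


@dataclass(frozen=True)
class FrugivoreRole:
    frugivore: str
    site: str
    season: str
    partner_diversity: float
    interaction_strength: float
    migratory_distance: float = 0.0


@dataclass(frozen=True)
class DietProfile:
    frugivore: str
    colour: dict = field(default_factory=dict)    # x, y, z, a weighted means
    nutrients: dict = field(default_factory=dict)  # nutrient -> weighted intake


# ---------------------------------------------------------------------------
# network construction


def _records_frame(visits) -> pd.DataFrame:
    rows = [
        (v.site, v.season, v.frugivore, v.plant, v.visits_per_hour,
         np.nan if v.fruits_per_visit is None else v.fruits_per_visit)
        for v in visits
    ]
    return pd.DataFrame(
        rows, columns=["site", "season", "frugivore", "plant",
                       "visits_per_hour", "fruits_per_visit"],
    )


def build_networks(visits, mode: str = "consumption") -> list[SeasonalNetwork]:
    """Assemble one SeasonalNetwork per observed (site, season).

    mode="consumption" multiplies visitation by per-visit consumption,
    imputing missing per-visit rates by the ladder: (1) same pair at
    another site, (2) the frugivore's mean over other plants, (3) the
    global mean over frugivores.  mode="visitation" uses visitation rates
    unchanged.
    """
    if mode not in ("consumption", "visitation"):
        raise ValueError(f"unknown mode {mode!r}")
    df = _records_frame(visits)
    if df.empty:
        raise ValueError("no visit records")

    if mode == "consumption":
        pair_mean = df.groupby(["frugivore", "plant"])["fruits_per_visit"].mean()
        frug_mean = df.groupby("frugivore")["fruits_per_visit"].mean()
        global_mean = df["fruits_per_visit"].mean()
        if np.isnan(global_mean):
            raise ValueError(
                "all per-visit consumption rates missing; the imputation "
                "ladder is exhausted (use mode='visitation')"
            )

        def fill(row):
            if not np.isnan(row.fruits_per_visit):
                return row.fruits_per_visit, "observed"
            pm = pair_mean.get((row.frugivore, row.plant), np.nan)
            if not np.isnan(pm):
                return pm, "imputed-pair"
            fm = frug_mean.get(row.frugivore, np.nan)
            if not np.isnan(fm):
                return fm, "imputed-frugivore-mean"
            return global_mean, "imputed-global-mean"

        filled = df.apply(lambda r: fill(r), axis=1, result_type="expand")
        df["fpv_filled"], df["provenance"] = filled[0], filled[1]
        df["f"] = df["visits_per_hour"] * df["fpv_filled"]
    else:
        df["f"] = df["visits_per_hour"]
        df["provenance"] = "observed"

    out = []
    for (site, season), grp in df.groupby(["site", "season"], sort=True):
        mat = grp.pivot_table(index="plant", columns="frugivore", values="f",
                              aggfunc="sum", fill_value=0.0)
        prov = grp.pivot_table(index="plant", columns="frugivore",
                               values="provenance", aggfunc="first")
        prov = prov.reindex(index=mat.index, columns=mat.columns).fillna("absent")
        out.append(SeasonalNetwork(site=str(site), season=str(season),
                                   matrix=mat, provenance=prov))
    return out


# ---------------------------------------------------------------------------
# role metrics


def _column(net: SeasonalNetwork, frugivore: str) -> np.ndarray:
    if frugivore not in net.matrix.columns:
        raise KeyError(f"frugivore {frugivore!r} absent from network "
                       f"({net.site}, {net.season})")
    return net.matrix[frugivore].to_numpy(float)


def partner_diversity(net: SeasonalNetwork, frugivore: str) -> float:
    """exp(Shannon H) of the diet distribution over plants, divided by the
    number of plants available in the network (natural log)."""
    f = _column(net, frugivore)
    tot = f.sum()
    if tot <= 0:
        raise ValueError(f"frugivore {frugivore!r} has zero consumption in "
                         f"network ({net.site}, {net.season})")
    p = f[f > 0] / tot
    H = float(-np.sum(p * np.log(p)))
    return float(np.exp(H) / net.matrix.shape[0])


def interaction_strength(net: SeasonalNetwork, frugivore: str) -> float:
    """Share of the network-wide fruit removal attributable to the frugivore."""
    total = net.matrix.to_numpy().sum()
    if total <= 0:
        raise ValueError("empty network: total consumption is zero")
    return float(_column(net, frugivore).sum() / total)


def diet_colour_profile(net: SeasonalNetwork, colours: dict,
                        frugivore: str) -> dict:
    """Interaction-weighted mean colour of consumed fruits (x, y, z, a)."""
    f = _column(net, frugivore)
    used = [p for p, w in zip(net.plants, f) if w > 0]
    if not used:
        raise ValueError(f"frugivore {frugivore!r} consumed nothing")
    missing = [p for p in used if p not in colours]
    if missing:
        raise KeyError(f"plants lacking colour coordinates: {missing}")
    w = np.array([fi for fi in f if fi > 0])
    out = {}
    for comp in ("x", "y", "z", "a"):
        vals = np.array([getattr(colours[p], comp)
                         if isinstance(colours[p], TetraColour)
                         else colours[p][comp] for p in used])
        out[comp] = float(np.sum(vals * w) / w.sum())
    return out


def diet_nutrient_intake(net: SeasonalNetwork, nutrients: pd.DataFrame,
                         pulp_mass: dict, frugivore: str) -> dict:
    """Pulp-mass- and interaction-weighted mean nutrient intake.

    ``nutrients`` is a plant-indexed frame (one column per nutrient, units
    per gram dry pulp); ``pulp_mass`` maps plant -> dry pulp mass per fruit
    (g), possibly a posterior draw from the allometric imputation model.
    """
    f = _column(net, frugivore)
    used = [(p, fi) for p, fi in zip(net.plants, f) if fi > 0]
    if not used:
        raise ValueError(f"frugivore {frugivore!r} consumed nothing")
    missing = [p for p, _ in used if p not in pulp_mass
               or not np.isfinite(pulp_mass[p])]
    if missing:
        raise KeyError(f"plants lacking pulp mass (no augmentation source): "
                       f"{missing}")
    out = {}
    for nut in nutrients.columns:
        num = den = 0.0
        for p, fi in used:
            n_i = nutrients.loc[p, nut]
            if not np.isfinite(n_i):
                raise KeyError(f"plant {p!r} lacking nutrient {nut!r}")
            m_i = pulp_mass[p]
            num += n_i * m_i * fi
            den += m_i * fi
        out[nut] = float(num / den)
    return out


def migratory_covariate(distance: float, season: str,
                        mode: str = "zeroed"):
    """Seasonal coding of migratory distance.

    zeroed: distance during summer/autumn (pre-migration and migration),
    0 during winter/spring.  raw: distance always.  period_interaction:
    (distance, period indicator, product).
    """
    if distance < 0:
        raise ValueError("migratory distance must be >= 0")
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")
    period = 1.0 if season in MIGRATION_SEASONS else 0.0
    if mode == "zeroed":
        return distance * period
    if mode == "raw":
        return distance
    if mode == "period_interaction":
        return (distance, period, distance * period)
    raise ValueError(f"unknown migratory coding mode {mode!r}")


# ---------------------------------------------------------------------------
# tidy outputs


def role_table(networks, frugivore_traits: pd.DataFrame | None = None,
               colours: dict | None = None,
               nutrients: pd.DataFrame | None = None,
               pulp_mass: dict | None = None,
               migratory_coding: str = "zeroed") -> pd.DataFrame:
    """One row per (network, frugivore) with roles and diet profiles.

    Frugivores with zero consumption in a network are dropped with a
    logged warning.  ``frugivore_traits`` provides a ``migratory_distance``
    column indexed by species.
    """
    rows = []
    for net in networks:
        totals = net.matrix.sum(axis=0)
        for j in net.frugivores:
            if totals[j] <= 0:
                logger.warning("dropping zero-consumption frugivore %s from "
                               "network (%s, %s)", j, net.site, net.season)
                continue
            rec = {
                "site": net.site, "season": net.season, "frugivore": j,
                "partner_diversity": partner_diversity(net, j),
                "interaction_strength": interaction_strength(net, j),
            }
            if frugivore_traits is not None and j in frugivore_traits.index:
                dist = float(frugivore_traits.loc[j, "migratory_distance"])
                cov = migratory_covariate(dist, net.season, migratory_coding)
                if migratory_coding == "period_interaction":
                    rec["migratory_distance"], rec["period"], \
                        rec["migdist_x_period"] = cov
                else:
                    rec["migratory_distance"] = cov
            if colours is not None:
                prof = diet_colour_profile(net, colours, j)
                rec.update({f"diet_{k}": v for k, v in prof.items()})
            if nutrients is not None and pulp_mass is not None:
                intake = diet_nutrient_intake(net, nutrients, pulp_mass, j)
                rec.update({f"intake_{k}": v for k, v in intake.items()})
            rows.append(rec)
    return pd.DataFrame(rows)


def read_interactions_csv(path) -> list[VisitRecord]:
    """Read visit records from CSV with columns site, season, frugivore,
    plant, visits_per_hour and optional fruits_per_visit."""
    df = pd.read_csv(path)
    has_fpv = "fruits_per_visit" in df.columns
    out = []
    for row in df.itertuples(index=False):
        fpv = getattr(row, "fruits_per_visit", None) if has_fpv else None
        if fpv is not None and np.isnan(fpv):
            fpv = None
        out.append(VisitRecord(
            site=str(row.site), season=str(row.season),
            frugivore=str(row.frugivore), plant=str(row.plant),
            visits_per_hour=float(row.visits_per_hour), fruits_per_visit=fpv,
        ))
    return out
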