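"""Published selection summaries from the Central European field study.

These are the printed posterior summaries of the two community-wide
analyses that this package re-implements, recorded from the original
field-data study of three European plant-frugivore networks (44 plant and
43 bird species): the colour-reward model (nutrient content of fruit pulp
regressed on the avian colour coordinates across plant species) and the
fruit-choice structural equation model (colour profiles and nutrient
intakes of frugivores regressed on their network roles and migratory
behaviour).

They serve as data inputs: cross-checking the Bayes-factor arithmetic
against printed (P, BF) pairs, computing marginal selection probabilities,
and reproducing the selection-probability concordance analysis.  They are
not fitted values produced by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "colour_reward_table",
    "fruit_choice_table",
    "COLOUR_COMPONENTS",
    "FRUGIVORE_TRAIT_TERMS",
]

COLOUR_COMPONENTS = ("x", "y", "z", "a")
FRUGIVORE_TRAIT_TERMS = ("partner_diversity", "interaction_strength",
                         "migratory_distance")

# response, term, estimate, ci_low, ci_high, P, BF, bf_bound
_COLOUR_REWARD = [
    ("lipid", "x", 0.02, -0.2, 0.3, 0.31, -1.6, ""),
    ("lipid", "y", 0.01, -0.1, 0.2, 0.29, -1.8, ""),
    ("lipid", "z", 0.004, -0.2, 0.2, 0.27, -2.0, ""),
    ("lipid", "a", 0.4, 0.0, 0.7, 0.95, 6.0, ""),
    ("sugar", "x", -0.009, -0.3, 0.2, 0.33, -1.4, ""),
    ("sugar", "y", 0.0, -0.2, 0.2, 0.29, -1.8, ""),
    ("sugar", "z", 0.0, -0.3, 0.3, 0.31, -1.6, ""),
    ("sugar", "a", -0.3, -0.7, 0.0, 0.77, 2.5, ""),
    ("protein", "x", 0.0, -0.3, 0.3, 0.34, -1.4, ""),
    ("protein", "y", 0.04, -0.1, 0.4, 0.37, -1.1, ""),
    ("protein", "z", 0.03, -0.2, 0.4, 0.36, -1.2, ""),
    ("protein", "a", 0.0, -0.3, 0.3, 0.32, -1.5, ""),
    ("anthocyanin", "x", -0.05, -0.5, 0.3, 0.44, -0.44, ""),
    ("anthocyanin", "y", 0.2, -0.01, 0.6, 0.68, 1.5, ""),
    ("anthocyanin", "z", 0.2, -0.07, 0.6, 0.57, 0.60, ""),
    ("anthocyanin", "a", -0.5, -0.9, 0.0, 0.97, 6.8, ""),
]

_COLOUR_REWARD_R2 = {
    "lipid": (0.23, 0.51), "sugar": (0.11, 0.23),
    "protein": (0.029, 0.16), "anthocyanin": (0.35, 0.42),
}

_FRUIT_CHOICE = [
    ("x", "partner_diversity", -0.01, -0.2, 0.04, 0.20, -2.7, ""),
    ("x", "interaction_strength", 0.007, -0.07, 0.2, 0.20, -2.8, ""),
    ("x", "migratory_distance", 0.02, -0.05, 0.2, 0.25, -2.2, ""),
    ("y", "partner_diversity", -0.1, -0.3, 0.0, 0.61, 0.87, ""),
    ("y", "interaction_strength", 0.008, -0.1, 0.2, 0.22, -2.5, ""),
    ("y", "migratory_distance", 0.09, -0.01, 0.3, 0.50, 0.0080, ""),
    ("z", "partner_diversity", 0.001, -0.09, 0.1, 0.19, -2.9, ""),
    ("z", "interaction_strength", -0.01, -0.2, 0.07, 0.23, -2.5, ""),
    ("z", "migratory_distance", -0.1, -0.4, 0.0, 0.70, 1.7, ""),
    ("a", "partner_diversity", 0.4, 0.2, 0.5, 1.0, 15.0, ">"),
    ("a", "interaction_strength", -0.009, -0.2, 0.07, 0.22, -2.5, ""),
    ("a", "migratory_distance", -0.3, -0.5, 0.0, 0.97, 7.1, ""),
    ("lipid", "partner_diversity", 0.04, -0.02, 0.2, 0.35, -1.3, ""),
    ("lipid", "interaction_strength", 0.1, 0.0, 0.3, 0.60, 0.80, ""),
    ("lipid", "migratory_distance", -0.003, -0.1, 0.1, 0.19, -2.8, ""),
    ("lipid", "x", 0.0, -0.1, 0.1, 0.19, -2.9, ""),
    ("lipid", "y", 0.3, 0.08, 0.4, 0.98, 7.9, ""),
    ("lipid", "z", -0.02, -0.2, 0.03, 0.22, -2.5, ""),
    ("lipid", "a", 0.4, 0.3, 0.6, 1.0, 15.0, ">"),
    ("sugar", "partner_diversity", 0.05, -0.02, 0.3, 0.37, -1.0, ""),
    ("sugar", "interaction_strength", -0.03, -0.3, 0.05, 0.30, -1.7, ""),
    ("sugar", "migratory_distance", -0.002, -0.1, 0.1, 0.22, -2.5, ""),
    ("sugar", "x", -0.1, -0.6, 0.02, 0.50, -0.036, ""),
    ("sugar", "y", -0.08, -0.4, 0.01, 0.46, -0.34, ""),
    ("sugar", "z", -0.07, -0.5, 0.1, 0.38, -0.99, ""),
    ("sugar", "a", -0.4, -0.6, -0.2, 1.0, 14.0, ""),
    ("protein", "partner_diversity", -0.03, -0.3, 0.03, 0.33, -1.5, ""),
    ("protein", "interaction_strength", 0.0, -0.1, 0.1, 0.19, -2.9, ""),
    ("protein", "migratory_distance", -0.002, -0.1, 0.09, 0.19, -2.9, ""),
    ("protein", "x", 0.1, 0.0, 0.5, 0.53, 0.25, ""),
    ("protein", "y", 0.3, 0.1, 0.5, 0.99, 8.6, ""),
    ("protein", "z", 0.05, -0.1, 0.4, 0.36, -1.1, ""),
    ("protein", "a", 0.02, -0.04, 0.2, 0.28, -1.9, ""),
    ("anthocyanin", "partner_diversity", 0.08, 0.0, 0.2, 0.72, 1.9, ""),
    ("anthocyanin", "interaction_strength", 0.01, -0.02, 0.1, 0.23, -2.5, ""),
    ("anthocyanin", "migratory_distance", 0.004, -0.009, 0.07, 0.13, -3.7, ""),
    ("anthocyanin", "x", 0.4, 0.1, 0.6, 0.99, 8.6, ""),
    ("anthocyanin", "y", 0.3, 0.2, 0.5, 1.0, 15.0, ">"),
    ("anthocyanin", "z", 0.6, 0.3, 0.8, 1.0, 15.0, ">"),
    ("anthocyanin", "a", -0.7, -0.9, -0.6, 1.0, 15.0, ">"),
]

_FRUIT_CHOICE_R2 = {
    "x": (0.0025, 0.75), "y": (0.015, 0.78), "z": (0.022, 0.60),
    "a": (0.17, 0.65), "lipid": (0.14, 0.78), "sugar": (0.091, 0.63),
    "protein": (0.041, 0.79), "anthocyanin": (0.48, 0.86),
}

_COLS = ["response", "term", "estimate", "ci_low", "ci_high", "P", "BF",
         "BF_bound"]


def colour_reward_table() -> pd.DataFrame:
    """Published colour-reward selection summary (44 plant species)."""
    df = pd.DataFrame(_COLOUR_REWARD, columns=_COLS)
    df["r2_marginal"] = df["response"].map(lambda r: _COLOUR_REWARD_R2[r][0])
    df["r2_conditional"] = df["response"].map(lambda r: _COLOUR_REWARD_R2[r][1])
    return df


def fruit_choice_table() -> pd.DataFrame:
    """Published fruit-choice SEM selection summary (165 observations,
    43 bird species, 3 sites, 4 seasons)."""
    df = pd.DataFrame(_FRUIT_CHOICE, columns=_COLS)
    df["r2_marginal"] = df["response"].map(lambda r: _FRUIT_CHOICE_R2[r][0])
    df["r2_conditional"] = df["response"].map(lambda r: _FRUIT_CHOICE_R2[r][1])
    return df
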