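"""Three-stage pipeline orchestration, marginal selection and concordance."""

import numpy as np
import pandas as pd
import pytest

from frugicue import bhm_engine as bhm
from frugicue import reference_tables as ref
from frugicue import sem_pipeline as sem
from frugicue import synthetic_data as sd
from frugicue.bhm_engine import McmcConfig
from frugicue.phylo import correlation_from_tree

FAST = dict(chains=2, iterations=800, burn_in=200, thin=2)


@pytest.fixture(scope="module")
def sem_data():
    return sd.sim_sem_observations(seed=21)


class TestSubmodel1:
    def test_complete_data_has_empty_augmentation(self):
        tree = sd.sim_tree(30, seed=1)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(n_plants=30),
                                        seed=2, mask=False)
        res = sem.run_submodel1(plants, tree,
                                McmcConfig(seed=3, **FAST))
        assert res.augmented["pulp_mass_g"] == {}
        summ = res.summaries["pulp_mass_g"]
        assert summ.loc[0, "term"] == "diameter_mm"
        assert summ.loc[0, "estimate"] > 0

    def test_masked_allometry_recovered(self):
        """ln(mass) = 2 ln(diameter) + noise with 20% of masses hidden:
        augmented posterior means must land near the held-out truths."""
        tree = sd.sim_tree(50, seed=4)
        plants, truth = sd.sim_plant_traits(
            tree, sd.SimConfig(n_plants=50,
                               mask_fractions={"pulp_mass_g": 0.2}),
            seed=5)
        res = sem.run_submodel1(plants, tree, McmcConfig(seed=6, **FAST))
        hidden = truth["masked"]["pulp_mass_g"]
        hits = 0
        for sp, est in res.augmented["pulp_mass_g"].items():
            err = abs(np.log(est) - np.log(hidden[sp]))
            hits += err < 0.5
        assert hits >= 0.8 * len(hidden)

    def test_conditional_r2_at_least_marginal(self):
        tree = sd.sim_tree(30, seed=7)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(n_plants=30),
                                        seed=8, mask=False)
        res = sem.run_submodel1(plants, tree, McmcConfig(seed=9, **FAST))
        v = res.variance["pulp_mass_g"]
        assert v["r2_conditional"] >= v["r2_marginal"]

    def test_draw_wise_intake_propagates_pulp_uncertainty(self):
        """Iterating intake profiles over pulp-mass posterior draws gives
        a distribution whose spread reflects the imputation uncertainty
        and whose mean tracks the posterior-mean propagation."""
        from frugicue import network_diets as nd
        tree = sd.sim_tree(12, seed=41)
        plants, _ = sd.sim_plant_traits(
            tree, sd.SimConfig(n_plants=12,
                               mask_fractions={"pulp_mass_g": 0.25}),
            seed=42)
        res = sem.run_submodel1(plants, tree, McmcConfig(seed=43, **FAST))
        species = list(plants.index)
        records = [nd.VisitRecord("s1", "autumn", "b", p, 1.0, 1.0)
                   for p in species]
        net = nd.build_networks(records)[0]
        nutrients = plants[["lipid"]]
        draws = sem.diet_intake_draws(net, nutrients, plants, res, "b",
                                      max_draws=30)
        assert len(draws) >= 20
        assert draws["lipid"].std() > 0
        pulp = plants["pulp_mass_g"].dropna().to_dict()
        pulp.update(res.augmented["pulp_mass_g"])
        point = nd.diet_nutrient_intake(net, nutrients, pulp, "b")
        assert draws["lipid"].mean() == pytest.approx(point["lipid"],
                                                      rel=0.1)

    def test_no_observed_mass_raises(self):
        tree = sd.sim_tree(10, seed=1)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(n_plants=10),
                                        seed=2, mask=False)
        plants["pulp_mass_g"] = np.nan
        with pytest.raises(ValueError, match="pulp mass"):
            sem.run_submodel1(plants, tree)


class TestSubmodel2:
    def test_brightness_selected_chroma_not(self):
        tree = sd.sim_tree(44, seed=10)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(), seed=11,
                                        mask=False)
        res = sem.run_submodel2(plants, tree,
                                McmcConfig(seed=12, **FAST),
                                nutrients=("anthocyanin",))
        summ = res.summaries["anthocyanin"].set_index("term")
        assert summ.loc["a", "BF"] > 2
        assert summ.loc["a", "estimate"] < 0
        for comp in ("x", "y", "z"):
            assert summ.loc[comp, "BF"] < 2

    def test_entirely_missing_nutrient_raises(self):
        tree = sd.sim_tree(20, seed=13)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(n_plants=20),
                                        seed=14, mask=False)
        plants["sugar"] = np.nan
        with pytest.raises(ValueError, match="sugar"):
            sem.run_submodel2(plants, tree, nutrients=("sugar",))

    def test_rerun_with_same_seed_is_identical(self):
        tree = sd.sim_tree(25, seed=15)
        plants, _ = sd.sim_plant_traits(tree, sd.SimConfig(n_plants=25),
                                        seed=16, mask=False)
        cfg = McmcConfig(seed=17, **FAST)
        a = sem.run_submodel2(plants, tree, cfg, nutrients=("lipid",))
        b = sem.run_submodel2(plants, tree, cfg, nutrients=("lipid",))
        pd.testing.assert_frame_equal(a.table(), b.table())


class TestSubmodel3:
    def test_path_table_covers_all_equations(self, sem_data):
        df, tree, _ = sem_data
        res = sem.run_submodel3(df, tree, config=McmcConfig(seed=18, **FAST))
        eqs = set(res.paths["response"])
        assert eqs == {"diet_x", "diet_y", "diet_z", "diet_a",
                       "intake_lipid", "intake_sugar", "intake_protein",
                       "intake_anthocyanin"}
        per_eq = res.paths.groupby("response")["predictor"].count()
        assert per_eq["diet_x"] == 3
        assert per_eq["intake_lipid"] == 7

    def test_alt2_adds_period_terms_same_equations(self, sem_data):
        df, tree, _ = sem_data
        res = sem.run_submodel3(df, tree, mode="alt2",
                                config=McmcConfig(seed=19, **FAST))
        assert set(res.paths["response"]).issuperset({"diet_a"})
        preds = set(res.paths[res.paths["response"] == "diet_a"]["predictor"])
        assert {"period", "migdist_x_period"} <= preds
        assert res.paths.groupby("response").ngroups == 8

    def test_missing_role_metric_raises(self, sem_data):
        df, tree, _ = sem_data
        broken = df.drop(columns=["partner_diversity"])
        with pytest.raises(ValueError, match="partner_diversity"):
            sem.run_submodel3(broken, tree)

    def test_single_equation_matches_direct_fit(self, sem_data):
        """The SEM is a deterministic pass of per-equation fits: the
        brightness equation must equal a direct sampler run with the same
        derived seed."""
        df, tree, _ = sem_data
        cfg = McmcConfig(seed=20, **FAST)
        res = sem.run_submodel3(df, tree, config=cfg)

        work = df.copy()
        work["ln_partner_diversity"] = np.log(work["partner_diversity"])
        work["ln_interaction_strength"] = np.log(work["interaction_strength"])
        work["ln_diet_a"] = np.log(work["diet_a"])
        period = work["season"].isin(("summer", "autumn"))
        work["md_coded"] = work["migratory_distance"] * period
        corr = correlation_from_tree(
            tree, sorted(work["frugivore"].astype(str).unique()))
        spec = sem._sem_specs("main", corr)["diet_a"]
        # diet_a is the 4th equation in the deterministic pass
        direct = bhm.fit(spec, work,
                         McmcConfig(seed=cfg.seed + 4000, **FAST))
        direct_summ = bhm.shrinkage_summary(direct)
        direct_summ["term"] = direct_summ["term"].map(
            lambda t: sem._TERM_ALIASES.get(t, t))
        sem_summ = res.submodel.summaries["diet_a"]
        pd.testing.assert_frame_equal(sem_summ.reset_index(drop=True),
                                      direct_summ.reset_index(drop=True))

    def test_indirect_effects_are_products_of_supported_paths(self, sem_data):
        df, tree, _ = sem_data
        res = sem.run_submodel3(df, tree, config=McmcConfig(seed=18, **FAST))
        if len(res.indirect):
            row = res.indirect.iloc[0]
            assert row["mediator"].startswith("diet_")
            assert row["ci_low"] <= row["estimate"] <= row["ci_high"]


class TestMarginalSelection:
    def test_uniform_probabilities_pass_through(self):
        rows = [(resp, comp, 0.9)
                for resp in ("lipid", "sugar", "protein", "anthocyanin")
                for comp in "xyza"]
        table = pd.DataFrame(rows, columns=["response", "term", "P"])
        out = sem.marginal_selection(table, axis="colour_reward")
        assert all(out[c] == pytest.approx(0.9) for c in "xyza")

    def test_absent_component_raises(self):
        table = pd.DataFrame({"response": ["lipid"], "term": ["a"],
                              "P": [0.9]})
        with pytest.raises(KeyError, match="'x'"):
            sem.marginal_selection(table, axis="colour_reward")

    def test_published_colour_reward_marginals(self):
        out = sem.marginal_selection(ref.colour_reward_table(),
                                     axis="colour_reward")
        assert out["a"] == pytest.approx(0.7525)
        assert out["x"] == pytest.approx(0.355)

    def test_published_sem_marginals(self):
        out = sem.marginal_selection(ref.fruit_choice_table(), axis="sem")
        assert out["a"] == pytest.approx(0.73, abs=1e-9)
        assert out["z"] == pytest.approx((0.19 + 0.23 + 0.70) / 3)


class TestConcordance:
    def test_component_independent_indicators_give_flat_slope(self):
        rng = np.random.default_rng(0)
        m2 = {"x": 0.2, "y": 0.4, "z": 0.6, "a": 0.8}
        draws = {c: (rng.random(6000) < 0.5).astype(float) for c in m2}
        res = sem.concordance(m2, draws)
        assert abs(res.slope) < 0.2

    def test_threshold_indicators_flag_separation(self):
        m2 = {"x": 0.2, "y": 0.3, "z": 0.6, "a": 0.9}
        draws = {c: np.full(2000, 1.0 if p > 0.5 else 0.0)
                 for c, p in m2.items()}
        res = sem.concordance(m2, draws)
        assert res.quasi_separation
        assert res.slope > 0

    def test_published_tables_reproduce_logistic_fit(self):
        m2 = sem.marginal_selection(ref.colour_reward_table(),
                                    axis="colour_reward")
        m3 = sem.marginal_selection(ref.fruit_choice_table(), axis="sem")
        res = sem.concordance(m2, m3, n_draws=2000)
        assert res.intercept == pytest.approx(-2.4, abs=0.1)
        assert res.slope == pytest.approx(4.6, abs=0.1)
        assert res.n_samples == 24000

    def test_constant_probabilities_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sem.concordance({"x": 0.5, "y": 0.5, "z": 0.5, "a": 0.5},
                            {"x": 0.2, "y": 0.2, "z": 0.2, "a": 0.2})

    def test_monotone_coupling_recovers_positive_slope(self):
        rng = np.random.default_rng(3)
        wins = 0
        for rep in range(10):
            m2 = {c: p for c, p in zip("xyza",
                                       rng.uniform(0.1, 0.9, size=4))}
            draws = {c: (rng.random(2000) < m2[c]).astype(float) for c in m2}
            res = sem.concordance(m2, draws)
            wins += res.slope > 0
        assert wins >= 9
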