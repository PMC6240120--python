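"""Gibbs sampler correctness, selection summaries and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from frugicue import bhm_engine as bhm
from frugicue.bhm_engine import (BayesFactor, FixedTerm, McmcConfig,
                                 ModelSpec, bayes_factor)
from frugicue.phylo import correlation_from_tree
from frugicue.synthetic_data import sim_tree


def make_posterior(indicator, beta, sigma2=None, X=None):
    """Assemble a minimal single-term Posterior from given draws."""
    indicator = np.asarray(indicator, float)
    beta = np.asarray(beta, float)
    D = len(indicator)
    sigma2 = sigma2 or {}
    sigma2.setdefault("beta", np.ones(D))
    sigma2.setdefault("resid", np.ones(D))
    return bhm.Posterior(
        terms=["x"], selectable=np.array([True]),
        alpha=np.zeros(D), beta=beta.reshape(D, 1),
        indicator=indicator.reshape(D, 1),
        sigma2=sigma2, ranef={},
        y_missing=np.empty((D, 0)), missing_rows=np.array([], int),
        chain=np.zeros(D, int), n_chains=1, draws_per_chain=D,
        X=X if X is not None else np.zeros((1, 1)),
        y_observed=np.zeros(1),
        response_transform={"mean": 0.0, "sd": 1.0, "log": False},
    )


class TestBayesFactor:
    @pytest.mark.parametrize("P,expected", [
        (0.68, 1.5), (0.70, 1.7), (0.72, 1.9), (0.5, 0.0)])
    def test_published_worked_examples(self, P, expected):
        assert round(bayes_factor(P).value, 1) == expected

    def test_unit_probability_reports_bound(self):
        bf = bayes_factor(1.0, n_draws=2000)
        assert bf.bound == ">"
        assert bf.value == pytest.approx(2 * np.log(1999.5 / 0.5))
        assert str(bf).startswith(">")

    def test_zero_probability_reports_lower_bound(self):
        bf = bayes_factor(0.0, n_draws=2000)
        assert bf.bound == "<"
        assert bf.value < 0

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(0.5, prior_p=1.0)

    def test_nondefault_prior_shifts_odds(self):
        assert bayes_factor(0.5, prior_p=0.2).value == pytest.approx(
            2 * np.log((1.0) / (0.25)))


class TestShrinkageSummary:
    def test_all_excluded_gives_zero_estimate(self):
        post = make_posterior(np.zeros(100), np.ones(100))
        row = bhm.shrinkage_summary(post).iloc[0]
        assert row["estimate"] == 0.0
        assert (row["ci_low"], row["ci_high"]) == (0.0, 0.0)

    def test_all_included_equals_beta_mean(self):
        beta = np.linspace(-1, 1, 100)
        post = make_posterior(np.ones(100), beta)
        row = bhm.shrinkage_summary(post).iloc[0]
        assert row["estimate"] == pytest.approx(beta.mean())

    def test_half_included_averages_in_zeros(self):
        ind = np.array([1.0] * 50 + [0.0] * 50)
        beta = np.full(100, 2.0)
        post = make_posterior(ind, beta)
        row = bhm.shrinkage_summary(post).iloc[0]
        assert row["estimate"] == pytest.approx(1.0)
        assert row["P"] == pytest.approx(0.5)


class TestRSquared:
    def test_null_model_has_zero_r2(self):
        D = 50
        post = make_posterior(np.zeros(D), np.zeros(D),
                              sigma2={"beta": np.ones(D),
                                      "resid": np.ones(D)},
                              X=np.random.default_rng(0).normal(size=(20, 1)))
        out = bhm.r_squared(post)
        assert out["r2_marginal"] == 0.0
        assert out["r2_conditional"] == 0.0

    def test_variance_ratio_plugin(self):
        # var_f = 1, species variance 1, residual 2 -> 0.25 and 0.50
        D, n = 10, 4000
        rng = np.random.default_rng(1)
        X = rng.normal(size=(n, 1))
        X = (X - X.mean()) / X.std()
        post = make_posterior(np.ones(D), np.ones(D),
                              sigma2={"beta": np.ones(D),
                                      "resid": np.full(D, 2.0),
                                      "species": np.ones(D)}, X=X)
        out = bhm.r_squared(post)
        assert out["r2_marginal"] == pytest.approx(0.25, abs=0.01)
        assert out["r2_conditional"] == pytest.approx(0.50, abs=0.01)
        assert out["component_shares"]["resid"] == pytest.approx(0.5, abs=0.01)


class TestFit:
    def test_intercept_only_recovers_location(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.normal(5.0, 1.0, size=400)})
        spec = ModelSpec(response="y", fixed=[], standardize=False)
        post = bhm.fit(spec, df, McmcConfig(chains=2, iterations=1500,
                                            burn_in=500, thin=2, seed=2))
        assert post.alpha.mean() == pytest.approx(df["y"].mean(), abs=0.1)

    def test_conjugate_oracle_equivalence(self):
        """Selection disabled + fixed variances: the Gibbs posterior of
        (alpha, beta) must match the closed-form conjugate normal."""
        rng = np.random.default_rng(0)
        n = 50
        X = rng.normal(size=(n, 2))
        y = 0.8 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"x1": X[:, 0], "x2": X[:, 1], "y": y})
        spec = ModelSpec(response="y", standardize=False,
                         fixed=[FixedTerm("x1", selectable=False),
                                FixedTerm("x2", selectable=False)])
        s2e, s2b = 0.25, 4.0
        post = bhm.fit(spec, df,
                       McmcConfig(chains=4, iterations=3000, burn_in=500,
                                  thin=5, seed=3),
                       fix_variances={"resid": s2e, "beta": s2b})
        # independent closed-form conjugate posterior
        M = np.column_stack([np.ones(n), X])
        P0 = np.diag([1e-4, 1 / s2b, 1 / s2b])
        Q = M.T @ M / s2e + P0
        cov = np.linalg.inv(Q)
        mean = cov @ (M.T @ y / s2e)
        draws = [post.alpha, post.beta[:, 0], post.beta[:, 1]]
        for i, d in enumerate(draws):
            mcse = d.std() / np.sqrt(len(d) / 4)  # conservative ESS guess
            assert abs(d.mean() - mean[i]) < 3 * mcse + 1e-3
            assert d.std() == pytest.approx(np.sqrt(cov[i, i]), rel=0.15)

    def test_strong_effect_is_selected(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.normal(size=n)
        y = 1.0 * x + rng.normal(0, 0.1, n)
        df = pd.DataFrame({"x": x, "y": y})
        post = bhm.fit(ModelSpec(response="y", fixed=[FixedTerm("x")]), df,
                       McmcConfig(chains=2, iterations=1500, burn_in=500,
                                  thin=2, seed=4))
        assert post.inclusion_probability("x") > 0.9

    def test_missing_responses_predicted_from_signal(self):
        """Masked strong-signal responses: augmented posterior means must
        track the held-out truths."""
        rng = np.random.default_rng(9)
        n = 120
        x = rng.normal(size=n)
        y_true = 2.0 * x + rng.normal(0, 0.3, n)
        y = y_true.copy()
        mask = rng.random(n) < 0.2
        y[mask] = np.nan
        df = pd.DataFrame({"x": x, "y": y})
        post = bhm.fit(ModelSpec(response="y",
                                 fixed=[FixedTerm("x", selectable=False)]),
                       df,
                       McmcConfig(chains=2, iterations=1500, burn_in=500,
                                  thin=2, seed=5))
        pred = post.augmented_means()
        truth = y_true[post.missing_rows]
        r = np.corrcoef(pred, truth)[0, 1]
        assert r > 0.7

    def test_phylo_variance_recovery(self):
        tree = sim_tree(100, 7)
        C = correlation_from_tree(tree)
        rng = np.random.default_rng(3)
        L = np.linalg.cholesky(C.matrix + 1e-10 * np.eye(100))
        y = L @ rng.normal(size=100) + rng.normal(0, 1, size=100)
        df = pd.DataFrame({"species": C.species, "y": y})
        spec = ModelSpec(response="y", fixed=[], phylo=C,
                         species_col="species", standardize=False)
        post = bhm.fit(spec, df, McmcConfig(chains=2, iterations=2500,
                                            burn_in=1000, thin=3, seed=11))
        assert abs(post.sigma2["phylo"].mean() - 1.0) < 0.4
        assert abs(post.sigma2["resid"].mean() - 1.0) < 0.4

    def test_same_seed_reproduces_draws(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=40),
                           "y": rng.normal(size=40)})
        spec = ModelSpec(response="y", fixed=[FixedTerm("x")])
        cfg = McmcConfig(chains=2, iterations=800, burn_in=200, thin=2,
                         seed=13)
        p1 = bhm.fit(spec, df, cfg)
        p2 = bhm.fit(spec, df, cfg)
        assert np.array_equal(p1.alpha, p2.alpha)
        assert np.array_equal(p1.indicator, p2.indicator)

    def test_missing_predictor_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan, 2.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            bhm.fit(ModelSpec(response="y", fixed=[FixedTerm("x")]), df)

    def test_species_not_in_correlation_rejected(self):
        tree = sim_tree(5, 1)
        C = correlation_from_tree(tree)
        df = pd.DataFrame({"species": ["nope", "t1"], "y": [1.0, 2.0]})
        with pytest.raises(KeyError, match="nope"):
            bhm.fit(ModelSpec(response="y", fixed=[], phylo=C,
                              species_col="species"), df,
                    McmcConfig(chains=1, iterations=300, burn_in=100,
                               thin=2, seed=0))


class TestConfigAndExport:
    def test_model_spec_from_dict(self):
        cfg = {"response": "lipid", "log_response": True,
               "fixed": ["x", {"name": "a", "selectable": True}],
               "species_col": "species", "species_iid": True,
               "site_col": "site"}
        spec = ModelSpec.from_dict(cfg)
        assert spec.response == "lipid"
        assert [t.name for t in spec.fixed] == ["x", "a"]
        assert spec.species_iid and spec.site_col == "site"

    def test_posterior_draws_round_trip_csv(self, tmp_path):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=30),
                           "y": rng.normal(size=30)})
        post = bhm.fit(ModelSpec(response="y", fixed=[FixedTerm("x")]), df,
                       McmcConfig(chains=2, iterations=400, burn_in=100,
                                  thin=2, seed=6))
        p = tmp_path / "draws.csv"
        post.write_draws_csv(p)
        back = pd.read_csv(p)
        assert len(back) == post.n_draws
        assert np.allclose(back["beta_x"], post.beta[:, 0])
        assert set(back["I_x"].unique()) <= {0, 1}


class TestDiagnostics:
    def _posterior_from_chains(self, chains):
        arr = np.concatenate(chains)
        D = len(chains[0])
        return bhm.Posterior(
            terms=[], selectable=np.array([], bool),
            alpha=arr, beta=np.empty((len(arr), 0)),
            indicator=np.empty((len(arr), 0)),
            sigma2={"beta": np.ones(len(arr)), "resid": np.ones(len(arr))},
            ranef={}, y_missing=np.empty((len(arr), 0)),
            missing_rows=np.array([], int),
            chain=np.repeat(np.arange(len(chains)), D),
            n_chains=len(chains), draws_per_chain=D,
            X=np.empty((1, 0)), y_observed=np.zeros(1),
            response_transform={"mean": 0, "sd": 1, "log": False})

    def test_identical_chains_have_unit_rhat(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=500) for _ in range(4)]
        post = self._posterior_from_chains(chains)
        rep = bhm.diagnostics(post)
        rhat = rep.loc[rep.parameter == "alpha", "rhat"].item()
        assert rhat == pytest.approx(1.0, abs=0.01)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = [rng.normal(size=500), rng.normal(5.0, 1.0, size=500)]
        rep = bhm.diagnostics(self._posterior_from_chains(chains))
        row = rep[rep.parameter == "alpha"].iloc[0]
        assert row["rhat"] > 1.05 and row["flagged"]

    def test_iid_draws_have_full_ess(self):
        rng = np.random.default_rng(2)
        chains = [rng.normal(size=1000) for _ in range(2)]
        rep = bhm.diagnostics(self._posterior_from_chains(chains))
        ess = rep.loc[rep.parameter == "alpha", "ess"].item()
        assert ess == pytest.approx(2000, rel=0.2)
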