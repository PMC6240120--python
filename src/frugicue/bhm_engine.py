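"""Bayesian hierarchical linear model with indicator variable selection.

The model is a Gaussian hierarchical regression

    y_i ~ Normal(mu_i, sigma_eps^2),      mu_i = eta_i + zeta_i,
    eta_i = alpha + sum_j theta_j X_ij,   theta_j = I_j * beta_j,

with optional random effects zeta_i = a_k[i] + v_k[i] + s_l[i] + t_m[i]:
a phylogenetic species effect a ~ N(0, sigma_a^2 C) with C the
standardized shared-branch-length correlation, an iid species effect v,
and iid site and season effects s, t.

Variable selection follows the Kuo-Mallick indicator construction with
global adaptation: each selectable slope carries an independent Bernoulli
indicator I_j with prior inclusion probability 0.5 and a slope prior
beta_j ~ N(0, sigma_beta^2) shared across terms, with
sigma_beta^2 ~ Uniform(0, 100) so the selection is self-tuning.  When
I_j = 0 the slope is refreshed from its prior to keep the chain
irreducible.  Residual and random-effect standard deviations carry
Uniform(0, 100) priors sampled by shrinkage slice steps.

Missing response values are treated by data augmentation: each is drawn
from its full conditional Normal(mu_i, sigma_eps^2), so predictions for
unobserved species borrow strength from the covariates and the phylogeny
and their uncertainty propagates into every downstream summary.

Evidence for a term is summarized by its posterior inclusion probability
P and by 2*ln(Bayes factor) = 2*ln[(P/(1-P)) / (p0/(1-p0))]; values > 2
indicate positive, > 6 strong, and > 10 decisive support.  Effect
estimates are reported with shrinkage (posterior mean of I_j * beta_j).
Model fit is summarized by the marginal r^2 (fixed effects only) and the
conditional r^2 (fixed plus random), computed per retained draw and then
averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .phylo import PhyloCorrelation, stable_inverse

__all__ = [
    "FixedTerm",
    "ModelSpec",
    "McmcConfig",
    "Posterior",
    "BayesFactor",
    "fit",
    "bayes_factor",
    "shrinkage_summary",
    "r_squared",
    "diagnostics",
]

_SD_UPPER = 100.0         # Uniform(0, 100) prior on sds
_SIGMA_BETA2_UPPER = 100.0  # Uniform(0, 100) prior on the shared slope variance
_ALPHA_PRIOR_SD = 100.0


@dataclass(frozen=True)
class FixedTerm:
    name: str
    selectable: bool = True
    log: bool = False


@dataclass
class ModelSpec:
    """Definition of one hierarchical regression equation."""

    response: str
    fixed: list = field(default_factory=list)   # FixedTerm or str
    log_response: bool = False
    phylo: PhyloCorrelation | None = None
    species_col: str | None = None   # used by both phylo and iid species terms
    species_iid: bool = False
    site_col: str | None = None
    season_col: str | None = None
    standardize: bool = True

    def __post_init__(self):
        self.fixed = [t if isinstance(t, FixedTerm) else FixedTerm(str(t))
                      for t in self.fixed]
        if self.phylo is not None and self.species_col is None:
            raise ValueError("phylo random term requires species_col")

    @classmethod
    def from_dict(cls, cfg: dict,
                  phylo: PhyloCorrelation | None = None) -> "ModelSpec":
        """Build a spec from a plain config mapping (YAML/JSON-friendly).

        Recognized keys: response, log_response, standardize, fixed (list
        of names or {name, selectable, log} mappings), species_col,
        species_iid, site_col, season_col, phylo_corr_csv (path, ignored
        when ``phylo`` is passed directly).
        """
        corr = phylo
        if corr is None and cfg.get("phylo_corr_csv"):
            from .phylo import read_correlation_csv
            corr = read_correlation_csv(cfg["phylo_corr_csv"])
        fixed = []
        for t in cfg.get("fixed", []):
            if isinstance(t, dict):
                fixed.append(FixedTerm(t["name"],
                                       selectable=t.get("selectable", True),
                                       log=t.get("log", False)))
            else:
                fixed.append(FixedTerm(str(t)))
        return cls(response=cfg["response"], fixed=fixed,
                   log_response=cfg.get("log_response", False),
                   phylo=corr, species_col=cfg.get("species_col"),
                   species_iid=cfg.get("species_iid", False),
                   site_col=cfg.get("site_col"),
                   season_col=cfg.get("season_col"),
                   standardize=cfg.get("standardize", True))


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 8
    iterations: int = 26000
    burn_in: int = 1000
    thin: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.draws_per_chain < 50:
            raise ValueError("(iterations - burn_in)/thin must be >= 50")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class Posterior:
    """Retained MCMC draws and the design metadata needed to summarize them."""

    terms: list[str]
    selectable: np.ndarray        # bool per term
    alpha: np.ndarray             # (D,)
    beta: np.ndarray              # (D, J)
    indicator: np.ndarray         # (D, J) in {0, 1}
    sigma2: dict                  # name -> (D,) arrays; keys: beta, resid, ...
    ranef: dict                   # name -> (D, size)
    y_missing: np.ndarray         # (D, n_missing) on the model scale
    missing_rows: np.ndarray
    chain: np.ndarray             # (D,)
    n_chains: int
    draws_per_chain: int
    X: np.ndarray                 # standardized design used in the fit
    y_observed: np.ndarray        # model-scale response (NaN where missing)
    response_transform: dict      # mean/sd/log for back-transformation
    prior_inclusion: float = 0.5

    def __post_init__(self):
        D = self.n_chains * self.draws_per_chain
        if self.alpha.shape[0] != D:
            raise ValueError("draw count mismatch")
        if self.indicator.size and not np.isin(self.indicator, (0, 1)).all():
            raise ValueError("indicator draws must be 0/1")
        for name, arr in self.sigma2.items():
            if (arr <= 0).any():
                raise ValueError(f"non-positive variance draws for {name}")

    @property
    def theta(self) -> np.ndarray:
        return self.indicator * self.beta

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0]

    def inclusion_probability(self, term: str) -> float:
        j = self.terms.index(term)
        return float(self.indicator[:, j].mean())

    def augmented_draws(self) -> np.ndarray:
        """Draws of augmented responses on the original scale, (D, n_mis)."""
        tr = self.response_transform
        draws = self.y_missing * tr["sd"] + tr["mean"]
        if tr["log"]:
            draws = np.exp(draws)
        return draws

    def augmented_means(self) -> np.ndarray:
        """Posterior means of augmented responses on the original scale."""
        return self.augmented_draws().mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Retained draws as a tidy table (one row per draw): chain,
        intercept, per-term slope and indicator, variances, augmented
        responses."""
        cols = {"chain": self.chain, "alpha": self.alpha}
        for j, t in enumerate(self.terms):
            cols[f"beta_{t}"] = self.beta[:, j]
            cols[f"I_{t}"] = self.indicator[:, j].astype(int)
        for k, v in self.sigma2.items():
            cols[f"sigma2_{k}"] = v
        for m, row in enumerate(self.missing_rows):
            cols[f"y_missing_{row}"] = self.y_missing[:, m]
        return pd.DataFrame(cols)

    def write_draws_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BayesFactor:
    """2*ln(Bayes factor); ``bound`` is '>' or '<' when P hit 0/1 under
    finitely many draws and only a bound can be reported."""

    value: float
    bound: str | None = None

    def __float__(self):
        return self.value

    def __str__(self):
        if self.bound:
            return f"{self.bound} {abs(self.value):.1f}"
        return f"{self.value:.1f}"


# ---------------------------------------------------------------------------
# sampler internals


def _slice_sample(logpdf, x0: float, lo: float, hi: float, rng) -> float:
    """Shrinkage slice sampling on a bounded interval (lo, hi)."""
    logy = logpdf(x0) - rng.exponential(1.0)
    left, right = lo, hi
    for _ in range(100):
        x1 = rng.uniform(left, right)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _sd_logpdf(size: float, ssq: float):
    """log-density kernel for an sd with Uniform(0, 100) prior given a
    centered normal vector of ``size`` entries and sum of squares ``ssq``."""
    def lp(s):
        if s <= 0:
            return -np.inf
        return -size * math.log(s) - ssq / (2.0 * s * s)
    return lp


def _draw_sd(size: int, ssq: float, current: float, rng) -> float:
    """Exact draw of an sd under a Uniform(0, 100) prior.

    The conditional density over sigma is sigma^-size * exp(-ssq/2sigma^2)
    on (0, 100); on the precision scale tau = sigma^-2 this is a
    Gamma((size-1)/2, ssq/2) kernel truncated to tau >= 1e-4, sampled by
    rejection (the truncation is almost never active) with a slice-step
    fallback."""
    shape = (size - 1) / 2.0
    if shape <= 0 or ssq <= 0:
        return _slice_sample(_sd_logpdf(size, ssq), current, 1e-9,
                             _SD_UPPER, rng)
    for _ in range(50):
        tau = rng.gamma(shape, 2.0 / ssq)
        if tau >= 1.0 / (_SD_UPPER * _SD_UPPER):
            return 1.0 / math.sqrt(tau)
    return _slice_sample(_sd_logpdf(size, ssq), current, 1e-9, _SD_UPPER, rng)


class _Design:
    """Preprocessed data for one equation."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        n = len(data)
        if n < 2:
            raise ValueError("need at least two observations")

        y_raw = data[spec.response].to_numpy(float)
        if spec.log_response:
            with np.errstate(invalid="ignore"):
                y_raw = np.log(y_raw)
        self.missing = ~np.isfinite(y_raw)
        if self.missing.all():
            raise ValueError("response entirely missing")
        obs = y_raw[~self.missing]
        if spec.standardize:
            mu, sd = float(obs.mean()), float(obs.std(ddof=0))
            if sd <= 0:
                raise ValueError("response has zero variance")
        else:
            mu, sd = 0.0, 1.0
        self.y = (y_raw - mu) / sd
        self.transform = {"mean": mu, "sd": sd, "log": spec.log_response}

        cols = []
        self.terms = []
        self.selectable = []
        for t in spec.fixed:
            x = data[t.name].to_numpy(float)
            if t.log:
                x = np.log(x)
            if not np.isfinite(x).all():
                raise ValueError(f"predictor {t.name!r} has missing values")
            if spec.standardize:
                s = x.std(ddof=0)
                if s <= 0:
                    raise ValueError(f"predictor {t.name!r} has zero variance")
                x = (x - x.mean()) / s
            cols.append(x)
            self.terms.append(t.name)
            self.selectable.append(t.selectable)
        self.X = np.column_stack(cols) if cols else np.empty((n, 0))
        self.selectable = np.array(self.selectable, dtype=bool)

        # random-effect index maps
        self.groups = {}   # name -> (index array, n_levels)
        if spec.phylo is not None or spec.species_iid:
            if spec.species_col is None:
                raise ValueError("species random terms require species_col")
            sp = data[spec.species_col].astype(str).to_numpy()
        if spec.phylo is not None:
            order = list(spec.phylo.species)
            missing_sp = sorted(set(sp) - set(order))
            if missing_sp:
                raise KeyError(
                    f"species missing from phylogenetic correlation: {missing_sp}")
            idx = np.array([order.index(s) for s in sp])
            self.groups["phylo"] = (idx, len(order))
            self.C_inv = stable_inverse(spec.phylo)
            counts = np.bincount(idx, minlength=len(order))
            # equal replication per species lets the phylo update reuse a
            # single eigendecomposition instead of a per-iteration Cholesky
            if np.all(counts == counts[0]):
                evals, evecs = np.linalg.eigh(self.C_inv)
                self.C_inv_eig = (np.maximum(evals, 1e-12), evecs)
            else:
                self.C_inv_eig = None
        else:
            self.C_inv = None
            self.C_inv_eig = None
        if spec.species_iid:
            levels, idx = np.unique(sp, return_inverse=True)
            self.groups["species"] = (idx, len(levels))
        for name, col in (("site", spec.site_col), ("season", spec.season_col)):
            if col is not None:
                levels, idx = np.unique(data[col].astype(str), return_inverse=True)
                self.groups[name] = (idx, len(levels))
        self.n = n


def _run_chain(design: _Design, config: McmcConfig, chain_idx: int,
               prior_inclusion: float, fix_variances: dict | None = None):
    fix = fix_variances or {}
    rng = np.random.default_rng(config.seed + chain_idx)
    n, X = design.n, design.X
    J = X.shape[1]
    miss = design.missing
    y = design.y.copy()

    # over-dispersed initial values
    alpha = rng.uniform(-2, 2)
    beta = rng.uniform(-2, 2, size=J)
    ind = (rng.random(J) < prior_inclusion).astype(float)
    ind[~design.selectable] = 1.0
    sig2_beta = fix.get("beta", rng.uniform(0.5, 5.0))
    sig_e = math.sqrt(fix["resid"]) if "resid" in fix \
        else rng.uniform(0.2, 3.0)
    u = {name: np.zeros(size) for name, (_, size) in design.groups.items()}
    sig = {name: rng.uniform(0.2, 3.0) for name in design.groups}
    y[miss] = rng.normal(0, 1, size=miss.sum())

    xx = (X * X).sum(axis=0) if J else np.empty(0)
    counts = {name: np.bincount(idx, minlength=size)
              for name, (idx, size) in design.groups.items()}

    D = config.draws_per_chain
    out = {
        "alpha": np.empty(D), "beta": np.empty((D, J)),
        "indicator": np.empty((D, J)),
        "sigma2": {"beta": np.empty(D), "resid": np.empty(D),
                   **{name: np.empty(D) for name in design.groups}},
        "ranef": {name: np.empty((D, size))
                  for name, (_, size) in design.groups.items()},
        "y_missing": np.empty((D, int(miss.sum()))),
    }

    log_prior_odds = math.log(prior_inclusion / (1 - prior_inclusion))
    store = 0
    for it in range(config.iterations):
        sig2_e = sig_e * sig_e
        zeta = np.zeros(n)
        for name, (idx, _) in design.groups.items():
            zeta += u[name][idx]
        theta = ind * beta
        res = y - alpha - (X @ theta if J else 0.0) - zeta

        # (1) intercept and slopes, conditional on indicators
        res += alpha
        prec = n / sig2_e + 1.0 / (_ALPHA_PRIOR_SD ** 2)
        mean = res.sum() / sig2_e / prec
        alpha = rng.normal(mean, 1.0 / math.sqrt(prec))
        res -= alpha

        for j in range(J):
            xj = X[:, j]
            res += xj * theta[j]
            if ind[j] == 1.0:
                prec = xx[j] / sig2_e + 1.0 / sig2_beta
                mean = (xj @ res) / sig2_e / prec
                beta[j] = rng.normal(mean, 1.0 / math.sqrt(prec))
            else:
                beta[j] = rng.normal(0.0, math.sqrt(sig2_beta))
            theta[j] = ind[j] * beta[j]
            res -= xj * theta[j]

        # (2) indicators (Kuo-Mallick conditional Bernoulli)
        for j in range(J):
            if not design.selectable[j]:
                continue
            xj = X[:, j]
            rj = res + xj * theta[j]
            rss0 = rj @ rj
            d1 = rj - xj * beta[j]
            rss1 = d1 @ d1
            logit = log_prior_odds + (rss0 - rss1) / (2.0 * sig2_e)
            p1 = 1.0 / (1.0 + math.exp(-min(max(logit, -700), 700)))
            ind[j] = 1.0 if rng.random() < p1 else 0.0
            theta[j] = ind[j] * beta[j]
            res = rj - xj * theta[j]

        # (3) shared slope variance, Uniform(0, 100) prior on the variance
        if J and "beta" not in fix:
            ssq = float(beta @ beta)
            lp = lambda v: (-J / 2.0) * math.log(v) - ssq / (2.0 * v)
            sig2_beta = _slice_sample(lp, sig2_beta, 1e-12,
                                      _SIGMA_BETA2_UPPER, rng)

        # (4) random-effect vectors
        for name, (idx, size) in design.groups.items():
            res += u[name][idx]
            rsum = np.bincount(idx, weights=res, minlength=size)
            if name == "phylo":
                b = rsum / sig2_e
                z = rng.normal(size=size)
                if design.C_inv_eig is not None:
                    evals, U = design.C_inv_eig
                    w = 1.0 / (evals / (sig[name] ** 2)
                               + counts[name][0] / sig2_e)
                    u[name] = U @ (w * (U.T @ b) + np.sqrt(w) * z)
                else:
                    Q = design.C_inv / (sig[name] ** 2)
                    Q[np.diag_indices(size)] += counts[name] / sig2_e
                    cf = sla.cho_factor(Q, lower=True,
                                        overwrite_a=True, check_finite=False)
                    mu_vec = sla.cho_solve(cf, b, check_finite=False)
                    u[name] = mu_vec + sla.solve_triangular(
                        cf[0], z, lower=True, trans="T", check_finite=False)
            else:
                prec = counts[name] / sig2_e + 1.0 / (sig[name] ** 2)
                mean = rsum / sig2_e / prec
                u[name] = rng.normal(mean, 1.0 / np.sqrt(prec))
            res -= u[name][idx]

        # (5) variance components, Uniform(0, 100) priors on the sds
        for name, (_, size) in design.groups.items():
            if name == "phylo":
                ssq = float(u[name] @ design.C_inv @ u[name])
            else:
                ssq = float(u[name] @ u[name])
            sig[name] = _draw_sd(size, ssq, sig[name], rng)
        if "resid" not in fix:
            sse = float(res @ res)
            sig_e = _draw_sd(n, sse, sig_e, rng)
            sig2_e = sig_e * sig_e

        # (6) augmentation of missing responses
        if miss.any():
            mu_mis = (y - res)[miss]
            newvals = rng.normal(mu_mis, sig_e)
            res[miss] += newvals - y[miss]
            y[miss] = newvals

        if it >= config.burn_in and (it + 1 - config.burn_in) % config.thin == 0:
            out["alpha"][store] = alpha
            out["beta"][store] = beta
            out["indicator"][store] = ind
            out["sigma2"]["beta"][store] = sig2_beta
            out["sigma2"]["resid"][store] = sig2_e
            for name in design.groups:
                out["sigma2"][name][store] = sig[name] ** 2
                out["ranef"][name][store] = u[name]
            out["y_missing"][store] = y[miss]
            store += 1
    assert store == D
    return out


def fit(spec: ModelSpec, data: pd.DataFrame,
        config: McmcConfig | None = None,
        prior_inclusion: float = 0.5,
        fix_variances: dict | None = None) -> Posterior:
    """Run the Gibbs sampler and return the retained posterior draws.

    Chains use seeds ``config.seed + chain`` and a fixed scan order
    (intercept/slopes, indicators, slope variance, random-effect vectors,
    variance components, missing-value augmentation), so results are fully
    reproducible for a given seed.  Selection is disabled per term via
    ``FixedTerm(selectable=False)``; ``fix_variances`` pins the "resid"
    and/or "beta" variance at a known value, which makes the coefficient
    posterior exactly conjugate for validation.
    """
    if not (0.0 < prior_inclusion < 1.0):
        raise ValueError("prior inclusion probability must be in (0, 1)")
    if config is None:
        config = McmcConfig()
    design = _Design(spec, data)
    chains = [_run_chain(design, config, c, prior_inclusion, fix_variances)
              for c in range(config.chains)]
    D = config.draws_per_chain

    def cat(key):
        return np.concatenate([c[key] for c in chains], axis=0)

    sigma2 = {k: np.concatenate([c["sigma2"][k] for c in chains])
              for k in chains[0]["sigma2"]}
    ranef = {k: np.concatenate([c["ranef"][k] for c in chains], axis=0)
             for k in chains[0]["ranef"]}
    return Posterior(
        terms=list(design.terms),
        selectable=design.selectable,
        alpha=cat("alpha"), beta=cat("beta"), indicator=cat("indicator"),
        sigma2=sigma2, ranef=ranef,
        y_missing=cat("y_missing"),
        missing_rows=np.flatnonzero(design.missing),
        chain=np.repeat(np.arange(config.chains), D),
        n_chains=config.chains, draws_per_chain=D,
        X=design.X, y_observed=np.where(design.missing, np.nan, design.y),
        response_transform=design.transform,
        prior_inclusion=prior_inclusion,
    )


# ---------------------------------------------------------------------------
# summaries


def bayes_factor(P: float, prior_p: float = 0.5,
                 n_draws: int | None = None) -> BayesFactor:
    """2*ln(Bayes factor) from a posterior inclusion probability.

    When P is exactly 0 or 1 under finitely many draws the true posterior
    odds are only bounded, and the bound 2*ln((n_draws - 0.5)/0.5) is
    returned with a '>' (or '<') flag.
    """
    if not (0.0 < prior_p < 1.0):
        raise ValueError("prior inclusion probability must be in (0, 1)")
    if not (0.0 <= P <= 1.0):
        raise ValueError("P must lie in [0, 1]")
    prior_odds = prior_p / (1 - prior_p)
    if P in (0.0, 1.0):
        if n_draws is None:
            raise ValueError("P of exactly 0 or 1 requires n_draws for a bound")
        bound = 2.0 * math.log(((n_draws - 0.5) / 0.5) / prior_odds)
        return BayesFactor(bound if P == 1.0 else -bound,
                           ">" if P == 1.0 else "<")
    return BayesFactor(2.0 * math.log((P / (1 - P)) / prior_odds))


def shrinkage_summary(post: Posterior) -> pd.DataFrame:
    """Per-term selection probability, 2ln(BF), shrinkage estimate
    (posterior mean of I_j*beta_j) and 95% credible interval."""
    rows = []
    theta = post.theta
    for j, term in enumerate(post.terms):
        draws = theta[:, j]
        P = float(post.indicator[:, j].mean())
        bf = bayes_factor(P, post.prior_inclusion, post.n_draws)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append({
            "term": term, "estimate": float(draws.mean()),
            "ci_low": float(lo), "ci_high": float(hi),
            "P": P, "BF": bf.value, "BF_bound": bf.bound or "",
            "selectable": bool(post.selectable[j]),
            "supported": bool(post.selectable[j] and bf.value > 2.0),
        })
    return pd.DataFrame(rows)


def r_squared(post: Posterior) -> dict:
    """Marginal and conditional r^2 and per-component variance shares.

    Computed per retained draw as variance ratios (fixed-effect variance
    over observations in the numerator; all variance components plus the
    residual in the denominator), then averaged over draws.
    """
    D = post.n_draws
    theta = post.theta
    if theta.shape[1]:
        var_f = (post.X @ theta.T).var(axis=0, ddof=0)
    else:
        var_f = np.zeros(D)
    comp_names = [k for k in post.sigma2 if k not in ("beta", "resid")]
    comp = np.column_stack([post.sigma2[k] for k in comp_names]) \
        if comp_names else np.zeros((D, 0))
    denom = var_f + comp.sum(axis=1) + post.sigma2["resid"]
    if np.all(denom <= 0):
        raise ValueError("zero total variance")
    r2m = var_f / denom
    r2c = (var_f + comp.sum(axis=1)) / denom
    shares = {k: float((comp[:, i] / denom).mean())
              for i, k in enumerate(comp_names)}
    shares["resid"] = float((post.sigma2["resid"] / denom).mean())
    return {
        "r2_marginal": float(r2m.mean()),
        "r2_conditional": float(r2c.mean()),
        "component_shares": shares,
        "r2_marginal_draws": r2m,
        "r2_conditional_draws": r2c,
    }


def diagnostics(post: Posterior, rhat_threshold: float = 1.05) -> pd.DataFrame:
    """Split-Rhat and effective sample size per scalar parameter."""
    import warnings

    import arviz as az

    params = {"alpha": post.alpha}
    for j, t in enumerate(post.terms):
        params[f"beta[{t}]"] = post.beta[:, j]
    for k, v in post.sigma2.items():
        if k == "beta" and not post.terms:
            continue  # untouched by the sampler in an intercept-only model
        params[f"sigma2[{k}]"] = v

    C, D = post.n_chains, post.draws_per_chain
    rows = []
    single = C < 2
    if single:
        import logging
        logging.getLogger(__name__).warning(
            "Rhat unavailable with a single chain")
    for name, draws in params.items():
        arr = draws.reshape(C, D)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1
                                                       else arr))["x"].values) \
                if not single else np.nan
            ess = float(az.ess(az.convert_to_dataset(arr))["x"].values)
        rows.append({"parameter": name, "rhat": rhat, "ess": ess,
                     "flagged": bool(rhat > rhat_threshold) if not single
                     else False})
    return pd.DataFrame(rows)
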