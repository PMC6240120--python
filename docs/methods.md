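# Methods

This note documents the models implemented in `frugicue`, the choices
made where the underlying field methodology leaves details open, and
what the synthetic-data tests do and do not demonstrate.

## Avian colour space

Reflectance spectra live on a fixed 300–700 nm grid with 5-nm steps.
Quantum catch of receptor i is the rectangle-rule integral
Q_i = Σ_λ R(λ) S_i(λ) I(λ) Δλ with each sensitivity curve S_i
normalized to unit area, so a flat spectrum under a flat illuminant
stimulates all cones equally. Relative catches (u, s, m, l) are the raw
catches divided by their sum.

**Receptor curves.** Measured, oil-droplet-corrected sensitivities of a
real retina are the gold standard; because such tables are
instrument-specific, the package ships parametric visual-pigment
templates instead — the Govardovskii A1 nomogram (alpha plus beta band)
or a Gaussian — with configurable peak wavelengths defaulting to
blue-tit-like values (371, 449, 502, 563 nm single cones; double cone at
the LWS peak). Users with measured curves can construct a `ReceptorSet`
directly. Oil-droplet filtering is not modelled separately; it is
treated as absorbed into whatever effective curves are supplied.

**Tetrahedron geometry.** The colour point is the catch-weighted mixture
of four fixed vertices of a regular tetrahedron with circumradius 0.75:
UVS at (0, 0, 0.75), LWS at (√0.5, 0, −0.25), MWS at
(−√0.125, √0.375, −0.25), SWS at (−√0.125, −√0.375, −0.25). Equal
catches land exactly at the origin (the achromatic point), and
chromaticity r = ‖(x, y, z)‖ ≤ 0.75. Published variants of tetrahedral
colour spaces differ from this one only by a rotation; this orientation
gives the conventional axis semantics (red +x, blue −x, green +y,
UV +z), which the tests verify with synthetic step spectra.

**Brightness.** The double-cone catch is divided by the catch of a
perfect reflector (R ≡ 1) under the same illuminant, making *a*
scale-free and confined to (0, 1] for physical reflectances. The
illuminant defaults to flat (ideal); a measured irradiance table may be
supplied. Two conventions the field leaves open are worth flagging: no
von Kries adaptation is applied (it cancels for relative catches under a
flat illuminant), and *a* is kept on the raw ratio scale here — the SEM
stage log-transforms it before modelling, which is where a
log-brightness convention would otherwise enter.

## Networks and diet profiles

Consumption rates are visitation rates (visits/h) times per-visit
consumption (fruits/visit). Missing per-visit rates are imputed by a
three-step ladder: the mean observed rate of the same plant–frugivore
pair in other networks; else the frugivore's mean over other plants;
else the global mean across frugivores. Every cell carries a provenance
flag (`observed`, `imputed-pair`, `imputed-frugivore-mean`,
`imputed-global-mean`), and an all-missing table is an error rather than
a silent fallback. A visitation-based network is available as a config
switch; when all per-visit rates are equal the two currencies give
identical ratio-based metrics, which the tests assert exactly.

Partner diversity uses the natural-log Shannon entropy (required for
e^H to be an effective number) over a frugivore's consumption shares,
divided by the number of plant species present in that seasonal network
— plants fruiting in the season, not the site's full list. Frugivores
with zero consumption in a network are dropped from that network's
metrics with a logged warning. Interaction strengths sum to one within
each network by construction.

Diet profiles are the interaction-weighted means
c̄_j = Σ c_i f_ij / Σ f_ij (colour) and
n̄_j = Σ n_i m_i f_ij / Σ m_i f_ij (nutrient intake per gram dry pulp,
weighted additionally by pulp mass m_i). Both are invariant to uniform
rescaling of f_ij and bounded by the consumed species' trait extrema.

Migratory distance is the absolute latitudinal distance (degrees)
between a site and a frugivore's wintering-range centroid, consumed as a
precomputed column; residents get 0. The default seasonal coding zeroes
the distance outside the pre-migration and migration periods (winter and
spring → 0; summer and autumn → distance); `raw` and
`period_interaction` codings implement the alternative models.

## Phylogenetic correlation

For tips k, l with root-to-tip depths d_k, d_l and root-to-MRCA shared
path t_shared, the correlation is C_kl = t_shared / √(d_k d_l): the
standardized shared-branch-length (Brownian-motion) matrix, with unit
diagonal and entries in [0, 1] on ultrametric trees, and a valid
correlation on non-ultrametric trees via the √(d_k d_l) scaling. No
branch-length transformation (e.g. Pagel's λ) is applied — none is
standard for this analysis — and scaling all branch lengths leaves C
unchanged. The sampler consumes the precision parameterization
C⁻¹, computed as the inverse of (C + ridge·I) with ridge 1e-8 and
escalation (with a logged warning) only for genuinely rank-deficient
matrices such as zero-length splits.

## Hierarchical model and sampler

The observation model is Gaussian:

    y_i ~ Normal(α + Σ_j θ_j X_ij + a_k[i] + v_k[i] + s_l[i] + t_m[i], σ_ε²)

with θ_j = I_j β_j (Kuo–Mallick indicator selection), a ~ N(0, σ_a² C)
the phylogenetic species effect, and iid species, site and season
effects. Priors: P(I_j = 1) = 0.5; β_j ~ N(0, σ_β²) shared across terms
with σ_β² ~ Uniform(0, 100) (global adaptation — the active terms set
the scale the inactive ones are refreshed from); α ~ N(0, 100²);
residual and random-effect standard deviations ~ Uniform(0, 100), a
weakly informative choice matching the style of the one prior the
methodology fixes (the uniform on σ_β²).

The Gibbs scan order is fixed: (1) α and each β_j (conjugate normal;
when I_j = 0, β_j is refreshed from its prior, keeping the chain
irreducible); (2) each I_j from its conditional Bernoulli odds
(prior odds times the residual-sum-of-squares likelihood ratio at the
current β_j); (3) σ_β² by a bounded slice step; (4) random-effect
vectors — the phylogenetic vector jointly from its multivariate normal
conditional using C⁻¹ (via a single precomputed eigendecomposition when
every species has the same replication, else a per-iteration Cholesky);
(5) variance components, drawn exactly from the truncated-gamma
conditional on the precision scale implied by the uniform-sd prior
(slice-step fallback for degenerate cases); (6) each missing response
from Normal(μ_i, σ_ε²), which is how trait augmentation borrows strength
from covariates and phylogeny and propagates its uncertainty downstream.

Chains are seeded `seed + chain` and initialized from over-dispersed
uniform draws (coefficients in ±2, sds in roughly (0.1, 5)); drawing
initial sds from the full Uniform(0, 100) prior would start chains at
absurd scales for standardized data, and the conditional updates forget
the initial value within a few sweeps anyway. The stock configuration is
8 chains × 26 000 iterations, burn-in 1000, thinning 100 (250 draws per
chain); tests and the acceptance script use reduced configurations
(2–4 chains, 1500–4000 iterations, thinning 2–10), sized so the full
suite runs on a desktop while leaving the Monte-Carlo error far below
the assertion tolerances.

Predictors and the response are z-standardized by default (after any log
transform), so effect sizes are comparable across equations; raw-scale
fitting is a flag. Whether the original field analyses standardized is
not documented; the default here is a package choice, not a claim about
those analyses.

**Summaries.** Selection probability P is the posterior mean of I_j;
evidence is 2·ln[(P/(1−P))/(p₀/(1−p₀))]. When P hits 0 or 1 under D
finite draws, the true odds are only bounded and the report is the bound
2·ln((D − 0.5)/0.5) with a `>` / `<` flag. Effect estimates are
posterior means of I_j β_j (shrinkage: excluded draws contribute zeros),
with percentile 95% intervals. r² is computed per retained draw —
marginal r²_m = var(Xθ)/(var(Xθ) + Σσ²_components + σ_ε²), conditional
r²_c adds the variance components to the numerator — then averaged;
per-component variance shares are reported the same way. Convergence is
summarized by split-R̂ (flagged above 1.05) and effective sample size
via ArviZ.

## SEM pipeline

Sub-model 1 regresses ln(pulp mass) on ln(diameter) with the plant
phylogeny; posterior draws of missing pulp masses are available for the
diet-profile weighting. The default propagation uses the posterior mean
per species; iterating the profile computation over draws is supported
and tested at reduced size, trading the full uncertainty propagation for
desk-scale runtime in the default path.

Sub-model 2 fits ln(lipid), ln(sugar), ln(protein), ln(anthocyanin)
each on (x, y, z, a) with selection enabled and the plant phylogeny;
missing nutrients are augmented.

Sub-model 3 fits eight equations: each diet-colour component on the
three frugivore traits, and each ln-intake on the traits plus the diet
colour profile, all with bird-phylogeny, species, site and season random
effects. Brightness, intakes, partner diversity and interaction strength
enter as natural logs; the chromatic coordinates, which may be negative,
stay raw. With fully observed tables the eight equations share no
unknowns, so the "joint" fit is implemented as one deterministic pass
with per-equation seeds derived from the master seed — identical to
independent fitting, which the tests assert by reproducing an equation
with a direct engine call. Indirect effects are full posterior
distributions of products of path draws along supported (BF > 2) chains.

The marginal selection probability of a colour component is its mean P
across the four nutrient responses (colour–reward model) or the mean P
of the three frugivore-trait predictors in its colour-profile equation
(SEM). The published methodology describes these two sources with
inconsistent sub-model labels in different sentences; this implementation
follows the summary tables (colour–reward model and fruit-choice SEM),
which is the reading consistent with the reported concordance figure.
The concordance analysis itself regresses pooled draw-level inclusion
indicators of the SEM's trait→colour paths on the matching component's
colour–reward marginal probability (binomial GLM); with only marginal
probabilities available it falls back to reconstructed counts, and
quasi-separation is flagged with a continuity correction rather than an
unbounded fit.

## Synthetic data

The generator emulates the statistical skeleton of a three-site,
four-season community study: an ultrametric pure-birth-style tree (unit
depth); plant brightness as a standardized latent with a configurable
phylogenetic share (default 0.5); ln-nutrients coupled to brightness
with slope sign·√(r²/(1−r²)) against unit-variance noise so the
population marginal r² equals its target (defaults: lipid +0.23, sugar
−0.11, protein 0, anthocyanin −0.35); chromatic coordinates drawn
independently of nutrients (the null the selection procedure should
respect); and visitation driven by
base + frugivore effect + γ_g·(generalism × brightness) −
γ_m·(migratory distance × brightness × migration period), with Poisson
counts at configurable effort (default 50 h — desk-scale totals of
~10³–10⁴ visits, not the field study's hundreds of thousands), lognormal
per-visit consumption with a masked fraction to exercise the imputation
ladder, and a recorded truth (slopes, preference coefficients, realized
expected rates and brightness profiles).

Reflectance spectra are optional and generated spectrum-first: a smooth
random shape (base level plus broad Gaussian bumps) is rescaled to the
species' target brightness — exact, since brightness is linear in
reflectance — and the table's (x, y, z, a) are then *derived* from the
spectrum, so the colour-space round trip holds by construction. The
alternative (inverting target coordinates into a spectrum) was rejected:
independently drawn chroma and brightness are frequently metamerically
unreachable by any physical reflectance under overlapping cone curves,
e.g. strong UV dominance combined with high double-cone brightness.

A second, direct generator (`sim_sem_observations`) produces the
fruit-choice SEM's observation table (~165 rows across 43 species,
3 sites, 4 seasons) with planted standardized paths at the published
effect scale (+0.4 partner diversity → brightness, −0.3 migratory
distance → brightness, +0.4/−0.4/−0.7 brightness → lipid/sugar/
anthocyanin) and null chromatic paths. It is the workhorse of the
recovery tests because it controls the estimand exactly, where the
network-level generator controls it only through the sampling process.

What passing these tests shows — and does not. Recovery on synthetic
data demonstrates that the sampler, selection and summaries are
internally correct at realistic dimensions and effect sizes. It does not
validate the observation process of real networks (detectability,
observer effects, taxonomic lumping are deliberately not modelled), and
tree-structured traits reduce the effective sample size, so
calibration-style checks of the r² targets use the independent-species
configuration; with a shared tree, empirical couplings at n = 44 scatter
widely around their targets, as they do in real communities.

## Numerical notes and limitations

* Spectra must be complete on the standard grid; no smoothing or
  interpolation is applied. An all-dark spectrum (zero total catch) is
  an error, not a NaN.
* The brightness round trip of synthesized spectra (when requested) is
  guaranteed only to 0.05 in (x, y, z, a); colour-space tests therefore
  operate on catches directly.
* Variance draws are bounded by the Uniform(0, 100) sd prior; a chain
  repeatedly pinned at the bound indicates a mis-scaled response and
  surfaces in the R̂/ESS report rather than being silently truncated.
* Responses with zero variance, predictors with missing values, and
  species absent from the correlation matrix raise immediately.
* Non-Gaussian responses, reversible-jump samplers, alternative
  selection priors, JND-based colour discrimination and network null
  models are out of scope.
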