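# frugicue

Do fruit colours tell frugivorous birds anything about the nutrients
inside, and do birds use that cue to regulate their diet? `frugicue` is
a reusable, tested pipeline for community-wide analyses of this question
in plant–frugivore networks. It is aimed at ecologists working with
seasonal interaction networks, fruit reflectance spectra and trait
tables, and at methodologists who want a transparent, scriptable
implementation of Bayesian hierarchical variable selection with
phylogenetic random effects.

The pipeline has four parts:

1. **Avian colour space** (`frugicue.colour_space`). Fruit reflectance
   spectra (300–700 nm, 5-nm steps) are converted to quantum catches of
   the four avian single cones, Q_i = Σ_λ R(λ)S_i(λ)I(λ)Δλ, and mapped
   into the tetrahedral colour space: chromatic coordinates (x, y, z)
   with the achromatic point at the origin (red +x, blue −x, green +y,
   UV +z; circumradius 0.75) and double-cone brightness *a*, normalized
   so a perfect reflector has a = 1. Receptor curves come from
   visual-pigment templates with blue-tit-like peaks, or from
   user-supplied tables.

2. **Networks and diet profiles** (`frugicue.network_diets`). Seasonal
   site networks of fruit consumption rates f_ij (visitation × per-visit
   consumption, with a documented imputation ladder for missing
   per-visit rates) yield each frugivore's partner diversity
   (e^H standardized by plant richness), interaction strength (share of
   total fruit removal), and interaction-weighted diet profiles:
   c̄_j = Σ_i c_i f_ij / Σ_i f_ij for colour and
   n̄_j = Σ_i n_i m_i f_ij / Σ_i m_i f_ij for nutrient intake per gram
   dry pulp.

3. **Hierarchical model engine** (`frugicue.bhm_engine`,
   `frugicue.phylo`). A Gibbs sampler for
   y_i ~ Normal(α + Σ_j I_j β_j X_ij + a_k + v_k + s_l + t_m, σ_ε²)
   with a phylogenetic random effect a ~ N(0, σ_a² C) built from shared
   branch lengths, Kuo–Mallick indicator variable selection with global
   adaptation (P(I_j = 1) = 0.5, β_j ~ N(0, σ_β²),
   σ_β² ~ Uniform(0, 100)), missing-response augmentation, and summaries
   matching field practice: shrinkage estimates (posterior mean of
   I_j β_j), 95% credible intervals, selection probabilities P,
   2·ln(Bayes factor), marginal/conditional r², split-R̂ and ESS.

4. **SEM pipeline** (`frugicue.sem_pipeline`). Three sub-models —
   allometric pulp-mass imputation, the colour–reward model (four
   nutrients on x, y, z, a across plant species), and the eight-equation
   fruit-choice SEM (colour profiles and nutrient intakes of frugivores
   on partner diversity, interaction strength and seasonally coded
   migratory distance) — plus a concordance analysis regressing SEM
   colour-path inclusion indicators on each component's colour–reward
   marginal selection probability.

A synthetic-data module (`frugicue.synthetic_data`) generates trees,
traits, spectra-equivalent colour coordinates and seasonal networks with
known generating parameters at the study's dimensions (44 plants, 43
birds, 3 sites, 4 seasons), so every stage can be validated against a
recorded truth.

## Worked example

```python
import numpy as np
from frugicue import sem_pipeline as sem
from frugicue import synthetic_data as sd
from frugicue.bhm_engine import McmcConfig

obs, bird_tree, truth = sd.sim_sem_observations(seed=4000)
res = sem.run_submodel3(obs, bird_tree,
                        config=McmcConfig(chains=4, iterations=4000,
                                          burn_in=1000, thin=10, seed=600))
row = res.paths.set_index(["response", "predictor"]).loc[
    ("diet_a", "partner_diversity")]
print(round(row["estimate"], 2), round(row["P"], 2), round(row["BF"], 1))
```

prints `0.45 1.0 15.6`: the planted partner-diversity → diet-brightness
path (+0.4 on the standardized scale) is recovered at 0.45, with
posterior inclusion probability 1.0 over the 1200 retained draws, so the
2·ln(Bayes factor) is reported as the finite-draw bound 15.6 ("> 15.6"),
decisive support. The `paths` table has one row per predictor and
equation; `res.indirect` lists mediated effects as products of posterior
draws along supported paths (here partner diversity → brightness →
lipid intake, and the migratory-distance routes to sugar and
anthocyanin).

The same engine reproduces the published concordance line from recorded
selection summaries alone:

```python
from frugicue import reference_tables as ref
m2 = sem.marginal_selection(ref.colour_reward_table(), axis="colour_reward")
m3 = sem.marginal_selection(ref.fruit_choice_table(), axis="sem")
conc = sem.concordance(m2, m3, n_draws=2000)
print(round(conc.intercept, 2), round(conc.slope, 2))
```

prints `-2.42 4.61` — the logistic fit of colour-path selection in the
fruit-choice SEM on colour–reward reliability.

There is also a thin CLI:

```bash
frugicue simulate --seed 1 --out sim/
frugicue build-networks --interactions sim/interactions.csv --out nets/
frugicue diet-profiles --interactions sim/interactions.csv \
    --plants sim/plants.csv --frugivores sim/frugivores.csv --out roles.csv
frugicue run-pipeline --plants sim/plants.csv --plant-tree sim/plant_tree.nwk \
    --observations roles.csv --bird-tree sim/bird_tree.nwk --seed 1 --out run/
```

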