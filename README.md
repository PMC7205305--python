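# gravmig

Cross-scale Bayesian gravity models of internal migration.

Subnational migration flows are often observed only at a coarse
administrative level (e.g. departments), while planning, vaccination and
epidemic-connectivity work needs origin–destination estimates at a finer
level (e.g. municipalities). `gravmig` fits a fine-scale spatial
interaction model directly to the coarse observations: fine-pair migration
proportions are predicted by a gravity-type logistic regression, aggregated
to coarse pairs by a population-weighted average, and confronted with the
observed counts through a binomial likelihood — so the fine-scale
coefficients are estimated without any fine-scale flow data.

## Model

For ordered fine-unit pairs (i, j), i ≠ j, the five-year migration
proportion is

```
logit(v_ij) = β0 + β1·DIST_ij + β2·POP_i + β3·POP_j + Σk βk·X_k
```

with covariates drawn from distance, populations, urban proportions,
per-capita economic product, population-percentile indicators (TINY,
MAJCEN, PERC) and contiguity (CONT). Continuous covariates are scaled to
mean 0, sd 0.5 and binary covariates centred to mean 0, range 1, so
coefficients are comparable across variables. Fine proportions aggregate to
coarse pairs (I, J) as

```
P_IJ = Σ_{i∈I} N_i (Σ_{j∈J} v_ij) / Σ_{i∈I} N_i
```

and the observed coarse counts M_IJ out of origin sample sizes N_I (a
census sampling fraction of the origin population) follow independent
binomials: M_IJ ~ Binomial(N_I, P_IJ), I ≠ J. Slopes carry Cauchy(0, 2.5)
priors and the intercept Cauchy(0, 10). Posteriors are sampled with
multi-chain adaptive random-walk Metropolis; convergence is monitored by
the Gelman–Rubin PSRF and models are compared by DIC, with forward stepwise
covariate selection starting from the basic gravity specification
{DIST_ij, POP_j, POP_i}. Fitted proportions convert to person flows,
aggregate exactly across nested partitions, and disaggregate uniformly for
broad-scale baselines; estimated and observed flow matrices are compared by
Pearson correlation (log10(x+1) scale by default).

A synthetic-landscape generator (nested units on a plane, log-normal
populations, Beta urban fractions, tessellation contiguity, binomial
sampling at a configurable census fraction) provides ground-truth studies
for every piece of the pipeline.

## Worked example

```python
import gravmig as gm

cfg = gm.LandscapeConfig(n_coarse=6, fine_per_coarse=5, seed=42)
units, adj, dist = gm.generate_landscape(cfg)
flows, truth = gm.simulate_flows(units, adj, dist, sampling_fraction=0.1, seed=43)

model = gm.GravityMigrationModel(n_chains=3, n_steps=20_000, thin=10, seed=44)
model.fit(units, flows, adjacency=adj, distances=dist)
print(model.summary_.round(3).to_string(index=False))
```

prints

```
parameter  median  ci_2.5  ci_97.5  rhat
Intercept  -5.995  -6.043   -5.948 1.002
  DIST_ij  -2.006  -2.139   -1.883 1.001
    POP_j  -0.112  -0.286    0.018 1.003
    POP_i   0.147   0.113    0.179 1.001
```

The generative coefficients were (−6.0, −2.0, −0.12, 0.16): every posterior
median lands within the 95% credible interval of its true value, with
R-hat ≈ 1 indicating the three chains mixed. Aggregating the fitted
fine-scale flows back to the coarse level and correlating with the observed
counts gives Pearson r = 0.997 on the log10(x+1) scale. `model.dic_`
(here 55524.9, with pD ≈ 4 ≈ the number of free parameters) is the
model-comparison score used by `ForwardDICSelector`.

The same workflow is scriptable from the shell via the `gravmig` command
(`simulate`, `fit`, `select`, `predict`, `validate`, `diagnose`), driven by
one YAML config plus a master seed; identical config and seed reproduce all
outputs byte for byte.

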