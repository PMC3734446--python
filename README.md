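# growthmap

Small-area Bayesian mapping of poor fetal growth.

Perinatal epidemiology often asks whether the incidence of an adverse birth
outcome varies geographically beyond what a known risk factor explains.
`growthmap` implements the full analytical chain for one canonical version of
that question: suburb-level counts of *poor fetal growth* — births whose
Proportion of Optimal Birth Weight (POBW, observed weight over the weight
expected from gestation, sex, parity and maternal height) falls strictly
below 80% — modelled against a standardised area socioeconomic index with
Besag–York–Mollié (BYM) convolution models. It is written for
epidemiologists and biostatisticians who want the whole pipeline — case
definition, adjacency construction, MCMC fitting, model comparison, effect
summaries and spatial tests — as reusable, tested Python.

## The model

For suburb *i* with *N<sub>i</sub>* eligible births and *R<sub>i</sub>* cases,

&nbsp;&nbsp;*R<sub>i</sub>* ~ Binomial(*N<sub>i</sub>*, *p<sub>i</sub>*)

four nested linear predictors are fitted:

| model  | logit(*p<sub>i</sub>*) |
|--------|------------------------|
| null   | β₀ |
| random effects | β₀ + *u<sub>i</sub>* + *v<sub>i</sub>* |
| fixed effect   | β₀ + β₁·*X<sub>i</sub>* |
| full   | β₀ + β₁·*X<sub>i</sub>* + *u<sub>i</sub>* + *v<sub>i</sub>* |

where *X<sub>i</sub>* is the socioeconomic index standardised to mean 0, SD 1
across the study area; *u* is a spatially-correlated random effect with an
intrinsic conditional autoregressive (ICAR) prior over the suburb adjacency
graph (scale σ<sub>u</sub>, sum-to-zero constrained); and *v* is an
exchangeable Normal(0, σ<sub>v</sub>²) effect. Priors are Normal(0, 100²)
for β₀, β₁ and half-Normal(scale 100) for both σ. Sampling is
Metropolis-within-Gibbs with chromatic (graph-coloured) single-site updates;
models are compared by DIC with pD = mean deviance minus the deviance at the
posterior-mean linear predictors. Between-suburb spread of any component is
reported as an **interquartile odds ratio** (IQOR): exp(q₇₅ − q₂₅) of the
per-suburb posterior-mean effects. Residual high-risk suburbs are flagged
when the posterior probability that exp(*u<sub>i</sub>* + *v<sub>i</sub>*) > 1
exceeds 0.90. Moran's I (values) and Oden's I_pop (cases/population)
provide frequentist checks of spatial pattern.

Because individual perinatal registries are confidential, the package ships
a first-class synthetic registry (`growthmap.simulate`): lattice suburb
geographies with an optional river whose banks are rejoined by flagged
supplementary adjacencies, spatially autocorrelated SES surfaces, counts
drawn from the convolution model with known parameters, and birth-level
records with eligibility fields, POBW missingness and an SGA
(small-for-gestational-age) indicator for the missing-data sensitivity
analyses.

## Worked example

```python
import pandas as pd
from growthmap import (SimulationParams, add_supplementary_edges,
                       contiguity_adjacency, generate_geography, generate_ses,
                       simulate_counts, BYMModel, McmcConfig, morans_i)
from growthmap.cohort import standardize_ses

geog = generate_geography(12, 12, river=True, seed=0)
adj = add_supplementary_edges(contiguity_adjacency(geog), geog, 0.5)
ses = generate_ses(geog, 0.8, seed=1)
tab = pd.DataFrame({"suburb_id": list(geog.ids), "ses_raw": ses.to_numpy()})
tab["ses_std"] = standardize_ses(tab["ses_raw"])
params = SimulationParams(beta1=-0.25, sigma_u=0.3, sigma_v=0.2, seed=2)
tab = simulate_counts(tab, adj, params)

res = BYMModel(tab, adj, "full").fit(McmcConfig(seed=3))
print(res.summary())
```

```
BYM binomial-logit model (full), 144 suburbs
  retained draws: 4000 (iterations 60000, burn-in 20000, thin 10)
  DIC = 19069.3   pD = 61.4
  p    = 0.049 (0.047, 0.051)
  b1   = -0.30 (-0.37, -0.23)
  sigma_u = 0.378 (0.229, 0.546)
  sigma_v = 0.133 (0.026, 0.218)
  Geweke z: beta0: +0.39, deviance: +1.70, beta1: -0.03, sigma_u: +0.25, sigma_v: -0.13
```

The fit recovers the generating conditions: the mean incidence sits at the
5% used to simulate (`p = 0.049`), the socioeconomic slope credible interval
contains the generating −0.25, and both random-effect scales are credibly
positive. Continuing,

```python
moran = morans_i(tab["ses_std"], adj, n_permutations=999, seed=4)
print(f"Moran's I of the SES surface: {moran.statistic:.2f} (p = {moran.p_value:.3f})")
print(f"IQOR, SES effect:             {res.iqor('ses'):.2f}")
print(f"IQOR, combined random effects: {res.iqor('u_plus_v'):.2f}")
print(f"Spatial share of RE variance:  {res.variance_partition():.2f}")
print(f"Suburbs flagged (P>0.90 of OR>1): {int(res.exceedance()['flagged'].sum())}")
```

```
Moran's I of the SES surface: 0.46 (p = 0.001)
IQOR, SES effect:             1.42
IQOR, combined random effects: 1.35
Spatial share of RE variance:  0.72
Suburbs flagged (P>0.90 of OR>1): 23
```

The IQOR of 1.42 says the odds of poor fetal growth at the 75th-centile
suburb of the SES effect are 42% higher than at the 25th-centile suburb;
the exceedance count is the number of suburbs whose residual odds ratio
exceeds 1 with posterior probability above 0.90.

A complete two-period run (simulate → fit 4 models × 2 periods → summaries
→ spatial tests, with a manifest of seeds and artifact checksums) is

```bash
growthmap pipeline --config run.yaml
```

with `simulate`, `fit`, `summarize` and `test-spatial` available as
stand-alone subcommands.

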