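# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `growthmap`, at the level of
detail a maintainer or reviewer needs to interpret the test suite.

## Cohort and case definition

Birth records are restricted to liveborn singletons of at least 33 completed
weeks gestation with a non-null POBW, in that order of precedence; the
filter logs one exclusion reason per record, so reasons partition the input.
The case threshold is strict: POBW < 0.80 is a case, exactly 0.80 is not
("under 80%"). SGA is likewise strict (birthweight strictly below the
sex-by-gestation 10th centile). The SES index is standardised to mean 0,
SD 1 with the population SD (divisor *n*); the convention is fixed here
because the index's own standardisation convention is not part of its
public description.

Missing-POBW sensitivity machinery:

* **2×2 odds ratio** with the Woolf log-scale 95% CI,
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)); zero cells require an explicit
  continuity-correction flag (+0.5 to all cells).
* **Breslow–Day homogeneity** of the odds ratio across SES-quintile strata:
  the classic statistic against the Mantel–Haenszel common OR (no Tarone
  correction), df = strata − 1. The expected cell count solves the standard
  quadratic and is taken in the admissible margin range.
* **Goodness-of-fit** of SGA cases among POBW-null records to model-fitted
  probabilities: each contributing suburb (≥1 null record) enters as a
  binomial two-cell Pearson term (O−E)²/(E(1−p̂ᵢ)) with E = n_null,i·p̂ᵢ;
  df = contributing suburbs − 1. The two-cell form is used because the
  one-cell version (dividing by E only) under-disperses against its
  chi-square reference for non-negligible p̂ and fails calibration under
  the null; with the two-cell form the p-value is uniform under data drawn
  from the fitted probabilities (tested by KS).

Degenerate inputs are errors, not silent results: constant vectors for
standardisation or correlation, zero-margin strata, null POBW passed to the
classifier, reference-table gaps.

## Adjacency

Queen contiguity (shared boundary *or* vertex) from unit footprints, using
shapely predicates; symmetric and irreflexive by construction, validated on
every constructor and on GAL read. A river is modelled geometrically: the
lattice is physically split by a 0.3-cell gap, so contiguity across it is
genuinely severed, and `add_supplementary_edges` rejoins bank pairs whose
footprints lie closer than a threshold (default 0.5 cell units, the
analogue of a "less than 1 km" rule), flagging those edges as
supplementary. Boundary-to-boundary distance is used rather than centroid
distance. Study-area filtering applies three rules with fixed precedence —
more than 50% of area outside the urban area, zero births in at least one
period, missing SES — logging the first matching reason per unit;
filtering is idempotent and restricting an adjacency never creates edges.
Units left neighbourless are retained as islands.

## The BYM models

Counts are binomial with logit link; the four nested predictors are the
null, random-effects, fixed-effect and full models described in the README.
Priors: Normal(0, 100²) on β₀ and β₁; half-Normal with scale 100 on both
random-effect SDs. The ICAR prior is the pairwise-difference form
−Σ_edges (uᵢ−uⱼ)²/(2σ_u²), i.e. uᵢ | u₋ᵢ ~ N(mean of neighbours, σ_u²/nᵢ),
identified by a sum-to-zero constraint per connected component; islands are
pinned at uᵢ = 0 and contribute nothing to the prior.

**Sampler.** Metropolis-within-Gibbs with Gaussian random walks:

* β₀ and β₁ scalar updates;
* *u* updated site-wise but in graph-coloured blocks (DSATUR colouring):
  within a colour class no two sites are neighbours, so all sites in a
  class have conditionally independent acceptances and are updated as one
  vectorised step;
* *v* updated elementwise in one vectorised step;
* σ_u, σ_v by random walks on the log scale, with the ICAR pseudo-density
  σ_u^−(n−c)·exp(−SS/2σ_u²) (n = non-island units, c = components) and the
  half-normal prior, including the log-scale Jacobian.

After each sweep *u* is re-centred to sum to zero; when the graph is a
single component covering all units the removed mean is absorbed into β₀
(an exact likelihood-preserving move), otherwise each component is
re-centred without compensation, the standard practical treatment of the
improper ICAR level. Proposal scales adapt toward 44% acceptance in windows
of 100 sweeps **during burn-in only**, so the post-burn-in chain is a
fixed-kernel Markov chain. All randomness flows from one integer seed;
same-seed runs are bit-identical.

**Defaults.** 60,000 iterations, 20,000 burn-in, thinning 10 (4,000
retained draws). These desk-scale defaults keep a 250-suburb full-model fit
to roughly ten seconds while leaving Monte Carlo error well below the
reported precision; the original six-figure run lengths remain available
through `McmcConfig`. Convergence is monitored with the Geweke diagnostic
(first 10% vs last 50%, spectral density at zero via a Bartlett-windowed
autocovariance sum with √m lags) on β₀, β₁, σ_u, σ_v and the deviance; any
|z| > 3 raises a `ConvergenceWarning` carrying the offending values rather
than failing silently.

**DIC.** The deviance omits the binomial-coefficient constant (it cancels
in every comparison). pD = mean deviance − deviance at the posterior means
of the per-suburb linear predictors (the "stochastic parents" plug-in);
this convention matters — pD is plug-in-dependent — and with it the null
and fixed-effect models show pD ≈ 1 and ≈ 2, their free-parameter counts,
on any data. DIC = mean deviance + pD. Fewer than 100 retained draws is an
error.

Open interpretive choices, resolved as follows: the credible interval for
the mean probability *p* reports inverse-logit(β₀), i.e. the mean-SES
suburb, not the marginal mean over suburbs; the variance partition
σ²_u/(σ²_u+σ²_v) is computed from the empirical across-suburb variances of
the sampled *u* and *v* vectors (mean over retained samples), because the
ICAR σ_u is a conditional scale and not comparable to σ_v as a
hyperparameter — the hyperparameter reading is available behind a flag.

## Effect summaries

IQOR = exp(q₇₅ − q₂₅) of per-suburb posterior-mean effects, with
linear-interpolation quantiles (the convention is fixed because at a few
hundred suburbs the quantile rule visibly moves the third digit). The SES
component uses mean(β₁)·Xᵢ per suburb — posterior-mean effect size, like
the random-effect components — rather than averaging per-sample IQORs.
Exceedance is the fraction of retained samples with uᵢ + vᵢ > 0; under the
full model this is automatically adjusted for SES because the β₁·X term is
excluded from the component. Between-period stability is the plain Pearson
correlation of aligned per-suburb summaries.

## Spatial tests

Moran's I uses binary weights from the adjacency (row-standardisation
available), with upper-tail permutation inference (default 9,999
permutations) or the normal approximation under randomisation; the two
agree in accept/reject on simulated lattices. Oden's I_pop is defined here
as the individual-level Moran's I of case indicators: every person carries
0/1, persons in adjacent suburbs get weight 1, persons within the same
suburb get weight 1, self-pairs are excluded. This admits both an exact
closed form on the aggregates (the implementation) and a literal
individual-expansion oracle (shipped as `oden_ipop_bruteforce`); the two
agree to 10⁻¹⁰. The statistic is invariant to relabelling and, up to an
O(1/min population) within-suburb correction, to proportional scaling of
cases and populations. Inference redistributes the observed case total
multinomially proportional to population (conditional randomisation),
since the form of inference used by proprietary implementations is not
documented.

## Synthetic registry

The generator reproduces the structural conditions the analysis assumes,
not any real place:

* **Geography**: unit-square lattices (a 16×17 lattice ≈ the 267-suburb
  scale after filtering); optional river as a physical 0.3-cell gap.
* **SES surface**: kernel-smoothed white noise — y = (1−s)e + s·My iterated
  ⌈s/(1−s)⌉ times with M the row-normalised queen adjacency of the gapless
  lattice (a river does not interrupt a city's socioeconomic gradient).
  s = 0 returns the iid field; s = 0.9 yields Moran's I ≈ 0.5–0.7 on a
  20×20 lattice. Values are rescaled to a census-like mean 1000, SD 100 and
  standardised downstream.
* **Counts**: births per suburb Poisson(mean 330, floored at 1) — chosen as
  the simplest total model consistent with a ~45,000-birth, ~270-suburb
  period; the true distribution of suburb totals in real registries is not
  modelled. *u* is drawn from the ICAR distribution by spectral
  pseudo-inverse of the per-component graph Laplacian (sum-to-zero exact,
  islands 0), *v* iid normal, and cases binomial through the logit link.
  True *u*, *v*, *p* are recorded for recovery tests.
* **Births**: per-suburb records whose POBW ratio is Normal(mᵢ, 0.125) with
  mᵢ set so P(POBW < 0.8) equals the suburb's generating probability;
  birthweight = POBW × expected weight, where the expected-weight function
  (a smooth gestation curve times sex, parity and maternal-height factors)
  is deliberately simple and documented — it is *not* the published POBW
  regression. The packaged SGA table is likewise synthetic: the 10th
  centile is placed 1.2816 ratio-SDs below the sex-specific median, so SGA
  behaves as a correlated-but-distinct alternative outcome. Default
  parameters: ~5% poor fetal growth, 1.5% baseline POBW missingness (the
  higher-missingness regime and a size-biased missingness tilt are
  parameters), small admixtures of stillbirths, twins and <33-week births
  for the eligibility filter to remove.

What passing tests on these data do **not** show: robustness to irregular
polygon geometries, non-Gaussian SES fields, informative birth-total
processes, overdispersion beyond the convolution structure, or any property
of a specific real registry.

## Problem sizes used in the checks

Parameter-recovery runs use 250 suburbs × 400 births (five seeded
replicates at the default MCMC settings; generating values β₁ = −0.25,
σ_u = 0.3, σ_v = 0.2 are required inside their 95% credible intervals in at
least four). Model-selection and SES-dominance replications use 20 seeds at
150 suburbs × ~300 births with 30,000/10,000/10 MCMC — DIC orderings and
IQOR comparisons are stable well below the default run length. Calibration
suites use 200 replicates (Moran permutation p uniformity; Geweke on iid
chains). These sizes are the package's reference experiment design and are
what `tests/test_acceptance.py` runs.

## Known limitations

* Single-chain sampler; between-chain diagnostics (R̂) are not computed.
* The ICAR impropriety is handled by re-centring, not by a constrained
  parameterisation; multi-component graphs re-centre without absorbing the
  shift into β₀ (exact only for connected graphs, which all shipped
  geographies are after supplementary edges).
* No proper-CAR or Leroux alternatives; no joint spatio-temporal model —
  periods are fitted separately by design.
* GeoJSON export assumes planar coordinates; no projections.
* The frequentist I_pop has several published variants; only the
  individual-expansion form defined above is implemented.
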