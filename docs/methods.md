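# Methods

## The scientific question

Across North American migratory songbirds, four decades of collision-salvaged
museum specimens show declining body size together with rising wing length.
Whether the wing-length increase is a climate response, a compensation for
shrinking bodies, or neither, can be separated by tracking *static allometry*
— the within-species, within-stage scaling of log wing length on log body
size — through time. If wings lengthen uniformly, the allometric intercept
rises; if the change depends on body size, the allometric slope moves too.
This package implements that analysis as a reusable, fully testable pipeline:
specimen preparation, climate-window covariates, a hierarchical Bayesian
varying-intercept/varying-slope model, probability-of-direction effect
tables, and a generative twin of the model for parameter-recovery
verification.

## Data preparation

Specimens carry species, collection year, ordinal date, season
(spring/autumn), age class (HY = hatch-year, AHY = after-hatch-year), sex,
tarsus length (mm; the body-size index) and relaxed wing length (mm).
Records missing any model-relevant field are dropped and counted. Gross
measurement errors are screened per species with a median-absolute-deviation
filter on the *raw* measurements: a record is removed if either trait lies
more than `k = 5` raw MADs (no 1.4826 consistency constant; a config switch
adds it) from the species median. Filtering is single-pass and precedes the
log transform. Survivors are log-transformed and standardized to mean 0 /
sample s.d. 1 (denominator n−1) within species, so the allometric intercept
reads as mean wing length at mean body size and effects are comparable
across species. Each record maps to one model population: HY (autumn by
definition — spring birds cannot be aged HY and such records are a
validation error), AHY-spring, or AHY-autumn. Species left with fewer than
two records, or zero log-variance in a trait, cannot be standardized and are
excluded with a logged warning. Sex is coded female = 0, male = 1
(configurable). The complete-case rule is configurable (`required_fields`)
because reasonable analyses differ on whether records missing phenology
fields should still enter the morphology model.

## Climate windows and the design matrix G

Each species' peak migration window is its mean ordinal collection date ±1
sample s.d., pooled across years, rounded to whole days (ties away from
zero) and clamped to [1, 366]; both ends are inclusive. The pre-breeding
window is the 30 days after the spring window ends; a window that would
cross 31 December is an error rather than silently wrapped, since no
wrap-around rule is defined for these temperate-breeding species. Breeding
and wintering are fixed calendar months (June, December). Daily series
(range-averaged min/max temperature and precipitation) aggregate as window
means — mean daily temperature is the max/min midpoint, and minimum rather
than mean temperature is used over the migratory range because these species
migrate at night; June/December values come from monthly products
(temperature anomalies against a 1951–1980 baseline, and precipitation).
Lagged terms for year y read the seasonal value of year y−L.

Each climate covariate, and by default the year term, is standardized to
mean 0 / s.d. 1 *within species* over the modelled year range. Scaling year
per species puts the temporal trend on the same standardized scale as the
climate effects; `scale_year=False` is available since the convention is not
forced by the model. G carries an explicit constant column because the
effect tables report an "(intercept)" term for both the allometric intercept
and slope regressions. Leap days participate naturally; ordinal dates are
taken as given.

Default per-population covariate lists encode the outcome of the upstream
individual-level screening stage (spring-migration temperature excluded
throughout): the HY model uses prior wintering temperature/precipitation
(lag 1), pre-breeding and breeding conditions of the collection year, and
year; the AHY models use the analogous most-recent and prior-season terms
(lags 1–2).

## The hierarchical model

For one population, with w and z the scaled log wing and body size of
specimen i in species-year cell y of species p, and s ∈ {0, 1} the sex:

    ŵ_i      = β0_y + β1_y·z_i + n0_p·s_i + n1_p·s_i·z_i
    w_i      ~ Normal(ŵ_i, σ_w)
    β*_y     ~ Normal(β̂*_y, τ*),   β̂*_y = I*[p,·]·G[y,·]
    I*[p,c]  ~ Normal(μ*[c], σ*[c])
    n*_p     ~ Normal(m_n*, s_n*)
    μ, m_n   ~ Normal(0, 2)
    all scales (σ_w, τ*, σ*[c], s_n*) ~ half-Cauchy(0, 5)

`*` is 0 (intercept) or 1 (slope). The global effects μ are the scientific
output: how climate and year shift the allometric intercept and slope across
species. Design choices where the model statement leaves room:

- one shared observation noise σ_w per fitted population (a per-species
  switch exists but is off by default);
- separate τ0/τ1 for intercept vs slope deviations;
- the sex effects are a two-level hierarchy, n*_p ~ Normal(m_n*, s_n*) with
  Normal(0,2)/half-Cauchy(0,5) hyperpriors, shared across species;
- sex enters only the individual-level regression, not the climate layer;
- half-Cauchy means Cauchy(0, scale) truncated to (0, ∞);
- species-year cells present in the specimens but absent from G (or vice
  versa) are dropped with a logged warning.

## Inference

Sampling is the No-U-Turn Sampler with analytic gradients, implemented in
`wingallometry.nuts` (recursive tree doubling with slice sampling,
dual-averaging step-size adaptation toward a target acceptance of 0.9 by
default, and a diagonal mass matrix re-estimated in expanding warmup
windows). Because the likelihood is Gaussian and linear in the cell-level
parameters, it is collapsed onto per-(cell, sex) sufficient statistics
(N, Σz, Σz², Σw, Σwz, Σw²), so one gradient evaluation costs the same for
40 or 40,000 specimens.

Hierarchical posteriors mix poorly when a level's parameterization fights
its information content: non-centering is right when the level prior
dominates, centering when the data do. Neither choice works across the
regimes this package must handle (weak-pooling OLS-limit checks want
centered β; tight-hierarchy recovery runs want non-centered β but centered
I). `fit` therefore runs a cheap empirical-Bayes pre-pass — per-cell OLS
from the sufficient statistics, then method-of-moments estimates of σ_w, τ,
σ and s_n — and uses it to (i) choose centered vs non-centered
independently for the β, I and n levels (a level is centered when its
measurement variance is below its estimated hierarchical variance), (ii)
start every chain at the moment estimates with a small jitter, and (iii)
seed the mass matrix from the local Gauss–Newton curvature. Explicit
overrides (`parameterization="centered"`, `"noncentered"`, or a per-level
dict) are available; prior-only sampling always uses the non-centered form.
The chosen flags are recorded in the fit diagnostics.

Scale parameters sample on the log scale with the Jacobian included.
Extremely large |log scale| (> 50) is treated as off-support so divergent
trajectories cannot overflow. The gradient evaluator has two
implementations asserted equal in the tests: a readable numpy reference and
a numba-compiled kernel (~20× faster) used automatically when numba is
importable. During warmup, windowed mass-matrix estimates are shrunk toward
the curvature-based starting metric rather than a fixed diagonal, because
the coordinate scales span orders of magnitude. `fit_robust` wraps `fit`
with the standard practitioner remedy for a failed convergence flag:
refit (up to twice) with the acceptance target raised to 0.99 and a fresh
derived seed — the decision keys only on the convergence diagnostics.
Defaults follow the full-scale convention:
4 chains × 4000 iterations with the first 2000 discarded; the desk-scale
tests use 2 chains and 600–1000 iterations, which the verification results
below show is sufficient at those problem sizes.

Convergence is summarized by split-chain R̂ computed per scalar parameter
(+∞ on zero-variance chains); a fit whose maximum R̂ exceeds the threshold
(default 1.05) completes with a warning and `converged=False` — never
silently. Divergent transitions are counted and reported. A modest number
of divergences is expected near the half-Cauchy funnel tips when only five
species inform a between-species scale; the global effects μ are robust to
them in the recovery experiments, but the reported σ/τ tails should be read
with that caveat.

## Posterior summaries

Effects are reported as posterior mean, s.d., and probability of direction
(pd): the share of pooled post-warmup draws agreeing in sign with the
majority, in [50%, 100%]; exact zeros count toward neither sign but stay in
the denominator. Effects with pd ≥ 90% are emphasized (bold in the text
renderer). Rows follow the model's covariate order: intercept block then
slope block, global rows (μ) then species rows (I). pd is computed from
draws pooled across chains; rounding to two decimals happens only at export.

## The synthetic-data generator

`simulate_dataset` is the generative twin of the model: climate covariates
are stationary AR(1) series per species (unit marginal variance, lag-1
autocorrelation 0.3 by default, optional linear trend in s.d. units/year);
I rows, β cells, sex effects and observations are drawn exactly as the model
assumes. Truth lives on the scaled (z, w) space. Raw measurements are
produced by inverting fixed log-scale parameters (tarsus log-mean 3.0 ≈ 20
mm, wing log-mean 4.2 ≈ 67 mm, log-s.d. 0.05); the emitted mm values are
winsorized at 4.5 MADs per species so the synthetic CSV emulates bounded
biological measurements and round-trips the 5-MAD screen without losses
(truth-space z/w are never clipped). Everything is bitwise reproducible from
the config seed via named seed-sequence streams.

Default study conditions: 5 species, years 1981–2016, 40 specimens per
species-year, three climate covariates plus year. Default effects follow
the fitted HY-model magnitudes (intercept 0.47 / slope 0.11 at the constant,
year effects +0.18 / −0.02, climate effects of order ±0.03); the remaining
variance components are not printed anywhere and were fixed once at
realistic values: between-species s.d. 0.05 (0.1 for the constant), τ =
0.05, observation noise σ_w = 0.8 on the scaled-wing axis (allometry
explains a minority of within-cell wing variance in such data), male
intercept advantage 0.2 with between-species s.d. 0.05, even sex ratio.

Scenario presets encode the canonical shift patterns that accompany longer
wings: `intercept_shift` (+0.2 year-on-intercept, 0 on slope: all birds'
wings lengthen alike), `slope_up` (+0.1 on slope: larger birds lengthen
more) and `slope_down` (−0.1: smaller birds lengthen more).

What the generator does **not** emulate: spatial range structure,
collision-sampling bias, phenological trends, measurement error beyond
additive Gaussian noise, and the empirical re-standardization drift — when
synthetic specimens round-trip through the preparation stage, z and w are
re-scaled against the realized sample, so pipeline-level intercepts are
relative to the sample mean rather than the generator's truth (parameter
recovery therefore fits on the truth-space z/w, and the pipeline round trip
is checked separately for sign/trend fidelity). Passing tests demonstrate
the machinery is correct under the model's own assumptions; they cannot
certify behaviour under real-data pathologies outside them.

## Verification design

- **Density oracle**: the hand-coded log joint equals an independently
  written scipy.stats observation-by-observation sum on 100 random tiny
  instances to 1e-8; analytic gradients match finite differences in all
  eight parameterization combinations.
- **Counting oracles**: the MAD mask and pd match brute-force loop
  recomputations on 1000 random vectors each.
- **OLS limit**: with a weak hierarchy (τ = 1, σ_w = 0.2) and 500 specimens
  per cell, posterior means of every β0_y/β1_y match per-cell least squares
  of w on {1, z, s, s·z} within 0.05, across 5 seeds.
- **Recovery**: 20 replicate simulate-and-refit rounds at the default study
  conditions (2 chains × 1000 iterations; target acceptance 0.95): every
  global μ is covered by its 95% credible interval in ≥ 18/20 replicates,
  and the year-on-intercept bias is below 0.03.
- **Scenario fidelity**: each preset reproduces its year-effect sign pattern
  in ≥ 4/5 seeds. The "slope ≈ 0" pattern of the intercept-shift preset is
  operationalized as |posterior mean| below half the preset slope magnitude;
  a pure "pd < 90" reading would be a coin flip for a true-zero effect
  (pd of a null effect is approximately uniform), so the magnitude criterion
  is the meaningful reading of "no slope shift". The +/− patterns require
  the matching sign at pd ≥ 90, the same emphasis rule the tables use.

Problem sizes in the test suite (numbers of species/years/specimens, chain
counts and iteration counts) were chosen so the whole verification runs on a
single CPU in minutes while leaving each check statistically meaningful; the
full-scale convention (4 × 4000 iterations) remains the default of
`SamplerConfig`.

## Known limitations

- Divergences are not eliminated near half-Cauchy funnel tips (few-species
  regimes); hierarchical scale tails are the least reliable part of the
  posterior.
- The split-R̂ threshold (1.05) on 2 × 500 draws is a pragmatic flag, not a
  guarantee; the recovery experiment records and excludes flagged
  replicates rather than hiding them.
- Phylogenetic covariance is deliberately omitted (the upstream screening
  found low phylogenetic signal); model comparison and posterior-predictive
  graphics are out of scope.
- Windows are pooled across years; per-year phenology windows, and
  pre-breeding windows that would cross the year boundary, are not
  supported.
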