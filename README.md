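# wingallometry

Hierarchical Bayesian analysis of wing-length allometry in migratory
songbirds: does climate — or anything that tracks calendar time — shift the
within-species scaling of wing length on body size?

Museum collections of collision-salvaged passerines provide dense
morphological time series: tens of thousands of birds measured by one
person over four decades, with species, date, age class (hatch-year vs
after-hatch-year), sex, tarsus length (the body-size index) and wing length.
Across such series, body size has declined while relative wing length has
increased. This package implements the analysis that separates the candidate
explanations by modelling *static allometry* — for each species-year cell y,
the regression of scaled log wing length w on scaled log body size z —

    ŵ = β0_y + β1_y·z + n0_p·s + n1_p·s·z          (sex s ∈ {0,1})

with the allometric intercepts and slopes themselves regressed, per species
p, on standardized climate covariates and year (the matrix G):

    β*_y ~ Normal(I*[p,·]·G[y,·], τ*),   I*[p,c] ~ Normal(μ*[c], σ*[c])

under weakly informative priors (μ ~ Normal(0, 2), scales ~ half-Cauchy(0, 5)).
The global effects μ — how wintering/pre-breeding/breeding temperature and
precipitation, and the year trend, move the allometric intercept and slope —
are the scientific output, reported with posterior mean, s.d. and
probability of direction (pd; effects with pd ≥ 90% are emphasized).

The package is organised as an analysis pipeline over a library:

- `wingallometry.morpho` — specimen ingestion, 5-MAD outlier screening,
  per-species log standardization, model-population assignment;
- `wingallometry.climate` — migration/pre-breeding window derivation from
  collection phenology, daily/monthly climate aggregation, the species-year
  design matrix G;
- `wingallometry.model` — the hierarchy above, fitted with an in-package
  No-U-Turn sampler using analytic gradients over per-cell sufficient
  statistics; split-R̂ and divergence diagnostics;
- `wingallometry.summary` — mean / s.d. / probability-of-direction effect
  tables;
- `wingallometry.simulate` — a generative twin of the model (known truth,
  seeded, AR(1) climate, scenario presets) so every stage is verifiable by
  parameter recovery without any downloads;
- `wingallometry.cli` — the `wingallom` command
  (`simulate | prepare | windows | run-all | recover`) over YAML configs.

The numbered scripts under `analysis/` run a small end-to-end demonstration
and write their outputs under `results/demo/`.

## Worked example

```sh
python analysis/01_simulate.py   # 5 species x 20 years x 30 birds, known truth
python analysis/02_prepare.py
python analysis/03_windows.py
python analysis/04_fit.py
python analysis/05_summarize.py
```

Step 01 reports the generator's truth:

```
wrote 3000 specimens for 5 species x 20 years
true year effect on intercept: +0.180, on slope: -0.020
```

Step 04 fits the hierarchy (2 chains here; the full-scale convention is
4 chains × 4000 iterations with 2000 discarded as warmup):

```
fit 3000 specimens over 100 species-year cells; max split-Rhat 1.021, 63 divergences
```

and step 05 prints the global effect table:

```
target                 term                            mean     sd  pd
allometric_intercept   **const**                      -0.16   0.03  100.0% (-)
allometric_intercept   **breeding_temp**              -0.08   0.04  97.5% (-)
allometric_intercept   breeding_precip                -0.01   0.13  54.4% (-)
allometric_intercept   wintering_precip               -0.03   0.04  80.4% (-)
allometric_intercept   **year**                        0.21   0.08  99.2% (+)
allometric_slope       const                           0.05   0.07  81.2% (+)
allometric_slope       **breeding_temp**               0.04   0.03  93.2% (+)
allometric_slope       breeding_precip                -0.01   0.04  59.9% (-)
allometric_slope       wintering_precip                0.05   0.09  76.2% (+)
allometric_slope       year                            0.04   0.07  78.7% (+)

year effect on the allometric intercept: +0.208 +/- 0.077 (pd 99.2%)
```

Read: wings lengthened through time at all body sizes (year effect on the
intercept +0.21 ± 0.08, pd 99.2%, covering the simulated truth of +0.18)
without a credible change in the allometric slope — the pattern in which
body size does not mediate the wing-length increase. Intercept-block
estimates after the pipeline's re-standardization are relative to the
realized sample mean, which is why the constant term differs from the
generator's truth while the climate and year effects recover theirs.

`python analysis/06_recovery.py` runs a small simulate-refit-compare loop
and prints per-effect bias, RMSE and credible-interval coverage.

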