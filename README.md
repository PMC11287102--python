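# tempyll

Temperature–mortality burden analysis on **years of life lost (YLL)**: a
three-stage time-series pipeline for multi-city studies of how daily mean
temperature shifts the mortality burden, with the burden split into cold
and heat components.

Intended for environmental-epidemiology work where the outcome is a daily
YLL series (each death weighted by its residual life expectancy) rather
than a death count, and where city-specific temperature–YLL curves must be
pooled and their spatial heterogeneity explained.

## The model

**Stage 1 — city-level distributed-lag nonlinear model (DLNM).** For each
city, daily YLL is regressed on a temperature×lag cross-basis plus
confounders, with Gaussian errors (daily YLL is approximately normal):

```
YLL_t = α + CB(Temp; t, lag 0..21) β + NS(time, 7 df/yr)
        + NS(RH, 3) + NS(SD, 3) + NS(WS, 3) + NS(AP, 3)
        + γ·DOW_t + δ·Holiday_t + ε_t
```

The temperature basis is a quadratic B-spline with internal knots at the
27.5th/72.5th percentiles of the city's daily mean temperature (4 columns);
the lag basis is a natural cubic spline over lags 0–21 days with knots
equally spaced on the log scale (4 columns). The 16 cross-basis
coefficients are reduced to the overall cumulative exposure–response curve
`η` (4 coefficients + covariance) by summing the lag dimension.

**Stage 2 — multivariate meta-regression.** The city curves `η_i ~ N(X_i μ,
S_i + Ψ)` are pooled by maximum likelihood. Heterogeneity is quantified by
the multivariate Cochran *Q* and *I*² = max(0, (Q − df)/Q)·100; city-level
meta-predictors (longitude, urbanization rate, GDP per capita, …) enter one
at a time and are tested with a Wald χ² on their 4 coefficients; models are
compared by AIC.

**Stage 3 — attribution.** Each city's BLUP curve defines its minimum-YLL
temperature (MMT). Days below/above the MMT contribute cold/heat
attributable YLL `a_t = B(x_t)η − B(MMT)η` (identity link — no relative-risk
transform), and the attributable fraction is AF = Σa_t / ΣYLL_t, pooled
across cities as a ratio of sums. 95% empirical CIs come from 1000 Monte
Carlo redraws of the curve coefficients.

A synthetic-data generator produces multi-city daily series from a known
V-shaped lagged truth, together with a brute-force oracle for the true AF,
so the whole pipeline is testable without access to any mortality registry.

## Worked example

```bash
tempyll simulate --out-dir data --n-cities 4 --seed 7
tempyll run --series-glob 'data/city*.csv' --meta-csv data/meta_predictors.csv \
            --out-dir results --n-mc 1000 --seed 7
```

which prints

```
wrote 4 city series to data
pooled AF: total 5.75% (eCI 5.08..6.48), cold 3.39%, heat 2.36%
```

— the share of all simulated YLL attributable to temperatures away from the
minimum-YLL temperature (total), split into the part from days colder than
the MMT and the part from warmer days, with the 95% empirical CI of the
total. `results/` then holds `city_curves.csv` (per-city reduced-curve
coefficients and BLUPs), `heterogeneity.csv` (Wald/AIC/Q/I² per
meta-predictor) and `attribution.csv` (per-city and pooled AFs with eCIs);
every file header records the config hash and seed that reproduce it.

The same analysis is available as a library:

```python
import tempyll

pairs, meta = tempyll.simulate_multicity(4, seed=7)
result = tempyll.run_pipeline([s for s, _ in pairs], meta,
                              tempyll.PipelineConfig(n_mc=1000, seed=7))
print(result.pooled.af_total, result.meta_intercept.i2_percent)
```

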