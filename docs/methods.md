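# Methods

## Outcome construction

Daily years of life lost (YLL) are built by aligning each death's sex and
completed age with a reference life-expectancy table and summing over all
deaths of the day; days without deaths are exact zeros, so the daily total
conserves the per-death sum. For a multi-year study period the reference
table is the elementwise mean of the tables at the period's ends. Ages
above the table's top band clamp to that band (standard practice for
open-ended abridged-table bands; how such ages were handled upstream is
generally not reported, so this is the package's choice), fractional ages
floor to completed years, and sexes outside the two table strata are
rejected rather than imputed. A synthetic Gompertz-law table
(`synthetic_life_table`) ships for self-contained runs; real analyses
supply their own CSV.

## First stage: city-level DLNM

The Gaussian identity-link regression is ordinary least squares (the two
coincide; no iterative fitting). Design blocks, in order: intercept;
16-column temperature×lag cross-basis; natural cubic time spline with
`round(7 × years)` df (49 for the 2557-day window), knots equally spaced
over the scaled date index; one 3-df natural cubic spline per
meteorological covariate (relative humidity, sunshine, wind speed, air
pressure) over the whole period, boundary knots at the observed min/max,
internal knots at equally spaced quantiles; six day-of-week indicators
(Monday reference); one holiday indicator. Whether the covariate splines
should be per-year was an open choice; whole-period splines keep the
design small and are the common default.

The temperature basis is a degree-2 B-spline, internal knots at the
27.5th/72.5th percentiles, boundary knots at the observed min/max, no
intercept — 4 columns, which is what fixes the Wald df at 4 and the
16-city Cochran df at 60. The lag basis is a natural cubic spline on lags
0..21 with intercept and 2 internal knots equally spaced on the
log(lag+1) scale — the customary placement concentrating flexibility at
short lags. Natural cubic splines are evaluated in the truncated-power
parameterization (numerically adequate here because the time axis is
rescaled to [0,1] before knot placement); B-splines are evaluated with
`scipy.interpolate.BSpline`.

Rows with incomplete lag history (the first 21 days) and rows with any
missing value are excluded listwise rather than padded — padding would
fabricate pre-study exposure. The cross-basis coefficients are reduced to
the overall cumulative curve by `η_j = Σ_k β_(j,k) S_k`, with `S_k` the
lag-basis column sums over integer lags; the covariance maps through the
same linear transform. Curves are centered at the city's median
temperature by default; centering is presentational only — pairwise
curve differences, and therefore all attribution results, are invariant
to it (tested to 1e-10).

`fit_city` accepts an optional shared temperature basis built from pooled
temperatures. Per-city bases (each city's own percentiles) are the
field's standard and the pipeline default, but coefficients estimated on
different bases are not strictly comparable: with identical true curves,
basis differences alone inflate the between-city Cochran Q (we measured
10–20% type-I error, growing with series length). When the cities'
exposure distributions are comparable — always true in the simulation
studies — the shared basis removes that artifact and is used there.

## Second stage: multivariate meta-regression

`η_i ~ N(X_i μ, S_i + Ψ)`, estimated by maximum likelihood with μ profiled
out (GLS given Ψ) and Ψ optimized on the Cholesky factor (log-diagonal
parameterization), which keeps it positive semidefinite without
constraints. L-BFGS-B, gradient tolerance 1e-6, at most 500 iterations;
the starting Ψ is the empirical between-city covariance minus the mean
within-city covariance, eigenvalue-floored. Meta-predictors are
z-standardized before fitting — Wald statistics are invariant to this,
but the optimizer is not scale-robust in practice. One predictor at a
time; AIC counts `p·v` mean parameters plus `v(v+1)/2` free Ψ parameters.
Cochran Q uses the fixed-effects (Ψ=0) residuals of the same predictor
structure, df = kv − pv; I² = max(0, (Q−df)/Q)·100.

BLUPs shrink each city toward its fitted mean by `A = Ψ(Ψ+S_i)^-1`; the
reported BLUP covariance is the conditional covariance `Ψ − AΨ` plus the
propagated uncertainty of the fitted mean. Whether pooling for BLUPs
should be univariate-per-coefficient or multivariate is ambiguous in this
literature; the package derives BLUPs from the multivariate
intercept-only fit (a univariate fit is a v=1 special case of the same
code path).

## Third stage: attribution

The minimum-YLL temperature is a 0.1 °C grid search restricted to the
city's 1st–99th temperature percentiles (configurable), ties broken
toward the colder temperature; a 0.001 °C oracle confirms the grid is
fine enough. Attribution is backward-perspective on the reduced
cumulative curve and identity-link: `a_t = B(x_t)η − B(MMT)η` in
person-years, cold/heat split by the day's temperature side of the MMT,
so cold + heat = total holds to machine precision. Out-of-range
temperatures are clamped to the basis boundaries and counted. Provincial
pooling divides summed attributable YLL by summed total YLL — never an
average of fractions.

Monte Carlo eCIs redraw the curve coefficients from N(η, V) (1000 draws
by default) and recompute all three AFs per draw; the 2.5th/97.5th
percentiles are reported. The MMT (hence the cold/heat partition) stays
fixed at the point estimate by default — matching the fixed cold/heat
definitions of published decompositions — with a `refind` policy that
re-searches it per draw. Negative per-draw contributions are retained so
the interval reflects full sampling uncertainty.

Under a null effect the *point* AF is positively biased (~2–3% here):
the MMT is the argmin of the noisy estimated curve, which makes every
daily contribution non-negative at the point estimate. This selection
effect is inherent to MMT-referenced attribution; the eCI, which does
propagate coefficient uncertainty, straddles zero in ≥90% of null
replicates and is the honest null diagnostic.

## Synthetic data

The generator emulates the structure the first-stage model assumes.
Temperature is an annual sinusoid (mean 17.4 °C, amplitude 7 °C, peak near
day 200) plus stationary AR(1) noise (ρ=0.7, innovation SD 1.5 °C), giving
a ~5.4 °C marginal SD over 2557 days — the subtropical-plateau climate of
the intended application. Covariates are independent seasonal sinusoids
with noise, clipped to physical ranges; they do not enter the outcome (the
model still adjusts for them). The outcome is a smooth seasonal baseline
(150 person-years/day per city, winter-peaking amplitude 10) plus a weekly
cycle, holiday bumps (a fixed pseudo-holiday calendar: Jan 1–3 plus ten
fixed dates per year, since a real holiday list is user-supplied), the
lagged temperature contribution, and iid Gaussian noise (SD 15).

The true exposure–lag surface is separable: `Σ_l w_l f(temp_{t−l})` with
exponentially decaying weights (e-folding 5 days, normalized to 1) and a
V-shaped cumulative curve `f` — cold slope 2.2, heat slope 5.6
person-years per °C around a 20 °C minimum, sized to give a true AF of
~6–9% split roughly 2:1 cold:heat. The V junction is blended
quadratically over ±3 °C (Huber-style), keeping distinct asymptotic
slopes while making the curve C¹-smooth: observed temperature–mortality
curves are smooth, and a hard kink lies provably outside the reach of the
4-column quadratic-spline family (its best possible projection already
misses by >20% of the effect range, which would make recovery studies a
test of an unreachable target rather than of the estimator). Temperature
gets a 21-day burn-in before the window so every in-window day has a full
lag history; the burn-in is stored with the truth so the AF oracle can
replay the exact generative contributions.

The oracle AF sums each day's noise-free lagged contribution (cold/heat
by the sign of each lagged temperature's departure from the true MMT)
over the total simulated YLL; cold + heat = total exactly, and a zero
effect yields exactly zero. Heterogeneous multi-city runs scale each
city's curve by `1 + h·z_i` with `z_i` the standardized urbanization
meta-predictor, so the true effect varies monotonically with a known
city-level covariate; all other meta-predictors are decoys.

What the generator does not emulate: spatial correlation of weather
between cities, covariate effects on the outcome, overdispersed or
count-valued outcomes, harvesting/mortality displacement, and
season-varying lag structures. Passing tests therefore demonstrate
correct recovery under the model's own assumptions plus mild curve
misspecification — not robustness to these real-data features.

## Validation design and problem sizes

Deterministic kernels are checked against independent textbook oracles
(Cox–de Boor recursion, natural-spline interpolation, explicit double
loops, normal equations, inverse-variance and empirical-Bayes closed
forms, fine-grid search). The stochastic studies use: 20 replicates of a
4-city × 2557-day province for pooled-curve and AF recovery (pointwise
median error within 15% of the effect range; median AF error within 1.5
points); 100 single-city replicates at 500 Monte Carlo draws for eCI
coverage (88–99% band); 500 homogeneous 16-city replicates with a 2-year
first stage for Cochran-Q calibration (5% nominal) plus 60+60 replicates
for Wald false-positive rate versus power at heterogeneity h=0.3; and 50
null replicates for AF null safety. These sizes are the package's chosen
balance of statistical resolution against a desktop-scale runtime.

## Known limitations

Standard errors are OLS-conditional: no autocorrelation-robust
correction, although daily YLL residuals can be serially dependent.
Between-city covariance is ML (not REML), so Ψ is slightly biased low at
small k. The eCI propagates curve-coefficient uncertainty only — not MMT
location or life-table uncertainty. Quadratic B-spline curves with two
knots cannot express sharp kinks; sensitivity of conclusions to `max_lag`
(14/21/28) and the spline dfs should be checked with the config sweep the
CLI exposes.
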