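# Methods

## Model

Daily death counts $Y_t$ are modelled with a log-link quasi-Poisson
regression,

$$\log E[Y_t] = \alpha + \boldsymbol\beta^\top W_t
  + \mathrm{ns}(t, 7\,\mathrm{df/year}) + \mathrm{ns}(\mathrm{RH}_t, 3)
  + \gamma_{\mathrm{dow}(t)} + \delta\,\mathrm{hod}_t,
  \qquad \mathrm{Var}[Y_t] = \phi\, \mu_t .$$

$W_t$ is the exposure–lag cross-basis of the distributed-lag nonlinear model
(DLNM): with a temperature basis $b_1..b_{v_x}$ and a lag basis
$c_1..c_{v_l}$ over lags $0..L$,

$$w_{t,(j,k)} = \sum_{l=0}^{L} b_j(T_{t-l})\, c_k(l).$$

The first $L$ days, which lack a complete lag history, are dropped (not
zero-padded) and the response and covariates are subset identically. The
cumulative log relative risk between temperature $T$ and a reference is the
inner product of $\hat{\boldsymbol\beta}$ with the contrast vector
$v_{(j,k)} = (b_j(T) - b_j(\mathrm{ref}))\sum_l c_k(l)$; lag-specific
contrasts replace the sum by $c_k(l)$. Cumulative and lag-specific log-RRs
are additive by construction, and this identity is asserted in tests to
1e-12.

Assumptions: counts are conditionally independent given the covariates
(overdispersion is handled through $\phi$, not autocorrelation); population
at risk is constant over the series (no offset); the trend spline with 7 df
per year absorbs seasonality and slow demographic drift; humidity enters only
as a smooth confounder.

### Estimation

Coefficients come from IRLS (delegated to `statsmodels.GLM` with a Poisson
family), converging when the relative deviance change falls below 1e-9
within 50 iterations. The dispersion is the Pearson statistic over residual
degrees of freedom — the standard quasi-Poisson choice, fixed so that CIs are
reproducible — and the coefficient covariance is $\phi\,(X^\top W X)^{-1}$.
Rank deficiency is detected up front by pivoted QR and reported with the
names of the collinear columns; zero-variance blocks (constant humidity,
no holidays in range) are dropped with a warning instead. Fits are compared
with QAIC, $-2\ell/\phi_{\mathrm{ref}} + 2\,\mathrm{rank}$, using one shared
reference dispersion (from the richest model under comparison) so nested
quasi-fits are on a common scale. Deviance explained,
$1 - D/D_{\mathrm{null}}$, is reported alongside.

### Bases

The natural cubic spline uses the restricted-cubic (truncated-power)
construction: column one is $x$; the remaining columns are differences of
scaled truncated cubics that cancel quadratic and cubic terms beyond the
boundary knots, so every column is linear outside the boundary and C²
inside. `df` columns imply `df − 1` interior knots, at equally spaced
quantiles by default (equally spaced values for the trend spline, whose
argument is uniform anyway); knot specs are frozen and serializable so a
published knot set can be plugged in and prediction reuses training knots.
There is no constant column — the model supplies the intercept.

Threshold bases: single high threshold $\max(0, T - h)$ and double threshold
$(\max(0, \ell - T), \max(0, T - h))$. The null region is closed: the
thresholds themselves contribute zero, so RR is exactly 1 at and between
them.

The lag basis always includes an intercept column (the standard cross-basis
convention, without which a constant lag structure is unrepresentable); a
lag `df` counts total columns including it. Lag-spline interior knots are
equally spaced on the lag scale (log-spacing available). Default lag window
L = 13 days with a 4-column lag basis: long enough to contain the few-day
effects the method targets, short enough to keep the cross-basis
well-conditioned over a 1.5 °C-SD exposure.

## Curves, MMT, percentile RRs

Pointwise standard errors are delta-method:
$\mathrm{se}(T) = \sqrt{v^\top V_{\hat\beta} v}$ restricted to the
cross-basis block; 95% intervals are Wald on the log scale with multiplier
1.96. (The delta-method SE is validated in tests against the SD of 10,000
Monte-Carlo draws of the coefficients.) Curves are evaluated on a 0.1 °C
grid over the observed range — finer than the 0.1 °C precision at which
thresholds and MMTs are reported.

The minimum mortality temperature is the grid argmin of the cumulative
curve inside the 10th–90th percentile window (spline tails are
variance-inflated, and empirical MMTs in tropical series sit interior);
ties break toward the lowest temperature, and a flat curve yields the window
midpoint with a warning. Percentile RRs (1st/5th/95th/99th by default) use
the type-7 (linear-interpolation) percentile rule throughout, and each
category's curve is re-centered at its own MMT before tabulation, so RR = 1
at the MMT by construction.

## Model simplification

1. **Spline stage.** Fit the NCS-NCS model, locate the cumulative curve's
   interior local minima (sign changes of first differences; plateaus
   collapse to their lowest-temperature point) within the 1st–99th
   percentile range.
2. **Threshold stage.** Two or more minima: double thresholds at the first
   and last. One minimum (or none): a single high threshold at the MMT.
3. **Search stage.** Grid-search candidates at 0.1 °C steps within ±1.5 °C
   of the stage-2 thresholds, bounded to the 1st–99th percentile range.
   Every candidate high is also fitted as a single-threshold model. Ranking
   is by QAIC by default (deviance explained optionally), with the reference
   dispersion taken from the spline stage. Among candidates within 2 QAIC
   units of the optimum, a single-threshold model is preferred; failing
   that, the double-threshold fit whose cold-arm slope is closest to null
   (smallest |z|). This operationalizes "keep the cold arm only if it earns
   its place": the collapse rule is explicit because intent alone does not
   fix a formula.

All stages share the lag basis and max lag, hence identical usable rows, so
criteria are directly comparable; the report asserts this. On a null
surface, threshold stages typically beat the spline stage by roughly twice
the parameter difference in QAIC — stages are "equivalent" in the sense that
no stage finds signal, and the report flags spreads ≤ 2 QAIC explicitly.

## Season-specific model

Stacked same-season days from successive years are not a continuous daily
series, so the seasonal model is OLS on the log-transformed count,

$$\log(Y_t + 1) = \alpha + \boldsymbol\beta_s^\top W_t
  + \mathrm{ns}(\mathrm{doy}_t, 4) + \mathrm{ns}(\tau_t, 3)
  + \mathrm{ns}(\mathrm{RH}_t, 3) + \gamma_{\mathrm{dow}(t)}
  + \delta\,\mathrm{hod}_t$$

per PAGASA season (DJF/MAM/JJA/SON by calendar month), with $\tau$ the
within-season day index. The +1 offset guards zero counts in sparse
categories and is configurable (+0.5 alternative). Crucially the cross-basis
is built on the **full** continuous series and only then subset to the
season's rows, so no lag history is fabricated across season boundaries.
DJF's day-of-year is re-indexed from December 1 so the within-season
seasonal spline sees a contiguous argument across the year boundary.
Effect curves are exponentiated contrasts with Gaussian-covariance delta
CIs — an RR-analogue, since the response is a log count rather than a rate.
A scalar per-season "slope" is reported as the cumulative contrast between
two temperatures divided by their difference; with a linear or threshold
predictor basis this is the literal slope. The predictor basis per season is
configurable (spline default; linear is the robust choice for
effect-modification comparisons, since sparse cold seasons may have no
exceedances of a high threshold).

## Synthetic-data generator

The generator is the model's forward direction with known truth, calibrated
to a Manila-like tropical climate:

| component | default | rationale |
|---|---|---|
| temperature | mean 28.8 °C, sinusoid amplitude 1.1 °C (May peak), AR(1) ρ=0.7, innovation SD 0.93 °C | overall SD ≈ 1.5 °C, range ≈ 24–33 °C, warmest quarter MAM |
| humidity | mean 73.9%, amplitude 4% (August peak), AR(1) ρ=0.6, innovation SD 5% | SD ≈ 7.5%, wet-season phase; clipped into (0, 100] |
| mortality | baseline 52 deaths/day, weekend multipliers 0.97, overdispersion ω = 1.2 | variance/mean of a large-city all-cause series |
| nuisance | log-scale seasonal sinusoid, amplitude 0.03, on by default | the trend spline exists to absorb exactly this; a generator without confounding would not exercise it |

Overdispersion uses a gamma-Poisson mixture with variance $\omega\mu$
(negative binomial with $k = \mu/(\omega-1)$), so the quasi-Poisson
dispersion estimand is ≈ ω directly. Truth surfaces factor as
$f(T, l) = g(T)\,w_l$ with normalized lag weights (default geometric-ish
decay 0.4/0.3/0.2/0.1 over lags 0–3): null, single-threshold, double-
threshold, or a piecewise-quadratic U-shape whose derivative at stated
reference hot/cold temperatures equals the stated slopes ($a_h = $
heat_slope$/2(T_{\mathrm{hot}} - \mathrm{MMT})$, and symmetrically for the
cold side; C¹ at the MMT). Optional per-season surface multipliers create
genuine seasonal effect modification. Category counts are a
temperature-dependent multinomial split of the daily total (logits shifted
by (multiplier − 1) × the day's cumulative effect), so they sum to the total
exactly while carrying different effective slopes. Randomness flows from one
seed through named substreams (weather / counts / split), so a change to one
component's draws cannot silently shift another's.

What the generator does **not** emulate: rainfall/typhoon episodes,
infectious-disease outbreaks, air-pollution co-exposure, mortality
displacement (harvesting) dynamics, demographic drift, and weather
measurement error. Passing tests therefore demonstrate correctness of the
estimator under the stated data-generating process, not robustness to those
real-data features.

## Verification and problem sizes

The test suite checks the numerical core against independent oracles: the
cross-basis against an explicit quadruple-loop construction (< 1e-10), the
spline basis against a generic truncated-power-with-natural-constraints
construction via null-space projection (column spans agree to < 1e-9 on a
1000-point grid), delta-method SEs against Monte-Carlo coefficient draws
(< 5% relative), and the GLM against simulated Poisson data with known truth.
Calibration and recovery use replicated 5-year simulations: 95% CI coverage
at the 99th percentile (500 replicates), null false-positive rate (500),
threshold and slope recovery (100), MMT recovery (100), and season
effect-modification detection (100). `scripts/acceptance.py` re-measures the
same quantities at 50–300 replicates per block, sized to finish in a few
minutes on one CPU while keeping Monte-Carlo error small relative to the
effects measured.

## Numerical conventions and degenerate inputs

- Percentiles: type 7 everywhere (the single rule all percentile
  temperatures depend on).
- Week convention Monday = 0; dow enters as six dummies against Monday.
- Trend df: round(7 × years), floor 3, generalizing the 7-df/year rule to
  fractional-year series.
- Date gaps are hard errors; `allow_gaps` splits rather than imputes,
  because lagged exposure requires contiguity.
- Holiday list is external and empty by default (no canonical list ships
  with the package).
- Tie-breaks (MMT, minima plateaus) always resolve toward the lowest
  temperature.
- Thresholds outside the observed range, lags outside the window, empty
  candidate grids, all-zero categories, constant responses and rank-deficient
  designs raise (or warn-and-skip where the pipeline can continue) with
  named columns/rows.

## Known limitations

- No penalized splines or automatic smoothness selection; df are chosen, not
  estimated.
- No autocorrelation-robust covariance; quasi-Poisson handles overdispersion
  only.
- The simplification collapse rule (2-QAIC window, smallest cold-arm |z|) is
  one defensible formalization of an informally stated procedure; the full
  search trace is returned so any other rule can be applied post hoc.
- Season-specific fits treat the log-count as Gaussian; sparse categories
  with many zero days lean on the +1 offset.
- Attributable deaths/fractions and harvesting correction are out of scope.
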