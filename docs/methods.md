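# Methods

## Design and model

The analysis is a time-stratified case-crossover study expressed as a
conditional Poisson regression. Observation days are grouped into strata by
municipality, calendar year, calendar month and day of week (ISO weekday
numbering; any consistent convention yields identical strata). Comparing
days only within a stratum removes, by design, everything constant within a
municipality-month at a given weekday: secular trends, seasonality at
monthly resolution, and the weekly cycle. Pooling municipalities adds
strata rather than shared parameters, so multi-municipality data are
analysed in one stage.

For stratum s and day t, the count model is

    Y_t ~ quasiPoisson(mu_t),   log mu_t = alpha_s + w_t' theta

where w_t is the day's cross-basis row. The cross-basis is the tensor
product of two natural cubic splines: an exposure basis b(x) (no intercept;
default interior knots at the 10th/75th/90th percentiles of the regional
temperature distribution, boundary knots at the observed range) and a lag
basis c(l) (intercept included; natural spline in log(l+1) with three
interior knots equally spaced on that scale), accumulated over lags
0..L (L = 21 by default, 6 in the sensitivity analysis):

    W[t,(j,k)] = sum_{l=0..L} b_j(x_{t-l}) c_k(l)

Columns are ordered exposure-major; lag windows are physical history on the
continuous municipal series and may cross stratum boundaries. Days lacking a
full L-day history are dropped (and counted) unless explicit history values
are supplied.

### Natural cubic splines

The basis is built from cubic B-splines with the two natural constraints
(zero second derivative at the boundary knots) projected out via the QR null
space, matching the dimension rule #interior + 1 (+1 with intercept).
Beyond the boundary knots the basis continues linearly by first-order Taylor
expansion from the boundary. Evaluations are deterministic given the spec.

## Estimation

The stratum intercepts are not materialised. At any theta the optimal
intercept has the closed form alpha_s = log(Y_s / sum_{t in s} e^{w_t'theta}),
which reduces the problem to the conditional multinomial likelihood given
stratum totals. The profiled likelihood is concave in theta; estimation is
Newton's method with step-halving (monotone likelihood ascent), initialised
at theta = 0, converging on relative coefficient change or score norm below
1e-8 within 100 iterations. Equivalence with the explicit stratum-dummy
Poisson GLM (coefficients to 1e-6, covariance sub-block to relative 1e-5) is
enforced by tests against statsmodels as an independent oracle.

Strata with zero total deaths or without variation in any design column
carry no information about theta and are dropped before fitting, with
logged reasons; single-day strata fall out via the no-variation rule.
Collinear (within-stratum) design columns raise an error naming the
null-space dimension rather than being silently dropped, because silent
dropping would corrupt the curve-reduction contrast geometry.

Overdispersion is quasi-likelihood style:

    phi_hat = sum_t (y_t - mu_t)^2 / mu_t  /  (n - p - S)

with stratum intercepts counted among the estimated parameters (S of them).
When the degrees of freedom are non-positive (degenerate toy inputs),
phi_hat is reported as 1. The coefficient covariance is phi_hat times the
inverse observed information of the profiled likelihood. Model comparison
uses qAIC = -2 loglik + 2 p phi_hat with the full Poisson log-likelihood
(including the log y! term) evaluated at the profiled optimum, so qAIC
differences are convention-free; ties break on fewer parameters, then
candidate order.

## Curve reduction, MMT and RR contrasts

Summing the lag basis over l collapses the surface to the overall
cumulative association. The contrast vector of temperature x versus
reference r is z(x) = (b(x) - b(r)) kron C with C_k = sum_l c_k(l), giving
log RR = z'theta and variance z'Vz. The curve's shape is invariant to the
centering reference; only the zero point moves, so the model is fitted
once and re-centred at the MMT without refitting.

The MMT is the argmin of the cumulative curve evaluated at 0.1-percentile
steps of the regional temperature distribution over a configurable search
window (default 1st-99th percentile). If the minimum sits at the upper
boundary and a fallback percentile is configured, the MMT is instead the
regional temperature at that percentile rank — by default the national
MMT's percentile, computed from a pooled national fit first. This
implements the fallback as "regional temperature at the national MMT's
percentile rank", which is an interpretation and is flagged in every output
row it affects. Cold and heat RRs are the curve at the regional 1st and
99th percentiles versus the MMT, with Wald CIs on the log scale (default
95%). MMT-location uncertainty is deliberately not propagated into the
CIs: inference is conditional on the located MMT.

Regional temperature distributions pool all municipality-day values of the
region unweighted (each day of each municipality counts once), and
quantiles use linear interpolation between order statistics. Subgroup
models refit the overall region's selected spec on the subgroup's own count
series, keeping the overall MMT and percentile contrasts, so effect
modification is assessed on a common reference; subgroup series thinner
than a configurable event floor are skipped with a log entry.

## Synthetic data generator

The generator emulates the structure, not the content, of restricted
mortality and gridded-weather inputs:

- **Temperature**: per municipality, level + seasonal sinusoid + AR(1)
  noise on real calendar dates. Defaults: level 24 °C with 2 °C
  between-municipality jitter, amplitude 5 °C with phase jitter, AR(1)
  rho = 0.7, innovation sd 1.5 °C — a warm climate with moderate seasonal
  swing and realistic day-to-day persistence. Municipalities are
  independent (no spatial correlation field).
- **Counts**: log mu = baseline + seasonal confounder (amplitude 0.10,
  random phase per series unless pinned) + weekly cycle (amplitude 0.05) +
  linear trend (0.10 over the window) + the distributed-lag effect
  sum_l w_l f(x_{t-l}). Baseline is log 2 (about two deaths/day, a
  mid-size-municipality scale that keeps counts informative but discrete).
  Sampling is negative-binomial (size 5) by default — the overdispersion the
  quasi-Poisson fit is designed for — or Poisson for calibration checks.
  The first L days are burn-in history and emit no counts. Subgroups of one
  population should share the confounder phase (the `season_phase`
  argument); their counts are otherwise independent draws.
- **Truth**: f is V-shaped — slope_cold per °C below the true MMT,
  slope_heat above — with geometric lag weights w_l proportional to q^l
  normalised to sum to 1, so the cumulative RR of sustained exposure has
  the closed form exp(f(x) - f(ref)). The V-truth is deliberately outside
  the fitted spline family, making recovery an approximation test rather
  than an exact-family exercise.

What passing recovery tests show: the pipeline recovers cumulative RRs and
curve shape from data whose confounding is exactly the kind the strata
absorb. What they do not show: robustness to spatially correlated exposure
error, to within-month confounding not aligned with the stratum structure,
or to the sociodemographic joint distribution of a real cohort.

## Numerical and protocol choices

- Percentile convention: linear interpolation (fractional rank 1+(n-1)p) —
  the dominant default in reference statistical software.
- Missing daily temperatures are a hard error, never imputed; gridded
  weights are renormalised per municipality so truncated (coastline)
  weight files are tolerated; an all-missing grid cell is an error.
- Cross-basis columns: exposure-major ordering is a contract shared with
  the contrast construction and checked dimensionally at reduction time.
- Curve grids: 200 equally spaced points across the observed range.
- Simulation scales in the test suite: oracle checks run at n <= 500;
  calibration uses 100 replicates of 10 municipalities x 5 years; recovery
  uses 50 replicates of 50 municipalities x 10 years; the lag-sensitivity
  direction check uses 20 replicates of 20 municipalities x 5 years, a size
  chosen so the direction signal is not swamped by MMT relocation noise
  between the lag-21 and lag-6 variants.

## Known limitations

- **MMT smoothing bias.** With a V-shaped truth whose heat arm is much
  weaker than its cold arm, the natural-spline curve smooths the kink and
  its argmin shifts toward the flatter (heat) side — of order 1 °C at the
  default knot placements even with very large samples. Cumulative RRs at
  the percentile contrasts are far less affected (the curve is well
  approximated away from the kink); MMT point estimates inherit this
  one-sided bias. This is a property of spline approximation to a kinked
  truth, not of the fitting algorithm.
- Exact conditional inference for very small strata is not implemented;
  the profiled likelihood is the conditional likelihood up to terms that
  vanish for the stratum structure used here.
- No two-stage (city-specific + meta-analysis) mode; the design is
  one-stage pooled by construction.
- Attributable-fraction measures and lag-specific 3-D surfaces are out of
  scope; the reduction is cumulative only.
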