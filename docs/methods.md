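# Methods

## Allometric model

Wet field-mass `M` (kg) of a shrub or aerial tip is related to stem
diameter `D` (cm; DRC for rooted shrubs, basal diameter for tips) by
`M = a·D^b`. Fitting is always OLS of `ln M` on `ln D`, because biomass
residuals are multiplicative: the log transform stabilises the variance
and makes the error term normal, `ln M = b ln D + ln a + ε`,
`ε ~ N(0, σ²)`. A fitted `LogLogAllometry` stores the sufficient
statistics `(intercept, slope, residual_scale, n, mean_logx, sxx)`,
from which the standard errors at any new diameter are

    se_fit(D)  = residual_scale · sqrt(1/n + (ln D − mean_logx)²/sxx)
    se_pred(D) = sqrt(residual_scale² + se_fit²)

`se_fit` is the uncertainty of the regression line itself; `se_pred`
adds the residual scatter and is the correct scale for predicting an
individual shrub. These formulas are recomputed from the stored
statistics rather than through a regression object so bands over
thousands of grid points are cheap; tests verify they agree with
statsmodels' `get_prediction` to 1e-8.

The 95% prediction interval is formed on the log scale,
`μ ± t_{n−2,0.975}·se_pred`, and exponentiated. It is therefore
multiplicatively symmetric (`lwr·upr = point²`) and positively skewed on
the arithmetic scale. "Uncertainty" everywhere in this package means
the interval range `upr − lwr`. Prediction bands are evaluated on an
inclusive grid (default step 0.01 cm over [2.5, 7.5] cm, 501 points;
the point count uses round-half-even on `(d_max−d_min)/step + 1`).

**Band overlap.** The self-similarity check compares the tip band with
the whole-shrub band as the grid mean of
`|[lwr_a,upr_a] ∩ [lwr_b,upr_b]| / |[lwr_a,upr_a]|`, with the tip band
as band *a*. No standard definition of "percent overlap" of two
prediction bands exists; this one is directional (how much of the tip
band lies inside the whole-shrub band), bounded in [0, 1], and equals 1
for identical bands. A zero-width reference interval counts as covered
when it lies inside the other band.

**Prediction-error law.** Regressing `ln(upr − lwr)` on `ln D` over a
band gives `PE = k·D^p`. The fitted, unrounded exponent is always used
downstream; rounded display values are never fed back into computation.

## Internode geometry and density

Internodes are conic frustra, `V = πL(D1² + D1·D2 + D2²)/12` (cm³;
divide by 1000 for litres). Two calibrations of mass on volume are
provided: a linear regression with a free intercept, whose slope is the
wet density (kg/L) with a standard error, and a log-log regression
whose slope near 1 indicates proportionality through the origin and
whose exponentiated intercept is the density. The log-log form is the
default mass model for internodes because log transformation removes
the heteroscedasticity visible in the linear fit. The density CI uses
a t quantile with df = n − 2; note that a CI recomputed from published
*rounded* coefficients can disagree with a published interval in the
last printed digit, since the inputs carry only 2–3 significant
figures.

Units are fixed: cm for lengths/diameters, cm³ internally and litres at
interfaces for volume, kg for mass, kg/L for density.

## Field algorithm and component estimates

`decompose` walks a stem tree depth-first. A segment whose base
diameter is ≤ `D_max` becomes a single aerial-tip component (the tie
`D1 = D_max` counts as a tip); a thicker segment contributes a frustrum
`(D1, D2, L)` and the walk continues into its children. Plants with
root-collar diameter < `D_min` (default 2.5 cm) are not tall shrubs and
yield no components. Multi-stemmed shrubs are handled by decomposing
each rooted stem independently and summing. The decomposition exactly
tiles the structure: every segment appears in exactly one component.

Tips are predicted by the tip allometry at their basal diameter;
frustra by the internode log-log model at their volume. The `se_log`
attached to every component is the **full** prediction standard error
`se_pred`, not `se_fit` alone: the propagated quantity is an
individual-shrub prediction, so the residual scatter belongs in it
(dropping it would shrink every plot interval below nominal coverage,
and the end-to-end coverage test would fail). Predictions outside the
calibration diameter range warn (`ExtrapolationWarning`) rather than
error, since tips below 2.5 cm routinely occur inside large shrubs.

## Plot-level Monte Carlo

Given component estimates `(μ_i, s_i)`, each mass is drawn from
`Lognormal(μ_i − s_i²/2, s_i)`. The `−s²/2` correction makes the
distribution's arithmetic mean equal `exp(μ_i)`, so the Monte-Carlo
point estimate and the allometric point estimate coincide. Components
are sampled independently (between and within shrubs), replicate totals
are summed, and the 0.025/0.975 empirical quantiles (linear
interpolation) of the 10,000 replicates (default) form the interval.
Independence makes the replicate variance the sum of component
variances, which the tests verify against the closed-form lognormal
variance.

Randomness is counter-based: component `i` under seed `s` draws from a
generator keyed by `SeedSequence([s, i])`, so results are bit-stable
for a fixed seed and unaffected by draws made elsewhere. The
single- versus two-component comparison uses two independent streams
derived from the one user seed.

## D_max selection

The stem-diameter density is a Gaussian KDE with the classical
rule-of-thumb bandwidth `0.9·min(sd, IQR/1.34)·n^(−1/5)`, evaluated on
a 512-point equispaced grid spanning `[min − 3·bw, max + 3·bw]`
(optionally clipped at zero). Expected prediction errors are Riemann
sums with `Δx = range/512` — deliberately the plain grid-sum
convention, reproducible with any software; the test suite checks it
against adaptive quadrature (≤1% on smooth densities) and a uniform
closed form (≤0.5%). Grid points at non-positive diameters contribute
nothing.

`P(D > D_max)` is the strict empirical exceedance fraction of the pilot
diameters. The expected time of a two-component measure is
`t1 + t2·P(D > D_max)`: every stem is measured once, and only stems
thicker than the threshold incur the extra frustrum measurements. A
candidate at the top of the observed range is a boundary case — no stem
exceeds it, the protocols coincide, and both ratios are exactly 1 (the
truncated integral is defined equal to the full one there, rather than
losing the kernel tail above the largest observation). The timing
coefficients come from an OLS of total plot time on the two measure
counts (needs ≥4 plots and full rank); its coefficient covariance is
retained for joint confidence-region checks.

The decision rule compares ratios, so rescaling the PE law (`k → c·k`)
can never change a verdict; the tests assert this invariance.

## Simulator

`shrubmass.simulate` generates the synthetic world the method assumes:

* **Architecture.** Stems taper as `(1 − taper_rate)^L` per internode
  (taper_rate 0.0025/cm, internode lengths uniform on 30–120 cm, the
  measured range of field internodes being a few tens to ~200 cm). At
  each node the cross-sectional area is split among 2–3 children by a
  Dirichlet draw (concentration 4), i.e. an area-preserving pipe-model
  split with jitter — this is what makes tips genuinely self-similar
  copies of whole shrubs. Recursion ends when a stem's base diameter
  falls to ≤ D_max; that whole stem is then one aerial tip.
* **Masses.** Tip mass is `0.07·D^2.437 · exp(N(0, 0.45²))`; internode
  mass is `0.9 kg/L · V · exp(N(0, 0.10²))`. The allometry coefficients
  are published field values for Alaskan alder/willow; 0.9 kg/L sits
  centrally in the published density CI (0.81–1.02). The tip residual
  scale is not published (only R² ≈ 0.8 is); 0.45 is chosen to give a
  comparable log-log R² over the tip diameter range and is an explicit
  free parameter. Internode noise is much smaller than tip noise —
  that asymmetry is the entire reason the two-component method wins.
* **Population.** Root-collar diameters are lognormal (meanlog 1.6,
  sdlog 0.55; median ≈ 5 cm, upper tail reaching tens of cm like the
  2.9–40.5 cm field range), truncated below at D_min so every generated
  plant is a tall shrub. Plots hold Poisson(84) shrubs by default
  (≈1,430 shrubs over 17 plots in the motivating survey).
* **Timing.** Plot time is `300 + 26·n1 + 111·n2 + N(0, 543²)` seconds,
  redrawn if non-positive; per-plot measure counts are gamma-mixed
  Poisson (CV 0.6) because real plots differ strongly in shrub density
  — with pure Poisson counts the timing regression would have far less
  leverage than a real field day.

What the simulator does **not** emulate: measurement error on diameters
and lengths, damaged/irregular shrubs, species differences in density
or allometry, spatial clustering within plots, and any violation of the
lognormal residual assumption. Passing tests therefore demonstrate
internal consistency of the estimation chain under its own assumptions,
not robustness to field pathologies.

## Numerical conventions and problem sizes

* Quantiles: `np.quantile` linear interpolation (type-7), t quantiles
  from scipy.
* Rounding only at presentation (2 decimals for kg/L, 1 for seconds);
  all stored and propagated values are full precision.
* Test-suite simulation sizes (e.g. 100–200 replicates for recovery
  suites, 150 plots for end-to-end coverage, 2,000–10,000 Monte-Carlo
  draws) were chosen as the smallest sizes at which the binomial or
  Monte-Carlo standard error is well below the tolerance being
  asserted.
* Degenerate inputs fail loudly: < 3 calibration samples, zero
  diameter spread, non-positive dimensions, rank-deficient timing
  designs and empty plots all raise `ValueError` rather than produce
  NaNs.

## Known limitations

* The PI-band overlap statistic is one of several defensible
  definitions; comparisons with other overlap conventions should
  recompute it from the stored bands.
* The D_max rule ignores frustrum prediction error in E[PE2] (it is an
  order of magnitude smaller than tip error); for stands where density
  calibration is poor this underestimates E[PE2] slightly.
* Components are assumed independent in the Monte Carlo; correlated
  errors (e.g. a biased density estimate shared by all frustra) would
  widen true intervals relative to reported ones.
* Single-fit coverage of prediction intervals is exact only marginally;
  conditional on one small calibration set it varies by a percent or
  two, which is visible in acceptance-report values across seeds.
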