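# Methods

This note documents the statistical machinery, the synthetic study
conditions, the numerical choices, and the known limitations of the
package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Source apportionment (weighted PMF)

The receptor model factorizes the day × species concentration matrix X
with paired uncertainties S as X ≈ G·F, G ≥ 0 (day × factor
contributions, µg/m³), F ≥ 0 (factor × species profiles), minimizing
the uncertainty-scaled objective Q = Σ((X − GF)/S)². The solver uses
weighted multiplicative updates

    G ← G ∘ [(W∘X) Fᵀ] / [(W∘(GF)) Fᵀ],   W = 1/S²,

and symmetrically for F. These updates are monotone in Q (asserted on
every test fit), dependency-free, and robust; they are not the
maximum-likelihood ME-2 engine used operationally by regulators, and
they converge slowly near flat optima, so the fit runs several random
nonnegative starts (default 10) and keeps the lowest Q. Convergence is
declared when the relative change in Q stays below 1e-8 for 10
consecutive iterations, capped at 5000 iterations (a warning is logged
and the best iterate returned otherwise). After fitting, profile rows
are normalized to sum to one with the scale moved into G, which leaves
the modeled total G·F unchanged.

Identifiability caveat: a nonnegative factorization is unique only when
both profiles and contributions contain enough zeros. On dense synthetic
mixtures a slightly rotated solution can fit equally well; the recovery
suite therefore evaluates matched-factor cosine similarity and
contribution correlation rather than element-wise equality, and the
exact-recovery test uses block-sparse profiles with source-absent days.

**Dispersion normalization.** Daily multipliers m_i = V_i/mean(V) from a
ventilation proxy V (mixing proxy × wind speed, or user-supplied) scale
X and S before factorization and are divided out of G afterwards. The
formula is this package's definition of the concept — the normalization
lives behind `DispersionNormalizer` precisely so an alternative proxy or
formula can be swapped in.

**Factor matching.** PMF factor order and scale are arbitrary, so
recovered profiles are aligned to references by maximizing total cosine
similarity over one-to-one assignments (Hungarian algorithm), validated
in tests against brute-force enumeration of permutations.

## Additive models (penalized cubic splines)

Each factor's daily contribution is regressed on smooth functions of
emissions and meteorology plus categorical calendar terms. Smooths use
cubic B-spline bases (default k = 10 basis functions) with interior
knots at evenly spaced quantiles of the training covariate and an
integrated-squared-second-derivative penalty, computed exactly by
two-point Gauss–Legendre quadrature per inter-knot interval (the
integrand is piecewise quadratic). Identifiability: B-spline columns
form a partition of unity, so each smooth is reparameterized onto the
null space of its training column-sum vector (a sum-to-zero
constraint); categorical terms are centered treatment contrasts. The
response is Gaussian with identity link — concentrations are modelled
directly, and negative predictions are permitted at this stage; clipping
happens only at the calibration step.

Smoothing parameters minimize GCV(λ) = n·RSS/(n − edf)², searched
coordinate-wise on a log10 grid from 10⁸ down to 10⁻⁴ (ties prefer the
smoother fit) followed by a Nelder–Mead polish; a profiled REML score is
available via `method="reml"`. The Bayesian posterior covariance
σ²(XᵀX + S_λ)⁻¹ supplies standard errors for any linear functional of
the fit, including per-day and mean prediction *differences* between
scenarios — the quantity the uncertainty bands need. One test
cross-checks the fitted curve against the reference GAM implementation
in R (mgcv, cubic regression splines) on a shared dataset.

**Extrapolation contract.** Counterfactual emissions routinely exceed
the factual training range. Beyond the boundary knots the basis is
extended linearly from the boundary value and slope, and every
extrapolated prediction row is flagged in the output; silent
extrapolation would hide the dominant error source of the whole
analysis.

**Feature selection.** Concurvity (the smooth analogue of collinearity)
is screened greedily: for each candidate pair, the R² of one covariate
regressed on the other's spline basis expansion (max over both
directions) above a threshold (default 0.8) drops the member less
correlated with the response, with alphabetical tie-breaks. Regulated
emission series share their policy timeline and are therefore strongly
concurve; the screen is what lets each factor's model keep the one
driver it actually responds to. Both the measure and the threshold are
this package's definitions.

**Calendar terms.** Day-of-year seasonality is carried as a month
categorical by default (rather than a smooth of day-of-year) to avoid
confounding the seasonal signal that should be attributed to
meteorology; day-of-week captures weekday/weekend activity. Rows with
missing values in any used column are dropped listwise and counted.

**Validation.** 10-fold cross-validation assigns rows to folds at
random under a named seed; pooled R² (squared Pearson correlation),
mean bias, and RMSE are computed on the concatenated out-of-fold
predictions. Permutation importance is the drop in correlation between
observations and predictions when one indicator's column is shuffled,
averaged over shuffles; an indicator absent from a model has importance
exactly zero by construction.

## Counterfactual engine

A scenario assigns each sector either its factual or counterfactual
emission trajectory; meteorology is identical by construction (and
asserted). Per factor,

    EI_t = prediction(counterfactual inputs) − prediction(factual inputs)
    CI_t = max(0, I_PMF,t + EI_t),

where I_PMF is the observed (apportioned) contribution. Calibration to
observations cancels additive model bias and keeps the counterfactual on
the scale health models are trained on. Negative calibrated values are
clipped at zero and the clip count reported as a diagnostic (the
handling of negative calibrated values is this package's choice).
Annual ratios are ratios of annual means of the daily series, not means
of daily ratios; the combined total is the sum of the factor series.
Because the models are additive without cross-sector interaction terms,
per-sector emission impacts sum exactly to the all-sector impact (a
tested invariant; configured interaction terms would break it, and the
equality is not asserted then).

## Uncertainty

Two components enter the 95% band on the counterfactual annual mean:

* **Emission Monte Carlo.** Counterfactual trajectories are perturbed
  multiplicatively — lognormal by default, since emissions are positive
  and inventory uncertainties are relative — with one draw per
  (sector, pollutant) series per replicate scaling the whole
  trajectory. The band is the 2.5th–97.5th percentile of the recomputed
  CI annual means across draws (default 1000 draws; tests use 200).
* **Model uncertainty.** ±2 standard errors of the predicted
  factual-to-counterfactual mean difference, from the posterior
  covariance of the fitted coefficients.

The two half-widths are combined by root-sum-square around the central
estimate; an envelope (outer hull) option exists. Bounds are clipped at
zero. Percent uncertainty is 100 · half-width / central annual mean.
The distribution family and scales of the emission uncertainty are
configuration, not constants: they belong to whatever inventory
analysis produced the counterfactual emissions.

## Synthetic study conditions

The generator emulates a 15-year (2005–2019) daily record by default:

* **Meteorology** — six fields (temperature, RH, wind speed, dew point,
  precipitation, sea-level pressure) as seasonal sinusoids plus
  stationary AR(1) noise, clipped to physical ranges (e.g. temperature
  15 ± 10 °C seasonal with AR coefficient 0.8 and 2 °C innovations).
* **Emissions** — EGU SO2/NOx at 1000/800 units·day⁻¹ baseline with
  three regulatory step reductions reaching cumulative 97%/88% by the
  final year, with 10% daily lognormal fluctuation (stack monitors
  report daily); mobile gasoline/diesel primary PM2.5 declining through
  annual 8%/13% fleet-turnover steps, interpolated piecewise-linearly
  between year midpoints (inventories are annual), against a
  flat-to-rising (+0.5–1%/yr) counterfactual. An `inverted` flag
  reproduces the diesel-SCR ammonia case where removing controls lowers
  emissions. Regulation steps whose dates fall outside a shorter
  simulated span are rescaled with the span.
* **Sources** — four factors (secondary sulfate, secondary nitrate,
  gasoline vehicles, diesel vehicles) with distinct 12-species
  profiles; contributions are baseline + additive responses (saturating
  in the driving emission for sulfate/gasoline, linear for
  nitrate/diesel, plus temperature/wind-speed terms) + seasonal cosine,
  multiplied by day-of-week factors, plus Gaussian noise (σ ≈ 0.3
  µg/m³, giving snr ≥ 3), rectified at zero. Noise draws are indexed by
  (day, factor) only, so factual and counterfactual worlds share them
  and their difference is the exact emission impact — the noise-free
  oracle the pipeline is judged against.
* **Speciation** — X = G·F + ε with ε ~ N(0, (0.1·true)² + (DL/3)²);
  uncertainties follow the speciation-network convention
  S = 0.1·X + DL/3, below-detection values censored to DL/2 with S
  inflated to 5·DL/6.

What the generator does **not** emulate: spatial transport and
chemistry, hourly resolution, instrument drift and batch effects,
correlated multi-pollutant measurement error, missing-data seasonality,
and economics-driven emission shocks. Passing the recovery suites
therefore demonstrates internal consistency of the estimator chain
under the stated error model, not performance on any real monitoring
record.

## Problem sizes used in validation

PMF recovery runs on 1000 days × 15 species at 10% proportional noise
with 10 random starts; the end-to-end counterfactual recovery on a
ten-year (3653-day) world; the coverage experiment on 200 replicated
four-year worlds with 200 Monte Carlo draws each and 20% lognormal
emission uncertainty, checking that the combined band covers the true
counterfactual annual mean at close to its nominal rate. These sizes
keep the whole validation fast on a single CPU while leaving each
estimate comfortably away from small-sample artifacts.

## Known limitations

* Multiplicative-update PMF offers no rotational controls (FPEAK), no
  bootstrap/displacement uncertainty, and no extra modelling
  uncertainty term.
* GAM inference assumes independent Gaussian errors; daily
  concentration residuals are autocorrelated in reality, so the ±2·SE
  band is optimistic for short averaging periods (less so for annual
  means).
* The counterfactual rests on extrapolating fitted responses beyond the
  observed emission range; flags quantify how often, not how wrong.
* Per-draw Monte Carlo perturbations are independent across
  (sector, pollutant) series unless configured otherwise; correlated
  inventory errors would widen the true band.
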