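# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the limitations of both.

## The abundance model

The response is the survey density d (individuals m⁻²) after two
transformations. First, ordinal density classes are converted to continuous
values by drawing from Normal(midpoint, cv·midpoint) with negative draws
rejected and class 0 mapped to exactly 0; cv = 0.30 reflects the precision
ceiling of categorical roadside surveys and is the same for every class.
Rejection (rather than truncation with a point mass at zero) keeps the
class-conditional mean at the midpoint and reserves zero for true absence;
at midpoint/sd = 1/cv ≈ 3.3 the rejection correction to the mean is
negligible. Second, the response is compressed as y = d^λ with λ = 1/6.
A log transform would be the usual variance stabiliser but cannot represent
absences; the sixth root maps 0 to 0 and is strictly increasing.

The regression model is a penalized-regression-spline GAM with negative
binomial variance and a square-root link:

    E[y] = μ,  √μ = η = β₀ + Σₛ fₛ(xₛ) + T(lon, lat, doy),
    Var[y] = μ + μ²/θ.

The response is a non-negative continuous quantity, not a count; the NB
deviance and log-likelihood are therefore evaluated as quasi-likelihoods at
non-integer y (Γ functions handle non-integer arguments). This deliberately
reproduces the unusual pairing of a count family with a transformed
continuous density; a config switch (pass the raw `sampled_density` column
as the response instead of `response`) supports fitting on the untransformed
density scale. In practice, on sixth-root responses the profiled θ often
runs to its upper bound — the transformed response is underdispersed
relative to NB, and the fit degenerates gracefully to the quasi-Poisson
corner. That is a property of the modelling configuration, not a bug.

### Smooths and penalties

* Univariate smooths use cubic B-splines on equally spaced knots, default
  basis dimension k = 10. The penalty is the exact integrated squared second
  derivative, assembled by Gauss–Legendre quadrature per knot interval
  (exact: the integrand is piecewise quadratic). Its null space is exactly
  the straight lines, so λ → ∞ collapses a smooth to a linear effect.
* Day-of-year is cyclic. The basis is a folded (periodic) B-spline basis
  with period 365 and phase (doy − 1) mod 365, so doy 366 coincides with
  doy 1 and the value and first two derivatives are continuous across the
  wrap. The cyclic penalty's null space is the constants.
* The space–time term T is a tensor-product smooth with marginal bases
  (cubic lon, cubic lat, cyclic doy), default k = (8, 8, 6), and the
  standard sum of marginal-penalty Kronecker terms, one smoothing parameter
  per margin.
* Every smooth carries a sum-to-zero constraint (1ᵀXβ = 0), absorbed by a
  Householder reparameterization, so smooth contributions average to zero
  over the training rows and the intercept is identifiable.
* A `linear` basis (one centred, unpenalized column) gives the GLM limit of
  each smooth; fitting the same covariates with `linear` terms yields the
  GLM that the GAM is compared against, under the identical family and link.

### Fitting

Penalized IRLS: working weights w = 4η²/V(μ) and working response
z = η + (y − μ)/(2η) for the square-root link; each step solves
(XᵀWX + Σλₛ Sₛ)β = XᵀWz. The square-root link is not canonical and
unguarded steps can cross zero, so η is floored at 10⁻³ during iterations,
initialisation is η = √(y + 0.1), and steps are accepted only if the
penalized deviance does not increase (step-halving up to 30 times).
Convergence is a relative penalized-deviance change below 10⁻⁷ (cap 200
iterations, failure raises with the trace).

Smoothing parameters minimise the GCV score of the converged working linear
model, n·RSS_w/(n − tr A)², coordinate-wise per penalty: a coarse log₁₀λ
grid scan over [−6, 10] followed by bounded refinement (±2 decades), for a
configurable number of outer sweeps (default 2). Each penalty matrix is
normalised to unit Frobenius norm so λ scales are comparable across
covariates with very different ranges. θ is estimated between sweeps by
bounded 1-D profile maximum likelihood on log θ ∈ [log 10⁻³, log 10⁷].

The coefficient covariance is the Bayesian posterior covariance
V = (XᵀWX + S_λ)⁻¹, standard for penalized splines; effective degrees of
freedom are per-block traces of (XᵀWX + S_λ)⁻¹XᵀWX, and
AIC = −2ℓ + 2(edf + 1) (the +1 for the profiled θ). Deviance explained is
1 − D/D₀ with D₀ from a one-parameter intercept-only fit of the same
family. The null deviance benchmark and the reported R² therefore share the
same θ.

Prediction clamps out-of-range covariates to the training range (count
logged) and returns η̂ = Xβ, μ̂ = η̂², se(η̂) = √diag(XVXᵀ). Response curves
report the smooth's link-scale contribution f̂ with a ±2 SD band and a
signal-to-noise mask (se < |f̂|/2, i.e. SNR ≥ 2), matching how such curves
are read: only regions passing the mask are interpreted.

## Feature selection

Selection operates on the standardized (mean 0, sd 1, training statistics
only) covariate table with the transformed response, under a Gaussian
GLM — consistent with the standardize-then-power-transform pipeline; the
family of the original selection stage is not part of the record, so
ordinary least squares is used as the natural default. The four fits:

* **GLM** — OLS with t-statistics and AIC = n·log(RSS/n) + 2(p+1)
  (convention recorded on the fit; the Gaussian constant is dropped).
* **Ridge** — closed-form (XᵀXc + λI)⁻¹Xᵀyc on centred data, intercept
  unpenalized, λ by tenfold-CV MSE over a log grid.
* **Lasso** — coordinate descent (objective RSS/(2n) + λ‖β‖₁) on a
  100-point log grid descending four decades from λ_max = max|Xᵀ(y−ȳ)|/n,
  tenfold CV with the one-standard-error rule. The grid and rule are a
  standard reproducible default, not an optimised choice.
* **Stepwise AIC** — greedy bidirectional search from the full model,
  applying the single add/drop move that most reduces AIC, stopping at a
  local minimum; ties break to the lowest column index so the path is
  deterministic given column order.

Variable importance is VI_j = |t_j|/Σ|t_k| × 100. Penalized fits have no
canonical t-statistic, so ridge/lasso importances use a post-selection OLS
refit on the active set; unselected covariates get VI 0.

## Covariates

Memory windows are inclusive of the survey date: a "10-day" window spans 11
daily values (the convention that matches a 5–15 March window for a
15 March survey), and advancing the survey date by one day shifts the
window by one day. Threshold counts (rain ≤ 0 mm "dry days", tmin < 18 °C,
tmax > 42 °C) are computed for both windows — six covariates — which makes
the candidate arithmetic close: 5 weather variables × 2 windows × 3
statistics − 2 rain minima (uninformative: almost always 0) + 6 counts +
NDVI + daylength + 3 soil fractions = 39 candidates. The 12-name exclusion
list (all tmin summaries, both rain maxima, the short-window tmax min/max,
both dry-day counts) yields the 27-covariate full model; with lon, lat and
doy in the tensor the model carries 30 variables. The exclusion list is
configurable — only the printed sizes (39/27/10) are contractual; the
reduced set of 10 names is fixed. Grid extraction is nearest-cell in degree
space (appropriate on a regular 0.05° lat-lon grid; ties go to the lower
index); NDVI comes from the calendar month containing the survey; rows with
negative NDVI or insufficient (< 60 days) weather history are dropped with
logged counts, so dropped + retained = input always holds. Daylength uses
the standard declination formula δ = −23.44°·cos(2π(doy+10)/365) with the
hour-angle equation; it agrees with the NOAA Fourier-series declination to
under 0.1 h away from the polar circles.

## Evaluation protocol

An 80:20 train/holdout split, with the training 80% further labelled into
ten CV folds: each CV iteration trains on 72% of all rows and tests on 8%.
CV is for model/hyperparameter choice only; reported metrics come from the
20% holdout unless labelled otherwise (each report row records its split).
RMSE is reported on the transformed (sixth-root) scale, the model's
estimand; rank correlations use average-rank ties (τ is τ-b). The
observed-vs-predicted diagnostic bins observed densities (zeros isolated in
the first bin, edges straddling 0.6 and 1.0 individuals m⁻²) and reports
the mean bias per bin.

## Mapping and uncertainty

Per-cell covariates are engineered identically to survey rows, so a cell
containing a survey site reproduces that survey's covariate row for the
same date. The total variance on the density scale combines two sources:

* model variance, delta-method through the link and back-transform:
  Var_model = (dD/dμ · dμ/dη)² · se(η̂)², with dμ/dη = 2η and
  dD/dμ = (1/λ)μ^(1/λ−1) when the sixth-root path is active;
* class-sampling variance: the predicted density is classified into the
  scheme and the variance of the class's sampling distribution is estimated
  by Monte Carlo (default 200 draws, fixed seed), i.e. the noise the
  class-to-density conversion would inject at that abundance.

The uncertainty fraction is √(total variance)/estimate. Cells farther than
50 km (haversine, spherical Earth R = 6371 km; ellipsoidal corrections
< 0.3% are irrelevant at this threshold) from every ever-surveyed site are
masked; the mask depends only on the site set, never on the date. Unmasked
cells are binned by terciles of estimate and uncertainty fraction into a
3 × 3 bivariate class, coloured by bilinear blending between white (low/
low), blue (high density, low uncertainty), yellow (low density, high
uncertainty) and grey (high/high). A constant field falls back to a single
bin with a warning. Grids export to CSV plus a JSON legend (no GeoTIFF
writer is included; the CSV carries cell centres explicitly).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular region or year:

* **Weather** — each daily field is a sinusoidal seasonal mean (southern-
  hemisphere phase, maxima mid-January) plus a static spatially smooth
  offset plus spatially smooth AR(1) anomalies (default autocorrelation
  0.7). Cross-field couplings exercise the covariate code paths: tmin is
  tmax minus a positive spread, vapour pressure increases with tmin, solar
  radiation is anti-correlated with rain. Rain is zero-inflated (wet day iff
  a smooth AR(1) latent exceeds a threshold; ~70% dry days at default),
  so dry-day counting is exercised.
* **NDVI** — monthly, smooth in space, seasonal, clipped to (−0.19, 1.0];
  occasional negatives (well under 1% of cells) exercise the NDVI filter.
* **Soils** — three smooth positive fields normalised to a spatially
  varying total slightly below 1 (an exact-constant total would make one
  fraction collinear with the intercept, which real soil products are not).
* **Surveys** — dates are restricted to September–May when `season_only`
  and always leave 60 days of weather history; locations mix points along
  synthetic piecewise-linear transects with ~10 km spacing (roadside
  clustering) and a uniform background, controlled by `roadside_bias`,
  recorded to 0.01°. The latent predictor is additive on the square-root
  scale — η = η₀ + Σf_j(x_j) + spatial hotspot + seasonal term, clamped at
  a floor of 0.05 (the square-root link needs η > 0) — so the GAM's
  estimand coincides with the generator's truth and parameter recovery is
  well-posed. Realised densities are Gamma–Poisson (negative binomial,
  dispersion θ = 0.5) counts over a 10 m² sampling unit, giving exact
  zeros and 0.1 m⁻² density granularity; classes come from the scheme's
  half-open intervals; positive surveys are nymph with probability 0.125,
  else adult.
* **Calibration** — η₀ = 0.08 at the default effect amplitudes puts the
  fraction of positive surveys at 31–35% across seeds, matching the ~32%
  presence rate characteristic of the surveillance programme.
* **Zero inflation** — an optional `zero_inflation` knob records truly
  occupied sites as absent with the given probability (detection failure).
  It is off by default; it exists because the documented advantage of
  positives-only (nymph) models arises from excess zeros the NB model
  cannot replicate, and a generator whose zeros are exactly NB-distributed
  does not show that effect.

What the generator does **not** emulate: migration and wind transport, egg
diapause and multi-generation dynamics, realistic road networks,
station-density-dependent interpolation error in the weather fields, or the
true (non-public) class boundaries and per-class survey frequencies of the
real programme, whose defaults here are illustrative. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
known structure under the stated assumptions — not predictive skill on the
real survey database, whose headline metrics are expressly out of scope.

## Problem sizes and determinism

Test and acceptance runs use 2,500–10,000 surveys on a 2° × 2° grid over a
single September–May season, and a full-size recovery experiment of 5,000
rows with k = (8, 8, 6) tensors; these sizes give stable estimates for
every quantity asserted while keeping the whole suite around a minute. All
randomness flows through seeded `numpy` generators (environment and surveys
draw independent substreams of the config seed), so every artefact is
bit-reproducible given the seed.

## Known limitations

* GCV on the working model (performance iteration) can undersmooth
  relative to exact REML; the recovery tests bound the practical effect.
* The NB quasi-likelihood on sixth-root responses usually profiles θ to
  very large values (see above); AIC comparisons across families should not
  be over-interpreted.
* Predictions at covariate values outside the training range are clamped,
  which flattens extrapolated response surfaces rather than extrapolating
  spline polynomials (a deliberate conservatism).
* The stepwise search is greedy; the exhaustive-enumeration test shows it
  reaches the global AIC optimum in most, not all, small problems.
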