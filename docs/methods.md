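# Methods

## Model

All estimators fit the same mean structure: a segmented linear
regression on the observation index `t = 1..N` with a single
interruption at `T_I`,

    Y_t = β₀ + β₁ t + β₂ D_t + β₃ (t − T_I) D_t + ε_t,

where `D_t = 1{t ≥ T_I}`.  Under this convention the level-change
indicator switches on at the first post-interruption observation while
the slope-change regressor is exactly zero at `T_I` and increments by
one thereafter, so β₂ is the instantaneous displacement from the
extrapolated pre-trend at the interruption and β₃ the subsequent
change in trend.  Series are eligible only with at least three points
in each segment; this is enforced at dataset construction, before any
design matrix exists.

When a series declares a transition window between the pre segment and
`T_I`, the design gains a transition-level indicator and a
within-window trend (1, 2, … over the window).  The transition points
are thereby absorbed by their own segment: β₂ and β₃ continue to
contrast the pre segment with the post segment, and the effect
extraction ignores the transition coefficients entirely (lookup is by
column role, not position).  A one-point transition window makes the
two transition columns identical and is rejected as rank deficient —
the error names the offending column.  When a file declares a second
interruption, the series is truncated just before it; only the first
interruption and its adjacent segments are modelled.  Calendar gaps
are not supported: time is the observation index.

## Error structure and estimators

Errors are stationary AR(1): ε_t = ρ ε_{t−1} + w_t, w_t ~ N(0, σ²),
stationary variance σ²/(1−ρ²).  Throughout, σ² denotes the innovation
variance and V(ρ) the covariance scale with entries
ρ^|i−j|/(1−ρ²).  The quasi-differencing (Prais-Winsten) transform —
first row scaled by √(1−ρ²), later rows r_t − ρ r_{t−1} — whitens
this structure exactly, so every generalised fit is an OLS on
transformed data; `log det V = −log(1−ρ²)` in closed form.  Dense
covariance matrices appear only in the test oracles.

- **OLS**: no adjustment; σ̂² = SSR/(N−p), t(N−p) inference.  The OLS
  root mean square error is the standardisation divisor used by the
  comparison stage.
- **NW**: OLS coefficients; Bartlett-kernel HAC sandwich with maximum
  lag 1 (weight ½ on lag-1 cross-products), small-sample factor
  N/(N−p), t(N−p) inference.  The point-estimate identity with OLS is
  exact by construction.
- **PW**: iterated feasible GLS.  ρ̂ is the lag-1 sample
  autocorrelation of the original-scale residuals
  (Σ e_t e_{t−1} / Σ e_t²); iteration stops when ρ̂ moves by less than
  1e-6 or after 100 rounds.  Iterated (not two-step) is used, matching
  the common default of the econometrics packages that popularised the
  method.
- **REML**: ρ̂ maximises the profiled restricted log-likelihood
  −½[(N−p)·log σ̂²(ρ) + log det V + log det XᵀV⁻¹X] over
  (−1+δ, 1−δ), δ = 1e-6, by bounded scalar minimisation (tolerance
  1e-8).  Coefficients are GLS at ρ̂ with the N−p variance divisor.
  Plain REML uses normal quantiles; the Satterthwaite variant computes
  per-coefficient ν = 2·Var(cᵀβ̂)²/(gᵀAg), with g the gradient of
  Var(cᵀβ̂) in (σ², ρ) and A the inverse observed information of the
  restricted likelihood (central differences with relative steps
  ≈ 1.2e-4), floored at 2.  With ρ known and fixed this reduces
  analytically to ν = N−p, which the tests verify to 1e-6.  A Wald
  interval for ρ̂ from the curvature of the profile likelihood
  (truncated to (−1, 1)) is attached; the choice of Wald-on-profile is
  an assumption — the original analyses do not document how their
  autocorrelation intervals were formed.
- **ARIMA**: exact Gaussian maximum likelihood for regression with
  AR(1) errors, stationary initial condition, evaluated by prediction-
  error decomposition and profiled to a scalar search over ρ (the ML
  variance divisor is N).  Standard errors default to the outer
  product of per-observation scores, which is what the classical
  AR(1)-regression software computes by default and is the variant
  under which the corpus' characteristic pattern — ARIMA standard
  errors systematically larger than every other method — reproduces;
  the observed-information (numerical Hessian) variant is available
  via `se_method="hessian"` and gives noticeably smaller standard
  errors on short series.  Inference is z-based.

Estimates of ρ on the boundary (|ρ̂| ≥ 1 − 1e-5) are flagged invalid
rather than clamped and are excluded from all comparisons, as are
fits whose iteration leaves (−1, 1).  Zero-residual (noise-free) data
are permitted: such fits carry a degenerate flag, report NaN p-values,
and are excluded from standardised comparisons because the RMSE
divisor must be positive.

## Synthetic collections

The generator replaces an unavailable corpus of 190 published
public-health series and reproduces the structure the analysis model
assumes, at the corpus' summary statistics:

- **Series length**: log-normal with μ = log 41 and σ = 0.774 (the
  mean of the two one-sided quartile fits to an IQR of 25–71),
  truncated to [8, 500] by resampling.  The pre-segment fraction is
  uniform on [0.25, 0.75], resampled until both segments have ≥ 3
  points; `T_I = n_pre + 1` always.
- **Autocorrelation**: true ρ from Beta(1.73, 1.66) scaled to
  (−0.5, 0.95), whose quartiles (−0.03, 0.24, 0.52) track the
  corpus-reported REML estimate summaries (median 0.20, IQR −0.01 to
  0.54).  Because ρ̂ is biased downward in short series, the observed
  REML medians on generated collections land near 0.14–0.20.
- **Effects**: level changes of {0, 1, 2}·σ and slope changes of
  {0, 0.1}·σ with random signs, echoing the corpus' standardised
  magnitudes (median |level| ≈ 1.2–1.5 σ, |slope| ≈ 0.13 σ); intercept
  10, trend 0.1, σ = 1 (scale-free downstream because everything is
  RMSE-standardised).

Every series derives its noise stream from a child seed spawned from
the collection seed, so collections and manifests are byte-identical
functions of their parameters.

What the generator does **not** emulate: count/binary/proportion
outcomes analysed with a linear model, seasonality, digitisation
error, heteroskedasticity, and model misspecification — all present in
real corpora.  Passing comparison patterns on synthetic collections
therefore demonstrates the machinery and the estimator-driven part of
the differences, not the full heterogeneity of published series.

## Comparison stage

Pairwise comparisons use only series where both methods produced valid
fits; denominators are reported per pair.  Direction is standardised
per pair by flipping both estimates when the anchoring method's
estimate is strictly negative (anchor = first method by default;
anchoring to the second is the sensitivity variant).  Limits of
agreement use the n−1 standard-deviation divisor.  Standard-error
agreement is computed on the log scale and re-expressed as geometric
mean ratios.  Significance is categorised with p ≤ 0.05 counted as
significant (the strict-inequality convention is a configuration
switch; the source analyses use both conventions in different places),
and the finer gradation uses boundaries 0.01/0.05/0.10 with the same
membership rule.  Kappa is unweighted Cohen's kappa and is reported
for the binary scheme; the fine scheme is descriptive.
Autocorrelation summaries are stratified at ≥ 24 and ≥ 100 points and
on the common-support subset where all three ρ-estimating methods are
valid.

## Numerical choices and edge cases

- Bounded scalar optimisation (Brent) for both likelihood searches;
  xatol 1e-8.  Boundary hits are exclusions, not clamps.
- Numerical Hessians use central differences with per-coordinate
  relative steps ≈ 1.2e-4, shrunk near the ρ boundary to stay inside
  (−1, 1).
- PW's ρ̂ update is bounded by 1 in magnitude by Cauchy-Schwarz, so
  divergence manifests as a boundary hit rather than an overflow.
- Ties in the fine p-value categories follow the configured boundary
  convention; boundary p-values are measure-zero on continuous data.

## Problem sizes

The test suite's Monte-Carlo checks use 1000 replicates at n = 100 for
parameter recovery (with the dense-matrix REML oracle evaluated on a
150-replicate subsample to establish the small-sample ρ̂ target), 1000
replicates at n = 10 and n = 12 for the short-series bias ordering,
and the default 190-series collection for the pipeline-level patterns.
These sizes give Monte-Carlo standard errors comfortably below the
tolerances asserted.

## Known limitations

- The transition-period encoding (own level + own trend) is one of
  several defensible parameterisations; published analyses rarely
  document theirs.
- REML autocorrelation confidence intervals are Wald-type on the
  profile likelihood; profile-likelihood inversion would be more
  accurate near the boundary.
- The Satterthwaite information matrix is numerical; analytic
  derivatives would be faster and marginally more accurate.
- Only lag-1 autocorrelation is modelled; higher-order ARMA error
  structures and seasonal terms are out of scope.
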