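# itscompare

Six-estimator comparison pipeline for interrupted time series (ITS)
segmented regression with lag-1 autocorrelated errors.

## The problem

An interrupted time series design evaluates a policy or exposure by
modelling an outcome measured repeatedly before and after an
interruption.  The standard analysis fits the segmented linear model
(Huitema–McKean parameterisation)

    Y_t = β₀ + β₁·t + β₂·D_t + β₃·(t − T_I)·D_t + ε_t

where `t = 1..N` is the observation index, `T_I` the first
post-interruption time point, `D_t` the post-interruption indicator,
β₂ the immediate **level change** and β₃ the **slope change**.  The
errors follow a stationary AR(1) process, ε_t = ρ·ε_{t−1} + w_t with
w_t ~ N(0, σ²).  Autocorrelation ρ is what makes the choice of
estimator matter: ignoring it understates standard errors; estimating
it from short series is badly biased.

`itscompare` implements six estimation methods for this model —

| method | adjustment for autocorrelation | inference |
|---|---|---|
| OLS | none | t(N−p) |
| NW | Newey-West lag-1 HAC standard errors | t(N−p) |
| PW | Prais-Winsten iterated feasible GLS | t(N−p) |
| REML | restricted maximum likelihood for ρ | z |
| REML-Satt | REML + Satterthwaite df (floored at 2) | t(ν) |
| ARIMA | exact Gaussian ML, AR(1) errors | z |

— and the comparison machinery used to contrast them across a
collection of series: RMSE-standardised effect estimates, Bland-Altman
mean differences and 95% limits of agreement, geometric mean ratios of
standard errors, confidence-interval width comparisons on a common
[−0.5, 0.5] scale, significance concordance (percent agreement and
Cohen's kappa) at the 5% level and on a finer gradation, and
autocorrelation summaries stratified by series length.

Because the published collections this kind of study draws on are
rarely deposited, the package ships a first-class synthetic-data
module that generates collections with the corpus' statistical
structure (log-normal series lengths, median 41, IQR 25–71; true ρ
from a scaled Beta with median ≈ 0.2; level changes of 0–2 σ).

## Worked example

```python
from itscompare import (SeriesParams, simulate_series, build_design,
                        fit_method, METHODS)

ds = simulate_series(SeriesParams(n_pre=20, n_post=20,
                                  beta=(10, 0.5, 2, 0.1),
                                  rho=0.4, sigma=1.0, seed=3))
design = build_design(ds)
for m in METHODS:
    fit = fit_method(m, design, ds.y)
    i = design.roles["level_change"]
    print(f"{m:9s} level={fit.beta[i]:6.3f} se={fit.se[i]:.3f} "
          f"rho={fit.rho_hat if fit.rho_hat is not None else float('nan'):.3f}")
```

prints

```
OLS       level= 3.137 se=0.719 rho=nan
NW        level= 3.137 se=0.586 rho=nan
PW        level= 3.134 se=0.738 rho=0.033
REML      level= 3.102 se=0.841 rho=0.185
REML-Satt level= 3.102 se=0.841 rho=0.185
ARIMA     level= 3.134 se=0.902 rho=0.039
```

The true level change is 2 in units of σ; all six methods agree on the
point estimate to within a few percent, but the standard errors fan
out from 0.59 (NW) to 0.90 (ARIMA) — exactly the spread that makes
significance statements method-dependent on real data.  Note that at
n = 40 the PW and ARIMA estimates of ρ (0.03–0.04) are far below the
generating value 0.4, while REML (0.18) is less biased.

The same analysis from the shell:

```
itscompare simulate --n-series 190 --seed 1 --out series/
itscompare fit series/sim0000.csv --method OLS --method REML
itscompare compare --input-dir series/ --out report/
itscompare report report/fits.csv
```

`compare` writes the full set of tables (per-series fits, exclusion
ledger, standardised estimates, pairwise Bland-Altman summaries,
CI-width comparisons, significance concordance, autocorrelation
summaries) as CSV.

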