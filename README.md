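# trendgls

**Is the trend you see in a small dataset real, or an artefact of
correlated noise?**

When the errors of nearby observations are positively correlated —
annual climate records, replicate measurements along a transect,
environmental or epidemiological monitoring data scattered over a region
— ordinary least squares (OLS) dramatically overstates the significance
of fitted trends.  Generalized least squares (GLS) corrects this *if*
the error correlation is known, but in small, highly correlated samples
the standard estimators of the AR(1) correlation parameter ρ (residual
lag-1 autocorrelation, 1 − d/2 from the Durbin–Watson statistic,
iterated maximum likelihood) are all biased toward zero, so GLS still
over-rejects the null.

`trendgls` implements the complete toolkit for this problem:

* **GLS trend estimation** with AR(1) correlation for equally spaced
  series (closed-form tridiagonal S⁻¹) and isotropic exponential
  correlation `exp(−r/r₀)` for data scattered in 1–3 dimensional space,
  including co-located observations from multiple source datasets
  (pseudo-distance ratio k_d).
* **Exact Durbin–Watson inference.**  The null moments
  E(d) = p/(N−k−1), V(d) = 2(q − pE(d))/((N−k−1)(N−k+1)) are computed
  from the design matrix (and, for GLS-transformed residuals, from the
  principal square root P of S⁻¹), and tail probabilities come from the
  beta approximation: d/4 ~ Beta(a, b) with moments matched to E(d),
  V(d).
* **The tanh-adjusted Durbin–Watson (TADW) estimator**

  ρ̂ = Re[ tanh( (artanh(1 − d/2) − artanh(1 − E(d)/2)) · c(N, k) ) ],

  which centers d at its exact null expectation and re-expands the
  small-sample compression of its distribution in artanh space
  (c = (N−k+2)/(N−k−4), → 1 as N → ∞).  TADW is markedly less biased
  than ML for ρ near +1 at small N.
* **Extrapolated t-values** t_extrap = 2·t_TADW − t_DW, which restore an
  approximate t(N−k−1) null distribution for the GLS slope t whenever
  ρ < ρ_max = 0.8·(N/100)^0.07, plus the matching extrapolated standard
  errors for prediction intervals.
* **The nearest-new-neighbour path**, which generalizes "successive
  residuals" to scattered points: start at the point with the greatest
  total distance to all others, repeatedly step to the nearest unvisited
  location, and treat path-ordered residual differences exactly like
  time-series forward differences.  The correlation length is recovered
  as r₀ = −r̄ / ln ρ̂ with r̄ the mean path step.  A weighted
  exponential-model semivariogram fit is included as the conventional
  comparator, and a full decision procedure (`auto_analyze`) chooses
  between OLS, the GLS candidates and extrapolation, or flags the model
  for revision.
* **Simulation harnesses** for AR(1) series and exponentially correlated
  spatial fields, with null-calibration, estimator-bias and
  trend-detection experiments.

Everything is exposed both as a statsmodels-style model/results API
(`TrendModel(...).fit(...)` → `TrendResults` with `params`, `bse`,
`tvalues`, `summary()`) and as a `trendgls` command line tool
(subcommands `fit`, `test`, `predict`, `path`, `semivariogram`,
`simulate`).

## Worked example

Sixty annual values with a genuine trend of 0.02 per year buried in
AR1(ρ = 0.6) noise:

```python
import numpy as np
import trendgls as tg

rng = np.random.default_rng(7)
t = np.arange(1980, 2040, dtype=float)
y = 0.02 * (t - t.mean()) + tg.gen_ar1(60, 0.6, rng)

report = tg.TrendModel.from_series(t, y, degree=1).fit_auto()
print(report.summary())
```

```
=== automated trend analysis ===
OLS trend fit
N = 60, k = 1, df_resid = 58, s = 1.11471
        term       estimate      std err         t   Pr(>|t|)
   intercept      -0.536206       0.1439    -3.726  0.0004429
           t       0.045299      0.00831     5.451  1.072e-06
DW (ols): d = 0.7653, E(d) = 2.0344, V(d) = 0.06434, 95% interval [1.5419, 2.5248], two-tailed p = 2.374e-08 -> fail
--- GLS candidate [dw]: rho = 0.6174
GLS trend fit [CorrelationModel(ar1, N=60, rho=0.6174)]
N = 60, k = 1, df_resid = 58, s = 1.11943
        term       estimate      std err         t   Pr(>|t|)
   intercept      -0.495683       0.2894    -1.713    0.09213
           t      0.0428867      0.01586     2.704   0.008982
DW (gls_transformed): d = 2.0847, E(d) = 2.0340, V(d) = 0.06435, 95% interval [1.5415, 2.5245], two-tailed p = 0.8436 -> pass
--- GLS candidate [tadw]: rho = 0.6742
GLS trend fit [CorrelationModel(ar1, N=60, rho=0.6742)]
N = 60, k = 1, df_resid = 58, s = 1.19504
        term       estimate      std err         t   Pr(>|t|)
   intercept      -0.484965       0.3383    -1.434      0.157
           t      0.0422921      0.01828     2.314    0.02423
DW (gls_transformed): d = 2.2018, E(d) = 2.0340, V(d) = 0.06435, 95% interval [1.5414, 2.5244], two-tailed p = 0.5097 -> pass
branch: gls_dw (chosen: dw)
naive OLS t vs corrected t: intercept: -3.73 -> -1.71, t: 5.45 -> 2.70
```

Reading the output: the OLS residuals have d = 0.77 where roughly 2.03
was expected under no correlation (p ≈ 2×10⁻⁸), so the naive slope
t = 5.45 cannot be trusted.  Both GLS candidates pass the
transformed-residual test; the one from ρ = 1 − d/2 tests slightly
better and is reported.  The corrected slope t is 2.70 — the trend is
still significant (it is real here by construction), but the evidence
is an order of magnitude weaker than OLS claimed.  A pointwise
prediction band at any future year comes from
`report.final_fit.predict([2045.0])`, which for this fit gives a mean
of 1.027 with 95% bounds [−1.548, 3.601].

The same workflow from a shell:

```sh
trendgls fit --input series.csv --time year --response co2 --degree 1
trendgls test --input field.csv --coords x,z --response y
trendgls simulate sweep --trials 100 --n 100 --rho 0.75 --seed 1
```

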