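# trendpower

Power, type-S and type-M error analysis for trend detection in **short,
noisy time series of abundance estimates** — the situation conservation
biologists face when monitoring cetaceans and other elusive, wide-ranging
species: a handful of survey estimates (3–13 points is typical), each with a
coefficient of variation of 10–50%, from which a population decline must be
detected and quantified.

## The model

Monitoring yields abundance (or density) estimates `ŷ_t` on `T` occasions.
All inference works on ratios to the first estimate, `p̂_t = ŷ_t / ŷ_1`.
If the population declines geometrically to a fraction `r` of its initial
size over the study period, the true ratios satisfy

```
p_t = r^((t-1)/(T-1)),    log p_t = x_t · β,    x_t = (t-1)/(T-1),  β = log r
```

so the trend is a **no-intercept linear regression of log ratios on scaled
time**: the line is anchored at the baseline (x=0, log ratio 0) and `r̂ = e^β̂`
is the estimated fraction remaining (`r = 0.5` means a 50% decline).
Estimates carry lognormal noise with per-occasion CVs drawn uniformly between
scenario bounds.  Because every ratio shares the baseline estimate `ŷ_1` in
its denominator, the regression errors are correlated — the central reason
naive significance tests misbehave on such data.

Three estimators of β are provided, as scikit-learn style regressors:

* **unregularized** — maximum likelihood (OLS through the origin);
* **normal prior** — MAP under an informative Normal(0, log(2)/2) prior
  spanning a halving to a doubling of the population;
* **cauchy prior** — MAP under a weakly-informative Cauchy(0, s) prior whose
  scale is set by a skeptical probability ξ that the population halves:
  `s = −log(2)/tan(π(ξ−1/2))`, so the no-change null is favoured with prior
  odds `(1−ξ)/ξ` (39:1 at ξ = 0.025).  Fit by a scale-mixture-of-normals EM;
  the heavy tail shrinks weak signals strongly but yields to strong ones.

A Monte Carlo engine sweeps a factorial grid of scenarios (study length 3–30,
overall decline 1–50%, five CV regimes; 5,320 cells) and reports power /
type-I error, type-S (wrong sign among significant estimates), type-M
(exaggeration ratio), bias and confidence-interval coverage per cell.
A case-study layer applies the same estimators to real `(year, estimate)`
series, reports annualised growth rates `r̂_a = r̂^(1/span)`, and tracks their
stability as an ongoing study accumulates data.

## Worked example

Generate a synthetic 10-year monitoring series (true decline 5%/yr, CV 0.2)
and fit the weakly-informative trend:

```
$ trendpower make-fixture --seed 5 --n-points 10 --annual-rate 0.95 --cv 0.2 --out demo.csv
$ trendpower fit --input demo.csv --prior cauchy --alpha 0.20
{
  "n_points": 10,
  "span_years": 9,
  "beta_hat": -0.0435,
  "se": 0.0497,
  "p_value": 0.4043,
  "r_hat": 0.9574,
  "ci_r": [0.8938, 1.0256],
  "annual_growth_rate": 0.9952,
  "ci_annual_growth_rate": [0.9876, 1.0028]
}
```

The fitted overall trend `r̂ = 0.957` (a 4.3% decline over the nine-year
span, annual growth rate 0.995) is not statistically significant at the 20%
level on these ten noisy points — the prior has pulled a noisy slope toward
no change (the unregularized fit on the same series gives `r̂_a = 0.985`,
p = 0.137).  Both estimates are attenuated relative to the true 5%/yr
decline, illustrating why power for small declines is low at this sample
size.  `trendpower stability --input demo.csv` refits on every prefix of the
series to show how the estimate settles as data accumulate, and
`trendpower simulate-grid` runs the full Monte Carlo sweep from a TOML/YAML
config (see `docs/metrics_schema.md` for the output columns).

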