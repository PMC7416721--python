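# Methods

## Data-generating mechanism

A population is observed on `T ≥ 3` evenly spaced occasions.  Its true
trajectory is geometric: the fraction remaining at occasion `t` is
`p_t = r^((t−1)/(T−1))`, so `p_1 = 1` and `p_T = r`.  `r` is the parameter
of interest — the fraction of the initial population remaining at the end of
the study period (`r = 1` is the no-trend null; `r = 0.5` a halving).

Each occasion yields an abundance estimate
`ŷ_t = baseline · p_t · exp(ε_t)`, with `ε_t ~ Normal(0, σ_t²)` and
`σ_t = sqrt(log(1 + cv_t²))` — the lognormal identity mapping a coefficient
of variation to a log-scale standard deviation.  Per-occasion CVs are drawn
independently `Uniform(cv_lower, cv_upper)`; the "CV = 0.1" regime is the
degenerate uniform with equal bounds.  No relationship between abundance
level and CV is assumed.  The noise is **median-unbiased** (`E[ε] = 0`, no
`−σ²/2` mean correction): the median of simulated `exp(log ratio)`
converges to `p_t`, which is the simplest reading of "estimates are
lognormal around the truth" and is property-tested.

Analysis operates on `x_t = (t−1)/(T−1)` and `y_t = log(ŷ_t/ŷ_1)`.  The
baseline abundance cancels exactly (scale invariance is tested), but the
baseline's noise `ε_1` enters every ratio, creating strong positive
correlation among the `y_t`.  This correlation is deliberate and central:
it is what makes the naive significance test anti-conservative, and the
package's Monte Carlo machinery exists to quantify that.  A diagnostic mode
(`baseline_noise=False`) sets `ε_1 = 0`, making the `y_t` independent; in
that design the t-test with `df = T − 2` is exact, which serves as the
engine's calibration oracle.

Default factorial grid: `T ∈ {3, …, 30}` (28 values), `r` on 38 equally
spaced values in `[0.50, 0.99]`, and five CV regimes (fixed 0.1; uniform
with upper bound 0.2, 0.3, 0.4, 0.5) — 5,320 scenarios, 10,000 replicates
each by default.  The `r` grid spacing is a package choice; any grid can be
supplied through `ScenarioGridConfig`.

## Estimation

The trend model is a no-intercept regression `y_t = x_t β + error`,
`β = log r`.  All fits use all `T` points including the anchored baseline
`(0, 0)`, and report `df = T − 1` residual degrees of freedom (the anchored
residual is identically zero; this mirrors a standard no-intercept Gaussian
GLM fit on the full series).  Writing `Sxx = Σx²`, `Sxy = Σxy`:

* **Unregularized (ML).**  `β̂ = Sxy/Sxx`; `σ̂² = RSS/(T−1)`;
  `se = sqrt(σ̂²/Sxx)`.
* **Normal prior (ridge MAP).**  Prior `β ~ Normal(0, s²)` with default
  `s = log(2)/2 ≈ 0.347`, chosen so that ~95% of the prior mass lies
  between a halving and a doubling over the study period.  The MAP estimate
  solves `β̂ = Sxy/(Sxx + σ̂²/s²)` jointly with `σ̂² = RSS(β̂)/(T−1)`, by
  fixed-point iteration; `se = sqrt(σ̂²/(Sxx + σ̂²/s²))`.
* **Cauchy prior (EM MAP).**  Prior `β ~ Cauchy(0, s)` with
  `s = −log(2)/tan(π(ξ−1/2))`; ξ (default 0.025) is the prior probability
  that the population halves (equivalently doubles, by symmetry), giving
  prior odds `(1−ξ)/ξ = 39:1` for the null.  The Cauchy is expressed as a
  normal scale mixture and fit by EM: each iteration solves the ridge above
  with an adaptive prior variance `s_p²`, updated as
  - `map` variant: `s_p² ← (β̂² + s²)/2` — the fixed point solves the exact
    penalized score equation `Σx(y−xβ̂)/σ̂² = 2β̂/(s² + β̂²)`, i.e. it is a
    stationary point of the penalized profile likelihood
    `−(T−1)/2·log RSS(β) − log(1 + (β/s)²)`;
  - `with_variance` variant (default): `s_p² ← (β̂² + V + s²)/2` where `V`
    is the current sampling variance of `β̂`, the update used by augmented
    iteratively reweighted least squares implementations of this prior.

  Priors act on the `β = log r` scale with absolute (not data-rescaled)
  scales, so "halving/doubling" retains its literal meaning.

EM numerical choices: start at the ML estimate; stop when `|Δβ̂| < 1e−8` or
after 100 iterations; after half the budget successive iterates are averaged
to damp oscillation; non-convergence is flagged on the result rather than
raised.  The dispersion is always re-estimated from the `T` real points only
(no pseudo-data in the RSS).  A perfect fit (`RSS = 0`, e.g. noiseless
input) short-circuits: the estimate is exact, `se = 0`, the p-value is
reported as 0 and the fit is flagged degenerate.

Under the heavy-tailed prior the penalized posterior can be **bimodal**
(a shrunken mode near 0 and a data mode near the ML estimate).  Starting
the EM at the ML estimate selects the data-side mode, which keeps `β̂`
continuous and monotone in the prior scale between total shrinkage (s→0)
and the ML estimate (s→∞); both properties are tested.  Oracle tests verify
the fixed points against brute-force grid search of the profile objective
in the tracked basin.

Inference: two-tailed p-values from the Student-t distribution on `T − 1`
df (dispersion is estimated); significance is strict (`p < α`); confidence
intervals are equal-tailed t intervals at level `1 − α`, so the CI level is
tied to the significance level in the Monte Carlo sweeps (95% with α=0.05,
80% with α=0.20); `r̂ = exp(β̂)` and its CI is the elementwise exponential.

## Monte Carlo error rates

For each (scenario, approach, α) the engine simulates replicate series
(shared across approaches and α levels within a scenario, so comparisons
are paired), fits, and reports:

* **rejection rate** `#(p < α)/n` — power when `r < 1`, type-I error when
  `r = 1`;
* **type-S rate** — among significant replicates, the fraction whose
  estimated trend has the wrong sign;
* **type-M ratio** — among significant replicates, the exaggeration ratio
  `mean(|β̂|)/|log r|` on the log scale; a companion ratio on the
  remaining-fraction scale (`mean(r̂−1)/(r−1)`) is emitted alongside since
  the scale convention is a genuine choice;
* **bias** — `mean(r̂) − r` over all replicates (plus the log-scale bias);
* **coverage** — unconditional, and conditional on significance.

Conditional quantities are undefined (`None`/missing, never zero or NaN
arithmetic) when the true effect is zero or no replicate is significant;
`n_significant = rejection_rate·n_reps` exactly.  Reproducibility: each
scenario gets a dedicated substream spawned deterministically from the
master seed, so grid output is byte-identical across reruns and worker
counts.

## Case studies

Real series are `(year, estimate[, cv])` CSVs; years may be unevenly
spaced, in which case `x` is scaled elapsed calendar time.  Estimate-level
CVs are carried but never used as weights — the method targets settings
where precision metadata is unreliable or absent.  Annual growth rates use
**elapsed calendar years**: `r̂_a = r̂^(1/(year_N − year_1))`, resolving the
ambiguity between "number of estimates" and "elapsed years" for uneven
series in favour of the physically meaningful exponent; CI endpoints are
transformed identically (monotone map).  The expanding-window analysis
refits prefixes of 3, 4, …, N estimates, each with its own elapsed span.
The fixture generator produces synthetic stand-ins for published monitoring
series (geometric decline, the same lognormal noise model, 3–13 yearly
points).

## What the simulations do and do not show

The generator reproduces the statistical skeleton of real monitoring data —
short series, large and heterogeneous CVs, ratio-to-baseline analysis and
the resulting correlation — but not survey-level structure: no density
dependence or process noise, no temporal autocorrelation in the *true*
trajectory beyond the geometric trend, no relationship between abundance
and precision, and evenly spaced occasions only (the case-study layer, not
the simulator, handles uneven spacing).  Passing tests therefore validate
the estimators' behaviour under the stated noise model, not under every
real survey design.

A substantive finding the acceptance checks make explicit: with shared
baseline noise, the unregularized test rejects a true null far above its
nominal level (about 42% at α=0.05 for T=10, CV∈[0.1,0.3]).  Regularization
with the weakly-informative prior reduces this (to about 30% in the same
scenario) and the informative prior sits in between, but a Wald test built
on any MAP fit with a heavy-tailed prior cannot fully repair it: the Cauchy
tail deliberately releases large estimates, and shared baseline noise
manufactures exactly such estimates under the null.  Full type-I control in
this design would require either modelling the baseline correlation
directly or a test calibrated against the correlated null distribution —
both outside this package's scope.

## Known limitations

* Type-I control of the regularized tests is partial, not absolute (above).
* The EM posterior bimodality means the reported mode depends on
  initialization by design; the `map` variant plus the grid-search oracle
  make this auditable.
* Degenerate (noiseless) inputs report `p = 0`, a convention that keeps
  pipelines running but should not be read as evidence.
* Regularized CIs are narrower than unregularized ones on average and
  almost always pointwise (strictly so for the Cauchy prior across the
  tested fixtures), but a strong signal with tiny residual noise can make
  the informative-prior CI slightly wider — the shrunken fit's larger
  residual variance can outweigh the penalty's precision gain.
* `n_reps` defaults to 10,000 per scenario; the acceptance script uses
  5,000, which resolves the reported rates to a Monte Carlo SE of well
  under one percentage point.
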