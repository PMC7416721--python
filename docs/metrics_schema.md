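# Metrics CSV schema

Output of `trendpower simulate-grid` / `trendpower.run_grid`: one row per
(scenario, approach, significance level).  UTF-8, header row, `.` decimal;
undefined conditional metrics are empty cells.

| column                 | meaning                                                                 |
|------------------------|-------------------------------------------------------------------------|
| `scenario_id`          | 0-based index of the scenario in the grid                                |
| `T`                    | number of sampling occasions                                             |
| `r`                    | true fraction of the population remaining at the end of the period       |
| `cv_lower`, `cv_upper` | bounds of the per-occasion uniform CV distribution                       |
| `approach`             | `unregularized`, `normal` (informative prior), `cauchy` (weakly-inf.)    |
| `alpha`                | significance level; CIs are at level `1 - alpha`                         |
| `n_reps`               | Monte Carlo replicates simulated for this scenario                       |
| `rejection_rate`       | fraction of replicates with `p < alpha` (power if `r < 1`, type-I if `r = 1`) |
| `n_significant`        | `rejection_rate * n_reps`, exact count                                   |
| `type_s_rate`          | among significant fits: fraction with the wrong trend sign (empty if `r = 1` or none significant) |
| `type_m_ratio`         | among significant fits: `mean(abs(beta_hat)) / abs(log r)` (log scale; empty as above) |
| `type_m_ratio_r`       | same exaggeration ratio on the remaining-fraction scale: `mean(r_hat - 1)/(r - 1)` |
| `bias_r`               | `mean(exp(beta_hat)) - r` over all replicates                            |
| `bias_beta`            | `mean(beta_hat) - log r` over all replicates                             |
| `coverage`             | fraction of replicates whose CI for `r` contains the true `r`            |
| `coverage_significant` | same, restricted to significant replicates (empty if none)               |
| `n_degenerate`         | replicates with a perfect fit (zero residual sum of squares)             |

Single-series output of `trendpower fit` is JSON with keys `beta_hat`, `se`,
`df`, `p_value`, `ci_beta`, `r_hat`, `ci_r`, `annual_growth_rate`,
`ci_annual_growth_rate`, `n_points`, `span_years`, `approach`, `alpha`.
`trendpower stability` emits one CSV row per expanding window with
`n_points`, `span_years`, `beta_hat`, `p_value`, `r_hat`,
`annual_growth_rate`, `ci_lower`, `ci_upper`.
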