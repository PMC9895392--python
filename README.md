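# metasmd

Random-effects meta-analysis of two-arm continuous outcomes: standardized
mean differences (Cohen's d / Hedges' g), DerSimonian–Laird pooling with
heterogeneity statistics (Q, I², τ²), Begg and Egger publication-bias tests,
leave-one-out and subset sensitivity analyses, and median/IQR → mean/SD
conversion (Luo mean / Wan SD estimators). The GDF-15/GDM study tables
(12 GEO expression datasets and 5 serum-protein articles) are packaged as
fixtures, so every published pooled estimate of that combined analysis can
be recomputed end-to-end. A synthetic-study generator provides seeded
random-effects collections for testing and operating-characteristic
simulations.

## Library quick start

```python
import metasmd as ms

coll = ms.load_gdf15_fixture("mRNA", "late")        # 12 studies
effects = ms.effects_from_collection(coll, method="cohen")
pool = ms.dersimonian_laird(effects)
print(pool.pooled, pool.ci_low, pool.ci_high)        # 0.486 0.143 0.829

ms.beggs_test(effects).p_value                       # > 0.05
ms.eggers_test(effects).p_value                      # > 0.05
ms.restricted_analysis(coll)                         # confounder-excluding subset
```

Key types: `ArmSummary` (n, mean, sd), `StudyRecord`/`StudyCollection`,
`EffectEstimate` (SMD, variance, 95% CI), `PoolResult` (pooled effect, CI,
normalized weights, Q/I²/τ²), `SimConfig` (synthetic-collection parameters).

## CLI

The console script `metasmd` exposes:

| subcommand | purpose |
|---|---|
| `convert` | quantile-summary CSV (n, median, q1, q3, min, max) → n/mean/sd CSV |
| `effects` | per-study SMD CSV from a study table |
| `pool` | fixed or DL pooling → JSON (plus optional forest-table CSV via `--forest`) |
| `bias` | Begg + Egger tests → JSON |
| `loo` | leave-one-out sensitivity CSV |
| `simulate` | seeded synthetic study CSV |
| `oc` | operating characteristics (rejection rates, τ̂², CI coverage) → JSON |
| `reproduce-paper` | rerun every packaged fixture analysis, report deviations → JSON |

Study tables are headered CSV with required columns `study_id, timing,
level, n_case, mean_case, sd_case, n_control, mean_control, sd_control`
(optional: `sample_type, country_year, diagnostic_criteria,
excludes_confounders`). Example:

```bash
metasmd simulate --k 10 --mu 0.5 --seed 7 -o studies.csv
metasmd pool studies.csv --model dl --method cohen
metasmd bias studies.csv
metasmd reproduce-paper
```

Pooling JSON fields: `k, model, pooled, se, ci_low, ci_high, q_stat, df,
i_squared, tau_squared, weights, study_ids`. Bias JSON: per test
`statistic` (Kendall score / intercept), `test_value` (z / t), `p_value`,
and `df` / `continuity_corrected` where applicable.

## Notes on conventions

- SMD sign is case minus control; default flavor is Cohen's d (which
  reproduces the published single-study result), Hedges' g is available.
- All confidence intervals use the normal approximation with z = 1.96.
- τ² is the DerSimonian–Laird moment estimator, clamped at 0; I² is
  reported in percent, clamped to [0, 100].
- The control-arm "reference range" helper (`pool_raw_means`) pools raw
  means with variance sd²/n under either model; mixed measurement units
  trigger a warning but do not stop pooling.
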