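# riverwq

Water-quality assessment and pollution source apportionment for
long-term river monitoring data.

Monitoring agencies publish years of monthly measurements — nutrients
(TP, TN), organic matter (BOD, COD), suspended solids, conductivity,
chlorophyll-a, coliform bacteria — across many sites, and the questions
are always the same: *how bad is the water, where is the pollution
coming from, and is it getting better?* `riverwq` answers these with
the standard toolkit of environmental statistics, implemented as a
tested, scriptable library with a CLI:

- **Water Quality Index** (weighted arithmetic): unit weights
  W_n = K/S_n with K = 1/Σ(1/S_n), sub-indices
  Q_n = (V_n − V_0)/(S_n − V_0)·100, overall WQI = ΣW_nQ_n/ΣW_n, with
  usability bands (≤25 excellent … >100 unsuitable).
- **PMF receptor model**: X ≈ GF with G, F ≥ 0, minimising the
  uncertainty-weighted objective Q = Σ[(x_ij − Σ_k g_ik f_kj)/u_ij]²,
  u = √((EF·x)² + (0.5·MDL)²); multi-start solver with a trust-region
  polish, and per-parameter source apportionment tables with R² fit
  diagnostics.
- **Mann–Kendall trend tests** with tie-corrected variance and
  continuity correction, per site × parameter.
- **Bray–Curtis hierarchical clustering** of sites with a
  similarity-threshold cut (default 60%).
- **Stepwise discriminant analysis** (Wilks' Λ partial-F entry/removal,
  SPSS-convention thresholds) with classification matrices.
- **Varimax PCA/FA** with Kaiser normalization, KMO and Bartlett
  sphericity diagnostics, and strong/moderate loading classification.
- **Significance-filtered Pearson correlation networks** (p < 0.05
  edges) and empirical log–log driver–response regressions, plus
  pre/post-impoundment fold changes and trophic/coliform threshold
  classifications.
- A **synthetic monitoring-data generator** with known ground truth
  (3-source mixture, pollution tiers, monsoon dilution/enrichment,
  injected trends) so every stage has a recovery test without any
  proprietary dataset.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a small basin (6 sites in three pollution tiers, 4 years
monthly) and run the core stages:

```python
from riverwq import (GeneratorConfig, generate_dataset, pivot_to_matrix,
                     compute_wqi, StandardsTable)
from riverwq.pmf import fit_pmf, apportion
from riverwq.synthetic import FACTOR_PARAMETERS

records, truth = generate_dataset(
    GeneratorConfig(n_sites=6, tier_counts=(2, 2, 2), years=4, seed=11))
matrix = pivot_to_matrix(records, site_tiers=truth.tier_of_site)

res = compute_wqi(matrix.values.iloc[0].to_dict(), StandardsTable())
print(res.wqi, res.quality_class)          # 364.3 unsuitable

X = matrix.values[list(FACTOR_PARAMETERS)]  # pH excluded from PMF
model = fit_pmf(X, p=3, n_starts=5, seed=0)
print(apportion(model, X).round(2).loc[["TP", "TCB"]])
```

```
           conc_factor1  conc_factor2  conc_factor3  pct_factor1  pct_factor2  pct_factor3    r2
parameter
TP                34.81         26.09        205.24        13.08         9.80        77.12  0.90
TCB             7685.64       2447.07       1777.83        64.53        20.55        14.93  0.80
```

The first row reads: of the mean TP concentration, 77% is
attributed to the third fitted source, and the reconstructed TP series
tracks the observed one with R² = 0.90. The sample WQI of 364
(site S1, a highly polluted tier-1 site, scored against the default
standards table) is deep in the "unsuitable" band — sub-indices are
percentages of standard values, so heavily polluted samples score far
above 100.

Trends on the full 16-site, 15-year default basin (river-wide monthly
means, seed 11):

```python
from riverwq.trend import trend_report
records, truth = generate_dataset(GeneratorConfig(seed=11))
matrix = pivot_to_matrix(records)
print(trend_report(matrix, grouping="river-wide"))
```

```
parameter    n     S        Z      p  direction
       TP  180 -7772  -9.6140 0.0000 decreasing
       TN  180 -6942  -8.5872 0.0000 decreasing
      BOD  180 -8306 -10.2746 0.0000 decreasing
      COD  180  8320  10.2920 0.0000 increasing
    CHL-a  180  8828  10.9204 0.0000 increasing
```

(other parameters: no trend) — exactly the drifts the generator
injected: nutrients and BOD falling, COD and chlorophyll rising.

## Command line

```sh
riverwq simulate --sites 16 --years 15 --seed 1 --out sim/
riverwq all --input sim/monitoring.csv --out results/ --seed 1
```

Subcommands `wqi`, `trend`, `cluster`, `da`, `fa`, `pmf`, `network`
run individual stages; `all` chains them and writes a JSON run
manifest with per-stage status. Outputs are CSV (reports, loadings,
apportionment), GraphML (networks) and Newick (dendrograms).

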