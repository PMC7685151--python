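# fluxiav

Seasonal compensation/amplification analysis of interannual variability
(IAV) in gridded monthly land-carbon fluxes.

## The problem

Year-to-year variability in gross primary production (GPP) and net
ecosystem exchange (NEE, positive = CO₂ source to the atmosphere) can take
two qualitatively different forms over a growing season. In one, monthly
anomalies are temporally coherent from spring through summer — a good year
is good all season — which **amplifies** the annual flux anomaly. In the
other, spring and summer anomalies are anticorrelated (for example, a warm
spring advances uptake that a hot, dry summer then cancels), so seasonal
**compensation** shrinks the annual anomaly even when monthly IAV is large.
Distinguishing the two matters for interpreting regional carbon budgets:
a region with modest mean fluxes but coherent anomalies can dominate the
IAV of a continent, as the semi-arid west of temperate North America does
relative to the more productive east.

`fluxiav` provides the full analysis chain for this question, for anyone
working with gridded monthly flux products (satellite-upscaled GPP,
atmospheric-inversion NEE, terrestrial biosphere model output) and
environmental driver fields (soil temperature, soil moisture,
precipitation) on regular latitude–longitude grids in CF-style NetCDF.

## The statistics

With Δ denoting monthly anomalies (baseline mean seasonal cycle removed,
optionally detrended), spring = Apr–Jun and summer = Jul–Sep:

```
ΔF_comp(y) = ΔF_Jul-Aug-Sep(y) − ΔF_Apr-May-Jun(y)     (compensation)
ΔF_amp(y)  = ΔF_Jul-Aug-Sep(y) + ΔF_Apr-May-Jun(y)     (amplification)

RATIO = Σ_y |ΔF_comp(y)| / Σ_y |ΔF_amp(y)|
```

RATIO > 1 means seasonal compensation dominates IAV; RATIO < 1 means
amplification dominates. The statistic is scale-free; it is unbounded when
the amplification sum vanishes, so degenerate denominators are flagged
rather than dropped.

Complementary diagnostics:

- **SVD modes** — a regional monthly anomaly series arranged as a 12 ×
  n_years matrix is decomposed by SVD; the fraction of variance explained
  by mode *i* is s_i²/Σ_j s_j², and each monthly pattern is classified as
  amplification-like (spring and summer means of one sign) or
  compensation-like (opposite signs).
- **Driver attribution** — per-cell Pearson correlations between yearly
  seasonal-window means of flux and driver anomalies (including the lagged
  Apr–Sep driver vs Jul–Sep flux pairing), with two-sided t-test p-values
  and a P < 0.05 mask; and regional OLS sensitivities of Apr–Sep seasonal
  flux totals (PgC per season) to Apr–Sep driver means (PgC K⁻¹,
  PgC (m³ m⁻³)⁻¹).
- **Regional summaries** — area-weighted aggregation to west/east regional
  totals, mean growing-season fluxes, mean |Apr–Sep anomaly| magnitudes,
  and their ratio (IAV as a percentage of the mean flux).

A synthetic-data generator produces gridded GPP/NEE/T/M fields with exactly
this structure — a mean seasonal cycle, regionally coherent amplification
and compensation year effects coupled to jointly normal temperature and
moisture anomalies, and white observation noise — so every stage is
testable without external downloads, and recovery of known parameters can
be demonstrated end to end.

## Worked example

```python
import fluxiav as fv

res = fv.run_pipeline({"simulate": {"preset": "two-region", "seed": 7}})
for v in ("GPP", "NEE"):
    c = res.contrasts[v]
    print(v, "RATIO west=%.2f east=%.2f" % (res.ratios[v]["west"].ratio,
                                            res.ratios[v]["east"].ratio))
    print("   west/east anomaly = %.0f%%, east/west mean flux = %.1fx"
          % (c.west_over_east_anomaly_pct, c.east_over_west_mean_ratio))
```

prints

```
GPP RATIO west=0.14 east=5.42
   west/east anomaly = 226%, east/west mean flux = 7.0x
NEE RATIO west=0.16 east=5.24
   west/east anomaly = 232%, east/west mean flux = 9.8x
```

The synthetic west is amplification-dominant (RATIO well below one) and the
east compensation-dominant (well above one); the west contributes more
growing-season IAV (anomaly ratio above 100%) despite the east carrying a
several-fold larger mean flux — the qualitative contrast the pipeline is
designed to detect, here recovered from data generated with known
parameters. The leading SVD mode classifies accordingly (amplification in
the west, compensation in the east, each explaining >90% of variance in
this noise regime).

The same analysis runs from the shell against NetCDF inputs:

```sh
fluxiav simulate --preset two-region --seed 7 --out sim/
fluxiav metrics --in sim/gpp.nc --var GPP --baseline 2001:2017 --table cells.csv
fluxiav run --config analysis.yaml --out results/
```

where `analysis.yaml` names either a `simulate:` preset or `inputs:` paths
per variable, plus optional `baseline`, `detrend` and `regions` settings
(see `docs/methods.md`).

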