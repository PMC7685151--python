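# Methods

This note documents the models, conventions and numerical choices behind
`fluxiav`, and what the synthetic experiments do and do not demonstrate.

## Anomaly definition

A monthly anomaly is the value minus the per-cell mean for that calendar
month over a baseline period (at least two contributing years per month,
else the climatology entry is flagged missing). Missing months are never
interpolated or imputed at any stage.

Optional detrending removes a single per-cell linear trend from the
deseasonalised series. The trend slope is fitted by ordinary least squares
against fractional-year time **centred within each calendar month** (the
analogue of a trend regression with month fixed effects). Centring matters:
climatology removal converts a linear ramp into a per-year staircase, and a
slope fitted against raw fractional time would leave a sawtooth residual of
order one-quarter of the annual trend increment. With month-centred time, a
pure seasonal cycle plus an exact linear ramp detrends to zero (to float
precision), the per-month baseline means remain zero, and on balanced
complete records the fitted slope is identical to the naive one. The
deseasonalise-then-detrend order follows the definition above; both
operations commute on complete balanced data.

Seasonal windows are fixed: spring = Apr–Jun (AMJ), summer = Jul–Sep (JAS),
growing season = Apr–Sep. A window mean for a year requires all its months
present, otherwise the year is excluded from whatever statistic consumes it
(never partially imputed), keeping RATIO's numerator and denominator on
identical year sets.

## The RATIO statistic

comp(y) = summer − spring, amp(y) = summer + spring window means;
RATIO = Σ|comp| / Σ|amp| over the analysis years. The year set is always an
explicit argument/result field, because the statistic is period-sensitive:
restricting a record to a sub-period (e.g. one containing a major drought)
changes RATIO, and the model-vs-observation table therefore reports every
dataset over both its full period and the common sub-period.

When Σ|amp| = 0 the ratio is reported as +inf with a `degenerate` flag and
both sums retained — the metric is unbounded when amplification is small,
and such cells must stay visible rather than disappear. If comp and amp are
independent zero-mean normals, E|X| = σ√(2/π) gives RATIO → σ_comp/σ_amp as
the number of years grows; this half-normal identity is the distributional
oracle used in the tests (10,000 years, 2%).

## SVD modes

Regional monthly anomalies are arranged into a 12 × n_years matrix (rows
Jan–Dec, columns ascending years; years with any missing month are
dropped — no EM imputation). A thin SVD is applied **without** centring or
standardisation: anomalies are near-zero-mean by construction, and the
decomposition should attribute any residual mean structure to the modes
rather than silently remove it (an optional centring flag could be added;
the default is deliberate). Variance fraction of mode i is s_i²/Σ s_j².

SVD sign is undefined, so each month vector is oriented to make its
Apr–Jun mean non-negative (ties broken on the Jul–Aug–Sep mean), with year
loadings flipped in step. Classification uses a = mean(Apr–Jun),
b = mean(Jul–Sep) of the unit vector: amplification if a·b > 0,
compensation if a·b < 0, with min(|a|, |b|) > θ = 0.05 required in either
case (unit-norm vectors concentrated outside the growing season fail the
threshold and are labelled "other"). θ is a free parameter of
`classify_mode`; 0.05 keeps roughly "5% of the vector's norm per window" as
the floor for calling a seasonal structure.

## Driver attribution

Per-cell correlations are Pearson r between yearly window means across
common years, pairwise-complete per cell, with the two-sided t-test on
n − 2 degrees of freedom (t = r√(n−2)/√(1−r²)) and a significance mask at
α = 0.05. Three pairings are emitted: AMJ–AMJ, JAS–JAS, and the lagged
JAS flux vs Apr–Sep driver pairing that captures spring climate
preconditioning summer fluxes. Years are treated as independent — no
autocorrelation correction — and no multiple-testing correction is applied
across cells; the per-cell mask is a display convention, not a familywise
claim, and this is a documented limitation.

Regional sensitivities regress yearly Apr–Sep seasonal flux anomaly totals
(window mean monthly anomaly × 6, in PgC per season, from area-weighted
regional totals) on yearly Apr–Sep regional driver anomaly means
(area-weighted means in native units), giving slopes in PgC K⁻¹ or
PgC (m³ m⁻³)⁻¹. Zero driver variance is a contract error, not a NaN.

## Grid geometry and aggregation

Cells are spherical quadrilaterals on a sphere of radius 6,371 km;
coordinates are cell centres, overlaps are computed on half-open cell-edge
intervals (no double counting), and cells crossing a pole are clipped at
±90°. Area-weighted regridding of intensive fields uses exact
sin-latitude × longitude overlap weights; missing source cells drop out of
the weight sum, and a target cell is flagged missing when valid-source
coverage of its area falls below `min_coverage` = 0.5 (configurable; the
cutoff is a judgement call with no canonical value). Regridding preserves
uniform fields exactly and the global area-weighted mean of complete fields
to rounding.

Regional aggregation: mode "total" is Σ value × area × weight × 10⁻¹⁵
(gC → PgC); mode "mean" (drivers) is the area-and-weight-weighted mean.
Months with partial coverage exclude the missing contribution and record
the coverage fraction; an all-missing month is NaN, never silently zero.

The default west/east masks are rectangles over 24–52°N, 125–65°W split at
103°W (west: lon < −103°), cells straddling a boundary getting fractional
weights by coordinate overlap. The split is an approximation to a boundary
that exists only as a map shading in the literature and is configurable
everywhere it is used.

NEE sign convention throughout: positive = flux from land to atmosphere, so
positive amp means enhanced emission over the growing season.

## The synthetic generator

Per cell in region r, year y, month m:

    GPP = clim_r(m) + β·t + a_y·amp(m) + c_y·comp(m) + ε,
    a_y = γ_T·ΔT_y + γ_M·ΔM_y + η_a,   η_a ~ N(0, σ_amp)
    c_y = κ·ΔT_y + η_c,                η_c ~ N(0, σ_comp)

with (ΔT_y, ΔM_y) jointly normal, s.d. 1 K and 0.01 m³ m⁻³, correlation
ρ_TM = −0.77 (warm years are dry years), and ε white per-cell noise.
amp(m) is a unit-norm half-sine over Apr–Sep; comp(m) is the unit-norm
+1 (Apr–Jun) / −1 (Jul–Sep) step — the simplest shapes with the required
coherent and see-saw semantics. The driver fields carry the year effects
uniformly over Apr–Sep plus small monthly noise; the "spring ΔT" entering
the compensation coupling is the same growing-season-coherent ΔT_y (the
generator does not resolve sub-seasonal driver structure). NEE is generated
around its own seasonal cycle as −λ × the GPP anomaly structure (λ = 0.5)
plus independent respiration noise; with κ > 0 a warm spring raises spring
GPP and, through −λ, advances NEE uptake — i.e. the effective NEE
compensation coupling is negative.

All randomness derives from one integer seed via counter-keyed streams:
region-level draws use stream (seed, 0, region) and per-cell noise
(seed, 1, i, j), so enlarging the grid does not reorder region-level
effects and identical seeds give bitwise-identical output.

Presets (defaults chosen once as a plausible mid-latitude setting):

- **west-like** — amplification-dominant: peak seasonal cycle G = 40
  gC m⁻² month⁻¹, σ_amp = 10, σ_comp = 2 (ratio 0.2), σ_ε = 2, γ_T = −5
  gC m⁻² month⁻¹ K⁻¹, γ_M = +500 per m³ m⁻³ (cool-wet years amplify
  uptake), κ = 0.
- **east-like** — compensation-dominant: σ_amp = 2, σ_comp = 10 (ratio 5),
  κ = +10 (warm springs shift the cycle earlier), γ_T = 0, γ_M = +150
  (moisture ties to the amplification component), large G.
- **two-region** — both on one 4° × 5° grid over 24–52°N, 125–65°W. The
  split is placed at 105°W — a cell edge of the default grid — so every
  generated cell belongs wholly to one region; the east seasonal amplitude
  (152 gC m⁻² month⁻¹) is then fixed so the east/west Apr–Sep total GPP
  ratio is 7.6 exactly by construction (same latitude band on both sides,
  so the area ratio is the longitude-width ratio 2). The analysis masks
  for two-region runs use the same 105°W split; `default_masks` keeps
  103°W as its general default with fractional boundary weights.

What the generator emulates: regionally coherent year effects, realistic
flux/driver coupling signs and magnitudes, the warm-dry correlation, white
observation noise, optional linear trends. What it does not: spatial
autocorrelation of weather within a region (year effects are perfectly
coherent, noise perfectly independent), sub-seasonal driver timing,
respiration dynamics, or specific historical years. Passing the recovery
tests therefore shows the pipeline correctly extracts this structure when
present at these signal-to-noise levels — not that any particular real
region has it; conclusions about real data require the real products.

## Pipeline and configuration

`run_pipeline` accepts a YAML file or dict:

```yaml
simulate: {preset: two-region, seed: 7}   # or inputs: {GPP: gpp.nc, NEE: nee.nc, T: t.nc, M: m.nc}
baseline: [2001, 2017]                    # default: full record
detrend: {GPP: true, NEE: false, T: true, M: true}   # defaults shown
regions: {lat_bounds: [24, 52], lon_bounds: [-125, -65], split_lon: -103.0}
```

NEE defaults to no detrending (short inversion records make a fitted trend
mostly noise); all other variables detrend by default. The run emits
long-format CSV tables (ratio maps with per-cell Apr–Sep mean T and M,
mode tables, driver correlations, sensitivities, region summaries) and a
JSON manifest (config hash, seed, package and library versions); two runs
with the same config are byte-identical.

The Figure-6-style summary quantities are defined as: mean Apr–Sep flux =
mean over years of (Apr–Sep mean monthly regional total × 6); mean anomaly
magnitude = mean over years of |Apr–Sep mean monthly anomaly total| × 6;
IAV-to-mean = 100 × the second over the first's magnitude. The west/east
anomaly ratio uses these seasonal-total magnitudes; "anomaly of the total"
is computed (aggregate first, then window means), not "total of anomalies"
per cell — the two differ in how cancellation across cells is counted, the
choice is an interpretation, and it is applied uniformly to every dataset
in a comparison.

## Test problem sizes

Statistical tests run at sizes chosen to make Monte-Carlo error negligible
against their thresholds: the half-normal RATIO limit at 10,000 years (2%
band); null calibration of the correlation p-values at 10,000 replicates of
n = 17 years (0.050 ± 0.010); slope-coverage calibration at 1,000 refits of
n = 100 years against the ±2 SE rule (true coverage ≈ 95%, threshold 93%;
n = 100 keeps the t-versus-normal gap in the 2-SE rule small, and 1,000
refits keep the sampling error of the observed rate well inside the
margin); parameter-recovery experiments at 100 seeded 17-year two-region
runs with a ≥95% per-seed success requirement.

## Known limitations

- Regridding is for intensive quantities on nested or near-nested grids;
  conservative regridding of extensive fields and map projections are out
  of scope.
- p-values assume independent years; serial correlation would inflate
  significance.
- No uncertainty intervals on RATIO (a bootstrap over years would be the
  natural extension).
- The alternative shift-metric normalising by mean absolute monthly
  anomalies (Butterfield-style) is deliberately not implemented; RATIO
  compares the two components directly.
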