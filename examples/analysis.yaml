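# Full-pipeline configuration. Either simulate a preset or point `inputs`
# at CF-style NetCDF files with GPP/NEE (gC m-2 month-1), T (K), M (m3 m-3).
simulate:
  preset: two-region
  seed: 7
# inputs:
#   GPP: data/gpp.nc
#   NEE: data/nee.nc
#   T: data/t.nc
#   M: data/m.nc
baseline: [2001, 2017]
detrend:
  GPP: true
  NEE: false
  T: true
  M: true
regions:
  lat_bounds: [24, 52]
  lon_bounds: [-125, -65]
  split_lon: -105.0
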