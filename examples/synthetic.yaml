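# Fully synthetic end-to-end run: two provenances observed at 5 gardens,
# calibrated with two initial conditions, projected under 5 scenario members.
#   budburst run-all examples/synthetic.yaml -o run
seed: 42
models: [MT, GDD1, GDD_DOY, BC_DOY, ALT]
periods:
  TP1: [1971, 2000]
  TP2: [2011, 2040]
  TP3: [2051, 2080]
projection_years: [1971, 2080]
ic:
  All: all
  S01: [S01]
synthetic:
  n_sites: 5
  n_bc: 5
  obs_years: [1971, 2000]
  warming_range: [0.35, 0.5]   # degC per decade across scenario members
  climate:
    annual_mean: 8.0
    warming_seasonality: 0.5   # warming concentrated toward winter
  truths:
    - provenance: P1           # early provenance: low forcing requirement
      model: GDD1
      params: {Tb: 4.0, Fcrit: 160.0}
      obs_noise_sd: 4.0
    - provenance: P2           # late provenance
      model: GDD1
      params: {Tb: 4.0, Fcrit: 220.0}
      obs_noise_sd: 4.0
calibration:
  n_chains: 8
  n_iterations: 10000
  warmup: 2000
analysis:
  alpha: 0.05
  n_boot: 1000
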