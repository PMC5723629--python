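# budburst

Ensemble projection of spring budburst (leaf-out of tree buds) under
climate change: process-based phenology models, Bayesian calibration, and
rank-based uncertainty partitioning.

The package is aimed at phenology and climate-impact modellers who want to
move beyond a single model run. It treats a budburst projection as an
ensemble over four nested sources of uncertainty:

* **initial conditions (IC)** — which observation subset constrains the
  parameters (all sites vs. a single site);
* **model classes (MC)** — structurally different models of bud physiology;
* **parameterization** — the joint posterior of each model's parameters;
* **boundary conditions (BC)** — the climate dataset driving the projection.

## Models

All temperature-sum models predict budburst on the first day *t* whose
accumulated forcing reaches the critical requirement,
`simDBB = min{ t : Sf(t) >= Fcrit }`, with August 1 as a failure cutoff. The
implemented classes are:

| Tag | Structure |
| --- | --- |
| `MT` | linear regression on mean February–April temperature, `DBB = I + k·T̄` |
| `GDD1` | degree-days above `Tb` from January 1: `Sf(t) = Σ max(0, T_i − Tb)` |
| `GDD_DOY` | degree-days from a calibrated start day `t0` |
| `SIG_DOY` | logistic forcing `1/(1+exp(b(T+c)))` from `t0` |
| `BC_DOY` | degree-days from `t0` weighted by photoperiod, `(DL/10)^EXPO` |
| `ALT` | degree-days from Jan 1 with `Fcrit = β·exp(−γ·Sc)`, `Sc` = chilling-day count |
| `SEQ` | triangular chilling; logistic forcing gated on `Sc ≥ Ccrit` |
| `UNI` | bell-shaped chilling, gated logistic forcing, and decaying `Fcrit` |

Calibration is Bayesian: uniform priors, a Gaussian-error likelihood built
on the sum of squared day residuals, and an adaptive Metropolis–Hastings
sampler with burn-in detection, autocorrelation thinning, chain selection,
and Kolmogorov–Smirnov consistency checks. The thinned posterior of each
model is resampled `n·100 + M` times (`n` parameters, `M` local posterior
modes) to build the projection ensemble, and projections are compared
between 30-year periods with Kruskal–Wallis rank tests, CI-standardized
effect sizes, and Bonferroni-corrected post hoc comparisons.

Everything runs on synthetic data generated by the package itself (seasonal
temperature cycle, AR(1) noise, latitude/altitude gradients, scenario
warming, truth-model observations), so the full pipeline is testable
without any external download.

## Worked example

Calibrate a degree-day model on synthetic observations whose truth is
`Tb = 4 °C, Fcrit = 180` degree-days, then project it under two warming
scenario members:

```python
import numpy as np
import budburst as bb
from budburst.calibration import CalibrationSettings, calibrate
from budburst.ensemble import EnsembleMember, draw_projection_samples, period_aggregate, project_ensemble
from budburst.models import ModelParameterSet
from budburst.synth import *

sites = generate_sites(3, seed=7)
climate = ClimateGeneratorConfig(warming_per_decade=0.4)
series = {s.site_id: generate_temperature(s, (1971, 2000), climate, seed=10 + i)
          for i, s in enumerate(sites)}
truth = TruthConfig(ModelParameterSet("GDD1", {"Tb": 4.0, "Fcrit": 180.0}), obs_noise_sd=3.0)
obs = generate_observations(truth, series, sites, range(1971, 2001), seed=1)

smap = {s.site_id: s for s in sites}
res = calibrate("GDD1", obs, series, smap,
                CalibrationSettings(n_chains=4, n_iterations=4000, warmup=800, seed=2))
pooled = res.posterior.pooled
for j, name in enumerate(res.posterior.param_names):
    lo, hi = np.percentile(pooled[:, j], [2.5, 97.5])
    print(f"{name}: median {np.median(pooled[:, j]):.2f}  95% CI [{lo:.2f}, {hi:.2f}]")

draws, plan = draw_projection_samples(res.posterior, seed=3)
bcs = generate_scenario_suite(sites, (1971, 2080), climate, 2, (0.35, 0.45), seed=4)
ens = project_ensemble([EnsembleMember("P1", "All", "GDD1", draws, plan)], bcs, smap, range(1971, 2081))
_, deltas = period_aggregate(ens, {"TP1": (1971, 2000), "TP3": (2051, 2080)})
print(f"shift {deltas.loc[0, 'delta_TP3_TP1']:+.1f} days")
```

Output:

```
Tb: median 3.97  95% CI [3.51, 4.25]
Fcrit: median 181.10  95% CI [165.88, 204.77]
shift -19.9 days
```

The posterior brackets both true parameter values, and the 2051–2080
ensemble advances budburst by about 20 days relative to 1971–2000 under a
0.4 °C/decade warming — the credible intervals quantify how much of that
signal survives parameter uncertainty.

The same pipeline is scriptable from the shell: `budburst run-all
config.yaml -o rundir` executes simulate → calibrate → project → analyze
and writes chain dumps, posterior samples, the long-format ensemble, failure
tables, period deltas, and pairwise comparison matrices (see
`budburst --help`).

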