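# Methods

This note documents the models, the calibration machinery, the ensemble
design, and the numerical choices made where the design was genuinely open.

## Phenology models and the prediction rule

Eight model classes span the structural range used for temperate and boreal
trees: one empirical regression (`MT`), three pure forcing models (`GDD1`,
`GDD_DOY`, `SIG_DOY`), one forcing–photoperiod model (`BC_DOY`), and three
chilling–forcing models (`ALT`, `SEQ`, `UNI`). All temperature-sum models
share one prediction rule: budburst falls on the first day whose
*end-of-day* accumulated forcing meets or exceeds the critical requirement
(`>=`, not `>`). If no day strictly before August 1 qualifies, the
simulation is a flagged failure rather than a late date — photoperiod
protects real buds from absurdly late flushing, and a model that cannot
reach its requirement by then has left its domain of validity. Failure
frequency is reported separately and is itself an analysis output.

Calendar conventions: day-of-year is 1-based on the real calendar; the
August-1 cutoff is day 213 in ordinary years and 214 in leap years, always
computed from the date. The forcing season runs from January 1 (or the
calibrated start day `t0`); chilling accumulation starts at `t2`, an
integer day offset where 1 = January 1 and negative values reach into the
preceding autumn, clamped at October 1 (the start of the data window; the
prior allows `t2 = −92`, which clamps by one day). Continuous sampler
proposals for the integer day parameters `t0`/`t2` are floored.

`SEQ` fixes `t2` = October 1 and the chilling temperature bounds −3.4 °C
and 10.4 °C at commonly accepted values; only `Topt`, `Tb`, `b`, `c`,
`Ccrit`, `Fcrit` are calibrated. `UNI` is fully implemented but excluded
from the default model list: its nine parameters on one seasonal signal
make it structurally prone to non-convergence, and a member that cannot be
calibrated reliably would contribute noise, not information, to the
ensemble.

Day length uses the standard solar-declination approximation
(declination −23.44°·cos(2π(doy+10)/365), sunset hour angle clamped to
[−1, 1] so polar day/night saturate at 24 h/0 h). Any astronomically sane
formula works here; the photoperiod factor `(DL/10)^EXPO` varies by a few
percent between conventions and `EXPO` absorbs the difference during
calibration.

Two printed ambiguities in the source equations were resolved as follows:
the sigmoid argument is `b·(T_t + c)` (its growth rate and inflection point
are parameters of a logistic in daily temperature), and `SEQ` accumulates
forcing exactly when `T_t ≥ Tb` **and** `Sc ≥ Ccrit` (the zero branch is
the complement of the accumulation branch). `ALT` shares a single `Tb`
between its chilling-day definition (`T < Tb`) and its degree-day forcing.

## Likelihood and error model

Observed budburst is modelled as the model prediction plus i.i.d. Gaussian
day error. The sufficient statistic is the sum of squared residuals
(`SSE`); failed simulations enter with the cutoff day as their prediction,
which keeps the residual finite and large and the chain mobile.
`log_likelihood` exposes the raw score `−SSE`.

For calibration the error variance is treated as unknown and integrated
out under the standard noninformative prior, giving the concentrated
log-likelihood `−(n/2)·ln(SSE/n)`. This choice matters: the raw `−SSE`
score corresponds to asserting an error variance of one half day², which
with residuals of several days makes the posterior roughly four times too
narrow in standard deviation — parameter-recovery simulations then show
credible intervals that essentially never cover the truth. With the
marginalized variance, posterior spread tracks the actual prediction-error
scale of the data. Both error models are available on
`LikelihoodEvaluator`; `calibrate()` defaults to the marginal one.

## Adaptive Metropolis–Hastings

Each model × observation-set combination is sampled by eight chains (a
setting) from random starting points in the prior box. The proposal has
three ingredients:

* a **warmup phase** (default 2,000 iterations) with a frozen wide diagonal
  Gaussian (SD = prior width/50). Almost all of these proposals are
  rejected, but the rare uphill acceptances perform a coarse stochastic
  search that moves the chain between likelihood basins;
* afterwards, a Gaussian whose covariance is the running covariance of the
  chain scaled by 2.38²/d plus a small diagonal jitter ((10⁻⁴·width)²),
  with the global scale λ tuned by a Robbins–Monro recursion towards an
  acceptance rate of 0.234. The scale recursion is what keeps chains mobile
  on very sharp posteriors: many observations make the likelihood surface a
  maze of tight plateaus, and a fixed-scale adaptive sampler freezes;
* a 5 %/5 % mixture of long jumps (the adapted covariance scaled ×8, which
  travels along the learned ridge directions) and wide diagonal hops
  (the warmup proposal), neither of which feeds the scale recursion.

Proposals outside the prior box are rejected outright (uniform priors
cancel in the acceptance ratio); likelihood evaluation failures count as
rejections and are logged. Chains are bit-reproducible from their seed.

Post-processing follows four rules. Burn-in ends at the first iteration
whose log-likelihood reaches the mean over the final 10 % of the trace; a
chain that only gets there inside that final stretch has no usable plateau
and is flagged unusable. Each parameter's thinning lag is the smallest lag
at which the sample autocorrelation (signed estimate) drops below 0.2; the
chain is thinned by the largest lag across parameters. Chains whose mean
post-burn-in log-likelihood falls more than 10 natural-log units (a
setting) below the best chain are discarded as stuck. Finally a two-sample
Kolmogorov–Smirnov test (α = 0.05) per parameter flags chains whose
thinned samples are inconsistent with the pooled posterior; flags are
recorded, not silently acted on.

## Posterior modes and the sampling plan

Multi-modal posteriors are real in this family (base temperature and
forcing requirement trade off; sigmoid growth rate and inflection point are
strongly anti-correlated), so chains that converged to different regions
must all be represented. Two kept chains share a mode iff every parameter
passes a pairwise KS test at α = 0.05; modes are connected components of
that agreement graph. With M modes and n parameters, each mode receives
`floor(n·100/M) + 1` draws (uniform over the mode's retained samples, with
replacement only when the mode is short), topped up in index order so the
total is exactly `n·100 + M` — every local mode contributes at least one
sample to the projection ensemble.

## Boundary conditions and elevation

Observation-driven calibration series are adjusted from grid-cell to site
elevation with the global standard lapse rate 6.4 °C/km applied to the
signed difference (grid minus site altitude). Scenario/boundary-condition
series are deliberately *not* adjusted: projections represent the grid-cell
level so that maps of the study region remain consistent. Scenario members
share the baseline climatology but carry independent noise realizations —
their year-to-year variation is uncorrelated with any observation series,
as with free-running climate-model output.

## Ensemble aggregation and rank statistics

Predictions are indexed by (provenance, IC, MC, sample, BC, site, year) and
aggregated into empirical CDFs per grouping and 30-year period (period
membership by budburst calendar year). Failed predictions are excluded from
CDFs and means but fully counted in failure tables; a model approaching
failure therefore shows an *apparent* drop in variability, which is a real
property of this design and is deliberately not masked.

Distributions are compared with the tie-corrected Kruskal–Wallis H
(chi-square p, df = groups − 1). The implementation is in-package because
the analysis needs per-group mean rank sums (the mean rank difference is
the area between two CDFs); scipy's version is used as an independent
cross-check in the tests. For plotting and cross-size comparability the
two-group statistic is standardized by the width of a percentile-bootstrap
95 % confidence interval of the mean-rank difference (B = 1,000, seeded) —
the CI construction is a package choice, made for being distribution-free
and consistent with the rank-based statistic. Post hoc pairwise comparisons
use two-group KW tests at the Bonferroni threshold α/(number of pairs),
reporting which group buds earlier (smaller mean rank). In the pipeline
driver, rank comparisons operate on a seeded subsample of at most 4,000
values per group (a setting): the standardization exists precisely because
group sizes differ, and full multi-hundred-thousand-value groups make the
bootstrap needlessly slow without changing the decisions.

Model fit is summarized by adj. R², AICc (`n·ln(SSE/n) + 2k +
2k(k+1)/(n−k−1)`), RMSE, and bias, computed for the maximum-likelihood
retained posterior sample. Spatial-variation trends regress the annual
across-site SD on the annual across-site mean by ordinary least squares
(the plain general linear model; no link function is warranted).
Observation series are screened with the 30-day rule: an additive
site + year model is fit by Tukey median polish and records deviating by
more than 30 days are flagged — flagged, never removed. The robust fit is
essential: a least-squares fit absorbs a genuine outlier into the effects
it helps estimate (in a 5 × 10 layout a 40-day deviation leaves only a
29-day residual) and the screen would miss exactly what it exists to find.

## Synthetic data

The generator emulates the *structure* of the real inputs: a site network
at 45–65 °N with altitudes 15–1,210 m and signed grid−site altitude
differences up to ±300 m; daily mean temperature as site mean (latitude
gradient −0.4 °C/degree, lapse 6.4 °C/km) + seasonal cosine (amplitude
10 °C, peak day 200, period 365.25 with real calendars) + optional
seasonally weighted warming trend + AR(1) noise (coefficient 0.7, marginal
SD 2.5 °C); and budburst observations as truth-model predictions plus
rounded Gaussian day noise (default SD 3 days, matching the 5–12-day
site-level SDs of long observation series once interannual signal is
included). Defaults were chosen so that truth-model calibrations land in
the adj. R² ≈ 0.5–0.75 regime typical of multi-site budburst data.

What the generator does **not** emulate — precipitation, heat-wave
clustering, spatial noise correlation between sites, observer error
structure, missing-data seasonality — bounds what passing tests show:
they validate the machinery and its statistical behaviour under a known
truth, not the climatology of any real region.

## Problem sizes

The test suite and the acceptance script run, on one CPU: oracle
equivalence on 1,000 randomized series per model class; parameter recovery
on 25 sites × 30 years with 8 chains × 20,000 iterations (20 replicates in
the suite, 6 in the script); the thinning contract on an AR(1) trace of
length 10⁵; Kruskal–Wallis type-I error over 10,000 replicates; and two
full pipeline runs (3 sites, 5 scenario members, 1971–2080) with 4 chains ×
5,000 iterations per model. These sizes are the package's own choices for a
desk-scale demonstration of each property.

## Known limitations

* **Marginal credible intervals are not guaranteed calibrated.** The
  posterior of a degree-day model lives on a long curved ridge
  (`t0`–`Tb`–`Fcrit` trade off), and where the start-day direction is flat
  — a truth start day below the thermal onset of spring, with a uniform
  prior spanning deep winter — the ridge volume at low `t0` pulls the
  `Tb`/`Fcrit` marginals systematically toward lower base temperatures and
  higher forcing requirements. Parameter-recovery simulations show joint
  (all-parameter) 95 %-interval coverage around 80 % (16/20 in the suite's
  replicate run) rather than ≥ 90 %; five-fold longer chains give the same
  intervals, so this is posterior geometry, not sampler error. Interval coverage claims for
  individual threshold parameters of ridge-shaped phenology posteriors
  should be made with profile likelihoods, informative priors, or
  identifiable reparameterizations.
* The likelihood treats day residuals as i.i.d. Gaussian; real records have
  observer- and site-dependent error and the model-error term is not
  separated from observation noise.
* Mode identification by pairwise KS grouping is a reproducible stand-in
  for what is ultimately a judgment call; at very large per-chain sample
  sizes the test becomes sensitive enough to split chains that agree for
  practical purposes.
* The unified model (`UNI`) is exercised by tests but not part of the
  default ensemble (see above); no alternative samplers (tempering, HMC)
  are provided.
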