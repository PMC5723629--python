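"""Bayesian calibration of the budburst models.

Each model x observation-set combination is calibrated by an adaptive
Metropolis-Hastings (AMH) sampler under uniform priors and a Gaussian-error
likelihood: the log-likelihood is the negative sum of squared prediction
residuals in days.  Simulations that fail to reach budburst before the
cutoff enter the likelihood with the cutoff day as their prediction, which
keeps the residual finite (and large) and the chain mobile.

Several chains are run from random starting points; each chain is
post-processed with the following rules:

* burn-in ends at the first iteration whose log-likelihood reaches the mean
  log-likelihood over the final 10% of the chain (a chain that only gets
  there inside that final stretch is unusable);
* each parameter's thinning lag is the smallest lag at which the sample
  autocorrelation drops below 0.2; the chain is thinned by the largest
  (common) lag;
* only chains whose mean post-burn-in log-likelihood is within a tolerance
  (default 10 natural-log units) of the best chain are kept;
* a two-sample Kolmogorov-Smirnov test per parameter flags chains whose
  thinned samples are inconsistent with the pooled posterior.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats as _sstats
from statsmodels.tsa.stattools import acf as _acf

from .engine import PredictorTable, predict_table
from .models import (
    MODEL_PARAM_NAMES,
    BudburstObservation,
    DailyTemperatureSeries,
    ModelParameterSet,
    SiteMeta,
)

__all__ = [
    "PriorSpec",
    "default_priors",
    "LikelihoodEvaluator",
    "build_evaluator",
    "log_likelihood",
    "ChainState",
    "PosteriorSet",
    "CalibrationSettings",
    "CalibrationResult",
    "run_amh",
    "detect_burn_in",
    "autocorrelation_thin",
    "select_chains",
    "ks_chain_consistency",
    "calibrate",
]


class CalibrationError(RuntimeError):
    """Raised when a model cannot be calibrated (no usable chain)."""


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter.

    ``model`` is usually a model tag (bounds are then validated against its
    parameter names); any other label gives a free-form prior, e.g. for
    sampling a synthetic target.
    """

    model: str
    bounds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.model in MODEL_PARAM_NAMES:
            names = MODEL_PARAM_NAMES[self.model]
            if set(self.bounds) != set(names):
                raise ValueError(f"prior must cover exactly {names}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior for {name}: need lower < upper, got ({lo}, {hi})")

    @property
    def names(self) -> tuple[str, ...]:
        if self.model in MODEL_PARAM_NAMES:
            return MODEL_PARAM_NAMES[self.model]
        return tuple(self.bounds)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.names])
        hi = np.array([self.bounds[n][1] for n in self.names])
        return lo, hi

    def contains(self, theta: np.ndarray) -> bool:
        lo, hi = self.arrays()
        return bool(np.all(theta >= lo) and np.all(theta <= hi))

    def replace(self, **bounds: tuple[float, float]) -> "PriorSpec":
        merged = dict(self.bounds)
        merged.update(bounds)
        return PriorSpec(self.model, merged)


# Literature-spanning default boxes.  Degree-day forcing requirements are in
# degree-days; sigmoid-unit requirements (SIG_DOY, SEQ) in forcing units.
_DEFAULT_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "MT": {"I": (0.0, 300.0), "k": (-20.0, 10.0)},
    "GDD1": {"Tb": (-5.0, 10.0), "Fcrit": (0.0, 2000.0)},
    "GDD_DOY": {"t0": (1.0, 120.0), "Tb": (-5.0, 10.0), "Fcrit": (0.0, 2000.0)},
    "SIG_DOY": {"t0": (1.0, 120.0), "b": (-3.0, 3.0), "c": (-20.0, 20.0), "Fcrit": (0.0, 100.0)},
    "BC_DOY": {"t0": (1.0, 120.0), "Tb": (-5.0, 10.0), "EXPO": (0.0, 3.0), "Fcrit": (0.0, 2000.0)},
    "ALT": {"t2": (-92.0, 60.0), "Tb": (-5.0, 10.0), "beta": (1e-6, 2000.0), "gamma": (0.0, 0.2)},
    "SEQ": {
        "Topt": (-3.39, 10.4), "Tb": (-5.0, 10.0), "b": (-3.0, 3.0),
        "c": (-20.0, 20.0), "Ccrit": (0.0, 150.0), "Fcrit": (0.0, 100.0),
    },
    "UNI": {
        "t2": (-92.0, 60.0), "ac": (0.0, 1.0), "bc": (-3.0, 3.0), "oC": (-5.0, 15.0),
        "dF": (-3.0, -1e-6), "fF": (0.0, 20.0), "Ccrit": (0.0, 150.0),
        "beta": (1e-6, 2000.0), "gamma": (0.0, 0.2),
    },
}


def default_priors(model: str) -> PriorSpec:
    """Default uniform prior box for a model class (all bounds overridable)."""
    if model not in _DEFAULT_BOUNDS:
        raise ValueError(f"unknown model tag {model!r}")
    return PriorSpec(model, dict(_DEFAULT_BOUNDS[model]))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class LikelihoodEvaluator:
    """Fast Gaussian-error log-likelihood over a fixed observation table.

    Two error models share the sum of squared residuals (failed simulations
    are scored at the cutoff day, keeping the residual finite and large):

    ``"sse"``
        ``logL(theta) = -SSE(theta)``, the raw negative sum of squared
        prediction residuals (a unit error variance up to scale).
    ``"marginal"``
        ``logL(theta) = -(n/2) ln(SSE(theta)/n)``: the Gaussian likelihood
        with the unknown error variance integrated out under the standard
        noninformative prior.  The posterior then spreads according to the
        actual prediction-error scale of the data, which is what makes
        credible intervals meaningful when residuals are several days.
    """

    def __init__(
        self,
        model: str,
        table: PredictorTable,
        obs_doy: np.ndarray,
        error_model: str = "sse",
    ):
        if len(obs_doy) != len(table):
            raise ValueError("one observation per table row required")
        if len(obs_doy) == 0:
            raise ValueError("no observations")
        if error_model not in ("sse", "marginal"):
            raise ValueError(f"unknown error model {error_model!r}")
        self.model = model
        self.table = table
        self.obs = np.asarray(obs_doy, float)
        self.error_model = error_model
        self._cut = table.cutoff.astype(float)

    def predictions(self, theta: np.ndarray) -> np.ndarray:
        return predict_table(self.model, theta, self.table)

    def sse(self, theta: np.ndarray) -> float:
        pred = predict_table(self.model, theta, self.table)
        sim = np.where(pred < 0, self._cut, pred)
        resid = sim - self.obs
        return float(resid @ resid)

    def __call__(self, theta: np.ndarray) -> float:
        sse = self.sse(theta)
        if self.error_model == "sse":
            return -sse
        n = len(self.obs)
        return -0.5 * n * np.log(max(sse, 1e-9) / n)


def build_evaluator(
    model: str,
    observations: Sequence[BudburstObservation],
    series_by_site: Mapping[str, DailyTemperatureSeries],
    sites: Mapping[str, SiteMeta],
    cutoff_date: _dt.date | None = None,
    error_model: str = "sse",
) -> LikelihoodEvaluator:
    if not observations:
        raise ValueError("no observations")
    table = PredictorTable.build(
        [(o.site_id, o.year) for o in observations], series_by_site, sites, cutoff_date
    )
    return LikelihoodEvaluator(
        model, table, np.array([o.doy for o in observations], float), error_model
    )


def log_likelihood(
    model_tag: str,
    params: ModelParameterSet | np.ndarray,
    observations: Sequence[BudburstObservation],
    series_by_site: Mapping[str, DailyTemperatureSeries],
    sites: Mapping[str, SiteMeta],
    cutoff_date: _dt.date | None = None,
) -> float:
    """Convenience one-shot log-likelihood (builds the table each call)."""
    ev = build_evaluator(model_tag, observations, series_by_site, sites, cutoff_date)
    if isinstance(params, ModelParameterSet):
        params = params.to_vector()
    return ev(np.asarray(params, float))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@dataclass
class ChainState:
    """One AMH trace with its post-processing labels."""

    theta: np.ndarray  # (n_iter, d)
    logl: np.ndarray  # (n_iter,)
    param_names: tuple[str, ...]
    seed: int
    n_accepted: int
    n_failed_evals: int = 0
    burn_in_index: int | None = None
    thin_lag: int | None = None
    thinned: np.ndarray | None = None
    thinned_logl: np.ndarray | None = None
    kept: bool = False
    ks_pass: np.ndarray | None = None

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / len(self.logl)

    @property
    def usable(self) -> bool:
        return self.burn_in_index is not None

    def post_burn_in(self) -> np.ndarray:
        if self.burn_in_index is None:
            raise ValueError("chain flagged unusable (no burn-in point)")
        return self.theta[self.burn_in_index :]


def run_amh(
    loglike: Callable[[np.ndarray], float],
    prior: PriorSpec,
    n_iterations: int,
    seed: int,
    warmup: int = 2000,
    adapt_scale: float | None = None,
    target_acceptance: float = 0.234,
    init: np.ndarray | None = None,
) -> ChainState:
    """Adaptive Metropolis-Hastings with covariance and scale adaptation.

    The proposal is Gaussian with covariance ``lambda^2 * (2.38^2/d) *
    (running covariance + jitter)``; the first ``warmup`` iterations use a
    diagonal shape (SD = prior width / 50) while the running covariance
    accumulates.  The global scale ``lambda`` is tuned by a Robbins-Monro
    recursion towards ``target_acceptance``, which keeps chains mobile even
    on very sharp posteriors (the sum-of-squares likelihood concentrates
    hard when many observations are available).  Proposals outside the
    prior box are rejected outright (uniform priors cancel in the
    acceptance ratio).  Fully reproducible from ``seed``.
    """
    lo, hi = prior.arrays()
    width = hi - lo
    d = len(lo)
    if adapt_scale is None:
        adapt_scale = 2.38**2 / d
    jitter = (1e-4 * width) ** 2

    rng = np.random.default_rng(seed)
    x = lo + rng.random(d) * width if init is None else np.asarray(init, float).copy()
    if not prior.contains(x):
        raise ValueError("initial point outside prior support")
    lx = float(loglike(x))
    n_failed = 0
    if not np.isfinite(lx):
        lx = -np.inf

    theta = np.empty((n_iterations, d))
    logl = np.empty(n_iterations)
    diag_sd = width / 50.0

    mean = x.copy()
    m2 = np.zeros((d, d))
    count = 1
    chol: np.ndarray | None = None
    log_lambda = 0.0
    n_acc = 0

    for i in range(n_iterations):
        adapted = not (i < warmup or count < 2 * d)
        if not adapted:
            # exploration phase: frozen wide diagonal proposal; rare uphill
            # acceptances move the chain between likelihood basins
            prop = x + diag_sd * rng.standard_normal(d)
        else:
            if chol is None or i % 10 == 0:
                cov = adapt_scale * (m2 / (count - 1)) + np.diag(jitter)
                chol = np.linalg.cholesky(cov)
            step = np.exp(log_lambda) * (chol @ rng.standard_normal(d))
            u = rng.random()
            if u < 0.05:
                step *= 8.0  # long jump along the learned (ridge) directions
                adapted = False
            elif u < 0.10:
                step = diag_sd * rng.standard_normal(d)  # basin hop
                adapted = False
            prop = x + step

        alpha = 0.0
        if np.all(prop >= lo) and np.all(prop <= hi):
            try:
                lp = float(loglike(prop))
            except Exception:
                lp = -np.inf
                n_failed += 1
            if not np.isfinite(lp):
                lp = -np.inf
            alpha = 1.0 if lp >= lx else np.exp(lp - lx)
            if alpha >= 1.0 or rng.random() < alpha:
                x = prop
                lx = lp
                n_acc += 1

        # Robbins-Monro scale recursion towards the target acceptance rate,
        # driven by the adapted component only
        if i >= warmup and adapted:
            log_lambda += (i - warmup + 1) ** -0.6 * (alpha - target_acceptance)

        theta[i] = x
        logl[i] = lx
        count += 1
        delta = x - mean
        mean += delta / count
        m2 += np.outer(delta, x - mean)

    return ChainState(theta, logl, prior.names, seed, n_acc, n_failed)


# ---------------------------------------------------------------------------
# chain post-processing
# ---------------------------------------------------------------------------


def detect_burn_in(logl: np.ndarray | ChainState) -> int | None:
    """Index of the first iteration whose log-likelihood reaches the mean
    over the final 10% of the trace; ``None`` if that only happens inside
    the final stretch itself (chain unusable)."""
    if isinstance(logl, ChainState):
        logl = logl.logl
    logl = np.asarray(logl, float)
    n = len(logl)
    if n < 10:
        raise ValueError("trace too short for burn-in detection")
    tail = logl[-max(1, n // 10) :]
    target = float(np.mean(tail))
    hits = np.nonzero(logl >= target)[0]
    if hits.size == 0:  # pragma: no cover - max >= mean guarantees a hit
        return None
    first = int(hits[0])
    if first >= n - len(tail):
        return None
    return first


def _first_lag_below(x: np.ndarray, threshold: float = 0.2) -> int:
    """Smallest lag with (signed) sample autocorrelation below ``threshold``."""
    n = len(x)
    if np.ptp(x) == 0.0:
        return 1  # constant trace: autocorrelation undefined, treat as iid
    nlags = min(n - 1, 200)
    while True:
        rho = _acf(x, nlags=nlags, fft=True)
        below = np.nonzero(rho[1:] < threshold)[0]
        if below.size:
            return int(below[0]) + 1
        if nlags >= n - 1:
            return n  # never decorrelates: keep a single sample
        nlags = min(n - 1, nlags * 5)


def autocorrelation_thin(
    chain: ChainState | np.ndarray,
    burn_in: int | None = None,
    threshold: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Thin a (post-burn-in) trace by the common autocorrelation lag.

    Returns ``(thinned_samples, lag)`` where lag is the maximum over
    parameters of the smallest lag with autocorrelation below ``threshold``.
    """
    if isinstance(chain, ChainState):
        samples = chain.post_burn_in()
    else:
        samples = np.asarray(chain, float)
        if burn_in:
            samples = samples[burn_in:]
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape
    if n < 10 * d:
        raise ValueError(f"post-burn-in trace too short to thin ({n} < {10 * d})")
    lag = max(_first_lag_below(samples[:, j], threshold) for j in range(d))
    return samples[::lag], lag


def select_chains(chains: Sequence[ChainState], tol: float = 10.0) -> list[bool]:
    """Keep chains whose mean post-burn-in log-likelihood is within ``tol``
    natural-log units of the best chain; at least one chain is always kept."""
    usable = [c for c in chains if c.usable]
    if not usable:
        raise CalibrationError("no usable chain (none reached its plateau)")
    means = {
        id(c): float(np.mean(c.logl[c.burn_in_index :])) for c in usable
    }
    best = max(means.values())
    flags = []
    for c in chains:
        flags.append(c.usable and means[id(c)] >= best - tol)
    return flags


def ks_chain_consistency(
    chain_samples: np.ndarray,
    pooled_samples: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample KS test of each parameter's chain marginal against the
    pooled posterior; returns (pass flags, p-values) per parameter."""
    chain_samples = np.atleast_2d(np.asarray(chain_samples, float))
    pooled_samples = np.atleast_2d(np.asarray(pooled_samples, float))
    if chain_samples.size == 0 or pooled_samples.size == 0:
        raise ValueError("empty sample set")
    d = chain_samples.shape[1]
    pvals = np.empty(d)
    for j in range(d):
        pvals[j] = _sstats.ks_2samp(chain_samples[:, j], pooled_samples[:, j]).pvalue
    return pvals > alpha, pvals


# ---------------------------------------------------------------------------
# full calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationSettings:
    """Tunables for one calibration run."""

    n_chains: int = 8
    n_iterations: int = 20_000
    warmup: int = 2_000
    logl_tolerance: float = 10.0
    ks_alpha: float = 0.05
    min_post_per_param: int = 10
    error_model: str = "marginal"
    seed: int = 0


@dataclass
class PosteriorSet:
    """Thinned, selected posterior samples with per-chain provenance."""

    model: str
    param_names: tuple[str, ...]
    chain_samples: list[np.ndarray]
    chain_ids: list[int]
    ks_pass: list[np.ndarray]
    mode_labels: np.ndarray | None = None  # per kept chain, set by identify_modes

    @property
    def pooled(self) -> np.ndarray:
        return np.vstack(self.chain_samples)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def parameter_set(self, theta: np.ndarray) -> ModelParameterSet:
        return ModelParameterSet.from_vector(self.model, theta)


@dataclass
class CalibrationResult:
    model: str
    chains: list[ChainState]
    posterior: PosteriorSet | None
    settings: CalibrationSettings

    @property
    def converged(self) -> bool:
        return self.posterior is not None


def calibrate(
    model: str,
    observations: Sequence[BudburstObservation],
    series_by_site: Mapping[str, DailyTemperatureSeries],
    sites: Mapping[str, SiteMeta],
    settings: CalibrationSettings | None = None,
    prior: PriorSpec | None = None,
    cutoff_date: _dt.date | None = None,
) -> CalibrationResult:
    """Run the full calibration pipeline for one model and observation set."""
    settings = settings or CalibrationSettings()
    prior = prior or default_priors(model)
    evaluator = build_evaluator(
        model, observations, series_by_site, sites, cutoff_date, settings.error_model
    )

    chain_seeds = np.random.SeedSequence(settings.seed).generate_state(settings.n_chains)
    chains: list[ChainState] = []
    for cs in chain_seeds:
        chain = run_amh(evaluator, prior, settings.n_iterations, int(cs), settings.warmup)
        chain.burn_in_index = detect_burn_in(chain.logl)
        if chain.usable:
            try:
                chain.thinned, chain.thin_lag = autocorrelation_thin(chain)
                chain.thinned_logl = chain.logl[chain.burn_in_index :: chain.thin_lag]
            except ValueError:
                chain.burn_in_index = None  # too few plateau samples: unusable
        chains.append(chain)

    try:
        kept_flags = select_chains(chains, settings.logl_tolerance)
    except CalibrationError:
        return CalibrationResult(model, chains, None, settings)
    for chain, keep in zip(chains, kept_flags):
        chain.kept = keep

    kept = [(i, c) for i, c in enumerate(chains) if c.kept]
    pooled = np.vstack([c.thinned for _, c in kept])
    ks_flags: list[np.ndarray] = []
    for _, chain in kept:
        chain.ks_pass, _ = ks_chain_consistency(chain.thinned, pooled, settings.ks_alpha)
        ks_flags.append(chain.ks_pass)

    posterior = PosteriorSet(
        model,
        prior.names,
        [c.thinned for _, c in kept],
        [i for i, _ in kept],
        ks_flags,
    )
    return CalibrationResult(model, chains, posterior, settings)
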