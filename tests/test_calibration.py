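"""Tests for the likelihood, the AMH sampler, and chain post-processing."""

import numpy as np
import pytest

from budburst.calibration import (
    CalibrationSettings,
    ChainState,
    PriorSpec,
    autocorrelation_thin,
    build_evaluator,
    calibrate,
    default_priors,
    detect_burn_in,
    ks_chain_consistency,
    log_likelihood,
    run_amh,
    select_chains,
)
from budburst.models import ModelParameterSet

from conftest import make_series


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


class TestLogLikelihood:
    """logL = -sum of squared day residuals, failures scored at the cutoff."""

    @pytest.fixture()
    def setup(self, flat_site):
        ser = make_series(flat_site.site_id, "1999-10-01", "2000-12-31", 5.0)
        series = {flat_site.site_id: ser}
        sites = {flat_site.site_id: flat_site}
        # GDD1 Tb=0 Fcrit=10 on constant 5 degC predicts day 2
        params = ModelParameterSet("GDD1", {"Tb": 0.0, "Fcrit": 10.0})
        return series, sites, params

    def _obs(self, doy, flat_site):
        from budburst.models import BudburstObservation

        return [BudburstObservation(flat_site.site_id, "P1", 2000, d) for d in doy]

    def test_exact_predictions_give_zero(self, setup, flat_site):
        series, sites, params = setup
        assert log_likelihood("GDD1", params, self._obs([2], flat_site), series, sites) == 0.0

    def test_single_residual(self, setup, flat_site):
        series, sites, params = setup
        # observed day 5, predicted day 2: residual 3
        assert log_likelihood("GDD1", params, self._obs([5], flat_site), series, sites) == -9.0

    def test_two_residuals(self, setup, flat_site):
        series, sites, params = setup
        # predicted 2 for both; observed 4 and -? construct residuals 2 and -5
        obs = self._obs([4, 7], flat_site)  # residuals 2-... pred-obs: -2, -5
        assert log_likelihood("GDD1", params, obs, series, sites) == -29.0

    def test_failure_scored_at_cutoff(self, setup, flat_site):
        series, sites, _ = setup
        params = ModelParameterSet("GDD1", {"Tb": 6.0, "Fcrit": 10.0})  # never accumulates
        obs = self._obs([100], flat_site)
        # leap year 2000: cutoff doy 214, residual 114
        assert log_likelihood("GDD1", params, obs, series, sites) == -(114.0**2)

    def test_no_observations_errors(self, setup):
        series, sites, params = setup
        with pytest.raises(ValueError, match="no observations"):
            log_likelihood("GDD1", params, [], series, sites)


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _quadratic_prior():
    return PriorSpec("GDD1", {"Tb": (-10.0, 10.0), "Fcrit": (0.0, 2000.0)})


class TestRunAMH:
    def test_deterministic_given_seed(self):
        prior = PriorSpec("GDD1", {"Tb": (-5.0, 5.0), "Fcrit": (0.0, 10.0)})
        ll = lambda th: -float(th @ th)
        a = run_amh(ll, prior, 2000, seed=7)
        b = run_amh(ll, prior, 2000, seed=7)
        assert np.array_equal(a.theta, b.theta) and np.array_equal(a.logl, b.logl)

    def test_stays_in_prior_support(self):
        prior = PriorSpec("GDD1", {"Tb": (-1.0, 1.0), "Fcrit": (5.0, 6.0)})
        chain = run_amh(lambda th: 0.0, prior, 5000, seed=3, warmup=100)
        lo, hi = prior.arrays()
        assert (chain.theta >= lo).all() and (chain.theta <= hi).all()

    def test_recovers_gaussian_target(self):
        """A quadratic log-likelihood implies a Gaussian: the chain's moments
        must match within Monte-Carlo error."""
        mu, sigma = 2.0, 0.7
        prior = PriorSpec("MT", {"I": (-50.0, 50.0), "k": (-50.0, 50.0)})
        ll = lambda th: -0.5 * ((th[0] - mu) ** 2 + (th[1] + mu) ** 2) / sigma**2
        chain = run_amh(ll, prior, 20000, seed=11, warmup=1000)
        post = chain.theta[5000:]
        ess = len(post) / (2 * 50)  # conservative effective size guess
        se = sigma / np.sqrt(ess)
        assert abs(post[:, 0].mean() - mu) < 4 * se
        assert abs(post[:, 1].mean() + mu) < 4 * se
        assert abs(post[:, 0].std() - sigma) < 0.15 * sigma

    def test_failing_likelihood_treated_as_rejection(self):
        prior = PriorSpec("GDD1", {"Tb": (-1.0, 1.0), "Fcrit": (0.0, 1.0)})
        calls = {"n": 0}

        def flaky(th):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return 0.0

        chain = run_amh(flaky, prior, 500, seed=1, warmup=50)
        assert chain.n_failed_evals > 0
        assert len(chain.theta) == 500


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------


class TestBurnIn:
    def test_constant_trace_index_zero(self):
        assert detect_burn_in(np.zeros(100)) == 0

    def test_rising_then_flat(self):
        trace = np.concatenate([np.linspace(-100, -10, 50), np.full(50, -10.0)])
        idx = detect_burn_in(trace)
        # plateau mean = -10; first index reaching -10 by linear scan
        assert idx == int(np.argmax(trace >= -10.0))

    def test_late_exceedance_is_unusable(self):
        # strictly increasing: only the final stretch reaches its own mean
        assert detect_burn_in(np.linspace(-1000.0, 0.0, 200)) is None

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            detect_burn_in(np.zeros(5))


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------


class TestThinning:
    def test_white_noise_lag_one(self):
        rng = np.random.default_rng(0)
        thinned, lag = autocorrelation_thin(rng.standard_normal(5000))
        assert lag == 1 and len(thinned) == 5000

    def test_ar1_lag_rule(self):
        # phi = 0.8: 0.8^l < 0.2 at l >= 8 (0.8^7 = 0.21, 0.8^8 = 0.17)
        rng = np.random.default_rng(42)
        n, phi = 100_000, 0.8
        z = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = z[0]
        for t in range(1, n):
            x[t] = phi * x[t - 1] + np.sqrt(1 - phi**2) * z[t]
        thinned, lag = autocorrelation_thin(x)
        assert lag in (7, 8, 9)
        from statsmodels.tsa.stattools import acf

        assert acf(thinned, nlags=1, fft=True)[1] < 0.25

    def test_common_lag_is_max_over_parameters(self):
        rng = np.random.default_rng(3)
        n = 50_000
        fast = rng.standard_normal(n)
        slow = np.convolve(rng.standard_normal(n + 9), np.ones(10) / 10, "valid")
        _, lag_fast = autocorrelation_thin(fast)
        _, lag_slow = autocorrelation_thin(slow)
        _, lag_common = autocorrelation_thin(np.column_stack([fast, slow]))
        assert lag_common == max(lag_fast, lag_slow) > lag_fast

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            autocorrelation_thin(np.random.default_rng(0).standard_normal((15, 2)))


# ---------------------------------------------------------------------------
# chain selection and KS consistency
# ---------------------------------------------------------------------------


def _fake_chain(mean_logl: float, n: int = 100, seed: int = 0) -> ChainState:
    rng = np.random.default_rng(seed)
    logl = mean_logl + rng.normal(0, 0.1, n)
    chain = ChainState(rng.normal(size=(n, 1)), logl, ("x",), seed, n // 2)
    chain.burn_in_index = 0
    return chain


class TestSelectChains:
    def test_identical_chains_all_kept(self):
        chains = [_fake_chain(-500.0, seed=i) for i in range(8)]
        assert select_chains(chains) == [True] * 8

    def test_stuck_chain_dropped(self):
        chains = [_fake_chain(-500.0, seed=i) for i in range(7)] + [_fake_chain(-5000.0)]
        flags = select_chains(chains)
        assert flags == [True] * 7 + [False]

    def test_single_chain_kept(self):
        assert select_chains([_fake_chain(-123.0)]) == [True]

    def test_unusable_never_kept(self):
        good = _fake_chain(-500.0)
        bad = _fake_chain(-500.0, seed=1)
        bad.burn_in_index = None
        assert select_chains([good, bad]) == [True, False]


class TestKSConsistency:
    def test_chain_against_itself_passes(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(size=(400, 2))
        passes, _ = ks_chain_consistency(samples, samples)
        assert passes.all()

    def test_shifted_uniform_fails(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, size=(500, 1))
        b = rng.uniform(0.5, 1.5, size=(500, 1))
        passes, _ = ks_chain_consistency(a, b)
        assert not passes.any()

    def test_tiny_samples_pass_without_error(self):
        passes, _ = ks_chain_consistency(np.array([[0.1], [0.2], [0.3]]), np.array([[5.0], [6.0], [7.0]]))
        assert passes.all()  # n = 3: no power, no rejection


# ---------------------------------------------------------------------------
# end-to-end calibration on the small network
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def result(synthetic_network):
    sites, series, obs, _ = synthetic_network
    settings = CalibrationSettings(n_chains=4, n_iterations=4000, warmup=800, seed=5)
    return calibrate("GDD_DOY", obs, series, sites, settings), sites, series, obs


class TestCalibrate:
    def test_converges_and_stays_in_prior(self, result):
        res, *_ = result
        assert res.converged
        lo, hi = default_priors("GDD_DOY").arrays()
        pooled = res.posterior.pooled
        assert (pooled >= lo).all() and (pooled <= hi).all()

    def test_deterministic(self, synthetic_network):
        sites, series, obs, _ = synthetic_network
        settings = CalibrationSettings(n_chains=2, n_iterations=1500, warmup=300, seed=9)
        a = calibrate("GDD1", obs, series, sites, settings)
        b = calibrate("GDD1", obs, series, sites, settings)
        assert np.array_equal(a.posterior.pooled, b.posterior.pooled)

    def test_max_likelihood_sample_has_lowest_rmse(self, result):
        """The best-scoring retained sample cannot be beaten on calibration
        RMSE by any other retained sample."""
        res, sites, series, obs = result
        ev = build_evaluator("GDD_DOY", obs, series, sites)
        pooled = res.posterior.pooled
        sses = np.array([ev.sse(th) for th in pooled])
        logls = np.concatenate([c.thinned_logl for c in res.chains if c.kept])
        assert len(logls) == len(pooled)
        assert sses[np.argmax(logls)] <= sses.min() + 1e-9

    def test_thinned_chains_decorrelated(self, result):
        res, *_ = result
        from statsmodels.tsa.stattools import acf

        for samples in res.posterior.chain_samples:
            if len(samples) < 30:
                continue
            for j in range(samples.shape[1]):
                if np.ptp(samples[:, j]) == 0:
                    continue
                rho1 = acf(samples[:, j], nlags=1, fft=True)[1]
                assert rho1 < 0.2 + 3.0 / np.sqrt(len(samples))
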