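"""Unit and property tests for the phenology models."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import budburst as bb
from budburst.calibration import default_priors
from budburst.engine import PredictorTable, predict_table
from budburst.models import ModelParameterSet, season_values

from conftest import make_series, oracle_day_length, oracle_predict


# ---------------------------------------------------------------------------
# windows and day length
# ---------------------------------------------------------------------------


class TestMeanTemperatureWindow:
    def test_constant_series(self, constant5):
        assert bb.mean_temperature_window(constant5, 2001) == pytest.approx(5.0)

    def test_hand_computed_mix(self, flat_site):
        # non-leap year: 28 days Feb at 0, 31 days Mar at 0, 30 days Apr at 8.9
        ser = make_series("s", "2001-01-01", "2001-12-31", 0.0)
        vals = ser.values.copy()
        apr = (dt.date(2001, 4, 1) - dt.date(2001, 1, 1)).days
        vals[apr : apr + 30] = 8.9
        ser = bb.DailyTemperatureSeries("s", ser.dates, vals)
        assert bb.mean_temperature_window(ser, 2001) == pytest.approx(8.9 * 30 / 89)

    def test_leap_february_included(self):
        ser = make_series("s", "2000-01-01", "2000-12-31", 1.0)
        assert bb.mean_temperature_window(ser, 2000) == pytest.approx(1.0)
        assert len(ser.window(dt.date(2000, 2, 1), dt.date(2000, 4, 30))) == 90

    def test_missing_window_errors(self):
        ser = make_series("s", "2001-03-01", "2001-12-31", 5.0)
        with pytest.raises(ValueError, match="does not cover"):
            bb.mean_temperature_window(ser, 2001)


class TestDayLength:
    def test_equator_near_12h(self):
        for doy in (1, 100, 200, 300):
            assert bb.day_length(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_seasonal_ordering_mid_latitude(self):
        assert bb.day_length(50.0, 172) > bb.day_length(50.0, 355)

    def test_polar_day_saturates(self):
        assert bb.day_length(70.0, 172) == pytest.approx(24.0)

    def test_matches_independent_formula(self):
        for lat in (-60, -23.5, 0.0, 35.0, 65.0):
            for doy in range(1, 366, 13):
                assert bb.day_length(lat, doy) == pytest.approx(
                    oracle_day_length(lat, doy), abs=1e-9
                )

    def test_bad_latitude(self):
        with pytest.raises(ValueError):
            bb.day_length(95.0, 100)


# ---------------------------------------------------------------------------
# the empirical regression model
# ---------------------------------------------------------------------------


class TestMT:
    def test_basic_arithmetic(self, constant5):
        p = ModelParameterSet("MT", {"I": 150, "k": -5})
        assert bb.predict_mt(p, constant5, 2001).doy == 125  # 150 - 25

    def test_slope_times_mean(self, flat_site):
        ser = make_series("s", "2001-01-01", "2001-12-31", 6.0)
        p = ModelParameterSet("MT", {"I": 150, "k": -5})
        assert bb.predict_mt(p, ser, 2001).doy == 120

    def test_steeper_slope(self):
        ser = make_series("s", "2001-01-01", "2001-12-31", 10.0)
        p = ModelParameterSet("MT", {"I": 150, "k": -5.5})
        assert bb.predict_mt(p, ser, 2001).doy == 95

    def test_cutoff_failure(self, constant5):
        p = ModelParameterSet("MT", {"I": 250, "k": 0})
        pred = bb.predict_mt(p, constant5, 2001)
        assert pred.failed and pred.doy is None

    def test_degenerate_negative_day(self, constant5):
        p = ModelParameterSet("MT", {"I": -10, "k": 0})
        pred = bb.predict_mt(p, constant5, 2001)
        assert pred.failed and pred.degenerate


# ---------------------------------------------------------------------------
# forcing / chilling accumulation
# ---------------------------------------------------------------------------


class TestAccumulation:
    def test_gdd_linear_in_time(self, constant5, flat_site):
        p = ModelParameterSet("GDD1", {"Tb": 0.0, "Fcrit": 10.0})
        traj = bb.accumulate_forcing("GDD1", p, constant5, flat_site, 2001)
        assert np.allclose(traj.sf[:10], 5.0 * np.arange(1, 11))

    def test_bc_doy_with_zero_exponent_equals_gdd_doy(self, flat_site):
        rng = np.random.default_rng(5)
        ser = make_series("s", "1999-10-01", "2000-12-31", 0.0)
        ser = bb.DailyTemperatureSeries(
            "s", ser.dates, rng.normal(5, 6, len(ser.dates))
        )
        pb = ModelParameterSet("BC_DOY", {"t0": 40, "Tb": 2.0, "EXPO": 0.0, "Fcrit": 90.0})
        pg = ModelParameterSet("GDD_DOY", {"t0": 40, "Tb": 2.0, "Fcrit": 90.0})
        tb = bb.accumulate_forcing("BC_DOY", pb, ser, flat_site, 2000)
        tg = bb.accumulate_forcing("GDD_DOY", pg, ser, flat_site, 2000)
        assert np.array_equal(tb.sf, tg.sf)

    def test_sigmoid_midpoint_rate(self, flat_site):
        ser = make_series("s", "1999-10-01", "2000-12-31", 0.0)
        p = ModelParameterSet("SIG_DOY", {"t0": 1, "b": -1.0, "c": 0.0, "Fcrit": 50.0})
        traj = bb.accumulate_forcing("SIG_DOY", p, ser, flat_site, 2000)
        assert traj.sf[0] == pytest.approx(0.5)

    def test_seq_chilling_triangle(self):
        p = ModelParameterSet(
            "SEQ", {"Topt": 3.0, "Tb": 5.0, "b": -0.3, "c": -8.0, "Ccrit": 50.0, "Fcrit": 20.0}
        )
        apex = make_series("s", "1999-10-01", "2000-12-31", 3.0)
        sc = bb.accumulate_chilling("SEQ", p, apex, 2000).sc
        # by Jan 1 (index 0), 92 autumn days + Jan 1 itself at rate 1.0
        assert sc[0] == pytest.approx(93.0)
        for t_out in (-3.4, 10.5):
            flat = make_series("s", "1999-10-01", "2000-12-31", t_out)
            assert bb.accumulate_chilling("SEQ", p, flat, 2000).sc[-1] == 0.0

    def test_alt_counts_cold_days(self):
        p = ModelParameterSet("ALT", {"t2": -91, "Tb": 5.0, "beta": 100.0, "gamma": 0.01})
        ser = make_series("s", "1999-10-01", "2000-12-31", 0.0)
        sc = bb.accumulate_chilling("ALT", p, ser, 2000).sc
        assert sc[0] == 93.0  # every day below Tb counts
        assert sc[9] - sc[0] == 9.0

    def test_critical_forcing_decay(self):
        p = ModelParameterSet("ALT", {"t2": 1, "Tb": 5.0, "beta": 100.0, "gamma": 0.01})
        assert bb.critical_forcing("ALT", p, 0.0) == pytest.approx(100.0)
        assert bb.critical_forcing("ALT", p, 50.0) == pytest.approx(100 * np.exp(-0.5))
        p0 = ModelParameterSet("ALT", {"t2": 1, "Tb": 5.0, "beta": 100.0, "gamma": 0.0})
        assert bb.critical_forcing("ALT", p0, 500.0) == 100.0

    def test_trajectories_monotone_nonnegative(self, synthetic_network):
        sites, series, _, _ = synthetic_network
        sid = next(iter(sites))
        for model, params in [
            ("SEQ", ModelParameterSet("SEQ", {"Topt": 2, "Tb": 4, "b": -0.2, "c": -7, "Ccrit": 40, "Fcrit": 15})),
            ("UNI", ModelParameterSet("UNI", {"t2": -60, "ac": 0.1, "bc": -0.5, "oC": 2, "dF": -0.4, "fF": 6, "Ccrit": 40, "beta": 300, "gamma": 0.005})),
        ]:
            sf = bb.accumulate_forcing(model, params, series[sid], sites[sid], 1995).sf
            sc = bb.accumulate_chilling(model, params, series[sid], 1995).sc
            assert (np.diff(sf) >= 0).all() and (sf >= 0).all()
            assert (np.diff(sc) >= 0).all() and (sc >= 0).all()


# ---------------------------------------------------------------------------
# prediction rule
# ---------------------------------------------------------------------------


class TestPredictBudburst:
    def test_gdd_ceiling_rule(self, constant5, flat_site):
        p = ModelParameterSet("GDD1", {"Tb": 0.0, "Fcrit": 10.0})
        assert bb.predict_budburst("GDD1", p, constant5, flat_site, 2001).doy == 2

    def test_no_accumulation_fails(self, flat_site):
        cold = make_series("s", "1999-10-01", "2000-12-31", -10.0)
        p = ModelParameterSet("GDD1", {"Tb": 0.0, "Fcrit": 10.0})
        pred = bb.predict_budburst("GDD1", p, cold, flat_site, 2000)
        assert pred.failed

    def test_seq_gate_blocks_forcing_before_chilling(self, flat_site):
        # warm winter: no chilling accumulates, so no forcing ever does
        warm = make_series("s", "1999-10-01", "2000-12-31", 15.0)
        p = ModelParameterSet(
            "SEQ", {"Topt": 3.0, "Tb": 0.0, "b": -3.0, "c": 10.0, "Ccrit": 5.0, "Fcrit": 0.5}
        )
        traj = bb.accumulate_forcing("SEQ", p, warm, flat_site, 2000)
        assert traj.sf[-1] == 0.0
        assert bb.predict_budburst("SEQ", p, warm, flat_site, 2000).failed

    def test_unknown_model(self, constant5, flat_site):
        with pytest.raises(ValueError, match="unknown model"):
            bb.predict_budburst("XXX", None, constant5, flat_site, 2000)

    @pytest.mark.parametrize("t,tb,fcrit", [(8.0, 2.0, 30.0), (5.0, 0.0, 10.0), (12.0, 4.5, 123.0)])
    def test_closed_form_constant_temperature(self, flat_site, t, tb, fcrit):
        ser = make_series("s", "1999-10-01", "2000-12-31", t)
        p = ModelParameterSet("GDD_DOY", {"t0": 20, "Tb": tb, "Fcrit": fcrit})
        pred = bb.predict_budburst("GDD_DOY", p, ser, flat_site, 2000)
        assert pred.doy == 20 - 1 + int(np.ceil(fcrit / (t - tb)))


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


def _random_series(seed: int, year: int = 2000) -> bb.DailyTemperatureSeries:
    rng = np.random.default_rng(seed)
    base = make_series("s", f"{year - 1}-09-01", f"{year}-12-31", 0.0)
    doy = base.dates.dayofyear.to_numpy(float)
    vals = 6 + 9 * np.cos(2 * np.pi * (doy - 200) / 365.25) + rng.normal(0, 3, len(doy))
    return bb.DailyTemperatureSeries("s", base.dates, vals)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), delta=st.floats(0.5, 6.0))
def test_warming_never_delays_forcing_models(seed, delta):
    """Uniformly warmer springs advance (or keep) budburst for all pure
    forcing models, including the sigmoid with a warm-increasing response."""
    site = bb.SiteMeta("s", 52.0, 10.0, 100.0, 100.0)
    ser = _random_series(seed)
    warm = ser.shifted(delta)
    cases = [
        ("GDD1", {"Tb": 2.0, "Fcrit": 180.0}),
        ("GDD_DOY", {"t0": 45, "Tb": 2.0, "Fcrit": 150.0}),
        ("BC_DOY", {"t0": 45, "Tb": 2.0, "EXPO": 1.0, "Fcrit": 160.0}),
        ("SIG_DOY", {"t0": 45, "b": -0.5, "c": -5.0, "Fcrit": 30.0}),
    ]
    for model, params in cases:
        p = ModelParameterSet(model, params)
        a = bb.predict_budburst(model, p, ser, site, 2000)
        b = bb.predict_budburst(model, p, warm, site, 2000)
        if not a.failed:
            assert not b.failed and b.doy <= a.doy, model


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_chilling_loss_never_advances_alt(seed):
    """Raising sub-threshold winter days to exactly Tb removes chilling days
    while leaving degree-day forcing untouched (max(0, Tb - Tb) = 0); the
    forcing requirement can only rise, so budburst never advances."""
    site = bb.SiteMeta("s", 52.0, 10.0, 100.0, 100.0)
    ser = _random_series(seed)
    vals = ser.values.copy()
    winter = ser.dates < np.datetime64("2000-02-01")
    vals_warm = vals.copy()
    vals_warm[winter] = np.maximum(vals_warm[winter], 6.0)  # = Tb: chill lost, no forcing gained
    p = ModelParameterSet("ALT", {"t2": -91, "Tb": 6.0, "beta": 400.0, "gamma": 0.02})
    a = bb.predict_budburst("ALT", p, ser, site, 2000)
    b = bb.predict_budburst(
        "ALT", p, bb.DailyTemperatureSeries("s", ser.dates, vals_warm), site, 2000
    )
    a_doy = a.doy if not a.failed else 999
    b_doy = b.doy if not b.failed else 999
    assert b_doy >= a_doy


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_seq_accumulates_nothing_before_chilling_met(seed):
    site = bb.SiteMeta("s", 52.0, 10.0, 100.0, 100.0)
    ser = _random_series(seed)
    p = ModelParameterSet(
        "SEQ", {"Topt": 2.0, "Tb": 3.0, "b": -0.4, "c": -6.0, "Ccrit": 60.0, "Fcrit": 25.0}
    )
    sf = bb.accumulate_forcing("SEQ", p, ser, site, 2000).sf
    sc = bb.accumulate_chilling("SEQ", p, ser, 2000).sc
    before = sc < p.Ccrit
    assert np.all(sf[before] == 0.0)


# ---------------------------------------------------------------------------
# oracle equivalence (reference implementation and compiled kernels)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("model", bb.MODEL_TAGS)
def test_oracle_equivalence_random_parameters(model, flat_site):
    """Reference per-series prediction, compiled kernel, and the brute-force
    day-scan oracle agree exactly on randomized series and parameters."""
    rng = np.random.default_rng(hash(model) % 2**31)
    lo, hi = default_priors(model).arrays()
    names = bb.MODEL_PARAM_NAMES[model]
    series = [_random_series(1000 + k) for k in range(5)]
    for k, ser in enumerate(series):
        tab = PredictorTable.build([("s", 2000)], {"s": ser}, {"s": flat_site})
        for _ in range(8):
            theta = lo + rng.random(len(lo)) * (hi - lo)
            params = ModelParameterSet.from_vector(model, theta)
            ref = bb.predict_budburst(model, params, ser, flat_site, 2000)
            ref_doy = -1 if ref.failed else ref.doy
            kern = predict_table(model, theta, tab)[0]
            orc = oracle_predict(model, dict(zip(names, theta)), ser, flat_site, 2000)
            orc_doy = -1 if orc is None else orc
            assert ref_doy == kern == orc_doy, (model, theta)
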