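"""Shared fixtures and an independent brute-force budburst oracle.

The oracle walks the calendar day by day with plain Python floats and
``math`` functions, re-deriving every model's forcing/chilling rules from
their definitions; it shares no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from budburst.models import DailyTemperatureSeries, SiteMeta

# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------


def oracle_day_length(latitude: float, doy: int) -> float:
    decl = math.radians(-23.44 * math.cos(2.0 * math.pi * (doy + 10.0) / 365.0))
    cos_h = -math.tan(math.radians(latitude)) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


def _sig(b: float, c: float, t: float) -> float:
    arg = min(500.0, max(-500.0, b * (t + c)))
    return 1.0 / (1.0 + math.exp(arg))


def oracle_predict(model, params, series, site, year):
    """Day-by-day scan; returns day-of-year or None (failure).

    ``params`` is a plain dict.  Temperatures are looked up by real date.
    """
    date0 = series.dates[0].date()

    def temp_on(date):
        return float(series.values[(date - date0).days])

    jan1 = dt.date(year, 1, 1)
    aug1 = dt.date(year, 8, 1)
    cutoff = (aug1 - jan1).days + 1  # doy of Aug 1

    if model == "MT":
        d, s, n = dt.date(year, 2, 1), 0.0, 0
        while d <= dt.date(year, 4, 30):
            s += temp_on(d)
            n += 1
            d += dt.timedelta(days=1)
        doy = math.floor(params["I"] + params["k"] * (s / n) + 0.5)
        return doy if 1 <= doy < cutoff else None

    start = 1
    if model in ("GDD_DOY", "SIG_DOY", "BC_DOY"):
        start = max(1, math.floor(params["t0"]))

    # chilling start date
    if model in ("ALT", "UNI"):
        t2 = math.floor(params["t2"])
        chill_start = max(jan1 + dt.timedelta(days=t2 - 1), dt.date(year - 1, 10, 1))
    elif model == "SEQ":
        chill_start = dt.date(year - 1, 10, 1)
    else:
        chill_start = None

    def chill_rate(t):
        if model == "ALT":
            return 1.0 if t < params["Tb"] else 0.0
        if model == "SEQ":
            topt = params["Topt"]
            if t <= -3.4 or t > 10.4:
                return 0.0
            if t <= topt:
                return (t + 3.4) / (topt + 3.4)
            return (t - 10.4) / (topt - 10.4)
        dev = t - params["oC"]
        arg = min(500.0, max(-500.0, params["ac"] * dev * dev + params["bc"] * dev))
        return 1.0 / (1.0 + math.exp(arg))

    sc = 0.0
    if chill_start is not None:
        d = chill_start
        while d < jan1:
            sc += chill_rate(temp_on(d))
            d += dt.timedelta(days=1)

    sf = 0.0
    for doy in range(1, cutoff):
        date = jan1 + dt.timedelta(days=doy - 1)
        t = temp_on(date)
        if chill_start is not None and date >= chill_start:
            sc += chill_rate(t)
        if doy >= start:
            if model in ("GDD1", "GDD_DOY", "ALT"):
                sf += max(0.0, t - params["Tb"])
            elif model == "SIG_DOY":
                sf += _sig(params["b"], params["c"], t)
            elif model == "BC_DOY":
                if t > params["Tb"]:
                    dl = oracle_day_length(site.latitude, doy)
                    sf += (t - params["Tb"]) * (dl / 10.0) ** params["EXPO"]
            elif model == "SEQ":
                if t >= params["Tb"] and sc >= params["Ccrit"]:
                    sf += _sig(params["b"], params["c"], t)
            elif model == "UNI":
                if sc >= params["Ccrit"]:
                    arg = min(500.0, max(-500.0, params["dF"] * (t - params["fF"])))
                    sf += 1.0 / (1.0 + math.exp(arg))
        if model in ("ALT", "UNI"):
            fcrit = params["beta"] * math.exp(-params["gamma"] * sc)
        else:
            fcrit = params["Fcrit"]
        if sf >= fcrit:
            return doy
    return None


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_series(site_id, start, end, values) -> DailyTemperatureSeries:
    dates = pd.date_range(start, end, freq="D")
    values = np.broadcast_to(np.asarray(values, float), (len(dates),)).copy()
    return DailyTemperatureSeries(site_id, dates, values)


@pytest.fixture(scope="session")
def flat_site() -> SiteMeta:
    return SiteMeta("S01", 50.0, 10.0, 100.0, 100.0)


@pytest.fixture(scope="session")
def constant5(flat_site) -> DailyTemperatureSeries:
    """Constant 5 degC from autumn 1999 through 2000 (non-leap prediction
    years use 2001)."""
    return make_series(flat_site.site_id, "1998-10-01", "2001-12-31", 5.0)


@pytest.fixture(scope="session")
def synthetic_network():
    """Small reproducible network: 3 sites x 10 years with observations from
    a known degree-day truth model."""
    from budburst.models import ModelParameterSet
    from budburst.synth import (
        ClimateGeneratorConfig,
        TruthConfig,
        generate_observations,
        generate_sites,
        generate_temperature,
    )

    sites = generate_sites(3, seed=42)
    cfg = ClimateGeneratorConfig()
    series = {
        s.site_id: generate_temperature(s, (1991, 2000), cfg, seed=300 + i)
        for i, s in enumerate(sites)
    }
    truth = TruthConfig(
        ModelParameterSet("GDD_DOY", {"t0": 60, "Tb": 5.0, "Fcrit": 150.0}),
        obs_noise_sd=3.0,
    )
    obs = generate_observations(truth, series, sites, range(1991, 2001), seed=99)
    return {s.site_id: s for s in sites}, series, obs, truth
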