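"""Synthetic site networks, daily temperature forcing, and budburst
observations.

The generator emulates the structure of the data the pipeline consumes
without any download: a network of mid/high-latitude sites with signed
differences between site and climate-grid altitude, daily mean temperature
with a seasonal cycle, AR(1) day-to-day noise, a latitudinal and lapse-rate
gradient and an optional (seasonally weighted) warming trend, and budburst
observations produced by a known truth model plus Gaussian day-noise.

It does not attempt weather-generator realism: there is no precipitation,
no heat-wave clustering, and no spatial correlation between sites beyond
the shared climatology.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    BudburstObservation,
    DailyTemperatureSeries,
    ModelParameterSet,
    SiteMeta,
    predict_budburst,
)

__all__ = [
    "ClimateGeneratorConfig",
    "TruthConfig",
    "generate_sites",
    "generate_temperature",
    "generate_scenario_suite",
    "generate_observations",
]


@dataclass(frozen=True)
class ClimateGeneratorConfig:
    """Knobs of the daily temperature generator.

    The defaults describe a north/central-European climate: an 8 degC annual
    mean at the 50 degN reference, a 10 degC seasonal amplitude peaking on
    day 200 (mid July), AR(1) day-to-day noise with coefficient 0.7 and a
    2.5 degC marginal SD, a -0.4 degC/degree latitude gradient, and the 6.4
    degC/km standard lapse rate.  ``warming_seasonality`` > 0 concentrates
    the trend in winter (peak mid January), mimicking the stronger winter
    warming of high-emission scenarios.
    """

    annual_mean: float = 8.0
    seasonal_amplitude: float = 10.0
    peak_doy: float = 200.0
    ar1: float = 0.7
    noise_sd: float = 2.5
    lat_gradient: float = -0.4
    ref_latitude: float = 50.0
    lapse_rate: float = 6.4
    warming_per_decade: float = 0.0
    warming_ref_year: int = 1971
    warming_seasonality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must be in [0, 1)")
        if self.noise_sd < 0.0:
            raise ValueError("noise SD must be >= 0")


@dataclass(frozen=True)
class TruthConfig:
    """Truth model and observation-noise settings for synthetic records."""

    params: ModelParameterSet
    provenance_id: str = "P1"
    obs_noise_sd: float = 3.0
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.obs_noise_sd < 0.0:
            raise ValueError("observation noise SD must be >= 0")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ValueError("missing probability must be in [0, 1)")


def generate_sites(
    n_sites: int,
    seed: int,
    lat_range: tuple[float, float] = (45.0, 65.0),
    lon_range: tuple[float, float] = (-6.0, 25.0),
    alt_range: tuple[float, float] = (15.0, 1210.0),
    alt_diff_range: tuple[float, float] = (-300.0, 300.0),
) -> list[SiteMeta]:
    """Reproducible site network spanning the configured geographic ranges."""
    if n_sites < 1:
        raise ValueError("need n_sites >= 1")
    rng = np.random.default_rng(seed)
    sites = []
    for i in range(n_sites):
        lat = rng.uniform(*lat_range)
        alt = rng.uniform(*alt_range)
        diff = rng.uniform(*alt_diff_range)
        sites.append(
            SiteMeta(
                site_id=f"S{i + 1:02d}",
                latitude=float(lat),
                longitude=float(rng.uniform(*lon_range)),
                site_altitude=float(alt),
                grid_altitude=float(max(0.0, alt + diff)),
            )
        )
    return sites


def generate_temperature(
    site: SiteMeta,
    year_range: tuple[int, int],
    config: ClimateGeneratorConfig,
    seed: int,
    altitude: float | None = None,
) -> DailyTemperatureSeries:
    """Daily mean temperature for one site.

    The series starts on January 1 of ``year_range[0] - 1`` (covering the
    preceding autumn needed to predict the first budburst year) and ends on
    December 31 of ``year_range[1]``.  ``altitude`` selects the elevation
    the series represents (site altitude by default; pass the grid altitude
    for grid-cell-level boundary-condition data).
    """
    y0, y1 = year_range
    dates = pd.date_range(_dt.date(y0 - 1, 1, 1), _dt.date(y1, 12, 31), freq="D")
    doy = dates.dayofyear.to_numpy(float)
    alt = site.site_altitude if altitude is None else altitude

    base = (
        config.annual_mean
        + config.lat_gradient * (site.latitude - config.ref_latitude)
        - config.lapse_rate * alt / 1000.0
    )
    seasonal = config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - config.peak_doy) / 365.25
    )
    elapsed_decades = (
        dates.year.to_numpy(float) + (doy - 1) / 365.25 - config.warming_ref_year
    ) / 10.0
    warming = (
        config.warming_per_decade
        * elapsed_decades
        * (1.0 + config.warming_seasonality * np.cos(2.0 * np.pi * (doy - 15.0) / 365.25))
    )

    rng = np.random.default_rng(seed)
    n = len(dates)
    noise = np.zeros(n)
    if config.noise_sd > 0.0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar1**2)
        z = rng.standard_normal(n)
        noise[0] = config.noise_sd * z[0]  # stationary start
        for t in range(1, n):
            noise[t] = config.ar1 * noise[t - 1] + innov_sd * z[t]

    return DailyTemperatureSeries(site.site_id, dates, base + seasonal + warming + noise)


def generate_scenario_suite(
    sites: Sequence[SiteMeta],
    year_range: tuple[int, int],
    config: ClimateGeneratorConfig,
    n_bc: int,
    warming_range: tuple[float, float],
    seed: int,
) -> dict[str, dict[str, DailyTemperatureSeries]]:
    """A boundary-condition ensemble of ``n_bc`` transient datasets.

    Members share the baseline climatology but have independent noise
    realizations (their year-by-year variation is uncorrelated with any
    observation-driven series, as with free-running climate model output)
    and warming rates drawn uniformly from ``warming_range`` (degC/decade).
    Series are generated at grid-cell altitude.
    """
    if n_bc < 1:
        raise ValueError("need n_bc >= 1")
    rng = np.random.default_rng(seed)
    rates = rng.uniform(*warming_range, size=n_bc)
    suite: dict[str, dict[str, DailyTemperatureSeries]] = {}
    for b in range(n_bc):
        label = f"BC{b + 1}"
        member_cfg = replace(config, warming_per_decade=float(rates[b]))
        member_seed = int(rng.integers(0, 2**31 - 1))
        suite[label] = {
            site.site_id: generate_temperature(
                site, year_range, member_cfg, member_seed + i, altitude=site.grid_altitude
            )
            for i, site in enumerate(sites)
        }
    return suite


def generate_observations(
    truth: TruthConfig,
    series_by_site: Mapping[str, DailyTemperatureSeries],
    sites: Mapping[str, SiteMeta] | Sequence[SiteMeta],
    years: Sequence[int],
    seed: int,
) -> list[BudburstObservation]:
    """Budburst records from a known truth model plus Gaussian day-noise.

    Noise is rounded to whole days and clipped to [1, 366]; records are
    dropped independently with the configured missing probability; truth
    failures yield no record.  A truth model failing on more than half of
    the site-years is considered degenerate and raises.
    """
    if not isinstance(sites, Mapping):
        sites = {s.site_id: s for s in sites}
    rng = np.random.default_rng(seed)
    model = truth.params.model
    records: list[BudburstObservation] = []
    n_total = 0
    n_failed = 0
    for sid, series in series_by_site.items():
        site = sites[sid]
        for year in years:
            n_total += 1
            pred = predict_budburst(model, truth.params, series, site, year)
            if pred.failed:
                n_failed += 1
                continue
            if truth.missing_prob > 0.0 and rng.random() < truth.missing_prob:
                continue
            doy = pred.doy + int(np.rint(rng.normal(0.0, truth.obs_noise_sd)))
            records.append(
                BudburstObservation(
                    sid, truth.provenance_id, int(year), int(np.clip(doy, 1, 366))
                )
            )
    if n_total and n_failed > 0.5 * n_total:
        raise ValueError(
            f"degenerate truth model: failed on {n_failed}/{n_total} site-years"
        )
    return records
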