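"""Process-based spring phenology (budburst) models.

Eight model classes are implemented, spanning the structural range commonly
used for boreal/temperate trees:

====== ====================================================================
Tag    Structure
====== ====================================================================
MT     empirical linear regression of budburst day on mean Feb-Apr temperature
GDD1   growing degree-days above a base temperature, accumulated from Jan 1
GDD_DOY degree-days from a calibrated starting day ``t0``
SIG_DOY sigmoidal (logistic) forcing response from ``t0``
BC_DOY  degree-days from ``t0`` modulated by a photoperiod factor (DL/10)^EXPO
ALT    "alternating": degree-day forcing from Jan 1 with the critical forcing
       requirement decaying exponentially with the number of chilling days
SEQ    "sequential": triangular chilling; sigmoidal forcing gated on the
       chilling requirement being met
UNI    "unified": bell-shaped chilling, sigmoidal forcing gated on chilling,
       and an exponentially decaying forcing requirement
====== ====================================================================

All temperature-sum models share one prediction rule: budburst falls on the
first day whose end-of-day accumulated forcing meets or exceeds the critical
requirement.  If no day before August 1 qualifies, the simulation is flagged
as failed (photoperiod protects real buds from absurdly late flushing, so a
model that cannot reach its requirement by then is counted as a failure
rather than assigned a late date).

Day-of-year is 1-based on the real calendar; the August-1 cutoff is day 213
in ordinary years and 214 in leap years, always derived from the date.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODEL_TAGS",
    "MODEL_PARAM_NAMES",
    "SEQ_FIXED",
    "DailyTemperatureSeries",
    "SiteMeta",
    "BudburstObservation",
    "BudburstPrediction",
    "ModelParameterSet",
    "ForcingTrajectory",
    "ChillingTrajectory",
    "day_length",
    "mean_temperature_window",
    "cutoff_doy",
    "season_values",
    "accumulate_forcing",
    "accumulate_chilling",
    "critical_forcing",
    "predict_mt",
    "predict_budburst",
]

#: Calibratable parameters per model class, in canonical vector order.
MODEL_PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "MT": ("I", "k"),
    "GDD1": ("Tb", "Fcrit"),
    "GDD_DOY": ("t0", "Tb", "Fcrit"),
    "SIG_DOY": ("t0", "b", "c", "Fcrit"),
    "BC_DOY": ("t0", "Tb", "EXPO", "Fcrit"),
    "ALT": ("t2", "Tb", "beta", "gamma"),
    "SEQ": ("Topt", "Tb", "b", "c", "Ccrit", "Fcrit"),
    "UNI": ("t2", "ac", "bc", "oC", "dF", "fF", "Ccrit", "beta", "gamma"),
}

MODEL_TAGS: tuple[str, ...] = tuple(MODEL_PARAM_NAMES)

#: SEQ constants held fixed during calibration: chilling starts October 1
#: (day offset -91 relative to Jan 1) and accumulates only between the
#: commonly accepted temperature bounds.
SEQ_FIXED = {"t2": -91, "Tmin": -3.4, "Tmax": 10.4}

#: Column of January 1 in a season window that starts on October 1 of the
#: preceding year (Oct+Nov+Dec = 92 days).
JAN1_COL = 92

_CHILLING_MODELS = frozenset({"ALT", "SEQ", "UNI"})
_T0_MODELS = frozenset({"GDD_DOY", "SIG_DOY", "BC_DOY"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMeta:
    """Location metadata for one phenological garden / site."""

    site_id: str
    latitude: float
    longitude: float
    site_altitude: float
    grid_altitude: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not (np.isfinite(self.site_altitude) and np.isfinite(self.grid_altitude)):
            raise ValueError("altitudes must be finite")

    @property
    def alt_diff(self) -> float:
        """Grid-cell altitude minus site altitude (m); sign matters for the
        lapse-rate adjustment."""
        return self.grid_altitude - self.site_altitude


@dataclass(frozen=True)
class BudburstObservation:
    """One observed budburst record (1-based day of year)."""

    site_id: str
    provenance_id: str
    year: int
    doy: int

    def __post_init__(self) -> None:
        if not 1 <= self.doy <= 366:
            raise ValueError(f"doy {self.doy} outside [1, 366]")


@dataclass(frozen=True)
class BudburstPrediction:
    """Simulated budburst: a day of year, or a failure flag when the model
    cannot reach its requirement before the cutoff."""

    doy: int | None
    failed: bool
    forcing_at_event: float = float("nan")
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.failed != (self.doy is None):
            raise ValueError("failed flag must mirror absence of doy")


class DailyTemperatureSeries:
    """Contiguous daily mean air temperature (degC) for one site."""

    __slots__ = ("site_id", "dates", "values")

    def __init__(self, site_id: str, dates: pd.DatetimeIndex, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if len(dates) != len(values):
            raise ValueError("dates and values length mismatch")
        if len(dates) > 1:
            step = np.diff(dates.values.astype("datetime64[D]").astype(int))
            if (step != 1).any():
                bad = int(np.argmax(step != 1))
                raise ValueError(
                    f"series for {site_id!r} is not daily-contiguous after "
                    f"{dates[bad].date()}"
                )
        self.site_id = site_id
        self.dates = dates
        self.values = values

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_frame(cls, site_id: str, frame: pd.DataFrame) -> "DailyTemperatureSeries":
        frame = frame.sort_values("date")
        idx = pd.DatetimeIndex(pd.to_datetime(frame["date"]))
        return cls(site_id, idx, frame["tmean_c"].to_numpy(float))

    def window(self, start: _dt.date, end: _dt.date) -> np.ndarray:
        """Values from ``start`` through ``end`` inclusive; raises if the
        series does not cover the window (naming the gap)."""
        start_ts, end_ts = pd.Timestamp(start), pd.Timestamp(end)
        if len(self) == 0 or self.dates[0] > start_ts or self.dates[-1] < end_ts:
            raise ValueError(
                f"series for {self.site_id!r} does not cover "
                f"{start_ts.date()}..{end_ts.date()} "
                f"(has {self.dates[0].date() if len(self) else '-'}.."
                f"{self.dates[-1].date() if len(self) else '-'})"
            )
        i0 = int((start_ts - self.dates[0]).days)
        i1 = int((end_ts - self.dates[0]).days)
        return self.values[i0 : i1 + 1]

    def shifted(self, delta_c: float) -> "DailyTemperatureSeries":
        return DailyTemperatureSeries(self.site_id, self.dates, self.values + delta_c)


@dataclass(frozen=True)
class ModelParameterSet:
    """Tagged parameter set for one model class.

    Parameters are stored by name; :meth:`to_vector` / :meth:`from_vector`
    give the canonical ordering used by the sampler and the kernels.
    """

    model: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.model not in MODEL_PARAM_NAMES:
            raise ValueError(f"unknown model tag {self.model!r}")
        names = MODEL_PARAM_NAMES[self.model]
        missing = set(names) - set(self.values)
        extra = set(self.values) - set(names)
        if missing or extra:
            raise ValueError(
                f"{self.model} parameters must be exactly {names}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        if self.model in ("ALT", "UNI"):
            if self.values["beta"] <= 0 or self.values["gamma"] < 0:
                raise ValueError("require beta > 0 and gamma >= 0")
        if self.model == "SEQ":
            if not SEQ_FIXED["Tmin"] < self.values["Topt"] <= SEQ_FIXED["Tmax"]:
                raise ValueError("require Tmin < Topt <= Tmax for SEQ")

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:  # pragma: no cover - attribute protocol
            raise AttributeError(name) from None

    def to_vector(self) -> np.ndarray:
        return np.array([self.values[n] for n in MODEL_PARAM_NAMES[self.model]], float)

    @classmethod
    def from_vector(cls, model: str, vector: Sequence[float]) -> "ModelParameterSet":
        names = MODEL_PARAM_NAMES[model]
        if len(vector) != len(names):
            raise ValueError(f"{model} expects {len(names)} parameters")
        return cls(model, dict(zip(names, (float(v) for v in vector))))


@dataclass(frozen=True)
class ForcingTrajectory:
    """Accumulated forcing Sf(t) on the day axis t = 1..len(sf), 1 = Jan 1."""

    model: str
    start_day: int
    sf: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.sf) < -1e-12).any() or (self.sf < -1e-12).any():
            raise ValueError("forcing must be non-negative and non-decreasing")


@dataclass(frozen=True)
class ChillingTrajectory:
    """Accumulated chilling Sc(t) on the day axis t = 1..len(sc); the value at
    t = 1 already includes autumn accumulation from the start day t2."""

    model: str
    t2: int
    sc: np.ndarray

    def __post_init__(self) -> None:
        if (np.diff(self.sc) < -1e-12).any() or (self.sc < -1e-12).any():
            raise ValueError("chilling must be non-negative and non-decreasing")


# ---------------------------------------------------------------------------
# calendar helpers
# ---------------------------------------------------------------------------


def cutoff_doy(year: int, cutoff: _dt.date | None = None) -> int:
    """Day-of-year of the failure cutoff (August 1 unless overridden)."""
    if cutoff is None:
        cutoff = _dt.date(year, 8, 1)
    return cutoff.timetuple().tm_yday


def season_values(series: DailyTemperatureSeries, year: int) -> np.ndarray:
    """Daily temperatures from Oct 1 of ``year - 1`` through Aug 1 of
    ``year``; column ``JAN1_COL`` (= 92) is January 1, column ``91 + d`` is
    day-of-year ``d``."""
    return series.window(_dt.date(year - 1, 10, 1), _dt.date(year, 8, 1))


def day_length(latitude: float, doy) -> np.ndarray | float:
    """Astronomical day length in hours.

    Uses the standard solar-declination approximation
    ``delta = -23.44 deg * cos(2*pi*(doy + 10)/365)`` with the sunset
    hour-angle argument clamped to [-1, 1], so polar day/night saturate at
    24 h / 0 h.
    """
    if np.any(np.abs(latitude) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    doy = np.asarray(doy, dtype=float)
    decl = np.deg2rad(-23.44 * np.cos(2.0 * np.pi * (doy + 10.0) / 365.0))
    cos_h = np.clip(-np.tan(np.deg2rad(latitude)) * np.tan(decl), -1.0, 1.0)
    dl = 24.0 / np.pi * np.arccos(cos_h)
    return float(dl) if dl.ndim == 0 else dl


def mean_temperature_window(series: DailyTemperatureSeries, year: int) -> float:
    """Arithmetic mean of daily temperature over Feb 1 .. Apr 30 (Feb 29
    included in leap years)."""
    vals = series.window(_dt.date(year, 2, 1), _dt.date(year, 4, 30))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------


def _sigmoid_forcing(temp: np.ndarray, b: float, c: float) -> np.ndarray:
    # logistic response in temperature; b < 0 makes it increase with warmth
    return 1.0 / (1.0 + np.exp(np.clip(b * (temp + c), -500.0, 500.0)))


def _gdd(temp: np.ndarray, tb: float) -> np.ndarray:
    return np.maximum(temp - tb, 0.0)


def _seq_chill_rate(temp: np.ndarray, topt: float) -> np.ndarray:
    """Triangular chilling efficiency: zero outside (Tmin, Tmax], rising
    linearly to 1 at Topt and falling back to zero at Tmax."""
    tmin, tmax = SEQ_FIXED["Tmin"], SEQ_FIXED["Tmax"]
    rate = np.zeros_like(temp)
    up = (temp > tmin) & (temp <= topt)
    rate[up] = (temp[up] - tmin) / (topt - tmin)
    down = (temp > topt) & (temp <= tmax)
    if topt < tmax:
        rate[down] = (temp[down] - tmax) / (topt - tmax)
    return rate


def _uni_chill_rate(temp: np.ndarray, ac: float, bc: float, oc: float) -> np.ndarray:
    dev = temp - oc
    return 1.0 / (1.0 + np.exp(np.clip(ac * dev * dev + bc * dev, -500.0, 500.0)))


def _start_day(params: ModelParameterSet) -> int:
    """Integer forcing start day (continuous t0 proposals are floored)."""
    if params.model in _T0_MODELS:
        return max(1, int(np.floor(params.t0)))
    return 1


def _t2_col(t2: float) -> int:
    """Season-window column of the chilling start day t2 (t2 = 1 is Jan 1,
    negative values reach into the preceding autumn; clamped to Oct 1)."""
    return max(0, JAN1_COL - 1 + int(np.floor(t2)))


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------


def accumulate_chilling(
    model_tag: str,
    params: ModelParameterSet,
    series: DailyTemperatureSeries,
    year: int,
) -> ChillingTrajectory:
    """Accumulated chilling Sc(t) for chilling-gated models.

    ALT counts days colder than the base temperature; SEQ weights days by the
    triangular efficiency; UNI uses a smooth bell around its optimum.
    """
    if model_tag not in _CHILLING_MODELS:
        raise ValueError(f"model {model_tag!r} has no chilling component")
    temps = season_values(series, year)
    n_days = len(temps) - JAN1_COL  # days Jan 1 .. Aug 1 inclusive
    t2 = SEQ_FIXED["t2"] if model_tag == "SEQ" else params.t2
    c0 = _t2_col(t2)
    if model_tag == "ALT":
        rate = (temps < params.Tb).astype(float)
    elif model_tag == "SEQ":
        rate = _seq_chill_rate(temps, params.Topt)
    else:
        rate = _uni_chill_rate(temps, params.ac, params.bc, params.oC)
    rate = rate.copy()
    rate[:c0] = 0.0
    sc_full = np.cumsum(rate)
    return ChillingTrajectory(model_tag, int(np.floor(t2)), sc_full[JAN1_COL : JAN1_COL + n_days])


def accumulate_forcing(
    model_tag: str,
    params: ModelParameterSet,
    series: DailyTemperatureSeries,
    site: SiteMeta | None,
    year: int,
) -> ForcingTrajectory:
    """Accumulated forcing Sf(t) on the day axis 1..cutoff for any
    temperature-sum model (``MT`` has no forcing trajectory)."""
    if model_tag == "MT" or model_tag not in MODEL_PARAM_NAMES:
        raise ValueError(f"no forcing trajectory for model {model_tag!r}")
    temps = season_values(series, year)
    spring = temps[JAN1_COL:]  # day t has index t-1
    start = _start_day(params)

    if model_tag in ("GDD1", "GDD_DOY", "ALT"):
        rate = _gdd(spring, params.Tb)
    elif model_tag == "SIG_DOY":
        rate = _sigmoid_forcing(spring, params.b, params.c)
    elif model_tag == "BC_DOY":
        if site is None:
            raise ValueError("BC_DOY requires site metadata (latitude)")
        dl = day_length(site.latitude, np.arange(1, len(spring) + 1))
        rate = _gdd(spring, params.Tb) * (dl / 10.0) ** params.EXPO
    elif model_tag == "SEQ":
        sc = accumulate_chilling("SEQ", params, series, year).sc
        gate = (spring >= params.Tb) & (sc >= params.Ccrit)
        rate = np.where(gate, _sigmoid_forcing(spring, params.b, params.c), 0.0)
    else:  # UNI
        sc = accumulate_chilling("UNI", params, series, year).sc
        rate = np.where(
            sc >= params.Ccrit,
            1.0 / (1.0 + np.exp(np.clip(params.dF * (spring - params.fF), -500.0, 500.0))),
            0.0,
        )
    rate = rate.copy()
    rate[: start - 1] = 0.0
    return ForcingTrajectory(model_tag, start, np.cumsum(rate))


def critical_forcing(model_tag: str, params: ModelParameterSet, sc_at_t) -> np.ndarray | float:
    """Critical forcing requirement; for ALT/UNI it decays exponentially with
    accumulated chilling, Fcrit = beta * exp(-gamma * Sc)."""
    if model_tag in ("ALT", "UNI"):
        return params.beta * np.exp(-params.gamma * np.asarray(sc_at_t, float))
    return params.Fcrit


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_mt(
    params: ModelParameterSet,
    series: DailyTemperatureSeries,
    year: int,
    cutoff_date: _dt.date | None = None,
) -> BudburstPrediction:
    """Empirical regression model: round(I + k * mean Feb-Apr temperature)."""
    tbar = mean_temperature_window(series, year)
    doy = int(np.floor(params.I + params.k * tbar + 0.5))
    cut = cutoff_doy(year, cutoff_date)
    if doy >= cut:
        return BudburstPrediction(None, True)
    if doy < 1:
        return BudburstPrediction(None, True, degenerate=True)
    return BudburstPrediction(doy, False)


def predict_budburst(
    model_tag: str,
    params: ModelParameterSet,
    series: DailyTemperatureSeries,
    site: SiteMeta | None,
    year: int,
    cutoff_date: _dt.date | None = None,
) -> BudburstPrediction:
    """Budburst = first day whose end-of-day accumulated forcing meets the
    (possibly chilling-dependent) critical requirement, strictly before the
    cutoff date; otherwise a flagged failure."""
    if model_tag == "MT":
        return predict_mt(params, series, year, cutoff_date)
    if model_tag not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown model tag {model_tag!r}")
    traj = accumulate_forcing(model_tag, params, series, site, year)
    cut = cutoff_doy(year, cutoff_date)
    sf = traj.sf[: cut - 1]  # candidate days 1 .. cutoff-1
    if model_tag in ("ALT", "UNI"):
        sc = accumulate_chilling(model_tag, params, series, year).sc[: cut - 1]
        fcrit = critical_forcing(model_tag, params, sc)
    else:
        fcrit = np.full_like(sf, critical_forcing(model_tag, params, 0.0))
    ok = sf >= fcrit
    ok[: traj.start_day - 1] = False
    hits = np.nonzero(ok)[0]
    if hits.size == 0:
        return BudburstPrediction(None, True)
    day = int(hits[0]) + 1
    return BudburstPrediction(day, False, forcing_at_event=float(traj.sf[day - 1]))
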