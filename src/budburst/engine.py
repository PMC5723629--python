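"""Vectorized prediction over tables of site-years.

Calibration evaluates the likelihood tens of thousands of times, and the
projection ensemble predicts hundreds of parameter draws over many
site-years, so temperatures are packed once into a dense array (rows =
site-years, columns = days from October 1 of the preceding year through
August 1) and the compiled kernels in :mod:`budburst._kernels` scan it.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _kernels
from .models import (
    JAN1_COL,
    MODEL_PARAM_NAMES,
    DailyTemperatureSeries,
    ModelParameterSet,
    SiteMeta,
    cutoff_doy,
    day_length,
)

__all__ = ["PredictorTable", "predict_table"]

_WIDTH = JAN1_COL + 214  # Oct 1 .. Aug 1 of a leap year


@dataclass
class PredictorTable:
    """Season-window temperatures for a set of (site, year) rows."""

    site_ids: list[str]
    years: np.ndarray  # int, per row
    temps: np.ndarray  # float64 (n_rows, width), col 92 = Jan 1
    cutoff: np.ndarray  # int32 day-of-year of the cutoff, per row
    latitudes: np.ndarray  # float, per row
    _dl: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def build(
        cls,
        site_years: Sequence[tuple[str, int]],
        series_by_site: Mapping[str, DailyTemperatureSeries],
        sites: Mapping[str, SiteMeta],
        cutoff_date: _dt.date | None = None,
    ) -> "PredictorTable":
        n = len(site_years)
        temps = np.full((n, _WIDTH), np.nan)
        cut = np.empty(n, np.int32)
        lats = np.empty(n, float)
        ids: list[str] = []
        years = np.empty(n, int)
        for i, (sid, year) in enumerate(site_years):
            vals = series_by_site[sid].window(
                _dt.date(year - 1, 10, 1), _dt.date(year, 8, 1)
            )
            temps[i, : len(vals)] = vals
            cut[i] = cutoff_doy(
                year, None if cutoff_date is None else cutoff_date.replace(year=year)
            )
            lats[i] = sites[sid].latitude
            ids.append(sid)
            years[i] = year
        return cls(ids, years, temps, cut, lats)

    def __len__(self) -> int:
        return self.temps.shape[0]

    @property
    def day_lengths(self) -> np.ndarray:
        """Day length (h) aligned with the temperature columns (lazy)."""
        if self._dl is None:
            dl = np.zeros_like(self.temps)
            doys = np.arange(1, _WIDTH - JAN1_COL + 1, dtype=float)
            for lat in np.unique(self.latitudes):
                rows = self.latitudes == lat
                dl[rows, JAN1_COL:] = day_length(float(lat), doys)
            self._dl = dl
        return self._dl


def _t2col(t2: float) -> int:
    return max(0, JAN1_COL - 1 + int(np.floor(t2)))


def predict_table(model: str, theta: np.ndarray | ModelParameterSet, table: PredictorTable) -> np.ndarray:
    """Predict budburst day-of-year for every row of ``table`` (-1 = failed).

    ``theta`` is a parameter vector in the canonical order of
    ``MODEL_PARAM_NAMES[model]`` (or a :class:`ModelParameterSet`).
    Continuous proposals for the integer day parameters t0/t2 are floored.
    """
    if isinstance(theta, ModelParameterSet):
        if theta.model != model:
            raise ValueError("parameter set tagged for a different model")
        theta = theta.to_vector()
    theta = np.asarray(theta, float)
    if theta.shape != (len(MODEL_PARAM_NAMES[model]),):
        raise ValueError(f"{model} expects {len(MODEL_PARAM_NAMES[model])} parameters")
    t, c = table.temps, table.cutoff
    if model == "MT":
        return _kernels.predict_mt(t, c, theta[0], theta[1])
    if model == "GDD1":
        return _kernels.predict_gdd(t, c, 1, theta[0], theta[1])
    if model == "GDD_DOY":
        return _kernels.predict_gdd(t, c, max(1, int(np.floor(theta[0]))), theta[1], theta[2])
    if model == "SIG_DOY":
        return _kernels.predict_sig(t, c, max(1, int(np.floor(theta[0]))), theta[1], theta[2], theta[3])
    if model == "BC_DOY":
        return _kernels.predict_bc(
            t, table.day_lengths, c, max(1, int(np.floor(theta[0]))), theta[1], theta[2], theta[3]
        )
    if model == "ALT":
        return _kernels.predict_alt(t, c, _t2col(theta[0]), theta[1], theta[2], theta[3])
    if model == "SEQ":
        return _kernels.predict_seq(t, c, theta[0], theta[1], theta[2], theta[3], theta[4], theta[5])
    if model == "UNI":
        return _kernels.predict_uni(
            t, c, _t2col(theta[0]), theta[1], theta[2], theta[3], theta[4],
            theta[5], theta[6], theta[7], theta[8],
        )
    raise ValueError(f"unknown model tag {model!r}")
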