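"""Readers and writers for the pipeline's tables and grids.

All tables are UTF-8 CSV with a header row; dates are ISO-8601; day-of-year
is always derived from dates, never stored ambiguously.  Gridded daily
temperature can be read from NetCDF (dims time, y, x) with sites mapped to
the nearest cell center.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import BudburstObservation, DailyTemperatureSeries, SiteMeta

__all__ = [
    "read_sites",
    "write_sites",
    "read_observations",
    "write_observations",
    "read_temperature",
    "write_temperature",
    "read_posterior_samples",
    "write_posterior_samples",
]

_SITE_COLS = ["site_id", "latitude", "longitude", "site_altitude", "grid_altitude"]
_OBS_COLS = ["site_id", "provenance", "year", "doy"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def read_sites(path: str | Path) -> dict[str, SiteMeta]:
    df = pd.read_csv(path)
    missing = set(_SITE_COLS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    sites = {}
    for _, row in df.iterrows():
        sites[str(row.site_id)] = SiteMeta(
            str(row.site_id),
            float(row.latitude),
            float(row.longitude),
            float(row.site_altitude),
            float(row.grid_altitude),
        )
    return sites


def write_sites(sites: Iterable[SiteMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.site_id, s.latitude, s.longitude, s.site_altitude, s.grid_altitude)
            for s in sites
        ],
        columns=_SITE_COLS,
    ).to_csv(path, index=False)


def read_observations(path: str | Path) -> list[BudburstObservation]:
    """Budburst records from CSV (site_id, provenance, year, doy).

    Malformed rows raise with their line number; duplicate
    (site, provenance, year) keys are an error.
    """
    df = pd.read_csv(path, dtype=str)
    missing = set(_OBS_COLS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                BudburstObservation(
                    str(row.site_id), str(row.provenance), int(row.year), int(row.doy)
                )
            )
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path}: line {i}: {exc}") from exc
    keys = [(o.site_id, o.provenance_id, o.year) for o in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise DataError(f"{path}: duplicate (site, provenance, year) records: {dupes[:5]}")
    return records


def write_observations(observations: Iterable[BudburstObservation], path: str | Path) -> None:
    pd.DataFrame(
        [(o.site_id, o.provenance_id, o.year, o.doy) for o in observations],
        columns=_OBS_COLS,
    ).to_csv(path, index=False)


def _series_from_long(df: pd.DataFrame, source: str) -> dict[str, DailyTemperatureSeries]:
    out = {}
    for sid, sub in df.groupby("site_id", sort=True):
        try:
            out[str(sid)] = DailyTemperatureSeries.from_frame(str(sid), sub)
        except ValueError as exc:
            raise DataError(f"{source}: {exc}") from exc
    return out


def read_temperature(
    path: str | Path,
    sites: Mapping[str, SiteMeta] | None = None,
    variable: str = "tmean_c",
) -> dict[str, DailyTemperatureSeries]:
    """Per-site daily mean temperature from long CSV or a NetCDF grid.

    CSV needs columns (site_id, date, tmean_c).  NetCDF needs dims
    (time, y, x) with 1-D coordinates ``lat`` and ``lon`` and a daily time
    axis; ``sites`` is then required and each site is mapped to the nearest
    cell center.  Gaps in a site's series raise naming the missing date.
    """
    path = Path(path)
    if path.suffix in (".nc", ".nc4", ".cdf"):
        import xarray as xr

        if sites is None:
            raise DataError("NetCDF input requires site metadata for grid mapping")
        ds = xr.open_dataset(path, engine="scipy")
        if variable not in ds:
            raise DataError(f"{path}: variable {variable!r} not found")
        times = pd.DatetimeIndex(ds["time"].values)
        step = np.diff(times.values.astype("datetime64[D]").astype(int))
        if len(step) and (step != 1).any():
            raise DataError(f"{path}: time axis is not daily")
        out = {}
        for sid, meta in sites.items():
            cell = ds[variable].sel(
                lat=meta.latitude, lon=meta.longitude, method="nearest"
            )
            out[sid] = DailyTemperatureSeries(sid, times, cell.values.astype(float))
        ds.close()
        return out
    df = pd.read_csv(path)
    missing = {"site_id", "date", "tmean_c"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    return _series_from_long(df, str(path))


def write_temperature(
    series_by_site: Mapping[str, DailyTemperatureSeries], path: str | Path
) -> None:
    frames = [
        pd.DataFrame(
            {
                "site_id": sid,
                "date": s.dates.strftime("%Y-%m-%d"),
                "tmean_c": np.round(s.values, 6),
            }
        )
        for sid, s in series_by_site.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_posterior_samples(
    samples_by_chain: Sequence[np.ndarray],
    chain_ids: Sequence[int],
    param_names: Sequence[str],
    path: str | Path,
) -> None:
    frames = []
    for cid, samples in zip(chain_ids, samples_by_chain):
        df = pd.DataFrame(samples, columns=list(param_names))
        df.insert(0, "chain", cid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_posterior_samples(path: str | Path) -> tuple[list[np.ndarray], list[int], list[str]]:
    df = pd.read_csv(path)
    param_names = [c for c in df.columns if c != "chain"]
    chains, ids = [], []
    for cid, sub in df.groupby("chain", sort=True):
        ids.append(int(cid))
        chains.append(sub[param_names].to_numpy(float))
    return chains, ids, param_names
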