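"""Projection ensembles over initial conditions, model classes, parameter
draws, and boundary conditions.

The joint posterior of each calibrated model is sampled ``n*100 + M`` times
(n = number of model parameters, M = number of distinct local posterior
modes): each mode receives ``floor(n*100/M) + 1`` draws, so every local mode
contributes at least one sample, and modes are topped up in index order to
hit the total exactly.  The draws are run against every boundary-condition
dataset for every requested site and year, and the predictions are
aggregated into empirical CDFs per grouping and time period.  Failed
simulations are excluded from CDFs and means but tallied in failure tables:
rising failure frequency then shows up as an apparent drop in variability,
which is a real property of this ensemble design and is deliberately not
masked.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import PosteriorSet, ks_chain_consistency
from .engine import PredictorTable, predict_table
from .models import DailyTemperatureSeries, SiteMeta

__all__ = [
    "STANDARD_LAPSE_RATE",
    "SamplingPlan",
    "identify_modes",
    "build_sampling_plan",
    "draw_projection_samples",
    "elevation_adjust",
    "EnsembleMember",
    "project_ensemble",
    "failure_rate",
    "CDFSummary",
    "period_aggregate",
]

logger = logging.getLogger(__name__)

#: Global standard temperature lapse rate (degC per km of elevation).
STANDARD_LAPSE_RATE = 6.4

ENSEMBLE_COLUMNS = ["provenance", "ic", "mc", "sample_id", "bc", "site_id", "year", "doy", "failed"]


# ---------------------------------------------------------------------------
# posterior modes and the sampling plan
# ---------------------------------------------------------------------------


def identify_modes(posterior: PosteriorSet, alpha: float = 0.05) -> tuple[np.ndarray, int]:
    """Group kept chains into local posterior modes.

    Two chains share a mode iff every parameter passes a pairwise two-sample
    KS test at ``alpha``; modes are the connected components of that
    agreement graph, labelled 0..M-1 in order of their lowest chain index.
    Deterministic given the samples.  Also stored on ``posterior``.
    """
    k = len(posterior.chain_samples)
    adj = np.eye(k, dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        passes, _ = ks_chain_consistency(
            posterior.chain_samples[i], posterior.chain_samples[j], alpha
        )
        adj[i, j] = adj[j, i] = bool(np.all(passes))
    labels = np.full(k, -1, int)
    mode = 0
    for i in range(k):
        if labels[i] >= 0:
            continue
        stack = [i]
        while stack:
            u = stack.pop()
            if labels[u] >= 0:
                continue
            labels[u] = mode
            stack.extend(v for v in range(k) if adj[u, v] and labels[v] < 0)
        mode += 1
    posterior.mode_labels = labels
    return labels, mode


@dataclass(frozen=True)
class SamplingPlan:
    """Per-mode allocation of posterior draws totalling ``n*100 + M``."""

    n: int
    m: int
    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if sum(self.counts) != self.total or any(c < 1 for c in self.counts):
            raise ValueError("per-mode counts must be >= 1 and sum to n*100 + M")

    @property
    def total(self) -> int:
        return self.n * 100 + self.m


def build_sampling_plan(n_params: int, n_modes: int) -> SamplingPlan:
    """Allocate ``floor(n*100/M) + 1`` draws per mode, topping modes up in
    index order until the total is exactly ``n*100 + M``."""
    if n_params < 1 or n_modes < 1:
        raise ValueError("need n_params >= 1 and n_modes >= 1")
    base = n_params * 100 // n_modes + 1
    counts = [base] * n_modes
    deficit = n_params * 100 + n_modes - base * n_modes
    for i in range(deficit):
        counts[i] += 1
    return SamplingPlan(n_params, n_modes, tuple(counts))


def draw_projection_samples(
    posterior: PosteriorSet, seed: int, alpha: float = 0.05
) -> tuple[np.ndarray, SamplingPlan]:
    """Draw the projection parameter sets from the thinned posterior.

    Within each mode, draws are uniform over the mode's retained samples,
    with replacement only when the mode holds fewer samples than its
    allocation.  Returns ``(draws, plan)`` with draws of shape (total, d).
    """
    if posterior.mode_labels is None:
        identify_modes(posterior, alpha)
    labels = posterior.mode_labels
    m = int(labels.max()) + 1
    plan = build_sampling_plan(posterior.n_params, m)
    rng = np.random.default_rng(seed)
    parts = []
    for mode, count in enumerate(plan.counts):
        pool = np.vstack(
            [s for s, lab in zip(posterior.chain_samples, labels) if lab == mode]
        )
        if len(pool) == 0:
            raise ValueError(f"mode {mode} has no retained samples")
        idx = rng.choice(len(pool), size=count, replace=len(pool) < count)
        parts.append(pool[idx])
    return np.vstack(parts), plan


# ---------------------------------------------------------------------------
# elevation adjustment
# ---------------------------------------------------------------------------


def elevation_adjust(
    series: DailyTemperatureSeries,
    alt_diff_m: float,
    lapse_rate: float = STANDARD_LAPSE_RATE,
) -> DailyTemperatureSeries:
    """Adjust grid-cell temperatures to site elevation.

    ``alt_diff_m`` is grid-cell altitude minus site altitude (m, signed); a
    site below its grid cell is warmed by ``lapse_rate`` degC per km.
    """
    return series.shifted(lapse_rate * alt_diff_m / 1000.0)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleMember:
    """One calibrated (provenance, IC, model) with its parameter draws."""

    provenance: str
    ic: str
    model: str
    draws: np.ndarray  # (n_samples, d)
    plan: SamplingPlan | None = None


def project_ensemble(
    members: Sequence[EnsembleMember],
    bc_datasets: Mapping[str, Mapping[str, DailyTemperatureSeries]],
    sites: Mapping[str, SiteMeta],
    years: Sequence[int],
    cutoff_date: _dt.date | None = None,
) -> pd.DataFrame:
    """Predict budburst for every (member, sample, BC, site, year).

    Boundary-condition series are used as-is at grid level (no elevation
    adjustment); site-years a dataset does not cover are skipped with a log
    entry.  Returns a long-format frame with one row per prediction, failed
    predictions flagged rather than dropped.
    """
    frames = []
    for bc_label, dataset in bc_datasets.items():
        site_years = []
        for sid, year in itertools.product(dataset, years):
            try:
                dataset[sid].window(_dt.date(year - 1, 10, 1), _dt.date(year, 8, 1))
            except ValueError:
                logger.warning("BC %s: no coverage for site %s year %d; skipped", bc_label, sid, year)
                continue
            site_years.append((sid, year))
        if not site_years:
            continue
        table = PredictorTable.build(site_years, dataset, sites, cutoff_date)
        sids = np.array(table.site_ids)
        yrs = table.years
        for member in members:
            preds = np.vstack(
                [predict_table(member.model, theta, table) for theta in member.draws]
            )
            s, r = preds.shape
            frames.append(
                pd.DataFrame(
                    {
                        "provenance": member.provenance,
                        "ic": member.ic,
                        "mc": member.model,
                        "sample_id": np.repeat(np.arange(s), r),
                        "bc": bc_label,
                        "site_id": np.tile(sids, s),
                        "year": np.tile(yrs, s),
                        "doy": preds.ravel(),
                        "failed": preds.ravel() < 0,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=ENSEMBLE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    for col in ("provenance", "ic", "mc", "bc", "site_id"):
        out[col] = out[col].astype("category")
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def failure_rate(ensemble: pd.DataFrame, grouping: Sequence[str]) -> pd.DataFrame:
    """Percent of predictions that failed, per group, to two decimals."""
    grouping = list(grouping)
    for key in grouping:
        if key not in ensemble.columns:
            raise KeyError(f"grouping key {key!r} not in ensemble")
    g = ensemble.groupby(grouping, observed=True)["failed"]
    out = g.agg(n="size", n_failed="sum").reset_index()
    out["failure_pct"] = (100.0 * out["n_failed"] / out["n"]).round(2)
    return out


@dataclass(frozen=True)
class CDFSummary:
    """Empirical CDF of non-failed budburst days for one group."""

    key: Mapping[str, object]
    values: np.ndarray  # sorted, failures excluded
    cdf: np.ndarray
    mean: float
    n_failed: int

    @classmethod
    def from_predictions(cls, key: Mapping[str, object], doy: np.ndarray, failed: np.ndarray) -> "CDFSummary":
        ok = np.sort(np.asarray(doy)[~np.asarray(failed, bool)]).astype(float)
        cdf = np.arange(1, len(ok) + 1) / len(ok) if len(ok) else np.empty(0)
        mean = float(np.mean(ok)) if len(ok) else float("nan")
        return cls(dict(key), ok, cdf, mean, int(np.sum(failed)))


def period_aggregate(
    ensemble: pd.DataFrame,
    periods: Mapping[str, tuple[int, int]],
    grouping: Sequence[str] = (),
) -> tuple[list[CDFSummary], pd.DataFrame]:
    """Aggregate predictions into per-period CDFs and period-mean deltas.

    Period membership is by budburst calendar year (bounds inclusive).
    Returns the CDF summaries and a frame with one row per group carrying
    each period's mean and the deltas of later periods against the first.
    """
    grouping = list(grouping)
    names = list(periods)
    summaries: list[CDFSummary] = []
    rows = []
    if grouping:
        grouped = ensemble.groupby(grouping, observed=True)
    else:
        grouped = [((), ensemble)]
    for gkey, sub in grouped:
        if not isinstance(gkey, tuple):
            gkey = (gkey,)
        row: dict[str, object] = dict(zip(grouping, gkey))
        for pname in names:
            y0, y1 = periods[pname]
            psub = sub[(sub["year"] >= y0) & (sub["year"] <= y1)]
            summ = CDFSummary.from_predictions(
                {**dict(zip(grouping, gkey)), "period": pname},
                psub["doy"].to_numpy(),
                psub["failed"].to_numpy(),
            )
            summaries.append(summ)
            row[f"mean_{pname}"] = summ.mean
            row[f"n_{pname}"] = len(summ.values)
            row[f"failed_{pname}"] = summ.n_failed
        base = names[0]
        for pname in names[1:]:
            row[f"delta_{pname}_{base}"] = row[f"mean_{pname}"] - row[f"mean_{base}"]
        rows.append(row)
    return summaries, pd.DataFrame(rows)
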