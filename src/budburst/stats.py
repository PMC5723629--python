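"""Rank-based comparison of projection distributions and fit diagnostics.

Empirical CDFs of budburst day are compared with the Kruskal-Wallis (KW)
rank test; the mean-rank difference between two groups measures the area
between their CDFs.  For comparisons across groups of unequal size the
statistic is standardized by the width of a bootstrap 95% confidence
interval of the mean-rank difference.  Post hoc pairwise comparisons use
two-group KW tests with a Bonferroni-corrected significance threshold and
report which group buds earlier (smaller mean rank).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sstats

__all__ = [
    "KWResult",
    "kruskal_wallis",
    "standardized_kw",
    "pairwise_posthoc",
    "FitStats",
    "fit_statistics",
    "spatial_variation_trend",
    "detect_outliers_30day",
    "spearman_rank",
]


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KWResult:
    h: float
    df: int
    pvalue: float
    mean_ranks: np.ndarray
    group_sizes: np.ndarray
    labels: tuple

    @property
    def pairwise_mean_rank_diff(self) -> np.ndarray:
        return self.mean_ranks[:, None] - self.mean_ranks[None, :]


def _as_groups(groups) -> tuple[list[np.ndarray], tuple]:
    if isinstance(groups, Mapping):
        labels = tuple(groups)
        arrays = [np.asarray(groups[k], float) for k in labels]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        labels = tuple(range(len(arrays)))
    return arrays, labels


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H with per-group mean rank sums.

    ``groups`` is a sequence of samples or a mapping label -> sample.  The
    p-value uses the chi-square approximation with g - 1 degrees of freedom.
    """
    arrays, labels = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([len(a) for a in arrays])
    if (sizes == 0).any():
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = _sstats.rankdata(pooled)
    bounds = np.cumsum(sizes)
    rank_sums = np.array(
        [ranks[lo:hi].sum() for lo, hi in zip(np.r_[0, bounds[:-1]], bounds)]
    )
    h = 12.0 / (n * (n + 1)) * np.sum(rank_sums**2 / sizes) - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if tie_term > 0:
        h /= tie_term
    else:
        h = 0.0  # all observations tied
    df = len(arrays) - 1
    return KWResult(
        float(h), df, float(_sstats.chi2.sf(h, df)), rank_sums / sizes, sizes, labels
    )


def _mean_rank_diff(a: np.ndarray, b: np.ndarray) -> float:
    ranks = _sstats.rankdata(np.concatenate([a, b]))
    return float(ranks[: len(a)].mean() - ranks[len(a) :].mean())


def standardized_kw(
    group_a,
    group_b,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Mean-rank difference standardized by its bootstrap 95% CI width.

    ``|mean rank(a) - mean rank(b)|`` divided by the width of the percentile
    bootstrap 95% confidence interval of that difference (both groups
    resampled with replacement, ``n_boot`` replicates, seeded).  Degenerate
    all-tied data yields 0.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    observed = _mean_rank_diff(a, b)
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = _mean_rank_diff(
            a[rng.integers(0, len(a), len(a))], b[rng.integers(0, len(b), len(b))]
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    width = hi - lo
    if width == 0.0:
        return float("inf") if observed else 0.0
    return abs(observed) / width


def pairwise_posthoc(groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise two-group KW tests with a Bonferroni threshold.

    Returns one row per pair: H, p, significance at ``alpha / n_pairs``, and
    the direction (label of the group with the smaller mean rank, i.e. the
    earlier distribution) when significant.
    """
    arrays, labels = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    threshold = alpha / len(pairs)
    rows = []
    for i, j in pairs:
        res = kruskal_wallis([arrays[i], arrays[j]])
        significant = bool(res.pvalue < threshold)
        direction = None
        if significant:
            direction = labels[i] if res.mean_ranks[0] < res.mean_ranks[1] else labels[j]
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "h": res.h,
                "p": res.pvalue,
                "alpha_adjusted": threshold,
                "significant": significant,
                "earlier": direction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitStats:
    adj_r2: float
    aicc: float
    rmse: float
    bias: float
    n: int
    k: int


def fit_statistics(observed, predicted, k: int) -> FitStats:
    """Goodness-of-fit of predictions against observations.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - k - 1) with R^2 measured about the
    observed mean; AICc = n ln(SSE/n) + 2k + 2k(k+1)/(n - k - 1); RMSE in
    days; bias = mean(predicted - observed).
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    n = len(obs)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    resid = pred - obs
    sse = float(resid @ resid)
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sstot if sstot > 0 else float("nan")
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    with np.errstate(divide="ignore"):
        aicc = n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    return FitStats(
        float(adj_r2), float(aicc), float(np.sqrt(sse / n)), float(resid.mean()), n, k
    )


def spatial_variation_trend(annual_means, annual_sds) -> tuple[float, float, float]:
    """OLS fit of across-site SD on across-site mean, one point per year.

    Returns (slope, intercept, slope p-value); used to ask whether spatial
    variation in budburst grows as budburst shifts earlier.
    """
    x = np.asarray(annual_means, float)
    y = np.asarray(annual_sds, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired annual values")
    if np.ptp(x) == 0.0:
        raise ValueError("constant predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return float(model.params[1]), float(model.params[0]), float(model.pvalues[1])


# ---------------------------------------------------------------------------
# observation screening and diagnostics
# ---------------------------------------------------------------------------


def detect_outliers_30day(observations: pd.DataFrame, threshold: float = 30.0) -> pd.Series:
    """Flag records deviating more than 30 days from an additive model.

    An additive site-effect + year-effect model is fit robustly by Tukey
    median polish (so a genuine outlier is not absorbed into the effects it
    helps estimate); records with |residual| > ``threshold`` are flagged.
    Flagged records are reported, not removed.  ``observations`` needs
    columns site_id, year, doy.
    """
    df = observations
    if df["site_id"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need at least two sites and two years")
    resid = df["doy"].astype(float).copy()
    for _ in range(20):
        step = 0.0
        for key in (None, "site_id", "year"):
            med = resid.median() if key is None else resid.groupby(df[key]).transform("median")
            resid = resid - med
            step = max(step, float(np.abs(np.asarray(med)).max()))
        if step < 1e-9:
            break
    return pd.Series(np.abs(resid) > threshold, index=df.index, name="outlier")


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation with tie handling and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length vectors of length >= 4")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("rank correlation undefined for a constant vector")
    rs, p = _sstats.spearmanr(x, y)
    return float(rs), float(p)
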