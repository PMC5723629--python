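"""Numba kernels: per-observation budburst prediction for whole tables.

Each kernel scans day by day with early exit, mirroring the per-series
reference implementations in :mod:`budburst.models` (tests assert exact
agreement).  Array layout: ``temps[row, col]`` with column 92 = January 1 of
the budburst year (the window starts October 1 of the preceding year), and
``cutoff[row]`` the day-of-year of the failure cutoff.  Predictions are
1-based day of year, or -1 for failure.
"""

from __future__ import annotations

import numpy as np
from numba import njit

JAN1 = 92
SEQ_TMIN = -3.4
SEQ_TMAX = 10.4


@njit(cache=False)
def _clip_exp(x):
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return np.exp(x)


@njit(cache=False)
def predict_mt(temps, cutoff, intercept, k):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    for i in range(n):
        ndays = 90 if cutoff[i] == 214 else 89  # Feb 1 .. Apr 30
        s = 0.0
        for c in range(JAN1 + 31, JAN1 + 31 + ndays):
            s += temps[i, c]
        doy = int(np.floor(intercept + k * (s / ndays) + 0.5))
        out[i] = doy if 1 <= doy < cutoff[i] else -1
    return out


@njit(cache=False)
def predict_gdd(temps, cutoff, t0, tb, fcrit):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    start = t0 if t0 > 1 else 1
    for i in range(n):
        s = 0.0
        hit = -1
        for d in range(start, cutoff[i]):
            v = temps[i, JAN1 - 1 + d] - tb
            if v > 0.0:
                s += v
            if s >= fcrit:
                hit = d
                break
        out[i] = hit
    return out


@njit(cache=False)
def predict_sig(temps, cutoff, t0, b, c, fcrit):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    start = t0 if t0 > 1 else 1
    for i in range(n):
        s = 0.0
        hit = -1
        for d in range(start, cutoff[i]):
            s += 1.0 / (1.0 + _clip_exp(b * (temps[i, JAN1 - 1 + d] + c)))
            if s >= fcrit:
                hit = d
                break
        out[i] = hit
    return out


@njit(cache=False)
def predict_bc(temps, dl, cutoff, t0, tb, expo, fcrit):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    start = t0 if t0 > 1 else 1
    for i in range(n):
        s = 0.0
        hit = -1
        for d in range(start, cutoff[i]):
            col = JAN1 - 1 + d
            v = temps[i, col] - tb
            if v > 0.0:
                s += v * (dl[i, col] / 10.0) ** expo
            if s >= fcrit:
                hit = d
                break
        out[i] = hit
    return out


@njit(cache=False)
def predict_alt(temps, cutoff, t2col, tb, beta, gamma):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    for i in range(n):
        sc = 0.0
        for col in range(t2col, JAN1):  # preceding-autumn chilling days
            if temps[i, col] < tb:
                sc += 1.0
        s = 0.0
        hit = -1
        for d in range(1, cutoff[i]):
            col = JAN1 - 1 + d
            t = temps[i, col]
            if col >= t2col and t < tb:
                sc += 1.0
            v = t - tb
            if v > 0.0:
                s += v
            if s >= beta * np.exp(-gamma * sc):
                hit = d
                break
        out[i] = hit
    return out


@njit(cache=False)
def _seq_chill(t, topt):
    if t <= SEQ_TMIN or t > SEQ_TMAX:
        return 0.0
    if t <= topt:
        return (t - SEQ_TMIN) / (topt - SEQ_TMIN)
    return (t - SEQ_TMAX) / (topt - SEQ_TMAX)


@njit(cache=False)
def predict_seq(temps, cutoff, topt, tb, b, c, ccrit, fcrit):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    for i in range(n):
        sc = 0.0
        for col in range(0, JAN1):  # chilling starts October 1
            sc += _seq_chill(temps[i, col], topt)
        s = 0.0
        hit = -1
        for d in range(1, cutoff[i]):
            t = temps[i, JAN1 - 1 + d]
            sc += _seq_chill(t, topt)
            if t >= tb and sc >= ccrit:
                s += 1.0 / (1.0 + _clip_exp(b * (t + c)))
            if s >= fcrit:
                hit = d
                break
        out[i] = hit
    return out


@njit(cache=False)
def _uni_chill(t, ac, bc, oc):
    dev = t - oc
    return 1.0 / (1.0 + _clip_exp(ac * dev * dev + bc * dev))


@njit(cache=False)
def predict_uni(temps, cutoff, t2col, ac, bc, oc, df, ff, ccrit, beta, gamma):
    n = temps.shape[0]
    out = np.empty(n, np.int32)
    for i in range(n):
        sc = 0.0
        for col in range(t2col, JAN1):
            sc += _uni_chill(temps[i, col], ac, bc, oc)
        s = 0.0
        hit = -1
        for d in range(1, cutoff[i]):
            col = JAN1 - 1 + d
            t = temps[i, col]
            if col >= t2col:
                sc += _uni_chill(t, ac, bc, oc)
            if sc >= ccrit:
                s += 1.0 / (1.0 + _clip_exp(df * (t - ff)))
            if s >= beta * np.exp(-gamma * sc):
                hit = d
                break
        out[i] = hit
    return out
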