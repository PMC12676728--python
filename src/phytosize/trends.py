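"""Long-term trend estimation on monthly series.

Linear trends are OLS of the metric against lagged month, with two-sided
t-tests on the slope; families of tests are corrected with the
Benjamini-Hochberg step-up.  Seasonality (period 12) is removed with an
STL (LOESS-based seasonal-trend) decomposition; the de-seasoned trend is
the OLS fit to trend + residual, reported alongside the direct fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.seasonal import STL

from .size_metrics import SizeSeries


@dataclass
class TrendResult:
    slope_per_month: float
    slope_per_year: float
    intercept: float
    p: float
    r2: float
    n: int
    q: float | None = None
    exact_fit: bool = False


@dataclass
class DecompositionResult:
    """Additive components aligned to a complete monthly index.

    ``observed`` is the gap-filled input; ``interpolated`` flags months
    that were absent in the input and filled by linear interpolation
    before decomposition.  trend + seasonal + residual reconstructs the
    observed series exactly at every point.
    """

    index: np.ndarray          # lagged months, complete grid
    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    residual: np.ndarray
    period: int
    interpolated: np.ndarray   # boolean mask


def _series_xy(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, SizeSeries):
        t, y = series.t, series.y
    elif isinstance(series, pd.DataFrame):
        t, y = series["lagged_month"].to_numpy(), series["value"].to_numpy()
    else:
        t, y = series
        t, y = np.asarray(t, dtype=float), np.asarray(y, dtype=float)
    ok = np.isfinite(np.asarray(t, dtype=float)) & np.isfinite(np.asarray(y, dtype=float))
    return np.asarray(t, dtype=float)[ok], np.asarray(y, dtype=float)[ok]


def linear_trend(series, y=None) -> TrendResult:
    """OLS of value against lagged month with a two-sided slope t-test.

    Accepts a SizeSeries, a (lagged_month, value) DataFrame, or two arrays.
    A constant series returns slope 0 with p = 1 by convention; an exact
    non-constant fit returns p = 0 with the ``exact_fit`` flag set.
    """
    t, v = _series_xy(series if y is None else (series, y))
    n = len(t)
    if n < 3:
        raise ValueError(f"need >= 3 points, got {n}")
    if len(np.unique(t)) < 2:
        raise ValueError("need >= 2 distinct lagged_month values")
    tbar, vbar = t.mean(), v.mean()
    sxx = ((t - tbar) ** 2).sum()
    sxy = ((t - tbar) * (v - vbar)).sum()
    syy = ((v - vbar) ** 2).sum()
    if syy == 0.0:  # constant series
        return TrendResult(0.0, 0.0, float(vbar), 1.0, 0.0, n)
    slope = sxy / sxx
    intercept = vbar - slope * tbar
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy
    if ss_res <= max(syy, 1.0) * 1e-14:  # exact fit: zero residual variance
        return TrendResult(float(slope), float(12 * slope), float(intercept), 0.0, 1.0, n, exact_fit=True)
    se = np.sqrt(ss_res / (n - 2) / sxx)
    tstat = slope / se
    p = 2.0 * stats.t.sf(abs(tstat), n - 2)
    return TrendResult(float(slope), float(12 * slope), float(intercept), float(p), float(r2), n)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def stl_decompose(series, period: int = 12, robust: bool = False, seasonal: int = 13) -> DecompositionResult:
    """Seasonal-trend decomposition by LOESS with an annual period.

    Interior gaps in the monthly grid are linearly interpolated before
    decomposition and flagged afterwards.  Requires at least two full
    periods of data.
    """
    t, y = _series_xy(series)
    if len(t) == 0:
        raise ValueError("empty series")
    t = t.astype(int)
    full = np.arange(t.min(), t.max() + 1)
    if len(full) < 2 * period:
        raise ValueError(f"need >= {2 * period} months of span, got {len(full)}")
    obs = pd.Series(np.nan, index=full)
    obs.loc[t] = y
    interpolated = obs.isna().to_numpy()
    filled = obs.interpolate(method="linear", limit_direction="both")
    res = STL(filled.to_numpy(), period=period, seasonal=seasonal, robust=robust).fit()
    return DecompositionResult(
        index=full,
        observed=filled.to_numpy(),
        trend=res.trend,
        seasonal=res.seasonal,
        residual=res.resid,
        period=period,
        interpolated=interpolated,
    )


def deseasoned_trend(series, period: int = 12, on: str = "trend+residual", **stl_kwargs) -> TrendResult:
    """Linear trend of the seasonally adjusted series.

    By default the adjusted series is trend + residual (observed minus the
    seasonal component) evaluated at the originally observed months;
    ``on='trend'`` fits the smoothed trend component alone.
    """
    t, _ = _series_xy(series)
    dec = stl_decompose(series, period=period, **stl_kwargs)
    if on == "trend+residual":
        adj = dec.trend + dec.residual
    elif on == "trend":
        adj = dec.trend
    else:
        raise ValueError("on must be 'trend+residual' or 'trend'")
    keep = ~dec.interpolated
    return linear_trend(dec.index[keep].astype(float), adj[keep])


def classify_trend(tr: TrendResult, alpha: float = 0.05, use_q: bool = False) -> str:
    """Three-way significance label: 'decline', 'increase', or 'none'."""
    p = tr.q if use_q and tr.q is not None else tr.p
    if tr.slope_per_month < 0 and p < alpha:
        return "decline"
    if tr.slope_per_month > 0 and p < alpha:
        return "increase"
    return "none"


def annual_relative_change(tr: TrendResult) -> float:
    """Percent change per year relative to the fitted value at t = 0.

    Missing (NaN) when the fitted baseline is not positive.
    """
    if not tr.intercept > 0:
        return float("nan")
    return 100.0 * tr.slope_per_year / tr.intercept


def seasonally_adjust_table(
    table: pd.DataFrame, value_col: str, by: str = "station_id", period: int = 12,
) -> pd.DataFrame:
    """Seasonally adjust a monthly panel column group-by-group.

    Returns the input with an added ``<value_col>_adj`` column holding
    trend + residual from the period-``period`` decomposition (the series
    with its seasonal cycle removed), computed within each ``by`` group.
    Used before driver models so that co-cyclic environmental factors
    cannot soak up purely seasonal variance of the response.
    """
    parts = []
    for key, g in table.groupby(by):
        g = g.sort_values("lagged_month")
        dec = stl_decompose((g["lagged_month"].to_numpy(float), g[value_col].to_numpy(float)), period=period)
        keep = ~dec.interpolated
        parts.append(
            pd.DataFrame(
                {
                    by: key,
                    "lagged_month": dec.index[keep],
                    f"{value_col}_adj": (dec.trend + dec.residual)[keep],
                }
            )
        )
    adj = pd.concat(parts, ignore_index=True)
    return table.merge(adj, on=[by, "lagged_month"], how="inner")


def trend_table(
    series_list,
    ids,
    alpha: float = 0.05,
    period: int = 12,
    deseason: bool = True,
    min_span_periods: int = 2,
) -> pd.DataFrame:
    """Fit direct and de-seasoned trends to a family of series, BH-correct
    each method's p-values across the family, and classify.

    Returns one row per (series, method) with slope, p, q and class.
    """
    rows = []
    for sid, s in zip(ids, series_list):
        methods = {"lm": linear_trend(s)}
        if deseason:
            t, _ = _series_xy(s)
            if t.max() - t.min() + 1 >= min_span_periods * period:
                methods["deseason"] = deseasoned_trend(s, period=period)
        for method, tr in methods.items():
            rows.append(
                {
                    "id": sid,
                    "method": method,
                    "slope_month": tr.slope_per_month,
                    "slope_year": tr.slope_per_year,
                    "intercept": tr.intercept,
                    "p": tr.p,
                    "r2": tr.r2,
                    "n": tr.n,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    for method in df["method"].unique():
        mask = df["method"] == method
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df["class"] = [
        classify_trend(TrendResult(r.slope_month, r.slope_year, r.intercept, r.p, r.r2, int(r.n)), alpha)
        for r in df.itertuples()
    ]
    return df
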