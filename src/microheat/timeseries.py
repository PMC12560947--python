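"""Hourly aggregation, gap imputation, and temporal summaries.

The processing chain mirrors a typical paired-logger deployment:

1. raw half-hourly records are averaged to clock-hour means with a
   per-hour quality flag (observed / partial / missing);
2. gaps are detected as maximal runs of missing hours and imputed from
   donor sensors in the same network via per-gap calibrated linear maps;
3. wet-bulb temperature is derived from the (possibly imputed) hourly
   T and RH;
4. summaries: daily extremes, monthly means of daily extremes, seasonal
   means of monthly values, and month x hour indoor-outdoor difference
   surfaces.

Imputed values are always flagged, and every summary can be recomputed
with imputed hours excluded, so no downstream number ever silently
depends on filled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .psychro import stull_domain_valid, wet_bulb_stull
from .synthetic import SensorSeries

__all__ = [
    "SEASON_OF_MONTH",
    "SEASONS",
    "hourly_aggregate",
    "detect_gaps",
    "impute_gaps",
    "add_wet_bulb",
    "daily_extremes",
    "seasonal_summary",
    "diff_surface",
]

# four-season mapping used throughout: calendar quarters
SEASON_OF_MONTH = {
    **{m: "cold_dry" for m in (1, 2, 3)},
    **{m: "hot_dry" for m in (4, 5, 6)},
    **{m: "monsoon" for m in (7, 8, 9)},
    **{m: "wet" for m in (10, 11, 12)},
}
SEASONS = ("cold_dry", "hot_dry", "monsoon", "wet")

_METRICS = ("min_T", "max_T", "min_Tw", "max_Tw")


def hourly_aggregate(raw: pd.DataFrame) -> SensorSeries:
    """Collapse half-hourly (or finer) records of one logger to hourly means.

    ``raw`` needs columns site_id, location, timestamp, T_c, RH_pct.
    Each clock hour becomes the mean of its available records; the flag is
    'observed' if all expected records are present, 'partial' if some,
    'missing' if none.  The output spans every clock hour between the
    first and last record — aggregation never invents or drops hours.
    """
    if raw.empty:
        raise ValueError("no records to aggregate")
    site_ids = raw["site_id"].unique()
    locations = raw["location"].unique()
    if len(site_ids) != 1 or len(locations) != 1:
        raise ValueError("hourly_aggregate expects records of exactly one logger")

    ts = pd.to_datetime(raw["timestamp"], errors="coerce")
    bad = ts.isna() & raw["timestamp"].notna()
    if bad.any():
        raise ValueError(f"unparseable timestamps at rows {list(raw.index[bad][:5])}")
    rh = pd.to_numeric(raw["RH_pct"], errors="coerce")
    out_of_range = rh.notna() & ((rh < 0) | (rh > 100))
    if out_of_range.any():
        raise ValueError(
            f"RH outside [0, 100] at rows {list(raw.index[out_of_range][:5])}"
        )
    t = pd.to_numeric(raw["T_c"], errors="coerce")

    df = pd.DataFrame({"T": t.to_numpy(), "RH": rh.to_numpy()},
                      index=ts).sort_index()
    per_hour = int(round(pd.Timedelta("1h") / df.index.to_series().diff().median())) \
        if len(df) > 1 else 1
    per_hour = max(per_hour, 1)

    grouped = df.groupby(df.index.floor("h"))
    agg = grouped.mean()
    counts = grouped["T"].count()

    full_idx = pd.date_range(agg.index.min(), agg.index.max(), freq="h")
    agg = agg.reindex(full_idx)
    counts = counts.reindex(full_idx, fill_value=0)

    flag = np.where(counts == 0, "missing",
                    np.where(counts >= per_hour, "observed", "partial"))
    agg["flag"] = flag
    return SensorSeries(str(site_ids[0]), str(locations[0]), agg)


def detect_gaps(series: SensorSeries) -> pd.DataFrame:
    """Maximal runs of missing hours: (start, end, length_h), plus fraction.

    The gap fraction over the whole series is attached as
    ``DataFrame.attrs['gap_fraction']``.
    """
    miss = (series.data["flag"] == "missing").to_numpy()
    runs = []
    i = 0
    n = len(miss)
    while i < n:
        if miss[i]:
            j = i
            while j + 1 < n and miss[j + 1]:
                j += 1
            runs.append(
                {"start": series.data.index[i], "end": series.data.index[j],
                 "length_h": j - i + 1}
            )
            i = j + 1
        else:
            i += 1
    out = pd.DataFrame(runs, columns=["start", "end", "length_h"])
    out.attrs["gap_fraction"] = float(miss.mean()) if n else 0.0
    return out


@dataclass
class _Calibration:
    donor_index: int
    r: float
    a: float
    b: float


def impute_gaps(
    target: SensorSeries,
    donors: list[SensorSeries],
    calib_window_days: int = 14,
    k: int = 3,
    min_overlap_h: int = 48,
) -> SensorSeries:
    """Fill gaps in ``target`` from donor sensors of the same network.

    For each gap run and each variable (T and RH independently): candidate
    donors are ranked by Pearson correlation with the target over the
    surrounding +/- ``calib_window_days`` days of shared non-missing
    hours; a least-squares linear map target ~ a + b * donor is fitted on
    that window for each of the top-``k`` donors; the gap is predicted as
    the correlation-weighted mean of the donor predictions.  Donors with
    under ``min_overlap_h`` hours of calibration overlap, or zero variance
    over the window, are excluded.  Hours no donor covers stay missing and
    are reported in ``DataFrame.attrs['unfilled']``.

    Wet-bulb temperature, if present, is recomputed from the imputed T/RH.
    """
    s = target.copy()
    df = s.data
    gaps = detect_gaps(target)
    idx = df.index
    unfilled = 0

    donor_mat = {
        var: np.column_stack(
            [d.data[var].where(d.data["flag"] != "missing").reindex(idx).to_numpy()
             for d in donors]
        ) if donors else np.empty((len(idx), 0))
        for var in ("T", "RH")
    }
    target_obs = {
        var: df[var].where(df["flag"] != "missing").to_numpy()
        for var in ("T", "RH")
    }
    values = {var: df[var].to_numpy(copy=True) for var in ("T", "RH")}

    flags = df["flag"].to_numpy(copy=True)
    half = pd.Timedelta(days=calib_window_days)
    for gap in gaps.itertuples(index=False):
        w0 = idx.searchsorted(gap.start - half)
        w1 = idx.searchsorted(gap.end + half, side="right")
        g0 = idx.searchsorted(gap.start)
        g1 = idx.searchsorted(gap.end, side="right")
        preds = {}
        have = np.ones(g1 - g0, dtype=bool)
        for var in ("T", "RH"):
            y = target_obs[var][w0:w1]
            D = donor_mat[var][w0:w1]
            cals = _calibrate(y, D, min_overlap_h, k)
            if not cals:
                have[:] = False
                break
            pred_num = np.zeros(g1 - g0)
            pred_den = np.zeros(g1 - g0)
            for cal in cals:
                dvals = donor_mat[var][g0:g1, cal.donor_index]
                ok = ~np.isnan(dvals)
                w = max(cal.r, 1e-6)
                pred_num[ok] += w * (cal.a + cal.b * dvals[ok])
                pred_den[ok] += w
            covered = pred_den > 0
            preds[var] = np.where(covered, pred_num / np.maximum(pred_den, 1e-12),
                                  np.nan)
            have &= covered
        # fill only records where both variables are predictable, so the
        # single per-hour flag stays truthful
        if have.any():
            for var in ("T", "RH"):
                values[var][g0:g1][have] = preds[var][have]
            flags[g0:g1][have] = "imputed"
        unfilled += int((~have).sum())
    for var in ("T", "RH"):
        df[var] = values[var]
    df["flag"] = flags
    if "Tw" in df.columns:
        add_wet_bulb(s)
    df.attrs["unfilled"] = unfilled
    return s


def _calibrate(y: np.ndarray, D: np.ndarray, min_overlap: int, k: int
               ) -> list[_Calibration]:
    """Rank donors by correlation with y and fit linear maps; top-k kept.

    Vectorized over donors: masked sums give per-donor overlap counts,
    Pearson correlations and least-squares slopes in a few matrix ops.
    """
    if D.shape[1] == 0:
        return []
    yok = ~np.isnan(y)
    M = ~np.isnan(D) & yok[:, None]
    n = M.sum(axis=0).astype(float)
    Dm = np.where(M, D, 0.0)
    Ym = np.where(M, y[:, None], 0.0)
    sx = Dm.sum(axis=0)
    sy = Ym.sum(axis=0)
    sxx = (Dm * Dm).sum(axis=0)
    syy = (Ym * Ym).sum(axis=0)
    sxy = (Dm * Ym).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_x = sxx - sx * sx / np.maximum(n, 1.0)
        var_y = syy - sy * sy / np.maximum(n, 1.0)
        cov = sxy - sx * sy / np.maximum(n, 1.0)
        r = cov / np.sqrt(var_x * var_y)
        b = cov / var_x
        a = sy / np.maximum(n, 1.0) - b * sx / np.maximum(n, 1.0)
    ok = (n >= min_overlap) & (var_x > 0) & (var_y > 0) & np.isfinite(r)
    order = [j for j in np.argsort(-np.where(ok, r, -np.inf)) if ok[j]][:k]
    return [_Calibration(int(j), float(r[j]), float(a[j]), float(b[j]))
            for j in order]


def add_wet_bulb(series: SensorSeries) -> SensorSeries:
    """Derive hourly wet-bulb temperature from T and RH (in place)."""
    df = series.data
    T = df["T"].to_numpy()
    RH = np.clip(df["RH"].to_numpy(), 0.0, 100.0)
    ok = ~np.isnan(T) & ~np.isnan(RH)
    tw = np.full(len(df), np.nan)
    tw[ok] = wet_bulb_stull(T[ok], RH[ok])
    df["Tw"] = tw
    df["Tw_valid"] = ok & stull_domain_valid(T, np.where(ok, RH, 50.0))
    return series


def daily_extremes(
    series: SensorSeries, min_valid_hours: int = 18, exclude_imputed: bool = False
) -> pd.DataFrame:
    """Calendar-day min/max of T and Tw; days with too few valid hours drop.

    A valid hour is observed or partial (plus imputed unless excluded).
    """
    df = series.data
    good_flags = {"observed", "partial"} | (set() if exclude_imputed else {"imputed"})
    valid = df["flag"].isin(good_flags) & df["T"].notna()
    sub = df.loc[valid, ["T", "Tw"]] if "Tw" in df.columns else df.loc[valid, ["T"]]
    if sub.empty:
        return pd.DataFrame(columns=["date", *_METRICS]).set_index("date")
    by_day = sub.groupby(sub.index.normalize())
    counts = by_day["T"].count()
    keep = counts[counts >= min_valid_hours].index
    out = pd.DataFrame(
        {
            "min_T": by_day["T"].min(),
            "max_T": by_day["T"].max(),
        }
    )
    if "Tw" in sub.columns:
        out["min_Tw"] = by_day["Tw"].min()
        out["max_Tw"] = by_day["Tw"].max()
    out = out.loc[keep]
    out.index.name = "date"
    return out


def seasonal_summary(
    daily: pd.DataFrame, site_id: str, location: str
) -> pd.DataFrame:
    """Seasonal values: monthly means of daily extremes, then season means.

    A season's value is the mean of its member months' values; seasons
    with no qualifying month are omitted (and listed in
    ``DataFrame.attrs['omitted_seasons']``).
    """
    if daily.empty:
        out = pd.DataFrame(columns=["site_id", "location", "season", *_METRICS])
        out.attrs["omitted_seasons"] = list(SEASONS)
        return out
    monthly = daily.groupby(daily.index.month).mean()
    monthly["season"] = [SEASON_OF_MONTH[m] for m in monthly.index]
    seasonal = monthly.groupby("season").mean()
    seasonal = seasonal.reindex([s for s in SEASONS if s in seasonal.index])
    out = seasonal.reset_index()
    out.insert(0, "location", location)
    out.insert(0, "site_id", site_id)
    out.attrs["omitted_seasons"] = [s for s in SEASONS if s not in set(out["season"])]
    return out


def diff_surface(
    pairs: list[tuple[SensorSeries, SensorSeries]],
    metric: str = "T",
    exclude_imputed: bool = True,
) -> pd.DataFrame:
    """Mean indoor-outdoor difference on a complete 12 x 24 month-hour grid.

    ``pairs`` holds (indoor, outdoor) series sharing a site_id.  Hours
    where either member is missing (or imputed, when excluded) contribute
    nothing to the mean.
    """
    good = {"observed", "partial"} | (set() if exclude_imputed else {"imputed"})
    diffs = []
    for indoor, outdoor in pairs:
        if indoor.site_id != outdoor.site_id:
            raise ValueError(
                f"pair mismatch: {indoor.site_id} vs {outdoor.site_id}"
            )
        if {indoor.location, outdoor.location} != {"indoor", "outdoor"}:
            raise ValueError("each pair must hold one indoor and one outdoor series")
        if indoor.location == "outdoor":
            indoor, outdoor = outdoor, indoor
        a, b = indoor.data.align(outdoor.data, join="inner", axis=0)
        ok = a["flag"].isin(good) & b["flag"].isin(good)
        d = (a.loc[ok, metric] - b.loc[ok, metric]).dropna()
        diffs.append(d)
    if not diffs:
        raise ValueError("no complete indoor/outdoor pairs supplied")
    alld = pd.concat(diffs)
    table = (
        alld.groupby([alld.index.month, alld.index.hour])
        .mean()
        .unstack(fill_value=np.nan)
    )
    table = table.reindex(index=range(1, 13), columns=range(24))
    table.index.name = "month"
    table.columns.name = "hour"
    return table
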