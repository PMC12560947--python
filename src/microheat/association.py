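"""Spearman associations between seasonal temperatures and land cover.

For every combination of temperature metric (seasonal min/max of T and
Tw), land-cover variable, season, indoor/outdoor location, and focal
window, a Spearman rank correlation across sites is computed (average
ranks for ties; two-sided p from the t approximation).  The focal window
used for modeling is then chosen per (metric, variable) pair as the one
maximizing the mean absolute correlation over all seasons and both
locations — the multi-scale selection rule of the analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "spearman_table",
    "mean_abs_rho",
    "select_window",
    "significance_stars",
]

TEMP_METRICS = ("min_T", "max_T", "min_Tw", "max_Tw")


def spearman_table(
    summaries: pd.DataFrame,
    features: pd.DataFrame,
    min_sites: int = 3,
) -> pd.DataFrame:
    """Correlate seasonal temperature metrics with focal features.

    ``summaries``: rows (site_id, location, season, min_T, max_T, min_Tw,
    max_Tw).  ``features``: rows (site_id, variable, window_m, season,
    value).  Returns one row per (temp_metric, variable, season, location,
    window) with rho, p, n and a ``degenerate`` flag for zero-variance
    cells (whose rho/p are NaN).
    """
    metrics = [m for m in TEMP_METRICS if m in summaries.columns]
    rows = []
    feat_groups = dict(list(features.groupby(["variable", "window_m", "season"])))
    for (loc, season), sub in summaries.groupby(["location", "season"]):
        for (var, window, f_season), feats in feat_groups.items():
            if f_season != season:
                continue
            merged = sub.merge(feats[["site_id", "value"]], on="site_id")
            merged = merged.dropna(subset=["value"])
            for metric in metrics:
                pair = merged.dropna(subset=[metric])
                n = len(pair)
                base = {
                    "temp_metric": metric, "lc_variable": var, "season": season,
                    "location": loc, "window_m": float(window), "n": n,
                }
                if n < min_sites:
                    rows.append({**base, "rho": np.nan, "p": np.nan,
                                 "degenerate": True})
                    continue
                x = pair["value"].to_numpy()
                y = pair[metric].to_numpy()
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    rows.append({**base, "rho": np.nan, "p": np.nan,
                                 "degenerate": True})
                    continue
                res = stats.spearmanr(x, y)
                rows.append({**base, "rho": float(res.statistic),
                             "p": float(res.pvalue), "degenerate": False})
    return pd.DataFrame(rows)


def mean_abs_rho(results: pd.DataFrame) -> pd.DataFrame:
    """Mean |rho| per (temp_metric, lc_variable, window) across the 8 cells.

    The 8 cells are 4 seasons x 2 locations; missing/degenerate cells are
    excluded from the mean, with the used-cell count reported.
    """
    if results.empty:
        raise ValueError("empty correlation table")
    df = results.copy()
    df["abs_rho"] = df["rho"].abs()
    out = (
        df.groupby(["temp_metric", "lc_variable", "window_m"])
        .agg(mean_abs_rho=("abs_rho", "mean"), n_cells=("abs_rho", "count"))
        .reset_index()
    )
    return out


def select_window(mean_abs: pd.DataFrame) -> pd.DataFrame:
    """Choose, per (metric, variable), the window maximizing mean |rho|.

    Ties break toward the smallest window.  Requires at least two
    candidate windows per pair.
    """
    rows = []
    for (metric, var), grp in mean_abs.groupby(["temp_metric", "lc_variable"]):
        grp = grp.dropna(subset=["mean_abs_rho"])
        if len(grp) < 2:
            raise ValueError(
                f"need >= 2 candidate windows for ({metric}, {var}), "
                f"got {len(grp)}"
            )
        grp = grp.sort_values(["mean_abs_rho", "window_m"],
                              ascending=[False, True], kind="mergesort")
        best = grp.iloc[0]
        rows.append(
            {"temp_metric": metric, "lc_variable": var,
             "window_m": float(best["window_m"]),
             "mean_abs_rho": float(best["mean_abs_rho"])}
        )
    return pd.DataFrame(rows)


def significance_stars(
    results: pd.DataFrame, alpha: float = 0.05, bh_adjust: bool = False
) -> pd.DataFrame:
    """Flag correlations significant at ``alpha`` (strict inequality).

    No multiplicity adjustment by default; ``bh_adjust=True`` applies
    Benjamini-Hochberg across the table's non-missing p-values first.
    """
    out = results.copy()
    p = out["p"].to_numpy(copy=True)
    if bh_adjust:
        ok = ~np.isnan(p)
        p_adj = np.full_like(p, np.nan)
        p_adj[ok] = stats.false_discovery_control(p[ok])
        p = p_adj
        out["p_adj"] = p
    with np.errstate(invalid="ignore"):
        out["starred"] = np.nan_to_num(p, nan=1.0) < alpha
    return out
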