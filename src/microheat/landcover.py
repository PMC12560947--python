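"""Spectral indices, monthly composites, and focal statistics around sites.

Index definitions follow the standard remote-sensing conventions:
NDVI = (NIR - Red)/(NIR + Red); broadband shortwave albedo via Liang's
weighted sum of blue/red/NIR/SWIR reflectances; surface water from the
modified normalized difference water index MNDWI = (Green - SWIR1) /
(Green + SWIR1) thresholded at 0.05 (strictly greater than).

Focal summaries use a circular neighborhood: the mean over all cells
whose centers lie within ``window_m`` meters (Euclidean) of the sensor.
For the binary water mask the mean is the areal water fraction.  Layers
entering the same computation must share their grid exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .rasters import Raster, require_same_grid
from .synthetic import LandCoverStack
from .timeseries import SEASON_OF_MONTH, SEASONS

__all__ = [
    "ndvi",
    "broadband_albedo",
    "water_mask",
    "monthly_composite",
    "focal_summary",
    "focal_features",
    "seasonal_feature_average",
]

LC_VARIABLES = ("bvol", "ndvi", "albedo", "water")

# Liang (2001) shortwave broadband albedo coefficients (Landsat heritage):
# blue, red, nir, swir1, swir2 and intercept.
_LIANG = {"blue": 0.356, "red": 0.130, "nir": 0.373, "swir1": 0.085,
          "swir2": 0.072}
_LIANG_INTERCEPT = -0.0018

MNDWI_THRESHOLD = 0.05


def ndvi(nir, red):
    """Normalized difference vegetation index; 0/0 cells become NaN."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if np.any(nir[~np.isnan(nir)] < 0) or np.any(red[~np.isnan(red)] < 0):
        raise ValueError("negative reflectance")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / denom, np.nan)
    return out if out.ndim else float(out)


def broadband_albedo(blue, red, nir, swir1, swir2):
    """Liang's shortwave broadband albedo, clipped to [0, 1].

    Any cell with a missing band is missing in the output.
    """
    bands = {"blue": blue, "red": red, "nir": nir, "swir1": swir1, "swir2": swir2}
    arrs = {}
    for name, b in bands.items():
        a = np.asarray(b, dtype=float)
        valid = a[~np.isnan(a)]
        if valid.size and (valid.min() < 0 or valid.max() > 1.2):
            raise ValueError(f"{name} reflectance outside [0, 1.2]")
        arrs[name] = a
    alpha = sum(_LIANG[n] * arrs[n] for n in _LIANG) + _LIANG_INTERCEPT
    out = np.clip(alpha, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def water_mask(green, swir1, threshold: float = MNDWI_THRESHOLD):
    """Binary water mask: 1 where MNDWI strictly exceeds the threshold.

    Cells where MNDWI is undefined (0/0) are mapped to 0 (non-water).
    """
    green = np.asarray(green, dtype=float)
    swir1 = np.asarray(swir1, dtype=float)
    if np.any(green[~np.isnan(green)] < 0) or np.any(swir1[~np.isnan(swir1)] < 0):
        raise ValueError("negative reflectance")
    denom = green + swir1
    with np.errstate(invalid="ignore", divide="ignore"):
        mndwi = np.where(denom > 0, (green - swir1) / denom, np.nan)
    mask = np.where(np.nan_to_num(mndwi, nan=-np.inf) > threshold, 1, 0)
    return mask if np.ndim(mask) else int(mask)


def monthly_composite(scenes: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Cellwise per-band median across the scenes of one month.

    Missing values are ignored per cell; an all-missing cell stays NaN.
    Indices should be derived from the composite, not composited themselves.
    """
    if not scenes:
        raise ValueError("need at least one scene")
    bands = scenes[0].keys()
    out = {}
    for band in bands:
        stack = np.stack([np.asarray(s[band], dtype=float) for s in scenes])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            out[band] = np.nanmedian(stack, axis=0)
    return out


def focal_summary(layer: Raster, x: float, y: float, window_m: float) -> float:
    """Mean of a layer over the circular window of radius ``window_m``.

    Includes every cell whose center is within the radius of (x, y);
    cells outside the raster simply don't exist, so the denominator is the
    count of in-raster, non-missing cells.  Returns NaN if the window
    captures no usable cell.
    """
    g = layer.grid
    # bounding box of candidate cells, then exact center-distance test
    col_lo = max(0, int(np.floor((x - window_m - g.xll) / g.cellsize)) - 1)
    col_hi = min(g.ncols, int(np.ceil((x + window_m - g.xll) / g.cellsize)) + 1)
    row_lo = max(0, int(np.floor((g.yll + g.nrows * g.cellsize - y - window_m)
                                 / g.cellsize)) - 1)
    row_hi = min(g.nrows, int(np.ceil((g.yll + g.nrows * g.cellsize - y + window_m)
                                      / g.cellsize)) + 1)
    if col_lo >= col_hi or row_lo >= row_hi:
        return np.nan
    cols = np.arange(col_lo, col_hi)
    rows = np.arange(row_lo, row_hi)
    cxs = g.xll + (cols + 0.5) * g.cellsize
    cys = g.yll + (g.nrows - rows - 0.5) * g.cellsize
    dx = cxs[None, :] - x
    dy = cys[:, None] - y
    inside = dx * dx + dy * dy <= window_m * window_m
    vals = layer.data[row_lo:row_hi, col_lo:col_hi][inside]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return np.nan
    return float(vals.mean())


def focal_features(
    lc: LandCoverStack, sites: pd.DataFrame, windows_m: tuple[float, ...]
) -> pd.DataFrame:
    """Monthly focal values for every site x variable x window.

    Building volume is static, so its monthly values repeat; water is the
    areal fraction of masked cells.  Returns a tidy frame with columns
    site_id, variable, window_m, month, value.
    """
    require_same_grid(lc.building_volume, *lc.ndvi.values(),
                      *lc.albedo.values(), *lc.water.values())
    rows = []
    for rec in sites.itertuples(index=False):
        if not lc.grid.contains(rec.x, rec.y):
            raise ValueError(f"site {rec.site_id} outside raster extent")
        for w in windows_m:
            bval = focal_summary(lc.building_volume, rec.x, rec.y, w)
            for mk in lc.months:
                layer_vals = {
                    "bvol": bval,
                    "ndvi": focal_summary(lc.ndvi[mk], rec.x, rec.y, w),
                    "albedo": focal_summary(lc.albedo[mk], rec.x, rec.y, w),
                    "water": focal_summary(lc.water[mk], rec.x, rec.y, w),
                }
                for var, val in layer_vals.items():
                    rows.append(
                        {"site_id": rec.site_id, "variable": var,
                         "window_m": float(w), "month": mk, "value": val}
                    )
    return pd.DataFrame(rows)


def seasonal_feature_average(monthly: pd.DataFrame) -> pd.DataFrame:
    """Average monthly focal values into seasons.

    Season value = mean of the member months present; static layers
    (building volume) therefore replicate across seasons.  Output columns:
    site_id, variable, window_m, season, value.
    """
    df = monthly.copy()
    df["season"] = [SEASON_OF_MONTH[int(mk.split("-")[1])] for mk in df["month"]]
    out = (
        df.groupby(["site_id", "variable", "window_m", "season"], sort=False)
        ["value"].mean().reset_index()
    )
    order = {s: i for i, s in enumerate(SEASONS)}
    out = out.sort_values(
        ["site_id", "variable", "window_m", "season"],
        key=lambda s: s.map(order) if s.name == "season" else s,
    ).reset_index(drop=True)
    return out
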