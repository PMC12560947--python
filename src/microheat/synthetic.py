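"""Synthetic paired-sensor network and land-cover rasters.

Emulates a one-year microclimate deployment in a monsoonal Indian city:
~45 dwellings stratified over administrative zones, each with a paired
indoor/outdoor hourly temperature/humidity logger, on a raster landscape
whose building volume decays — and vegetation increases — from the urban
core to the periphery.  Every statistical feature the downstream analysis
is designed to detect is *programmed* here with known sign and size, so
the whole pipeline can be tested for recovery without any downloads.

Programmed structure
--------------------
* outdoor dry-bulb = annual harmonic + diurnal harmonic + land-cover
  effects entering separately on the daily minimum (building volume
  warms, vegetation cools) and the daily maximum (signs reversed) +
  iid Gaussian noise;
* indoor dry-bulb = first-order low-pass filter of the outdoor signal
  (damped, lagged) + insulation offset, with land-cover effect sizes
  multiplied by ``indoor_effect_scale``;
* relative humidity = anti-correlated with the diurnal temperature
  anomaly (saturation-deficit style) + additive monsoon boost;
* missingness = contiguous gap runs with geometric run lengths
  (bursty logger outages), with the pre-gap truth retained in a hidden
  channel for recovery testing.

All outputs are pure functions of (config, seed): named substreams are
derived from the single config seed, so reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .config import SimConfig
from .rasters import Grid, Raster

__all__ = [
    "LandCoverStack",
    "SensorSeries",
    "generate_landcover",
    "generate_sites",
    "generate_sensor_series",
    "inject_gaps",
]

# substream tags so each generator stage has its own independent stream
_STREAM_LANDCOVER = 101
_STREAM_SITES = 202
_STREAM_SENSORS = 303
_STREAM_GAPS = 404

# landscape constants (per 30 m cell)
_BVOL_MAX = 30000.0          # m^3 per cell at the city core
_NDVI_CORE, _NDVI_RIM = 0.05, 0.60
_ALBEDO_MEAN, _ALBEDO_SD = 0.25, 0.05

# seasonal NDVI modulation: greening through/after the monsoon
_NDVI_SEASON = {1: 1.00, 2: 0.95, 3: 0.90, 4: 0.82, 5: 0.78, 6: 0.80,
                7: 0.95, 8: 1.05, 9: 1.12, 10: 1.15, 11: 1.10, 12: 1.05}

_SEASONAL_PEAK_DOY = 135     # mid-May: hottest time of year pre-monsoon
_DIURNAL_PEAK_HOUR = 15      # mid-afternoon temperature maximum


@dataclass
class LandCoverStack:
    """Gridded land-cover layers on one shared projected grid.

    ``building_volume`` is static; NDVI, albedo and the water mask are
    monthly (keyed by 'YYYY-MM').
    """

    grid: Grid
    building_volume: Raster
    ndvi: dict[str, Raster]
    albedo: dict[str, Raster]
    water: dict[str, Raster]
    ndvi_base: Raster = None  # noiseless base NDVI field (truth channel)

    @property
    def months(self) -> list[str]:
        return sorted(self.ndvi)


@dataclass
class SensorSeries:
    """One logger's hourly record.

    ``data`` is indexed by a clock-aligned hourly DatetimeIndex with
    columns T (degC), RH (%), flag in {observed, partial, imputed,
    missing}, and optionally Tw plus hidden truth columns T_true /
    RH_true written by :func:`inject_gaps`.
    """

    site_id: str
    location: str  # 'indoor' | 'outdoor'
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.location not in ("indoor", "outdoor"):
            raise ValueError(f"location must be indoor/outdoor, got {self.location}")
        idx = self.data.index
        if len(idx) > 1:
            deltas = np.diff(idx.asi8)
            if not np.all(deltas == 3_600_000_000_000):
                raise ValueError("timestamps must be strictly increasing hourly")

    def copy(self) -> "SensorSeries":
        return SensorSeries(self.site_id, self.location, self.data.copy())


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def generate_landcover(cfg: SimConfig) -> LandCoverStack:
    """Build the synthetic city landscape.

    Building volume decays exponentially with distance from the city
    center while NDVI rises, producing a strongly negative correlation
    between the two across space; albedo is an independent smooth random
    field; water is one meandering river plus scattered ponds.
    """
    gs = cfg.grid_size
    if gs < 32:
        raise ValueError(
            f"grid_size must be >= 32 cells for a meaningful landscape, got {gs}"
        )
    rng = _rng(cfg.seed, _STREAM_LANDCOVER)
    grid = Grid(ncols=gs, nrows=gs, xll=0.0, yll=0.0, cellsize=cfg.cell_size)

    xs, ys = grid.cell_centers()
    cx = cfg.cell_size * gs / 2.0
    r = np.hypot(xs - cx, ys - cx)
    r0 = 0.55 * cfg.cell_size * gs / 2.0

    # noise amplitude scales with cfg.noise_sd so a noise-free config
    # yields noise-free (strictly monotone) landscape fields too
    nsc = cfg.noise_sd / 0.5

    bvol = _BVOL_MAX * np.exp(-r / r0)
    bvol = bvol * np.exp(nsc * 0.22 * rng.standard_normal(bvol.shape))
    ndvi_base = _NDVI_CORE + (_NDVI_RIM - _NDVI_CORE) * (1.0 - np.exp(-r / r0))
    ndvi_base = ndvi_base + nsc * 0.035 * rng.standard_normal(ndvi_base.shape)
    ndvi_base = np.clip(ndvi_base, -1.0, 1.0)

    albedo_field = gaussian_filter(rng.standard_normal((gs, gs)), sigma=6.0)
    sd = albedo_field.std()
    if sd > 0:
        albedo_field = albedo_field / sd
    albedo_base = np.clip(_ALBEDO_MEAN + _ALBEDO_SD * albedo_field, 0.0, 1.0)

    water = _river_and_ponds(gs, rng)
    bvol = np.where(water == 1, 0.0, bvol)

    months = _month_keys(cfg)
    ndvi_m, albedo_m, water_m = {}, {}, {}
    water_r = Raster(grid, water.astype(float))
    for mk in months:
        month = int(mk.split("-")[1])
        f = _NDVI_SEASON[month]
        layer = np.clip(
            ndvi_base * f + nsc * 0.01 * rng.standard_normal((gs, gs)), -1.0, 1.0
        )
        ndvi_m[mk] = Raster(grid, layer)
        alb = np.clip(
            albedo_base + nsc * 0.005 * rng.standard_normal((gs, gs)), 0.0, 1.0
        )
        albedo_m[mk] = Raster(grid, alb)
        water_m[mk] = water_r

    return LandCoverStack(
        grid=grid,
        building_volume=Raster(grid, bvol),
        ndvi=ndvi_m,
        albedo=albedo_m,
        water=water_m,
        ndvi_base=Raster(grid, ndvi_base),
    )


def _river_and_ponds(gs: int, rng: np.random.Generator) -> np.ndarray:
    water = np.zeros((gs, gs), dtype=int)
    # meandering river crossing the city top to bottom, ~2 cells wide
    rows = np.arange(gs)
    center_col = gs * 0.55 + 0.12 * gs * np.sin(2 * np.pi * rows / gs * 1.5)
    for row, cc in zip(rows, center_col):
        c0 = int(round(cc))
        water[row, max(0, c0 - 1): min(gs, c0 + 1)] = 1
    # scattered ponds
    n_ponds = max(4, gs // 12)
    for _ in range(n_ponds):
        pr, pc = rng.integers(2, gs - 2, size=2)
        size = int(rng.integers(1, 3))
        water[pr: pr + size, pc: pc + size] = 1
    return water


def _month_keys(cfg: SimConfig) -> list[str]:
    start = pd.Timestamp(cfg.period_start)
    end = pd.Timestamp(cfg.period_end)
    return [str(p) for p in pd.period_range(start, end, freq="M")]


def generate_sites(cfg: SimConfig, lc: LandCoverStack) -> pd.DataFrame:
    """Place dwellings round-robin across a block partition of the grid.

    Returns a table (site_id, zone, row, col, x, y) with one row per
    dwelling; no two sites share a cell and no site sits in water.
    """
    rng = _rng(cfg.seed, _STREAM_SITES)
    gs = cfg.grid_size
    nz = cfg.n_zones
    zr, zc = _zone_layout(nz)
    row_edges = np.linspace(0, gs, zr + 1).astype(int)
    col_edges = np.linspace(0, gs, zc + 1).astype(int)
    water = next(iter(lc.water.values())).data

    zone_cells: list[list[tuple[int, int]]] = []
    for zi in range(zr):
        for zj in range(zc):
            cells = [
                (r, c)
                for r in range(row_edges[zi], row_edges[zi + 1])
                for c in range(col_edges[zj], col_edges[zj + 1])
                if water[r, c] == 0
            ]
            zone_cells.append(cells)

    taken: set[tuple[int, int]] = set()
    records = []
    for i in range(cfg.n_sites):
        zone = i % nz
        free = [c for c in zone_cells[zone] if c not in taken]
        if not free:
            raise ValueError(f"no free cells left in zone {zone} for site {i}")
        r, c = free[rng.integers(len(free))]
        taken.add((r, c))
        x = lc.grid.xll + (c + 0.5) * lc.grid.cellsize
        y = lc.grid.yll + (gs - r - 0.5) * lc.grid.cellsize
        records.append(
            {"site_id": f"S{i + 1:02d}", "zone": zone, "row": r, "col": c,
             "x": x, "y": y}
        )
    return pd.DataFrame(records)


def _zone_layout(nz: int) -> tuple[int, int]:
    """Most-square (rows, cols) factorization of the zone count."""
    best = (1, nz)
    for a in range(1, int(np.sqrt(nz)) + 1):
        if nz % a == 0:
            best = (a, nz // a)
    return best


def generate_sensor_series(
    cfg: SimConfig, sites: pd.DataFrame, lc: LandCoverStack
) -> list[SensorSeries]:
    """Simulate paired hourly indoor/outdoor T and RH series for every site."""
    rng = _rng(cfg.seed, _STREAM_SENSORS)
    idx = pd.date_range(
        pd.Timestamp(cfg.period_start),
        pd.Timestamp(cfg.period_end) + pd.Timedelta(hours=23),
        freq="h",
    )
    doy = idx.dayofyear.to_numpy(float)
    hour = idx.hour.to_numpy(float)
    month = idx.month.to_numpy()

    seasonal = cfg.seasonal_amp * np.cos(
        2 * np.pi * (doy - _SEASONAL_PEAK_DOY) / 365.25
    )
    d = np.cos(2 * np.pi * (hour - _DIURNAL_PEAK_HOUR) / 24.0)
    w_max = np.clip(d, 0.0, None)   # weight near the daily maximum
    w_min = np.clip(-d, 0.0, None)  # weight near the daily minimum
    in_monsoon = np.isin(month, cfg.monsoon_months).astype(float)
    # monsoon cloud cover shrinks the diurnal cycle: cooler afternoons,
    # warmer nights -- this is what makes wet-bulb minima peak in monsoon
    diurnal_scale = 1.0 - cfg.monsoon_diurnal_damp * in_monsoon

    out: list[SensorSeries] = []
    for rec in sites.itertuples(index=False):
        bvol_n = lc.building_volume.data[rec.row, rec.col] / _BVOL_MAX
        ndvi_n = lc.ndvi_base.data[rec.row, rec.col]
        baseline = cfg.site_baseline_sd * rng.standard_normal()

        for location in ("outdoor", "indoor"):
            scale = 1.0 if location == "outdoor" else cfg.indoor_effect_scale
            e_min = scale * (cfg.effect_bvol_minT * bvol_n
                             + cfg.effect_ndvi_minT * ndvi_n)
            e_max = scale * (cfg.effect_bvol_maxT * bvol_n
                             + cfg.effect_ndvi_maxT * ndvi_n)
            # cloud cover damps the harmonic but not the land-cover
            # effects, whose configured sizes are degC per unit on the
            # daily extremes in every season
            t_clean = (
                cfg.base_temp + baseline + seasonal
                + diurnal_scale * cfg.diurnal_amp_out * d
                + e_min * w_min + e_max * w_max
            )
            if location == "indoor":
                t_clean = _lowpass(t_clean, cfg.indoor_damping, cfg.indoor_lag)
                t_clean = t_clean + cfg.indoor_offset
                anomaly = t_clean - (cfg.base_temp + baseline
                                     + cfg.indoor_offset)
            else:
                # anomaly relative to the annual-mean baseline: both the
                # diurnal and the seasonal excursion dry the air
                anomaly = t_clean - (cfg.base_temp + baseline)

            T = t_clean + cfg.noise_sd * rng.standard_normal(len(idx))
            rh_clean = (
                cfg.rh_base - cfg.rh_temp_slope * anomaly
                + cfg.monsoon_rh_boost * in_monsoon
            )
            RH = rh_clean + 4.0 * (cfg.noise_sd / 0.5) * rng.standard_normal(len(idx))
            RH = np.clip(RH, 2.0, 99.5)

            df = pd.DataFrame(
                {"T": T, "RH": RH, "flag": "observed"}, index=idx
            )
            out.append(SensorSeries(rec.site_id, location, df))
    return out


def _lowpass(x: np.ndarray, alpha: float, lag: int) -> np.ndarray:
    """First-order exponential filter of a lagged input; identity at alpha=1."""
    if lag > 0:
        x = np.concatenate([np.full(lag, x[0]), x[:-lag]])
    if alpha >= 1.0:
        return x
    # y_t = (1 - a) y_{t-1} + a x_t, steady-state initialisation
    y, _ = lfilter([alpha], [1.0, -(1.0 - alpha)], x, zi=[(1.0 - alpha) * x[0]])
    return y


def inject_gaps(series: SensorSeries, gap_fraction: float, seed: int,
                mean_run: float = 6.0) -> SensorSeries:
    """Remove contiguous runs of hours until ~gap_fraction is missing.

    Run lengths are geometric with the given mean (bursty logger
    outages).  Removed T/RH values are retained in hidden ``T_true`` /
    ``RH_true`` columns so imputation can be scored against truth; all
    non-removed records are untouched.
    """
    if not (0.0 <= gap_fraction < 0.5):
        raise ValueError(f"gap_fraction must be in [0, 0.5), got {gap_fraction}")
    s = series.copy()
    df = s.data
    if "T_true" not in df.columns:
        df["T_true"] = df["T"]
        df["RH_true"] = df["RH"]
    if gap_fraction == 0.0:
        return s

    rng = _rng(seed, _STREAM_GAPS)
    n = len(df)
    target = int(round(gap_fraction * n))
    missing = np.zeros(n, dtype=bool)
    p = 1.0 / mean_run
    while missing.sum() < target:
        start = int(rng.integers(n))
        length = int(rng.geometric(p))
        length = min(length, target - int(missing.sum()) + 2)
        missing[start: min(n, start + length)] = True

    # trim overshoot from the tail of the last-marked region
    excess = int(missing.sum()) - target
    if excess > 0:
        marked = np.flatnonzero(missing)
        missing[marked[-excess:]] = False

    df.loc[missing, ["T", "RH"]] = np.nan
    if "Tw" in df.columns:
        df.loc[missing, "Tw"] = np.nan
    flags = df["flag"].to_numpy(copy=True)
    flags[missing] = "missing"
    df["flag"] = flags
    return s


def write_sensor_csvs(series: list[SensorSeries], out_dir) -> list[str]:
    """One CSV per logger matching the ingestion contract."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in series:
        df = pd.DataFrame(
            {
                "site_id": s.site_id,
                "location": s.location,
                "timestamp": s.data.index.strftime("%Y-%m-%dT%H:%M:%S"),
                "T_c": s.data["T"].round(4),
                "RH_pct": s.data["RH"].round(3),
            }
        )
        path = out_dir / f"{s.site_id}_{s.location}.csv"
        df.to_csv(path, index=False)
        paths.append(str(path))
    return paths
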