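"""Configuration objects for the simulator and the end-to-end pipeline.

Both configs are plain dataclasses that round-trip losslessly through TOML
(read with :mod:`tomllib`, written with a small emitter sufficient for the
flat key space used here).  Every pipeline run writes its resolved config
beside its outputs so any number in any output table can be traced back to
the exact settings and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["SimConfig", "PipelineConfig", "load_toml", "dump_toml"]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic sensor network.

    Defaults emulate a Surat-like deployment: 45 dwellings stratified over
    9 administrative zones, paired indoor/outdoor hourly loggers for a full
    year spanning a July–September monsoon, and a city raster grid with a
    dense built-up core grading into vegetated periphery.
    """

    n_sites: int = 45
    n_zones: int = 9
    grid_size: int = 96           # cells per side (square grid)
    cell_size: float = 30.0       # meters
    period_start: str = "2023-05-01"
    period_end: str = "2024-04-30"
    seed: int = 0

    # temperature dynamics (degC)
    base_temp: float = 27.0       # annual mean dry-bulb, Gujarat plains
    diurnal_amp_out: float = 5.0  # half peak-to-trough of outdoor diurnal cycle
    seasonal_amp: float = 6.0     # half amplitude of the annual harmonic
    site_baseline_sd: float = 0.3  # between-site random offset

    # humidity regime
    rh_base: float = 55.0         # mean RH (%) outside the monsoon
    rh_temp_slope: float = 2.5    # % RH drop per degC of diurnal warming
    monsoon_months: tuple[int, ...] = (7, 8, 9)
    monsoon_rh_boost: float = 25.0  # additive % RH during monsoon months
    monsoon_diurnal_damp: float = 0.3  # cloud-cover shrinkage of diurnal cycle

    # indoor thermal response
    indoor_damping: float = 0.3   # low-pass smoothing factor in (0, 1]
    indoor_lag: int = 1           # hours
    indoor_offset: float = 0.7    # insulation offset, degC

    # land-cover effects (degC per unit of the normalized layer value)
    effect_bvol_minT: float = 2.0
    effect_ndvi_minT: float = -2.0
    effect_bvol_maxT: float = -1.0
    effect_ndvi_maxT: float = 1.0
    indoor_effect_scale: float = 0.5

    noise_sd: float = 0.5         # iid hourly measurement noise, degC
    gap_fraction: float = 0.083   # fraction of hourly records removed
    gap_mean_run: float = 6.0     # mean length (hours) of a gap run

    def __post_init__(self) -> None:
        if not (0.0 <= self.gap_fraction < 0.5):
            raise ValueError(f"gap_fraction must be in [0, 0.5), got {self.gap_fraction}")
        if not (0.0 < self.indoor_damping <= 1.0):
            raise ValueError(f"indoor_damping must be in (0, 1], got {self.indoor_damping}")
        if self.n_sites < self.n_zones:
            raise ValueError("n_sites must be >= n_zones")
        self.monsoon_months = tuple(int(m) for m in self.monsoon_months)


@dataclass
class PipelineConfig:
    """Settings for a full single-city analysis run."""

    out_dir: str = "microheat_out"
    sensors_dir: str | None = None    # None => must simulate
    rasters_dir: str | None = None
    sites_path: str | None = None
    seed: int = 0

    windows_m: tuple[float, ...] = (50.0, 100.0, 500.0, 1000.0)
    exclude_imputed: bool = False     # drop imputed hours from summaries

    # imputation
    calib_window_days: int = 14
    n_donors: int = 3

    # GAM settings
    gam_variants: tuple[str, ...] = ("1", "2", "3", "4", "3A", "4A")
    te_basis: int = 8                 # marginal basis size of te(hour, doy)
    s_basis: int = 10                 # basis size of univariate smooths
    temporal_hour_step: int = 1       # fit temporal models on every k-th hour

    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        self.windows_m = tuple(float(w) for w in self.windows_m)
        self.gam_variants = tuple(str(v) for v in self.gam_variants)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)

    def config_hash(self) -> str:
        """Short stable digest of the analysis-relevant configuration.

        Filesystem paths are excluded so the same analysis written to two
        directories carries the same hash.
        """
        d = dataclasses.asdict(self)
        for key in ("out_dir", "sensors_dir", "rasters_dir", "sites_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_toml(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = SimConfig(**raw.pop("sim", {}))
    return PipelineConfig(sim=sim, **raw)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the resolved config as TOML (flat tables only)."""
    lines = []
    d = dataclasses.asdict(cfg)
    sim = d.pop("sim")
    for k, v in d.items():
        if v is None:
            continue
        lines.append(f"{k} = {_toml_value(v)}")
    lines.append("")
    lines.append("[sim]")
    for k, v in sim.items():
        lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")
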