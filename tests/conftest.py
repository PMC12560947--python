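import numpy as np
import pandas as pd
import pytest

from microheat.config import PipelineConfig, SimConfig
from microheat.synthetic import (
    generate_landcover,
    generate_sensor_series,
    generate_sites,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A compact full-year network: 9 sites over 9 zones on a 32-cell grid."""
    return SimConfig(n_sites=9, n_zones=9, grid_size=32, seed=7)


@pytest.fixture(scope="session")
def small_network(small_cfg):
    """Landscape, sites and complete (gap-free) paired series."""
    cfg = SimConfig(**{**small_cfg.__dict__, "gap_fraction": 0.0})
    lc = generate_landcover(cfg)
    sites = generate_sites(cfg, lc)
    series = generate_sensor_series(cfg, sites, lc)
    return cfg, lc, sites, series


@pytest.fixture(scope="session")
def smoke_pipeline_cfg(tmp_path_factory) -> PipelineConfig:
    """Reduced pipeline settings for end-to-end smoke runs."""
    out = tmp_path_factory.mktemp("run")
    return PipelineConfig(
        out_dir=str(out),
        seed=11,
        temporal_hour_step=4,
        s_basis=6,
        sim=SimConfig(n_sites=12, n_zones=6, grid_size=40, seed=11),
    )


@pytest.fixture()
def hourly_index():
    def make(start="2023-05-01", hours=48):
        return pd.date_range(start, periods=hours, freq="h")

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
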