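"""Generator properties: determinism, programmed structure, gap injection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from microheat.config import SimConfig
from microheat.landcover import focal_summary
from microheat.synthetic import (
    generate_landcover,
    generate_sensor_series,
    generate_sites,
    inject_gaps,
)


class TestLandcover:
    def test_deterministic(self, small_cfg):
        a = generate_landcover(small_cfg)
        b = generate_landcover(small_cfg)
        np.testing.assert_array_equal(a.building_volume.data,
                                      b.building_volume.data)
        for mk in a.months:
            np.testing.assert_array_equal(a.ndvi[mk].data, b.ndvi[mk].data)

    def test_noiseless_volume_decreases_radially(self):
        cfg = SimConfig(grid_size=32, noise_sd=0.0, seed=3)
        lc = generate_landcover(cfg)
        xs, ys = lc.grid.cell_centers()
        c = cfg.cell_size * cfg.grid_size / 2
        r = np.hypot(xs - c, ys - c).ravel()
        v = lc.building_volume.data.ravel()
        land = v > 0  # river/pond cells are zeroed
        order = np.argsort(r[land])
        rs, vs = r[land][order], v[land][order]
        distinct = np.diff(rs) > 1e-9
        assert np.all(np.diff(vs)[distinct] < 0)

    def test_volume_ndvi_strongly_anticorrelated_at_sites(self):
        cfg = SimConfig(seed=1)
        lc = generate_landcover(cfg)
        sites = generate_sites(cfg, lc)
        b = lc.building_volume.data[sites.row, sites.col]
        n = lc.ndvi_base.data[sites.row, sites.col]
        assert spearmanr(b, n).statistic <= -0.6

    def test_riverside_water_fraction_exceeds_central(self, small_network):
        cfg, lc, sites, _ = small_network
        water = next(iter(lc.water.values()))
        riv_rows, riv_cols = np.nonzero(water.data)
        i = len(riv_rows) // 2
        x = lc.grid.xll + (riv_cols[i] + 0.5) * lc.grid.cellsize
        y = lc.grid.yll + (lc.grid.nrows - riv_rows[i] - 0.5) * lc.grid.cellsize
        riverside = focal_summary(water, x, y, 100.0)
        dry = np.argwhere(water.data == 0)
        # a land cell far from any water cell
        best, best_d = None, -1
        wset = np.argwhere(water.data == 1)
        for r, c in dry[:: max(1, len(dry) // 200)]:
            d = np.min(np.hypot(wset[:, 0] - r, wset[:, 1] - c))
            if d > best_d:
                best_d, best = d, (r, c)
        bx = lc.grid.xll + (best[1] + 0.5) * lc.grid.cellsize
        by = lc.grid.yll + (lc.grid.nrows - best[0] - 0.5) * lc.grid.cellsize
        assert riverside > focal_summary(water, bx, by, 100.0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_size"):
            generate_landcover(SimConfig(grid_size=16))

    def test_index_bounds(self, small_network):
        _, lc, _, _ = small_network
        for mk in lc.months:
            assert lc.ndvi[mk].data.min() >= -1 and lc.ndvi[mk].data.max() <= 1
            assert lc.albedo[mk].data.min() >= 0 and lc.albedo[mk].data.max() <= 1
            assert set(np.unique(lc.water[mk].data)) <= {0.0, 1.0}


class TestSites:
    @pytest.mark.parametrize("n_sites,n_zones,per_zone", [(9, 9, 1), (45, 9, 5)])
    def test_round_robin_stratification(self, n_sites, n_zones, per_zone):
        cfg = SimConfig(n_sites=n_sites, n_zones=n_zones, grid_size=48, seed=2)
        lc = generate_landcover(cfg)
        sites = generate_sites(cfg, lc)
        counts = sites["zone"].value_counts()
        assert len(counts) == n_zones
        assert (counts == per_zone).all()

    def test_no_shared_cells_and_deterministic(self, small_cfg):
        lc = generate_landcover(small_cfg)
        a = generate_sites(small_cfg, lc)
        b = generate_sites(small_cfg, lc)
        pd.testing.assert_frame_equal(a, b)
        assert not a.duplicated(subset=["row", "col"]).any()

    def test_impossible_placement_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=5, n_zones=9)


class TestSensorSeries:
    def test_identity_filter_makes_indoor_equal_outdoor(self):
        cfg = SimConfig(
            n_sites=9, n_zones=9, grid_size=32, seed=5, noise_sd=0.0,
            indoor_damping=1.0, indoor_lag=0, indoor_offset=0.0,
            indoor_effect_scale=1.0,
        )
        lc = generate_landcover(cfg)
        sites = generate_sites(cfg, lc)
        series = generate_sensor_series(cfg, sites, lc)
        by_site = {}
        for s in series:
            by_site.setdefault(s.site_id, {})[s.location] = s
        for members in by_site.values():
            np.testing.assert_allclose(
                members["indoor"].data["T"], members["outdoor"].data["T"],
                atol=1e-10,
            )

    def test_diurnal_contrast_matches_observed_pattern(self, small_network):
        # indoors warmer at night, cooler in the afternoon (outside monsoon)
        _, _, _, series = small_network
        by_site = {}
        for s in series:
            by_site.setdefault(s.site_id, {})[s.location] = s
        diffs = []
        for members in by_site.values():
            diffs.append(members["indoor"].data["T"] - members["outdoor"].data["T"])
        d = pd.concat(diffs)
        hour, month = d.index.hour, d.index.month
        nonmon = ~np.isin(month, (7, 8, 9))
        assert d[(hour >= 12) & (hour <= 18) & nonmon].mean() < 0
        assert d[((hour >= 22) | (hour <= 6)) & nonmon].mean() > 0

    def test_monsoon_rh_boost_at_every_site(self, small_network):
        _, _, _, series = small_network
        for s in series:
            rh = s.data["RH"]
            m = rh.index.month
            monsoon = rh[np.isin(m, (7, 8, 9))].mean()
            assert monsoon > rh[m == 6].mean()
            assert monsoon > rh[m == 10].mean()

    def test_deterministic(self, small_cfg):
        lc = generate_landcover(small_cfg)
        sites = generate_sites(small_cfg, lc)
        a = generate_sensor_series(small_cfg, sites, lc)
        b = generate_sensor_series(small_cfg, sites, lc)
        for sa, sb in zip(a, b):
            pd.testing.assert_frame_equal(sa.data, sb.data)


class TestInjectGaps:
    def test_zero_fraction_is_identity(self, small_network):
        _, _, _, series = small_network
        out = inject_gaps(series[0], 0.0, seed=1)
        pd.testing.assert_frame_equal(
            out.data[["T", "RH", "flag"]], series[0].data[["T", "RH", "flag"]]
        )

    def test_realized_fraction_near_target(self, small_network):
        _, _, _, series = small_network
        out = inject_gaps(series[0], 0.083, seed=9)
        frac = (out.data["flag"] == "missing").mean()
        assert abs(frac - 0.083) <= 0.01

    def test_same_seed_same_gaps_and_truth_conserved(self, small_network):
        _, _, _, series = small_network
        a = inject_gaps(series[1], 0.1, seed=4)
        b = inject_gaps(series[1], 0.1, seed=4)
        pd.testing.assert_frame_equal(a.data, b.data)
        kept = a.data["flag"] != "missing"
        np.testing.assert_array_equal(
            a.data.loc[kept, "T"], series[1].data.loc[kept, "T"]
        )
        np.testing.assert_array_equal(a.data["T_true"], series[1].data["T"])

    def test_rejects_half_or_more(self, small_network):
        _, _, _, series = small_network
        with pytest.raises(ValueError):
            inject_gaps(series[0], 0.5, seed=1)
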