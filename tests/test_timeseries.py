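"""Aggregation, gap handling, imputation, and temporal summaries."""

import numpy as np
import pandas as pd
import pytest

from microheat import timeseries as ts
from microheat.config import SimConfig
from microheat.synthetic import (
    SensorSeries,
    generate_landcover,
    generate_sensor_series,
    generate_sites,
    inject_gaps,
)


def _raw(records):
    return pd.DataFrame(
        [{"site_id": "S01", "location": "outdoor", "timestamp": t,
          "T_c": v, "RH_pct": rh} for t, v, rh in records]
    )


class TestHourlyAggregate:
    def test_mean_of_two_halfhours_is_observed(self):
        s = ts.hourly_aggregate(_raw([
            ("2023-05-01T10:00:00", 30.0, 50.0),
            ("2023-05-01T10:30:00", 31.0, 52.0),
        ]))
        assert s.data["T"].iloc[0] == pytest.approx(30.5)
        assert s.data["RH"].iloc[0] == pytest.approx(51.0)
        assert s.data["flag"].iloc[0] == "observed"

    def test_singleton_is_partial(self):
        s = ts.hourly_aggregate(_raw([
            ("2023-05-01T10:00:00", 28.4, 60.0),
            ("2023-05-01T10:30:00", 28.4, 60.0),
            ("2023-05-01T11:00:00", 29.0, 61.0),
        ]))
        assert s.data["T"].iloc[1] == pytest.approx(29.0)
        assert s.data["flag"].iloc[1] == "partial"

    def test_empty_hour_is_missing_and_no_hours_invented(self):
        s = ts.hourly_aggregate(_raw([
            ("2023-05-01T10:00:00", 30.0, 50.0),
            ("2023-05-01T10:30:00", 30.0, 50.0),
            ("2023-05-01T13:00:00", 32.0, 45.0),
            ("2023-05-01T13:30:00", 32.0, 45.0),
        ]))
        # exactly the clock hours 10..13 are present
        assert list(s.data.index.hour) == [10, 11, 12, 13]
        assert list(s.data["flag"]) == ["observed", "missing", "missing",
                                        "observed"]
        assert s.data["T"].isna().tolist() == [False, True, True, False]

    def test_bad_rows_reported(self):
        with pytest.raises(ValueError, match="unparseable"):
            ts.hourly_aggregate(_raw([("not-a-time", 30.0, 50.0)]))
        with pytest.raises(ValueError, match="RH"):
            ts.hourly_aggregate(_raw([("2023-05-01T10:00:00", 30.0, 140.0)]))


class TestDetectGaps:
    def test_complete_series_has_no_gaps(self, small_network):
        _, _, _, series = small_network
        gaps = ts.detect_gaps(series[0])
        assert gaps.empty and gaps.attrs["gap_fraction"] == 0.0

    def test_single_hole_reported_once(self, hourly_index):
        idx = hourly_index(hours=48)
        df = pd.DataFrame({"T": 25.0, "RH": 50.0, "flag": "observed"}, index=idx)
        df.iloc[10:16, df.columns.get_loc("flag")] = "missing"
        gaps = ts.detect_gaps(SensorSeries("S01", "outdoor", df))
        assert len(gaps) == 1
        assert gaps["length_h"].iloc[0] == 6

    def test_fraction_matches_injection_target(self, small_network):
        _, _, _, series = small_network
        gappy = inject_gaps(series[2], 0.083, seed=21)
        gaps = ts.detect_gaps(gappy)
        assert abs(gaps.attrs["gap_fraction"] - 0.083) <= 0.01


class TestImputeGaps:
    def _series_pair(self, hours=24 * 40, offset=0.0, seed=1):
        idx = pd.date_range("2023-05-01", periods=hours, freq="h")
        rng = np.random.default_rng(seed)
        base = 28 + 5 * np.sin(2 * np.pi * np.arange(hours) / 24)
        base = base + 0.2 * rng.standard_normal(hours)
        rh = np.clip(55 - 2 * np.sin(2 * np.pi * np.arange(hours) / 24), 5, 99)
        target = SensorSeries("S01", "outdoor", pd.DataFrame(
            {"T": base, "RH": rh, "flag": "observed"}, index=idx))
        donor = SensorSeries("S02", "outdoor", pd.DataFrame(
            {"T": base + offset, "RH": rh, "flag": "observed"}, index=idx))
        return target, donor

    def test_identical_donor_recovers_exactly(self):
        target, donor = self._series_pair()
        gappy = inject_gaps(target, 0.05, seed=2)
        filled = ts.impute_gaps(gappy, [donor])
        m = filled.data["flag"] == "imputed"
        assert m.any()
        np.testing.assert_allclose(
            filled.data.loc[m, "T"], filled.data.loc[m, "T_true"], atol=1e-8
        )

    def test_offset_donor_calibrated_away(self):
        target, donor = self._series_pair(offset=3.5)
        gappy = inject_gaps(target, 0.05, seed=3)
        filled = ts.impute_gaps(gappy, [donor])
        m = filled.data["flag"] == "imputed"
        err = filled.data.loc[m, "T"] - filled.data.loc[m, "T_true"]
        assert np.abs(err).max() < 0.5

    def test_constant_donor_excluded(self):
        target, donor = self._series_pair()
        donor.data["T"] = 25.0
        donor.data["RH"] = 50.0
        gappy = inject_gaps(target, 0.05, seed=4)
        filled = ts.impute_gaps(gappy, [donor])
        assert (filled.data["flag"] == "imputed").sum() == 0
        assert filled.data.attrs["unfilled"] > 0

    def test_no_donor_leaves_gap_missing(self):
        target, _ = self._series_pair()
        gappy = inject_gaps(target, 0.05, seed=5)
        filled = ts.impute_gaps(gappy, [])
        assert (filled.data["flag"] == "missing").sum() > 0
        assert filled.data.attrs["unfilled"] > 0

    def test_network_imputation_rmse_below_noise_ceiling(self):
        # one seed of the paper-scale recovery check (seeds 1-5 live in the
        # acceptance suite): bursty 8.3 % gaps, donor network of 8 sites
        cfg = SimConfig(n_sites=9, n_zones=9, grid_size=32, seed=31)
        lc = generate_landcover(cfg)
        sites = generate_sites(cfg, lc)
        series = [s for s in generate_sensor_series(cfg, sites, lc)
                  if s.location == "outdoor"]
        gappy = [inject_gaps(s, 0.083, seed=100 + i)
                 for i, s in enumerate(series)]
        errs = []
        for i, s in enumerate(gappy):
            donors = [d for j, d in enumerate(gappy) if j != i]
            filled = ts.impute_gaps(s, donors)
            m = filled.data["flag"] == "imputed"
            errs.append((filled.data.loc[m, "T"]
                         - filled.data.loc[m, "T_true"]).to_numpy())
        e = np.concatenate(errs)
        assert np.sqrt(np.mean(e ** 2)) <= 1.5 * cfg.noise_sd


class TestDailyExtremes:
    def _const_day(self, value=25.0, hours=24):
        idx = pd.date_range("2023-06-01", periods=hours, freq="h")
        df = pd.DataFrame({"T": value, "RH": 50.0, "flag": "observed"},
                          index=idx)
        return SensorSeries("S01", "outdoor", df)

    def test_constant_day(self):
        out = ts.daily_extremes(self._const_day())
        assert out["min_T"].iloc[0] == out["max_T"].iloc[0] == 25.0

    def test_sampled_sinusoid_extremes(self):
        idx = pd.date_range("2023-06-01", periods=24, freq="h")
        t = 30 + 5 * np.sin(2 * np.pi * (np.arange(24) / 24))
        s = SensorSeries("S01", "outdoor", pd.DataFrame(
            {"T": t, "RH": 50.0, "flag": "observed"}, index=idx))
        out = ts.daily_extremes(s)
        assert out["min_T"].iloc[0] == pytest.approx(25.0, abs=0.1)
        assert out["max_T"].iloc[0] == pytest.approx(35.0, abs=0.1)

    def test_short_day_dropped(self):
        s = self._const_day(hours=12)
        assert ts.daily_extremes(s).empty

    def test_exclude_imputed_mode(self):
        s = self._const_day()
        s.data.iloc[:10, s.data.columns.get_loc("flag")] = "imputed"
        assert len(ts.daily_extremes(s, exclude_imputed=False)) == 1
        assert ts.daily_extremes(s, exclude_imputed=True).empty


class TestSeasonalSummary:
    def test_season_mapping_is_total_and_disjoint(self):
        assert set(ts.SEASON_OF_MONTH) == set(range(1, 13))
        assert set(ts.SEASON_OF_MONTH.values()) == set(ts.SEASONS)

    def test_monthly_means_average_into_season(self):
        days = pd.date_range("2023-01-01", "2023-03-31", freq="D")
        vals = np.where(days.month == 1, 2.0,
                        np.where(days.month == 2, 4.0, 6.0))
        daily = pd.DataFrame(
            {"min_T": vals, "max_T": vals + 10,
             "min_Tw": vals - 1, "max_Tw": vals + 9}, index=days)
        out = ts.seasonal_summary(daily, "S01", "outdoor")
        row = out[out["season"] == "cold_dry"].iloc[0]
        assert row["min_T"] == pytest.approx(4.0)
        assert row["max_T"] == pytest.approx(14.0)

    def test_min_never_exceeds_max(self, small_network):
        _, _, _, series = small_network
        s = ts.add_wet_bulb(series[0].copy())
        out = ts.seasonal_summary(ts.daily_extremes(s), s.site_id, s.location)
        assert (out["min_T"] <= out["max_T"]).all()
        assert (out["min_Tw"] <= out["max_Tw"]).all()

    def test_monsoon_wet_bulb_minimum_exceeds_hot_dry(self, small_network):
        # the monsoon humidity regime pushes nighttime wet-bulb up even
        # though dry-bulb peaks pre-monsoon
        _, _, _, series = small_network
        for s in series[:6]:
            s2 = ts.add_wet_bulb(s.copy())
            out = ts.seasonal_summary(ts.daily_extremes(s2), s.site_id,
                                      s.location).set_index("season")
            assert out.loc["monsoon", "min_Tw"] > out.loc["hot_dry", "min_Tw"]

    def test_empty_season_omitted_and_reported(self):
        days = pd.date_range("2023-01-01", "2023-02-28", freq="D")
        daily = pd.DataFrame(
            {"min_T": 10.0, "max_T": 20.0, "min_Tw": 8.0, "max_Tw": 15.0},
            index=days)
        out = ts.seasonal_summary(daily, "S01", "indoor")
        assert list(out["season"]) == ["cold_dry"]
        assert set(out.attrs["omitted_seasons"]) == {"hot_dry", "monsoon", "wet"}


class TestDiffSurface:
    def _pair(self, delta=0.0):
        idx = pd.date_range("2023-01-01", periods=24 * 365, freq="h")
        t = 25 + 4 * np.sin(2 * np.pi * np.arange(len(idx)) / 24)
        base = pd.DataFrame({"T": t, "RH": 50.0, "flag": "observed"}, index=idx)
        outdoor = SensorSeries("S01", "outdoor", base)
        indoor = SensorSeries("S01", "indoor", base.assign(T=t + delta))
        return indoor, outdoor

    def test_identical_pair_gives_zero_surface(self):
        surf = ts.diff_surface([self._pair(0.0)])
        assert surf.shape == (12, 24)
        np.testing.assert_allclose(surf.to_numpy(), 0.0, atol=1e-12)

    def test_constant_offset_recovered_everywhere(self):
        surf = ts.diff_surface([self._pair(2.0)])
        np.testing.assert_allclose(surf.to_numpy(), 2.0, atol=1e-12)

    def test_synthetic_pattern_night_warm_afternoon_cool(self, small_network):
        _, _, _, series = small_network
        for s in series:
            ts.add_wet_bulb(s)
        by_site = {}
        for s in series:
            by_site.setdefault(s.site_id, {})[s.location] = s
        pairs = [(m["indoor"], m["outdoor"]) for m in by_site.values()]
        surf = ts.diff_surface(pairs, "T")
        nonmon = [m for m in range(1, 13) if m not in (7, 8, 9)]
        assert (surf.loc[nonmon, 2] > 0).all()
        assert (surf.loc[nonmon, 15] < 0).all()

    def test_mismatched_pair_rejected(self):
        indoor, outdoor = self._pair()
        other = SensorSeries("S02", "outdoor", outdoor.data)
        with pytest.raises(ValueError):
            ts.diff_surface([(indoor, other)])
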