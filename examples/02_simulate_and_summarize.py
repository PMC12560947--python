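"""Simulate a paired sensor network and summarize its temporal structure.

Generates a compact synthetic city (9 dwellings, one year of paired
hourly indoor/outdoor loggers), derives wet-bulb temperature, and prints
the two headline temporal summaries: seasonal extremes for one site and
the indoor-outdoor difference at night vs afternoon.
"""

import numpy as np

from microheat import SimConfig, generate_landcover, generate_sensor_series, \
    generate_sites
from microheat.timeseries import add_wet_bulb, daily_extremes, diff_surface, \
    seasonal_summary

cfg = SimConfig(n_sites=9, n_zones=9, grid_size=32, seed=42, gap_fraction=0.0)
lc = generate_landcover(cfg)
sites = generate_sites(cfg, lc)
series = generate_sensor_series(cfg, sites, lc)
for s in series:
    add_wet_bulb(s)

s0 = next(s for s in series if s.location == "outdoor")
summary = seasonal_summary(daily_extremes(s0), s0.site_id, s0.location)
print(f"seasonal summary, site {s0.site_id} (outdoor):")
print(summary.round(2).to_string(index=False))

by_site = {}
for s in series:
    by_site.setdefault(s.site_id, {})[s.location] = s
pairs = [(m["indoor"], m["outdoor"]) for m in by_site.values()]
surf = diff_surface(pairs, "T")
nonmon = [m for m in range(1, 13) if m not in (7, 8, 9)]
print()
print(f"mean indoor-outdoor T at 02:00 (non-monsoon): "
      f"{surf.loc[nonmon, 2].mean():+.2f} degC")
print(f"mean indoor-outdoor T at 15:00 (non-monsoon): "
      f"{surf.loc[nonmon, 15].mean():+.2f} degC")
print()
print("Indoors stays warmer through the night (thermal mass + insulation)")
print("and cooler through the afternoon (damped diurnal cycle); the")
print("monsoon wet-bulb minimum exceeds the hot-dry one:")
row = summary.set_index("season")
print(f"  min Tw monsoon {row.loc['monsoon', 'min_Tw']:.1f} degC vs "
      f"hot_dry {row.loc['hot_dry', 'min_Tw']:.1f} degC")
assert np.isfinite(surf.to_numpy()).all()
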