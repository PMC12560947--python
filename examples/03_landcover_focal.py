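"""Spectral indices and multi-scale focal statistics around sensors.

Shows the index layer derivations (NDVI, Liang broadband albedo, MNDWI
water mask) on toy reflectances, then summarizes the synthetic city's
building volume around two contrasting sites at the four focal windows.
"""

import numpy as np

from microheat import SimConfig, generate_landcover, generate_sites
from microheat.landcover import broadband_albedo, focal_summary, ndvi, \
    water_mask

# index arithmetic on a toy pixel
print("NDVI(nir=0.5, red=0.1)      =", round(ndvi(0.5, 0.1), 4))
print("albedo(flat spectrum 0.5)   =",
      round(broadband_albedo(0.5, 0.5, 0.5, 0.5, 0.5), 4))
print("water(green=0.30, swir=0.10) ->", water_mask(0.30, 0.10),
      " (MNDWI = 0.5 > 0.05)")

cfg = SimConfig(n_sites=9, n_zones=9, grid_size=48, seed=3)
lc = generate_landcover(cfg)
sites = generate_sites(cfg, lc)

# most central vs most peripheral site
c = cfg.cell_size * cfg.grid_size / 2
d = np.hypot(sites.x - c, sites.y - c)
central = sites.iloc[int(d.idxmin())]
rim = sites.iloc[int(d.idxmax())]

print()
print("building volume (m^3/cell) by focal window radius:")
print(f"{'window':>8s} {'central site':>14s} {'peripheral site':>16s}")
for w in (50, 100, 500, 1000):
    bc = focal_summary(lc.building_volume, central.x, central.y, w)
    br = focal_summary(lc.building_volume, rim.x, rim.y, w)
    print(f"{w:>6d} m {bc:>14.0f} {br:>16.0f}")
print()
print("The urban core carries several times the built volume of the rim;")
print("larger windows smooth the contrast toward the city-wide mean.")
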