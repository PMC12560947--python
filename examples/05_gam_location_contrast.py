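"""Do indoor and outdoor microclimates follow distinct patterns?

Fits the four additive models on one synthetic city and prints the
comparison tables: Model 1 vs 2 (hourly temperature as a cyclic tensor
smooth of hour and day-of-year, pooled vs split by location) and Model 3
vs 4 (seasonal minima as smooths of land cover, pooled vs split).
Negative AIC change means the location-split model wins.
"""

from microheat import gam
from microheat.config import SimConfig
from microheat.evaluation import landcover_analysis
from microheat.pipeline import _temporal_frame, spatial_model_frame

sim = SimConfig(n_sites=16, n_zones=8, grid_size=48, seed=2, gap_fraction=0.0)
lc, sites, series, summaries, features, corr, selection = \
    landcover_analysis(seed=2, sim=sim)

tdf = _temporal_frame(series[:8], step=3)
f1 = gam.fit_temporal(tdf, variant="1")
f2 = gam.fit_temporal(tdf, variant="2")
c12 = gam.compare(f1, f2)
print("temporal models (hourly T, n = {:,}):".format(f1.n))
print(f"  Model 1 pooled : adj R2 {f1.adj_r2:.3f}  AIC {f1.aic:,.0f}")
print(f"  Model 2 split  : adj R2 {f2.adj_r2:.3f}  AIC {f2.aic:,.0f}")
print(f"  change in AIC  : {c12.delta_aic:,.0f}   p = {c12.p:.2e}")

frame = spatial_model_frame(summaries, features, selection, "min_T")
f3 = gam.fit_spatial(frame, response="min_T", variant="3")
f4 = gam.fit_spatial(frame, response="min_T", variant="4")
c34 = gam.compare(f3, f4)
print()
print(f"spatial models (seasonal min T, n = {f3.n}):")
print(f"  Model 3 pooled : adj R2 {f3.adj_r2:.3f}  AIC {f3.aic:.1f}")
print(f"  Model 4 split  : adj R2 {f4.adj_r2:.3f}  AIC {f4.aic:.1f}")
print(f"  change in AIC  : {c34.delta_aic:.1f}   p = {c34.p:.2e}")
print()
print("The generator gives indoor locations damped dynamics and half-size")
print("land-cover effects, so the location-split models should - and do -")
print("win decisively on both axes.")
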