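# medsupply

Spatio-temporal disparity analysis of healthcare-service supply across a
panel of cities.

Regional health planning repeatedly asks the same three questions of a
city-year panel: *how unequal* is the supply of healthcare services across
cities, *how is that inequality arranged in space*, and *which socio-economic
drivers push it where*.  `medsupply` implements the full workflow as a
tested Python library and CLI:

1. **Composite supply index** — four per-capita indicators (healthcare
   institutions, beds, doctors, health expenditure per resident) are pooled
   min-max normalized and summed with equal weights, giving an index in
   [0, 4].  Cities are classified into a four-way typology by the geometric
   mean of their index over years (high vs low, threshold 1.27) and its
   temporal coefficient of variation (equal vs unequal, threshold 0.32).
2. **Distribution dynamics** — per-year Gaussian kernel densities
   f(x) = (1/nh) Σᵢ φ((x−xᵢ)/h), coefficient of variation, and the Gini
   coefficient G = ΣᵢΣⱼ|xᵢ−xⱼ| / (2n²x̄).
3. **Spatial association** — global Moran's I with normal-approximation
   (randomization variance) or permutation inference, local Moran
   Iᵢ = zᵢ Σⱼ wᵢⱼ zⱼ with conditional-permutation p-values, and
   HH/LL/LH/HL Moran-quadrant shares; spatial weights by queen contiguity
   (polygons) or symmetrized k-nearest neighbors, with GAL export.
4. **Dynamic-LISA time paths** — each city's year-by-year trajectory
   through the Moran scatterplot, summarized by relative length
   Ñᵢ = N·lenᵢ/Σⱼlenⱼ and curvature Dᵢ = lenᵢ / ‖L_{i,T} − L_{i,1}‖.
5. **GTWR** — geographically and temporally weighted regression
   yᵢ = β₀(uᵢ,vᵢ,tᵢ) + Σₖ βₖ(uᵢ,vᵢ,tᵢ)xᵢₖ + εᵢ, fit by local weighted
   least squares with Gaussian kernel weights
   wᵢⱼ = exp(−[(Δu)²+(Δv)²+τ(Δt)²]/h²), leave-one-out CV bandwidth
   selection, local t-values, and coefficient-surface summaries.  The
   estimator follows the scikit-learn protocol (`GTWR().fit(X, y,
   coords=...)`) and composes with sklearn tooling.

Because real city panels of this kind are typically not redistributable,
the package ships a first-class synthetic generator
(`medsupply.simulate`) that emulates the study design — 41 cities × 13
years, spatially autocorrelated covariates, space-time varying coefficient
surfaces, positive per-capita indicators — and returns the full ground
truth, so every stage can be validated against known answers.

## Worked example

```python
from medsupply import (SimulationConfig, generate_panel, composite_index,
                       classify_cities, knn_weights, global_moran, fit_gtwr)
from medsupply.dynamics import inequality_series
from medsupply.simulate import COVARIATES

panel, truth = generate_panel(SimulationConfig(seed=1))   # 41 x 13 panel
panel = composite_index(panel)

print(inequality_series(panel).iloc[[0, -1]].round(4).to_string(index=False))
#  year     cv   gini
#  2007 0.5853 0.3264
#  2019 0.5234 0.2904

print(classify_cities(panel)["type_label"].value_counts().to_dict())
# {'low-unequal': 30, 'low-equal': 5, 'high-unequal': 4, 'high-equal': 2}

geom = panel.drop_duplicates("city_id").sort_values("city_id")
W = knn_weights(geom[["u", "v"]].to_numpy(), ids=geom["city_id"].tolist())
vals = panel[panel.year == 2019].sort_values("city_id")["supply_index"]
res = global_moran(vals.to_numpy(), W)
print(f"Moran I(2019) = {res.I:.4f}, z = {res.z:.2f}, p = {res.p:.4f}")
# Moran I(2019) = 0.2777, z = 3.21, p = 0.0007

model = fit_gtwr(panel, COVARIATES, bandwidth=None, tau=1.0)
print(f"GTWR: h* = {model.bandwidth_}, adj R2 = {model.adj_r2_:.4f}")
# GTWR: h* = 0.15, adj R2 = 0.9499
```

Cross-city inequality (CV, Gini) declines over the simulated period while
the index distribution shifts upward; the index is significantly positively
spatially autocorrelated (neighboring cities cluster at similar supply
levels); and the CV-selected GTWR bandwidth of 0.15 — a fraction of the
unit-square domain — indicates strongly local covariate effects.

The same pipeline runs from the shell:

```bash
medsupply simulate --n-cities 41 --n-years 13 --seed 1 --out panel.csv
medsupply index panel.csv
medsupply run-all --seed 1 --outdir run/
```

`run-all` writes per-stage CSV tables (typology, inequality series, Moran
tables, LISA quadrants, time-path geometry, GTWR coefficients and
diagnostics), a GAL weights file, and a JSON manifest sufficient to
reproduce the run bit-identically.

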