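# Methods

This note documents the statistical procedures implemented in `medsupply`,
the defaults chosen where the methodology is genuinely open, and what the
synthetic validation does and does not demonstrate.

## Composite supply index

Each of the four raw indicators (healthcare institutions, beds, doctors,
health expenditure) is divided by resident population, min-max normalized,
and the four normalized values are summed with equal (unit) weights, so the
index ranges over [0, 4].

**Normalization scope.** Normalization is *pooled* over all city-years, not
per-year.  Cross-year statements — a density peak moving from one index
level to a higher one, a single high/low threshold applied to a multi-year
geometric mean — only make sense on a common scale, which per-year
normalization would destroy.  A per-year mode is deliberately not offered.

**Typology.** Per city, the geometric mean of the index over years measures
level (threshold 1.27, `>=` is high) and the temporal coefficient of
variation measures inter-annual stability (threshold 0.32, `<=` is equal).
Both boundary conventions are deterministic and documented; the CV uses the
sample (n−1) standard deviation here and everywhere else in the package.
The geometric mean requires strictly positive index values; a record that
is the pooled minimum of all four per-capita indicators at once would score
exactly 0, so inputs with such records are rejected with a domain error.

**Deflation.** Currency series can be converted to base-year prices with
`deflate` (output_t = nominal_t · deflator(base)/deflator(t)); it is
optional and applied only to columns the configuration lists, since
deflator series are data-source specific.

## Distribution dynamics

The per-year cross-city density is a Gaussian KDE,
f(x) = (1/nh) Σᵢ φ((x−xᵢ)/h).  The bandwidth default is Silverman's rule
h = 0.9·min(sd, IQR/1.34)·n^(−1/5) with an explicit override; peak
summaries report the argmax over a 512-point grid spanning
[min−4h, max+4h], a range on which the trapezoid mass is 1 to within 1e-3.

Inequality uses the unweighted mean-absolute-difference Gini
G = ΣᵢΣⱼ|xᵢ−xⱼ|/(2n²x̄) (computed via the equivalent sorted-rank identity)
and the CV.  Cities are the unit of analysis; population weighting is
deliberately not applied, consistent with a city-as-unit framing.

## Spatial weights and Moran statistics

Weights default to queen contiguity when polygon geometry is available and
to union-symmetrized k-nearest neighbors (k = 4) on coordinates otherwise;
both are standard for irregular city lattices.  Rows are standardized to
sum to one so the spatial lag is a neighbor average; units without
neighbors make standardization impossible and are reported by name.

Global Moran's I = (n/S₀)·ΣᵢΣⱼwᵢⱼzᵢzⱼ/Σᵢzᵢ² is tested one-sided for
positive autocorrelation either under the normal approximation with the
closed-form randomization variance, or by Monte-Carlo permutation with
p = (#{I_perm ≥ I_obs}+1)/(n_perm+1), n_perm = 999 by default.  Both are
provided because published z-scores on comparable data rarely state which
convention produced them.

Local Moran Iᵢ = zᵢΣⱼwᵢⱼzⱼ uses *population*-sd z-scores so the
decomposition identity (1/n)ΣᵢIᵢ = I is exact.  Quadrants (HH, LL, LH, HL)
are assigned from the signs of (zᵢ, lag); zero is treated as positive — a
deterministic tie rule.  Quadrant shares include every unit regardless of
significance; conditional-permutation p-values (hold unit i fixed, permute
the remaining values into its neighbor slots) are reported separately.

## Dynamic-LISA time paths

Index values are z-standardized per year (cross-sectional, population sd),
so each year's (zᵢₜ, lagᵢₜ) pair lives on the Moran-scatterplot scale; a
pooled standardization would conflate level growth with movement through
the scatterplot.  Per city: relative length Ñᵢ = N·lenᵢ/Σⱼlenⱼ (so
ΣᵢÑᵢ = N exactly) and curvature Dᵢ = lenᵢ/‖L_{i,T}−L_{i,1}‖.

The curvature denominator deserves a prominent flag: defined as the ratio
of total path length to *net start-to-end displacement*, Dᵢ is the standard
trajectory tortuosity — 1 exactly for straight monotone paths, ≥ 1 always
(triangle inequality), larger for volatile local dynamics.  Cities whose
trajectory returns to its starting point have undefined Dᵢ and are reported
as NaN rather than failing the batch; stationary cities get Ñᵢ = 0.

## GTWR

At every observation i, β̂(i) = (XᵀW(i)X)⁻¹XᵀW(i)y with Gaussian kernel
weights wᵢⱼ = exp(−d²ᵢⱼ/h²) over the combined distance
d²ᵢⱼ = (Δu)² + (Δv)² + τ(Δt)².  Only the *ratio* τ of temporal to spatial
scale is identifiable jointly with h, so a single τ is exposed (default
grid {0.25, 0.5, 1, 2, 4}).  Coordinates are normalized to the unit square
and time to [0, 1] by default, making h interpretable as a fraction of the
study domain; the kernel is non-truncated and no adaptive (k-nearest)
bandwidth mode is offered.

Bandwidth selection minimizes leave-one-out CV RSS with the self-weight set
to zero, over the default grid {0.05, 0.1, 0.15, 0.2, 0.3, 0.45, 0.7, 1.0};
grid points where every local fit is singular are marked invalid rather
than fatal.  Effective degrees of freedom use tr(S) (the first-form GWR
convention, not 2tr(S)−tr(SᵀS)): σ̂² = RSS/(nT−tr(S)),
adj R² = 1−(1−R²)(nT−1)/(nT−tr(S)−1).  Local variances are the sandwich
(XᵀWX)⁻¹XᵀW²X(XᵀWX)⁻¹σ̂²; the significance threshold |t| ≥ 1.96
approximates the two-sided 5% level.  Coefficient summaries report annual
means, the share of observations with nonnegative sign (zero counted as
positive so positive + negative = 100), and the share with |t| above the
threshold.

Covariates are z-standardized before fitting (toggleable) so local
coefficient magnitudes are comparable across variables.  Rank-deficient
local designs receive one ridge pass of 1e-8 times the mean normal-matrix
diagonal; persistent singularity raises an error naming the observation.
All local solves are batched with einsum, so a full 41×13 fit including
grid CV takes well under a second.

**Numerical caveat.** Exact recovery of constant coefficients on noiseless
data holds for any bandwidth at which the local design is numerically full
rank; at bandwidths far below the inter-city spacing the kernel leaves
effectively one observation per fit and the local problem degenerates.

## Synthetic data generator

The generator emulates a 41-city × 13-year study panel (defaults, both
configurable): coordinates uniform on the unit square (cities are not a
lattice; a grid layout exists for geometry-sensitive tests), covariates
built by the SAR-style smoother (I−ρW)⁻¹ε with row-standardized 4-NN
weights (ρ = 0.6 by default; invertible for ρ < 1) plus AR(1) temporal
persistence (φ = 0.7), pooled-standardized.  The response is assembled
exactly as intercept-surface + Σ surface·covariate + N(0, 0.1²) noise;
surfaces may be constant, linear in (u, v, t), or Gaussian bumps, and the
default intercept declines along the v axis, producing the north–south
index gradient typical of real supply panels.  Population is log-normal
(sd 0.5); the four raw indicators are positive per-capita values
exp(latent + indicator noise) × population sharing the response as latent,
so the rebuilt composite index correlates with, but does not equal, the
simulated response.  If one record happens to be the pooled minimum of all
four indicators simultaneously (which would put the composite at exactly 0,
outside the geometric-mean domain), the lowest two values of a single
indicator are swapped — a minimal, deterministic non-degeneracy guarantee.

The full ground truth (coefficient surfaces evaluated per record, noise
draws, coordinates) is returned, enabling the reconstruction identity
response − (β₀ + Σβₖxₖ) = ε to machine precision and parameter-recovery
comparisons: on bump-surface panels the GTWR coefficient RMSE against truth
is roughly half the pooled-OLS RMSE, and CV selects a smaller bandwidth for
varying-surface than constant-surface data.

**What the generator does not emulate:** measurement error and revisions in
yearbook statistics, administrative boundary changes, population mobility
between cities, non-Gaussian indicator noise, and real contiguity geometry.
Passing tests therefore certify the *statistical machinery*, not the
substantive conclusions one would draw from any particular real panel.

## Problem sizes used in validation

Unit tests run on panels between 3×2 (hand-checkable oracles) and 41×13
(the emulated study design).  Monte-Carlo checks use 200 replicates for the
spatial-null calibration, 100 paired replicates for the autocorrelation
ordering, 2000 permutations for the Moran null mean, and 20 seeded
replicates for GTWR parameter recovery — sizes at which the full suite
completes in a few seconds while leaving the Monte-Carlo error well below
the effect sizes being detected.

## Known limitations

- Queen contiguity requires polygon geometry; no polygon generator is
  included, so simulated runs default to k-NN weights.
- The permutation p-value granularity is 1/(n_perm+1); with 999
  permutations the smallest attainable p is 0.001.
- GTWR inference is conditional on the selected (h, τ); selection
  uncertainty is not propagated.
- No mixed (partially constant) GTWR, no spatial-autoregressive error
  models, no bivariate or Getis–Ord statistics, and no map rendering —
  coordinates and labels are exported for external GIS tools.
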