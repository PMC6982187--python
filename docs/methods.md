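# Methods

This note documents the models, defaults, numerical choices, and known
limitations of the package, in the spirit of a statistical software
methods appendix.

## The analysis in one paragraph

Each food outlet anchors three active-travel neighborhoods: the network
locations reachable within 0.40 km walking, within 8.04 km bicycling, and
within a walk–ride–walk transit composition (0.40 km walk to a stop,
5.36 km along-route ride, 0.40 km egress walk around every reachable
stop). Within each neighborhood the outlet receives a Revealed
Accessibility Index — an inverse-square distance-decay sum over the
competing outlets located inside the neighborhood, each weighted by its
revenue per square foot (max-normalized) — whose square root is the
regression outcome. Zonal covariates (demographics, environment, urban
morphology) are transferred onto the neighborhoods by areal interpolation
and, for counts, normalized per km² of neighborhood area. Per mode, after
Pearson screening and a VIF filter, three estimators are compared: OLS,
a maximum-likelihood spatial lag model, and GWR; global Moran's I
diagnoses clustering of the outcome and of each model's residuals, and
AICc (with a decisiveness margin of 3) ranks the models.

## Service areas

- Distances are always measured along the network. Outlets snap to the
  nearest edge by perpendicular projection with a 100 m tolerance; reach
  is computed by Dijkstra from the snap point with the source edge split
  there, so partial-edge truncation `reached = budget − distance to the
  entering endpoint` is exact on every edge and no staircase artifact
  appears on long edges.
- The transit composition is walk → single-route ride → walk. Transfers
  between routes are deliberately excluded: only the two distances are
  specified by the study design, not a transfer rule, so the conservative
  single-ride reading is used. If no stop is walkable the transit area
  equals the walk area.
- Polygonization dilates the reached edge portions by 50 m and unions
  them (buffer resolution 32 segments per quadrant, so the end-cap area
  error is below 0.1%). Dilation rather than a convex hull keeps
  unreached gaps out of the polygon — the point of edge-effect control.
  Area is reported in km² from planar geometry; all coordinates are
  planar meters in an abstract projected frame, and no geodesy is used
  anywhere.

## The index

`RAI_j = (m−1)^(−1) Σ_{k≠j} w_k c_jk^(−2)` with competitors restricted,
by default, to outlets whose location lies inside j's mode-specific
service-area polygon (an all-city scope is available by configuration).
Distances `c_jk` are network shortest paths in km between outlet snap
nodes; km units make a 1 km spacing a decay factor of 1, and a global
unit change only rescales the index without affecting standardized model
fits. The floor `min_distance_km = 0.05` bounds the index when outlets
are co-located (c^−2 diverges at 0). An outlet with no competitor in
scope receives RAI = 0 — "no revealed interaction" — rather than an
undefined 0/0; this convention matters because the prefactor divides by
the competitor count. Competitors are all food outlets, both types. The
weight uses the competitor k's revenue per square foot (the subscript in
the definition), not the focal outlet's. Note the formula as defined
*increases* when close, high-weight competitors are present; the package
implements the formula literally and leaves its interpretation to the
analyst.

## Areal interpolation

Extensive attributes transfer as `Σ_z value_z · area(z∩target)/area(z)`
and are then divided by the service-area size in km²; intensive
attributes are area-weighted means and are never densified (dividing a
mean by an area is dimensionally wrong). Intersections are exact polygon
operations, which is why extensive totals are conserved over arbitrary
partitions of the extent to float precision (the pycnophylactic
property), and intensive values are bounded by the min/max of the
intersected zones. A target disjoint from every zone raises an error
instead of silently contributing zero.

## Spatial statistics

Weights are `w_ij = 1/max(d_ij, 1 m)` on Euclidean distances between
outlet points with a zero diagonal — outlet locations, not service-area
centroids. Moran's I uses the analytic null moments; z and p default to
the **normality** assumption, with the randomization variance available
behind a flag (the study reports z-scores against ±1.96 without naming a
variance formula; normality is the documented choice here). Residual
diagnostics standardize the residuals first, which changes nothing
numerically (I is scale-invariant) but keeps reported residual vectors on
a common scale. The residual-Moran normal approximation is adequate from
roughly n ≳ 100; at a few dozen observations it rejects slightly above
the nominal rate because regression residuals are not exchangeable.

## Estimators

**OLS** is statsmodels under a thin Model/Results surface. AICc uses the
Gaussian ML log-likelihood with variance RSS/n and k = p + 1 parameters
(coefficients plus variance), `AICc = AIC + 2k(k+1)/(n−k−1)`.

**Spatial lag (SAR).** `y = ρWy + Xβ + ε` with W row-standardized
inverse distance. The printed model family also carries a lagged-X
(Durbin) term `WXγ`; it is implemented behind a flag defaulting to off
because the study's result tables report no γ estimates. The
concentrated log-likelihood over ρ uses the exact Jacobian
`Σ ln(1 − ρλ_i)` from the eigenvalues of W (real, since the
row-standardized matrix is similar to a symmetric one) and is maximized
by bounded scalar search over the stability interval
(1/λ_min, 1/λ_max); a fixed ρ can be supplied instead, and ρ = 0
reduces the estimator to OLS exactly. Standard errors come from the
classical information matrix of (β, ρ, σ²). The reported SAR R² is a
pseudo-R²: the squared correlation between y and the model-implied
fitted values (I − ρW)⁻¹Xβ̂. AICc counts k = p + 2 (adds ρ).

A caution on identification: with inverse-distance weights over points
scattered uniformly, W is nearly rank-one (every row spreads mass over
everything) and ρ is weakly identified — estimates scatter widely even
when the model is exactly correct. Clustered point patterns, which real
outlet data show (commercial corridors), make W nearly block-local and ρ
well identified; the recovery experiments therefore use the
`clustered_coords` generator (40 cluster centers over a 10 km frame,
30 m within-cluster spread), under which 100 replicates at n = 200
recover ρ = 0.5 to within ±0.05 on average.

**GWR.** At each location i, weighted least squares with Gaussian kernel
`exp(−½(d/h_i)²)`, where `h_i` is the distance to the b-th nearest
neighbor (adaptive bandwidth). b is an integer searched over [p+2, n] by
golden section with a final local scan, minimizing
`AICc = 2n ln σ̂ + n ln 2π + n(n + tr S)/(n − 2 − tr S)`; ties break
toward the larger (smoother) bandwidth. tr S comes from the exact hat
diagonal. Reported per covariate are the min and max of the local
coefficients, matching the result-table layout; a `kernel_scale` factor
can inflate every kernel to approach the global (OLS) limit, which the
tests assert to 1e-4. Adjusted R² uses (n−1)/(n−tr S).

**Comparison.** Lowest AICc wins; "decisively better" requires a margin
of ≥ 3 against every other model. Percent changes in R² and AICc against
the OLS baseline are reported as `100·(local − ols)/|ols|`. Standardized
coefficients are `β_j · sd(x_j)/sd(y)` (intercept undefined). Two-sided
tests with significance stars at 0.1 / 0.05 / 0.01.

## Screening

Pearson correlation with √RAI, two-sided p < 0.05 retains a covariate;
retained sets are harmonized across modes (the union) by default so the
mode tables stay comparable. The pipeline then drops, per mode:
(near-)constant columns — a covariate can be degenerate in one mode only,
e.g. when every bicycling area covers the entire city; the worst-VIF
covariate repeatedly until all VIF < 10; and, if the standardized design
is still numerically fragile (condition number > 1e8), further worst-VIF
columns. Model size is capped at ~n/4 covariates (strongest outcome
correlations kept) to prevent overfitting on small cities. The exposure
indicator (restaurant vs grocer) is always kept.

## The synthetic-city generator

What it emulates: a mid-sized city street grid (8 × 8 km, 400 m spacing,
15% node jitter — planar, connected, controllable density), straight bus
routes along grid rows/columns with ~800 m stop spacing, outlet counts
matching the smaller study city (57 restaurants + 9 grocers by default;
the larger city's 141 + 22 is a config away), lognormal revenue
(median ≈ $490k/yr) and floor area (median ≈ 2400 sq ft), ~100 covariate
zones tiling the extent, and 15 zonal covariates in the three study
categories with means/sds at plausible urban magnitudes. Zone attributes
are Gaussian-kernel-smoothed white noise (a cheap Gaussian-random-field
stand-in) with per-covariate spatial range, optional pairwise
cross-correlation injected at the noise stage, and nonnegativity
clipping. Outlets snap to network nodes at generation time, which makes
downstream snapping unambiguous. Every component (network, transit,
outlets, zones, outcome) draws from its own stream spawned from the
master seed, so changing outlet counts never perturbs the network.

What it does not emulate: real street topology (one-way streets, limited
pedestrian crossings), transit headways or timetables, correlated
revenue–location structure, irregular census geographies, or
measurement error in outlet classification. Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted statistical structure — not that any substantive finding about a
real city would replicate.

`plant_sar_outcome` inverts the spatial lag model exactly —
`y = (I − ρW)⁻¹(Xβ + ε)` — for estimator-recovery experiments, and
rejects ρ outside the stability interval of the weights.

## Numerical choices and degenerate inputs

- Interval bookkeeping merges reached edge portions with a 1 nm slack;
  fractions are capped at 1.
- Distance matrices are symmetrized (averaging float round-off) and
  disconnected pairs carry +inf, excluded from index sums with a warning.
- Zero-variance outcomes make Moran's I and standardization undefined;
  both raise rather than return NaN.
- Exact collinearity reports VIF = +inf; a singular OLS design raises an
  error naming the collinear columns.
- Empty reaches, empty point sets, disjoint interpolation targets, zero
  outlets, and non-positive extents all raise with specific messages.
- Report serialization sorts keys and uses shortest-repr floats, so a
  fixed config + seed reproduces byte-identical output.

## Problem sizes used in tests

Unit and property tests run on compact cities (3–4 km extents, ~30
outlets, ≤ 36 zones) chosen so the full suite exercises every stage —
including two full pipeline runs — in well under a minute of compute,
while the oracle checks (index brute force at 200 outlets, Dijkstra on
10×10 grids, 10,000-permutation Moran null, 100-replicate SAR and GWR
recoveries at n = 200–400) run at the sizes stated in their docstrings.

## Known limitations

- The transit composition ignores transfers and timetables; it is a
  distance catchment, not a travel-time isochrone.
- The SAR pseudo-R² is one of several conventions; comparisons with
  other software should use AICc or the log-likelihood.
- GWR inference is descriptive here: local coefficient ranges are
  reported without local standard errors or multiple-testing control.
- The distance-matrix snap is to the nearest network node (exact for
  generated cities, approximate within the 100 m tolerance otherwise).
- With strongly smoothed zonal fields, interpolated covariates can be
  highly correlated across neighboring service areas; the VIF and
  condition-number guards then legitimately prune the model, and small
  demo cities may end with few covariates.
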