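# Methods

This note documents the models implemented in `landmetab`, the assumptions
and defaults behind them, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the underlying method
left the design open.

## Spatial model

All computation happens on a planar, equal-area coordinate frame. The land
cover is a row-major integer raster (top-left origin, square cells); areas
are cell counts × cell area, with no spherical correction and no
reprojection — inputs are assumed to be already projected.

Analysis units are regular hexagons (flat-top by default, pointy-top
available), generated row-wise from the top-left of the extent and clipped
to it, so interior cells share the exact nominal area (relative tolerance
1e-6) while edge cells are smaller. The number of whole-cell equivalents of
an extent is `ceil(area / cell_area)` — the design figure of 502 units for
1,004,000 ha at 2,000 ha per unit.

A raster cell belongs to the hexagon containing its center; a center on a
shared edge goes to the lower hexagon id. Hexagons are retained when their
valid-data area reaches `min_valid_fraction` (default 0.5) of the polygon
area and they contain at least one valid cell; retained rows of the cover
matrix P_ij are renormalised over valid cells and always sum to 1.

## Heterogeneity (H′)

Normalised Shannon entropy over *habitat categories*, not raw classes:
covers are first grouped via the legend (the default grouping has eight
potential-habitat categories — forest, shrubland, grassland, heterogeneous
crops, sugarcane, pastures, water, rock/sand — plus one "no habitat"
category collecting urban/industrial fabric, degraded land and roads, so
J = 9). `H′ = −Σ p ln p / ln J` is log-base invariant after normalisation
and lies in [0, 1]; J is configurable and reported in run metadata.

## Connectivity (ECI)

For each functional ecological area `b` (seven terrestrial classes —
forest, shrubland, grassland/paramo, agroforestry mosaic, crops, pastures,
sugarcane — plus the hydrological network as its own area):

1. **Friction**: `base_cost / affinity(area(cell), b)` per cell, with
   `base_cost = 1` per cell length. Permeable barrier cells (roads,
   degraded soil) cost `base_cost / barrier_affinity` (default 0.1);
   impermeable barriers (urban fabric) are removed from the graph. Each
   barrier class additionally adds its `impact` to every cell within its
   Euclidean halo radius. The affinity and impact coefficients shipped as
   defaults are placeholders ordered by ecological proximity (water–forest
   0.8, sugarcane ≤ 0.3 with everything); real applications should supply
   expert-derived matrices.
2. **Sources**: all cells of area `b` in patches of at least
   `min_patch_cells` (default 1, 8-connected).
3. **Accumulated cost**: exact multi-source Dijkstra on the 8-connected
   (configurable 4-connected) cell graph; edge weight = mean of the two
   cell frictions × step length (1, or √2 on diagonals). Verified against
   exhaustive path enumeration on small grids.
4. **Transform**: `ECI_b = 10 − 9·[ln(1+X_i)/ln(1+X_t)]³`, decreasing from
   10 at X_i = 0 to 1 at X_i = X_t. The cubed-ratio placement of the
   exponent is the package default; the alternative reading (cube on the
   denominator, i.e. 3·ln(1+X_t)) is selectable per config for sensitivity
   analysis — note it maps X_i = X_t to 7, not 1. `X_t` defaults to the
   grid diagonal (in steps) × the maximum open-cell friction and can be
   overridden by a constant; costs above X_t (including unreachable cells)
   are clamped to X_t with a warning, or rejected in strict mode.
5. **Totals**: per-cell mean over the m areas that have sources; the
   nominal index range is 0–10 but the transform itself spans [1, 10], so a
   min–max rescaled field is emitted alongside the raw one. Hexagon ECI is
   the mean over the hexagon's valid cells.

Because X_t moves with the friction maximum, comparisons across barrier
scenarios should fix X_t (the monotonicity guarantee — more barriers, lower
ECI — holds at fixed X_t; the cost field itself scales exactly linearly
when friction is scaled).

## Metabolism (HANPP)

Per class, in t C/ha/yr: `ΔNPP_Lu = NPP_0 − NPP_act`,
`HANPP = ΔNPP_Lu + NPP_h`, `HANPP% = 100·HANPP/NPP_0`. Harvest above actual
production is rejected at load. ΔNPP_Lu may be negative (irrigated or
fertilised systems out-produce the potential baseline); the raw percent is
preserved in outputs and a [0, 100]-clamped variant feeds the disturbance
composite, with clamping logged per class. NPP is supplied per class
(table); the mixed raster/census provenance of real applications is
emulated by the table route. Hexagon values are P_ij-weighted class values
— convex combinations, so they respect the class min/max.

## Complexity composite (IDC)

`Le = (a·H′ + b·ECI/10)/(a+b)` blends pattern and process; the weights
default to a = b = 1 (the canonical orthogonalisation coefficients of the
original index family are not published), and a data-driven option
equalises the across-hexagon variance of H′ and ECI/10. The pattern term L
is identified with H′ — the only pattern metric the pipeline computes; this
is an explicit assumption. `IDC = Le·(1 − HANPP%/100)` ∈ [0, 1].

Configuration labels: *anthropic* for 0.05 < IDC < 0.3 (the published
band); *natural* for 0.3 ≤ IDC < 0.5 **and** natural covers
(forest/seminatural + water typologies) above 50% of the hexagon; *mosaic*
for IDC ≥ 0.5; otherwise unclassified. The natural band and mosaic
threshold are package defaults, configurable, and validated for
non-overlap. IDC is monotone: non-increasing in HANPP at fixed Le,
non-decreasing in H′ and ECI at fixed HANPP.

## Ecosystem services (ESC, MF)

Expert responses (0–5 Likert; six classes from "not relevant" to "very
high") are arithmetically averaged — all experts weighted equally, no
trimming — into supply and demand matrices over 21 CICES-derived services
in three sections (8 provisioning, 9 regulation & support, 4 cultural).
Capacity per service is supply − demand; per cover, ESC_i is the mean over
the 21 services, which preserves the [−5, 5] scale (a sum variant exists
behind config). Multifunctionality per cover is
`MF_i = 5·(1/3)·Σ_sections (#services with mean supply ≥ threshold)/(#section
services)` with threshold 3 ("medium") — a reconstruction of the verbal
"breadth across categories" definition; threshold and rule variant are
config. Hexagon ESC_j and MF_j are P_ij-weighted sums (the multifunctional
analogue of the capacity equation; the source's printed MF_j equation
repeats the capacity symbol, an evident typo).

## Statistics

Stepwise OLS is bidirectional and deterministic: candidates are scanned in
column order and the single best add/remove move by AIC (BIC or
p-value-threshold stepping with enter 0.05 / remove 0.10 as alternatives)
is taken until no move improves the criterion; a numerically perfect fit
stops the search. Cover proportions sum to one, so the design with an
intercept is collinear by construction; no transformation is applied — the
intercept is kept, selection discards redundant terms, and any residual
rank deficiency is resolved by dropping terms and reported, never silent.
p values are two-sided t tests; the significance flag is p < 0.050 with no
multiple-testing correction (flagged in the report). The report reproduces
the conventional layout: residual quantiles, coefficient block with
significance stars, R², adjusted R², residual standard error, F statistic
with degrees of freedom. The ESC–IDC relationship is a simple OLS line
with R² as squared Pearson correlation.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
geography:

* **Landscape**: a 60×100-cell grid (100 m cells) split into three
  elevation-like column bands — valley (40% of columns, 75% sugarcane with
  urban fabric and pastures), slope (35%, a heterogeneous mix of five
  mosaic classes, pastures, forest, shrubland and paramo), highland (25%,
  forest/paramo/shrubland-dominated) — with one river and two road lines
  rasterised on top. Allocation is a modified-random-clusters scheme: per
  band and class, `round(N^(1−c))` seeded nuclei (c = clustering, default
  0.6) grown round-robin from seeded frontiers until class cell counts
  match the band targets exactly (tolerance 0.5 percentage points);
  clustering 0 degenerates to a cellwise multinomial draw. Every generator
  is a pure function of scenario + seed.
* **NPP tables**: class draws consistent with land-use intensity — natural
  covers NPP_act ≈ NPP_0 and no harvest (HANPP ≈ 0); built fabric
  NPP_act ≈ 0 (HANPP ≈ 100%); sugarcane an irrigation-boosted
  NPP_act = 1.15–1.4 × NPP_0 with 65–80% of it harvested (HANPP ≈ 60%);
  mosaics and pastures intermediate.
* **Expert panel**: 27 experts; each scores the rounded latent
  supply/demand value for every (service, cover), perturbed ±1 with
  probability 0.2 and clipped to 0–5. Latents are section-level constants
  per cover family (natural covers high supply / near-zero demand, urban
  the reverse, mosaics broad intermediate supply).

What passing tests on these data do show: the formulas, aggregation
plumbing, determinism, range invariants, and the qualitative
intensification gradient (valley hexagons score higher HANPP and lower H′,
ECI, IDC and ESC than slope hexagons). What they do not show: agreement
with the real region's class areas, expert matrices or regression
coefficients — the study geodata is not deposited, and the reference
surface-distribution table is the only published input the package can (and
does) reproduce exactly. The real per-cover ESC/MF tables are published
only as images and cannot be used for validation.

## Problem sizes and numerics

Default test-scale sizes — 60×100 cells, 50-ha hexagons (≈ 130 units),
27×21×23 panel, n = 502 synthetic compositions for regression calibration —
were chosen so the full pipeline runs in seconds on one core while keeping
every statistical check well-powered; all scale linearly (cost distance:
O(cells log cells) per functional area). Tolerances: compositions sum to 1
within 1e-9; OLS matches the normal-equation solution to 1e-10 relative;
interior hexagon areas match to 1e-6 relative. Tie-breaks are deterministic
everywhere (edge cells to the lower hexagon id, stepwise candidates in
column order). Degenerate inputs raise typed errors rather than propagate
NaNs (all-nodata rasters, zero-variance regressors, J < 2 categories,
overlapping classification bands, masked-out source sets).

## Known limitations

* No reprojection, vector ingestion or map updating; rasters must share
  one planar equal-area frame.
* Connectivity coefficients are illustrative defaults, not calibrated
  values; corridor delineation and graph-theoretic patch metrics (IIC/PC)
  are out of scope.
* No spatial autocorrelation correction in the regressions — hexagon
  observations are treated as independent, as in the reference analysis;
  coefficients on compositional predictors should be read comparatively,
  not causally.
* HANPP back-calculation from census yields is not implemented; the NPP
  table is the interface.
* The zonation gradient is a one-dimensional band index; no DEM, climate
  or soil forcing is modelled.
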