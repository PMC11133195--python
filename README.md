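# landmetab

Landscape-metabolism assessment of metropolitan green infrastructures.

`landmetab` is a tested, reusable implementation of an integrated
socio-ecological pipeline for metropolitan regions under rapid urbanisation
and agricultural intensification (its reference setting is a tropical Andean
valley: industrial sugarcane monocultures on the flats, smallholder
agroforestry mosaics on the slopes, forest and paramo in the highlands). It
is aimed at landscape ecologists and land-use planners who have a
categorical land-cover map and agricultural production data and want
spatially explicit indicators of landscape functionality and ecosystem
services — without proprietary GIS tooling.

From a land-cover raster, per-class NPP tables and an expert Likert panel,
the pipeline computes, on an equal-area hexagonal grid (study design:
2,000-ha hexagons; 1,004,000 ha ⇒ 502 analysis units):

* **H′ — landscape heterogeneity.** Normalised Shannon entropy over habitat
  categories: `H′ = −Σ p_j ln p_j / ln J ∈ [0, 1]`.
* **ECI — ecological connectivity.** Least accumulated cost `X_i` from the
  nearest source patch of each functional ecological area `b` (friction =
  inverse ecological affinity, plus additive barrier halos; exact Dijkstra
  on the 8-connected cell graph), transformed as
  `ECI_b = 10 − 9·[ln(1+X_i)/ln(1+X_t)]³` and averaged over the `m` areas:
  `ECI = Σ ECI_b / m`.
* **HANPP — human appropriation of net primary production.**
  `ΔNPP_Lu = NPP_0 − NPP_act`, `HANPP = ΔNPP_Lu + NPP_h` (t C/ha/yr), also
  as a percent of `NPP_0`; hexagon values are cover-weighted:
  `HANPP_hex = Σ w_i P_i`.
* **IDC — intermediate-disturbance complexity.**
  `Le = (a·H′ + b·ECI/10)/(a+b)`, `IDC = Le·(1 − HANPP/100) ∈ [0, 1]`.
  High IDC marks heterogeneous, well-connected landscapes under
  intermediate appropriation; hexagons are classified into
  anthropic / natural / mosaic landscape-metabolic configurations.
* **ESC / MF — ecosystem-service capacity and multifunctionality.** A
  27-expert panel scores supply and demand of 21 CICES-derived services on
  a 0–5 Likert scale; capacity is mean supply-minus-demand (∈ [−5, 5]),
  multifunctionality the breadth of services offered across the
  provisioning / regulation / cultural sections (∈ [0, 5]); both are
  cover-weighted per hexagon (`ESC_j = Σ ESC_i·P_ij`).
* **Statistics.** Deterministic bidirectional stepwise OLS of IDC on the 22
  cover-class proportions (AIC by default), reported in the conventional
  coefficient-table layout, and a simple linear fit of ESC on IDC.

A synthetic-data module generates neutral landscapes with the
valley/slope/highland zonation, NPP tables and expert panels, so the whole
pipeline is testable with no external data.

## Worked example

```bash
landmetab simulate --seed 1 --out demo        # write synthetic inputs
cat > demo/config.yaml <<EOF
raster_path: demo/landcover.asc
legend_path: demo/legend.csv
affinity_path: demo/affinity.csv
barriers_path: demo/barriers.csv
npp_path: demo/npp.csv
expert_path: demo/experts.csv
out_dir: demo/out
cell_area_ha: 50.0
EOF
landmetab run-all --config demo/config.yaml
```

This writes `demo/out/hex_metrics.csv` with one row per retained hexagon:

```
hex_id,hprime,eci,hanpp_tC_ha,hanpp_pct,le,idc,config_label,esc,mf
0,0.000000,8.241619,7.631968,64.215285,0.412081,0.147462,anthropic,-1.620811,0.000000
1,0.000000,8.388903,7.631968,64.215285,0.419445,0.150097,anthropic,-1.620811,0.000000
2,0.250807,8.359358,7.680863,69.990185,0.543372,0.163065,anthropic,-1.550123,0.000000
```

The first hexagons sit in the monoculture valley: a single dominant cover
(H′ ≈ 0), two thirds of potential production appropriated (HANPP ≈ 64%),
hence a very low IDC (≈ 0.15, the *anthropic* configuration) and negative
service capacity. Across the 145 retained hexagons of this run the
configuration counts are 51 anthropic, 51 mosaic, 11 natural and 32
unclassified, and the ESC–IDC line has slope ≈ 10.5 with R² ≈ 0.84 —
service capacity rises along the disturbance-complexity gradient.
`demo/out/regression.txt` holds the stepwise coefficient table; in this run
sugarcane plantations (−0.43) and urban areas (−0.53) carry the strongest
negative IDC associations, mirroring the intensification gradient the
generator builds in.

The same stages are available as library functions
(`landmetab.compute_eci`, `landmetab.compute_hanpp_class`,
`landmetab.stepwise_mrm`, …) on in-memory objects.

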