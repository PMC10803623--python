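# Methods

This note documents the models implemented in `littoral`, the choices made
where the underlying survey methodology leaves room, and what the synthetic
data do and do not establish.

## Bathymetry and littoral slope

Depth rasters are built from a shoreline polygon (treated as the 0 m
contour) and depth-labelled isobath polylines, all in planar metric
coordinates. Contour vertices are densified to roughly one point per cell
and interpolated linearly over their Delaunay triangulation
(`scipy.interpolate.LinearNDInterpolator`); in-lake cells outside the
point hull — concave pockets, and the region inside the deepest closed
contour — are filled by nearest-neighbour extrapolation. Hydrologically
corrected interpolants (ANUDEM-style "topo to raster") enforce drainage
structure that has no meaning inside a lake basin; linear interpolation
between contours is transparent, testable, and exact for the piecewise
planar basins used in validation. Isobaths that cross each other or the
shoreline are rejected with the offending depth named.

Slope is Horn's 3×3 finite-difference operator,
`slope = arctan(‖∇z‖)` in degrees — the stencil documented for the
standard GIS slope tool. Cells outside the lake are filled before the
stencil by a first-order extension of the valid surface: each missing cell
takes depth + gradient × offset from its nearest interior cell (two
erosions in, where central differences are clean). A plain nearest-value
fill would flatten the gradient in the shore-adjacent ring of cells and
bias transect slopes low by several tenths of a degree at steep shores;
with the first-order fill an affine basin yields its exact slope at every
cell, and end-to-end recovery of planted slopes in [0.5°, 16°] through
contour interpolation → Horn → zonal mean is accurate to < 0.01°
(tolerance asserted in tests: 0.1°).

Per-transect slopes are arithmetic means over a rectangular strip, 30 m
wide, running along the transect's inward normal from the shore anchor to
where the centerline first reaches the target depth: 1 m for `Sl_1m`, and
for `Sl_Cmax` the labelled isobath nearest the lake's maximum colonisation
depth (ties broken toward the deeper isobath). Membership is
cell-center-in-rectangle. The survey literature does not state whether the
zonal statistic was computed over a line or a buffer, nor whether mean or
median was used; the rectangle zone and the arithmetic mean are the
defaults here, both isolated behind `transect_zone` / `zonal_slope` so
either choice can be swapped. If the target depth is never reached (a
transect aimed across a shallow arm), the zone is truncated at the
centroid side of the basin and a warning is logged.

Percent grade is `tan(deg)·100`, reported half-up to one decimal; the
class thresholds gentle < 1.32° and steep > 8.42° reproduce their printed
percent twins 2.3 % and 14.8 % exactly under this rounding. Both
thresholds are strict inequalities, so 1.32° and 8.42° themselves class as
moderate.

## Effective fetch and wind exposure

Fetch rays are cast from the transect anchor along the inward normal and
at ±22.5° and ±45° (the extreme rays subtend 90°). Each ray's length is
the distance to the end of the first open-water segment of its
intersection with the basin polygon (shoreline minus islands), which
handles islands and concave shores uniformly; a ray whose first open-water
segment does not begin at the anchor (concave anchor) gets length 0 with a
warning. Effective fetch is the weighted mean with the cosine weights
1, 0.92388 and 0.70711 (Σw = 4.26198).

Daily wind is summarised from hourly records: arithmetic mean speed, and
direction via the Linear Directional Mean — `arctan(Σsin/Σcos)` resolved
by the explicit four-branch sign correction. The scalar implementation and
the vectorised per-day path share the same branches and agree with an
independent `atan2` resultant-vector oracle to 10⁻⁹ degrees; a day whose
resultant vanishes (no mean direction) is dropped with a log entry.

The exposure index is `E = log(1 + f·w·h·d⁻²)`. Two conventions are
deliberately configurable because the survey methodology does not pin them
down:

* **Log base** — natural log by default (`log_base` exposed). Plausible
  inputs then bracket the exposure ranges reported for this lake
  population; the printed ranges alone cannot distinguish bases.
* **"Wind directed towards the site"** — a day counts as toward when its
  daily-mean FROM-direction lies within ±45° of the onshore normal, the
  same 90° sector the fetch rays span (`toward_half_angle_deg` exposed,
  and a `convention="to"` flag for stations recording travel direction).

Mean speed h is taken over all days in the window, not only toward-days:
the formula separates w and h as independent factors. Site depth d is 1 m
for the helophyte zone (`Exp_1m`) and the lake's maximum colonisation
depth for the hydrophyte zone (`Exp_Cmax`).

## Status indices

Shannon diversity uses the natural log, hence Pielou's J' = H'/ln S —
the standard convention; the source methodology is silent. For a
monodominant stand (S = 1), ln S = 0 leaves J' undefined; J' = 0 is the
default as the conservative reading for a degradation-sensitive index,
with `monodominant_evenness` overridable to 1. The iso-2.5 area in the
lake index is computed from the depth raster as (cells with depth ≤ 2.5 m)
× cell area, in ha; the 2.5 m constant in the transect index is the same
depth normaliser in metres. N (vegetated area) is carried in hectares,
consistent with P in hectares. Both indices are clipped to [0, 1); they
are zero exactly when the evenness or abundance factor is zero, strictly
increasing in each argument otherwise, and the lake and transect forms
coincide on a single-transect lake whose ratios match
(N/iso2.5 = C_max_TR/2.5, N/P = C_max_TR/Z_max) — all asserted in tests.

## Indicator analysis and class statistics

IndVal follows the Dufrêne–Legendre group-mean form: specificity
A = (group mean abundance)/(sum of group means), fidelity B = occurrence
share within the group, IndVal = A·B, reported per syntaxon as the maximum
over groups. The later total-abundance variant is available via
`abundance_base="total"`. Significance is a label-permutation test,
p = (r+1)/(n_perm+1) with 999 permutations by default, seedable; no
multiple-testing correction is applied, matching common practice for these
tables. The indicator *flag* requires IndVal ≥ 0.50 and p < 0.05; the
table itself reports all syntaxa as computed, since published indicator
tables routinely list entries below the flag threshold. Syntaxa with
fewer than four occurrences are dropped before multivariate analysis.
Under an exchangeable null the test is type-I calibrated (the p < 0.05
rate is 5 % within binomial error at 999 permutations), and a community
planted on steep-class transects at the survey's class sizes (36/180/44 of
260) is recovered as a flagged steep indicator.

SIMPER splits each between-group transect pair's Bray–Curtis
dissimilarity per syntaxon as |xᵢₖ − xⱼₖ| / Σₖ(xᵢₖ + xⱼₖ) and averages
over pairs, so contributions sum exactly to the mean pairwise
dissimilarity. Spearman correlations, Kruskal–Wallis (tie-corrected) and
Mann–Whitney follow-ups delegate to `scipy.stats`; correlation tables
carry the conventional reporting flags (hidden above p = 0.1,
marked non-significant in [0.05, 0.1)). A constant variable has undefined
rank correlation and is reported missing rather than guessed.

## Synthetic data: what it emulates

Lakes are star-shaped: a circle, an ellipse, or a radius perturbed by
low-order Fourier terms (k = 2–5), which keeps polygons simple and gives
every ray a unique first shoreline hit. Depth is a function of
distance-to-shore along the radial ray: conic (linear to the centre),
planar-shelf (constant shore slope, flat central shelf), or two-slope.
These profiles have analytically known gradients, which is the point: the
full raster pipeline must reproduce them. Transect anchors are spaced
evenly by arc length (inverted arclength integral) and are exact polygon
vertices, with inward normals from the analytic tangent; each transect's
maximum colonisation depth is drawn uniformly from the surveyed 2.0–8.5 m
range, truncated below 90 % of the depth reachable along its own ray.

Wind is a hierarchical von Mises model: a daily mean direction around the
station mean (concentration 0 = uniform, ∞ = point mass) emulating
synoptic variability, hourly scatter around the day mean (concentration 12
by default), and Rayleigh-shaped Weibull speeds calibrated to a 3.5 m s⁻¹
mean — six years of hourly records, the standard averaging window.

Communities are drawn per transect from a Dirichlet over 3–10 syntaxa
selected from a pool of 69 (two thirds hydrophytes, a fifth charophytes),
with lake-level commonness weights. The lake's total phosphorus, uniform
on 0.015–0.049 mg l⁻¹, multiplies charophyte presence odds and cover
weights by `exp(trophic_effect · z(TP))` (default effect −1.5), so the
TP–charophyte association analysed downstream exists by construction and
its recovery can be asserted. Relative covers sum to 100 per transect by
construction.

The default study scale — 16 lakes, 260 transects total with 8–27 per
lake, per-lake shore-slope angles log-uniform over 0.6–16° so all three
slope classes are populated — mirrors the monitoring campaign the pipeline
is built around. The generator does **not** emulate: real lake outlines
(multi-basin shapes, non-star-shaped shorelines), any coupling of
colonisation depth or community evenness to slope or exposure, wave
physics, station-to-lake distance effects, or observation error in cover
estimates. Passing tests therefore demonstrate that the *computational
chain* is correct and well calibrated, not that the ecological effects
measured on real lakes are reproduced; the correlation tables computed on
synthetic runs reflect the generator's couplings only (TP–charophytes
planted, slope–community null).

## Numerical choices and scales

Rasters are registered to cell centers, row 0 at the southern edge;
vector data round-trip through GeoJSON and rasters through ESRI ASCII
grid, both plain text. Default raster resolution in the pipeline is 2 m
(the validation suite shows recovery errors far below tolerance at this
resolution; 1 m is available where fidelity matters more than time).
Shorelines and isobaths are discretised at 720 vertices plus the anchor
angles. Ray intersections use a 10⁻⁹ m transversal tolerance; anchors off
the shoreline by more than one cell are rejected. Degenerate inputs fail
loudly: empty zones, all-missing grids, zero-length direction resultants,
crossing isobaths, covers not summing to 100.

All stochastic stages take explicit integer seeds and are bit-reproducible;
the pipeline writes a manifest with its config echo and SHA-256 hashes of
every output table, and identical configs produce byte-identical CSVs.

## Known limitations

* The depth field of non-circular synthetic lakes is radial, so its
  isobaths are exact only where the shore distance is radial; slope
  recovery fixtures use circular planar-shelf basins where truth is exact.
* Fetch treats the wind fan as the same 90° sector for all five rays of
  one transect; no directional weighting of fetch by wind climatology is
  attempted (the exposure index carries the climatology through w and h).
* The transect-zone rectangle is axis-aligned with the transect, not
  curved with the shoreline; on strongly curved shores the outer corners
  of wide zones can sample neighbouring slopes.
* Lake-level evenness pools syntaxon covers by averaging across transects
  before computing J'; weighting by vegetated area per transect is not
  available in the inputs.
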