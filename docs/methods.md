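# Methods

## Measurement model

The pipeline quantifies two aspects of protein distribution in a stained
grain cross-section: the outer-to-inner gradient in protein concentration on
an area basis, and the size distribution of individual protein bodies as a
function of their distance from the endosperm outline. All geometry lives in
a single convention: (row, col) coordinates, 0-based, pixel centres at
integer positions; physical distances are pixels × scale (µm/pixel) and
areas pixels × scale². The scale is always user-supplied — microscope
magnification alone does not determine µm/pixel, so nothing is guessed from
image metadata.

### Pixel classification

Protein detection is classical supervised maximum-likelihood classification.
Each class — one protein class and one or more background subclasses, so
users can cover the different tones of unstained tissue — is a full-
covariance Gaussian over RGB fitted to the pooled pixels of its training
ROIs (sample mean, sample covariance with denominator n−1). Priors are equal
across classes, since nothing is known in advance about class abundance.
A ridge ε·I (default ε = 10⁻³ on the 0–255 scale) keeps covariances
positive-definite even for a perfectly uniform ROI; ROIs must contain ≥ 4
pixels so the covariance is estimable. Assignment maximises
ln π − ½ln|Σ| − ½(x−μ)ᵀΣ⁻¹(x−μ); ties go to the lowest class index (labels
are processed in sorted order, so the rule is deterministic). There is
deliberately no spatial smoothing or morphological clean-up: the decision is
strictly per pixel, and small-object suppression happens later, explicitly,
via the body-size filter. The replicated-training protocol (default three
training sets per image) is first-class: every downstream table carries
`replicate_id`, and a pairwise replicate-agreement statistic is exposed as a
QC number without a hard pass/fail threshold, since acceptable agreement
depends on stain quality.

### Zonation

Zones are defined on the exact Euclidean distance transform of the endosperm
mask, with everything outside the region — including the canvas border — as
the distance source. With d_max the deepest in-mask distance, band width is
w = d_max/K and a pixel at distance d gets zone ⌊d/w⌋+1 (half-open bands,
the single deepest pixel folded into zone K). This makes the zones span the
full outer-to-inner range of each individual grain, which is also why the
modelling variable downstream is the physical mid-band distance
(zone−½)·w·scale rather than the zone index: d_max differs between grains
and treatments. An alternative construction — geometric inward buffering of
the outline polygon — differs from distance-transform thresholding by
sub-pixel amounts on concave outlines; the distance-transform definition is
the one implemented and tested. The default K = 5 can be checked per dataset
with `choose_zone_count`, which scans K = 3..7 and picks the best linear
concentration-vs-distance fit by R², defaulting to 5 on ties.

### Protein bodies

Bodies are 8-connected components of the classified raster (diagonal joins
count: stained deposits sectioned at 1 µm are compact and often touch
corner-to-corner). The midpoint is the pixel centroid of the component —
more robust to irregular shapes than a bounding-box centre — and the
reported distance is the shortest Euclidean distance from that midpoint to
the outline polygon (minimum over its segments), not from the body's nearest
edge. Components below `min_area_px` (default 4 px, 1 disables) are
discarded as classification specks; the default is deliberately permissive
because genuine protein bodies can be very small. Size histograms default to
12 log-spaced bins over the observed range, reflecting the strongly
right-skewed size distribution.

### Calibration

Area fraction of stain is a proxy: water content and within-body protein
density can shift detection efficiency between treatments. For each
treatment × experimental-replicate grouping a conversion factor

    cf = (nitrogen% × k / 100) / (Σ protein area / Σ zone area)

anchors the imagery to the chemically measured protein concentration, with
k the nitrogen-to-protein multiplier (default 5.7, the standard wheat
value; pass protein % directly with k = 1 if that is what was measured).
This orientation of the ratio is the only one under which applying the
factor to the per-zone fractions makes their area-weighted mean equal the
measured grain protein % — an algebraic identity the tests assert to 10⁻¹⁰.
Because cf is a positive scalar per grouping, zone ordering and gradient
sign are never altered by calibration. Per-section factors are available
when section-level nitrogen data exist.

### Gradient statistics

Trends are ordinary least squares per treatment group: calibrated
concentration vs mid-band distance (classification replicates averaged per
zone first), and ln(body area) vs body distance (replicates pooled,
replicate id retained). The natural log stabilises the body-area variance;
back-transform with exp for reporting. Linearity is checked by a nested
F-test against a model with an added distance² term
(F = ((RSS₁−RSS₂)/1)/(RSS₂/(n−3))); data that are exactly linear give F = 0
and p = 1 by construction. Group comparisons are Welch-type z contrasts of
slopes and are labelled descriptive: the proper inferential analysis of such
experiments is a REML linear mixed model with the nesting
(room·block)/pot/section-replicate/zone/analysis-replicate, which is
standard in dedicated statistics software and out of scope here — the tidy
exported tables are its input. For the same reason no variance components
are estimated or reported.

## Synthetic sections

The generator emulates the structure the pipeline must recover, not
histology. The endosperm outline is the union of two circular lobes with a
tapering crease notch from the top (exercising concave-polygon distance
code); defaults render a ~1300 × 800 px grain on a 1500 × 1000 px canvas at
1 µm/pixel — a mid-grain-filling cross-section a few millimetres across.
Protein coverage is programmed directly as an area-fraction gradient
f(d) = a + b·d (defaults a = 0.14, b = −1.5×10⁻⁴ per µm), and body areas are
log-normal with ln-mean µ(d) = c + s·d (defaults c = ln 40 µm², s = −0.0012
per µm, σ = 0.45): moderate stain coverage falling outward-to-inward and
bodies of a few tens of µm² shrinking toward the grain centre, with many
small and few large bodies.

Placement is an inhomogeneous hard-core point process: ellipses of random
orientation and 1–1.6 axis ratio are proposed at uniform positions zone by
zone and rejected if their one-pixel-dilated footprint touches an existing
body (so placed bodies stay distinct under 8-connectivity). Two design
details keep the realised section faithful to the programmed laws. First,
each body keeps its standardised size draw across placement retries —
otherwise rejection would select against large bodies in crowded zones and
flatten the realised size gradient. Second, placed pixels are credited to
the zone they actually land in (zones filled outermost-first), so bodies
straddling band boundaries do not inflate the small innermost zone.
Rendering is hard pixel membership without anti-aliasing, so ground-truth
areas are exact pixel counts; ground truth is nevertheless re-extracted from
the rendered raster, so any residual merging would be reflected honestly.
Colours are Gaussian RGB noise (sd 12) around a dark blue-black protein mean
(45, 45, 90) and a pale background (205, 195, 185) — cosmetic defaults
approximating the stain, fully configurable. All randomness flows from one
seed; identical configs produce byte-identical artifacts.

Training ROIs are sampled from known truth regions (2×2 protein blocks, 3×3
background blocks), stratified over the zones; distinct seeds emulate the
triplicate manual-training protocol.

What the generator does **not** emulate: cell walls and anatomical texture,
the aleurone layer, stain-intensity drift across a section, stitching
artefacts of composite images, or partially stained pixels at body edges.
Passing recovery tests therefore shows the geometry, accounting and
statistics of the pipeline are correct and that classification works when
classes are Gaussian-ish and separable — not that real sections classify
this accurately; on real data the replicate-agreement QC and visual checks
of exported masks remain essential.

Named parameter sets ("control", "high-temperature", "low-nitrogen")
programme the qualitative ordering observed in grain-filling experiments —
steeper negative gradients under elevated temperature, shallower under
nitrogen limitation — and are used to check that the pipeline preserves
slope ordering end to end. They make no claim about effect magnitudes.

## Experiment-design utilities

Thermal time uses the photoperiod-weighted daily mean
(T_day·h + T_night·(24−h))/24 minus a base temperature (default 4.1 °C for
wheat); symmetric day/night transition ramps cancel in the daily mean and
are ignored. Equivalent sampling days between regimes scale by the ratio of
daily thermal times and round to the nearest day, halves away from zero.
Nutrient nitrogen totals sum molarity × N-atoms × 14.0067 mg/mmol × volume ×
applications over the recipe; chelator-bound nitrogen (FeNaEDTA) is excluded
by default because it is not plant-available on the relevant timescale — an
`include_chelators` flag adds it.

## Numerical choices and problem sizes

- Polygon rasterisation uses the pixel-centre rule with boundary centres
  counted inside (deterministic tie rule); masks derived from 0/255 label
  images get their outline from marching squares at the 0.5 level, which
  rasterises back to exactly the labelled region. Masks must be a single
  connected component without holes.
- The distance transform is `scipy.ndimage.distance_transform_edt` on a
  zero-padded raster (canvas border = outside).
- Classification solves each class's quadratic form by Cholesky
  factorisation; the brute-force log-density argmax is kept as a test oracle
  only.
- Degenerate inputs fail loudly: empty or disconnected masks, zones with
  zero area, bodies with midpoints outside the mask, non-positive areas
  before log transform, constant-distance regression designs.
- Test and validation problem sizes: oracle suites run on ≤ 64×64 rasters
  (100 random cases per primitive); recovery runs use the generator's
  default 1500 × 1000 px canvas (~3000 bodies), with a reduced 360 × 520 px
  configuration for quick unit tests. Sign-recovery sweeps use 20 seeded
  full-size runs with a single classification replicate each.

## Known limitations

- The pipeline measures; it does not infer. Treatment effects should be
  tested with the full mixed model on the exported tables.
- Fused protein bodies are counted as one: no watershed splitting, and no
  3-D reconstruction across serial sections.
- Background heterogeneity must be covered by training subclasses; the
  classifier has no colour-deconvolution or illumination-correction stage.
- Calibration assumes the nitrogen measurement and the imaged sections come
  from the same material; grouping mismatches are the user's responsibility
  beyond simple key checks.
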