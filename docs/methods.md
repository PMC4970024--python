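# Methods

## Problem and model

The package processes a colored triangular mesh of a ~1 m × 1 m field
plot, in meters, as fused from a top-view RGB-D depth scan of a young
maize stand infested with weeds. The scientific model has three parts.

**Dual segmentation.** The crop is assumed strictly taller than every
weed: maize in the target growth window spans 0.40–0.55 m while grasses
reach at most 0.20 m and broad-leaved weeds stay under 0.10 m. A face
with any vertex above the height threshold (measured perpendicular to the
ground plane fitted through the white sampling frame) seeds a crop
region; the region grows across faces that share an *edge* (shared
vertices do not connect — a pinch point between two touching plants must
not leak a selection) and that pass the vegetation color test. Weeds
cannot be found by height — tilled soil has ~2 cm of microrelief, the
same scale as a young broadleaf — so the crop-free remainder is
partitioned by color alone: a vertex is vegetation when its excess-green
index ExG = 2G − R − B exceeds a threshold, and a face is weed when at
least two of its three vertices are vegetation. The face-level 2-of-3
vote keeps the partition well defined across color-gradient boundaries.

**Volume.** Each class mesh becomes a volume by polyhedral mass
properties: for a closed, coherently oriented surface the enclosed volume
is exactly Σ det([a b c])/6 over triangles. Canopy surfaces seen from
above are open, so they are first sealed against the ground plane
(below). The prism estimator (projected face area × mean vertex height,
valid only for single-layer height-field surfaces) is retained as a
documented fallback, and a voxel-parity counter serves as an independent
oracle in tests only.

**Statistics.** Estimated volumes are related to dry biomass and weed
density by Pearson correlation and simple OLS (raw p-values from the
exact t transform, no multiple-testing correction — a handful of planned
comparisons). Weed class (monocots / dicots / mixture) is predicted from
the per-quadrat weed height features (max, p90) by canonical discriminant
analysis: axes solve the generalized symmetric eigenproblem
Sb·w = λ·Sw·w with Sw the pooled within-group scatter, eigenvectors
Sw-normalized so that nearest-centroid classification in canonical space
equals the Mahalanobis rule under pooled covariance with equal priors.
Confusion matrices are row-normalized percentages, rows ordered
monocots, dicots, mixture; leave-one-out is the default scheme because
it is the less optimistic of the two offered.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| height threshold | 0.30 | m | midpoint of the 0.20 m weed maximum and 0.40 m maize minimum |
| ExG threshold | 20 | 8-bit index | standard agronomic greenness cut; Otsu auto-threshold available |
| ground clearance | 0.02 | m | faces entirely below it may be absorbed into a crop region but never relay growth, so a flood fill cannot run along the soil where a stalk meets the ground |
| isolated-point radius | 0.01 | m | a genuine surface sample from a dense scan always has a neighbor within 1 cm; flying pixels do not |
| white threshold / chroma | 200 / 30 | 8-bit | all channels bright and nearly equal: shaded white paint stays in, sunlit leaves stay out |
| degenerate face area | 1e-12 | m² | numerically zero at scene scale |
| CDA ridge | 1e-8 × trace | — | pooled scatter can be singular when features are collinear (p90 proportional to max); logged when applied |

## Frame detection and geometry

White vertices (low-chroma bright) are plane-fitted by PCA; their
in-plane projection is fitted with a minimum-area rotated rectangle whose
corners define the frame. Corners are ordered counterclockwise from the
minimum-(x+y) corner — a rule stable under millimeter detection noise,
unlike lexicographic ordering. Cropping keeps faces whose centroid lies
inside the frame polygon and discards any face touching a white vertex;
the quadrat split assigns by face centroid with half-open midline
intervals (a centroid exactly on a midline goes to the higher-index
quadrat). Faces carry persistent ids through every subsetting step so a
segmentation can always be compared against generator truth.

## Sealing open canopies

`close_to_ground` repairs the winding coherently (breadth-first edge
propagation, per-component sign fixed to non-negative volume), decomposes
the boundary into simple directed cycles — splitting at pinch vertices
where several holes meet — and treats cycles two ways. Large cycles (the
canopy silhouette) are extruded: each boundary edge gets two wall
triangles down to its orthogonal projection on the ground plane and a fan
from the projected centroid forms the base. Because base faces lie *in*
the plane their determinant contribution is zero, so even a self-crossing
base triangulation cannot bias the volume. Small cycles (≤ 12 edges,
typically sensor-dropout holes high on a plant) are instead patched in
place with a centroid fan: extruding a high hole to the ground would
carve a spurious shaft through the solid, an error proportional to hole
area × height. Surfaces whose boundary cannot be closed fall back to the
prism estimate with a warning, and the volume report records which method
produced each number.

## The synthetic field generator

The generator emulates the sampling campaign the analysis assumes: ten
1 m × 1 m frames, each split into four 0.5 m quadrats, 20 on the crop row
and 20 inter-row, with an explicit composition mix (default 8 weed-free,
11 grass-only, 11 broadleaf-only, 10 mixed). Scenes contain:

- a soil height field (cubic-upsampled coarse noise scaled to ±2 cm, plus
  0.8 mm fine grain) at 5 mm sampling, colored brown with lightness-only
  texture so its ExG stays near zero;
- a flush white frame band (4 cm wide, inside the outer 1 m square, which
  is the reference the detector recovers);
- plants as closed lofted star-section solids: maize as a tapered stalk
  with 4–6 Gaussian leaf lobes (the lowest wall ring spans 0–2.6 cm so
  the base cap stays edge-adjacent to faces above the ground clearance),
  grass tufts of 5–9 thin leaning blades, and broadleaf rosettes as
  wavy-margin domes. Every plant's enclosed volume is computed at
  construction by the same determinant sum the volumetry module uses, so
  ground truth is exact to numerical precision;
- sensor degradation: 3 mm Gaussian jitter along the vertical view axis,
  1 % isolated outlier vertices injected ≥ 2 cm from every surface point
  (and from each other, so the 1 cm rule removes them all), optional face
  dropout, and Gaussian color noise (sd 3).

Biomass is simulated per quadrat and class as B = a·V·(1+ε) with
a = 14 000 g/m³ (maize) and 10 000 g/m³ (weeds) — order-of-magnitude
agronomic choices; canopy volume overestimates tissue, so the factors are
effective densities — and ε ~ N(0, σ) truncated at −1. σ is back-solved
numerically so that corr(V, B), including the truncation and the
weed-free zeros, equals a requested population value (defaults 0.77 for
maize, 0.83 for weeds); the volume moments entering that inversion come
from a cached fixed-seed Monte Carlo of 1500 quadrats. Truth-only study
generation skips meshes and colors but consumes identical geometry draws,
so both modes agree record for record at the same seed.

What the generator does **not** emulate: occlusion (soil under a canopy
is still meshed), registration drift between fused views, specular or
shadow color casts, botanically realistic organ shapes, and plants
touching each other or the soil mesh. Passing tests therefore demonstrate
the correctness and noise-robustness of the algorithms under the stated
geometric and radiometric assumptions, not field-grade performance.

## Numerical choices and degenerate inputs

- Component ids order by descending face count, ties to the lower minimum
  face index; empty meshes yield empty labelings rather than errors.
- `signed_volume` refuses open meshes (every edge must bound exactly two
  faces) and directs the caller to the closure; orientation is repaired
  rather than trusted.
- A constant regression response is well defined: slope 0, r² = 0.
- Leave-one-out refits that would leave a 2-sample group with one member
  score that sample against the full fit instead.
- The voxel oracle shifts its grid by an irrational sub-voxel offset so
  vertical rays never hit edges exactly; it cannot resolve the ~2 mm
  grass blades at its default 5 mm voxel and is used on thicker organs.
- Quadrat-sample validation tolerates vertices within one face diameter
  outside the rectangle, since assignment is by centroid.

## Problem sizes

Default scenes carry ~110 k vertices / ~215 k faces (5 mm sampling); the
test suite processes a handful of full scenes, twenty pristine quadrats
for the exact-recovery check, and 200 truth-only replicate studies for
the correlation-recovery check, which together run in a few minutes on
one core.

## Known limitations

- Maize identification assumes the height separation holds; lodged or
  stunted maize below the threshold would be classified as weed.
- ExG with a fixed threshold is sensitive to strong color casts; the
  Otsu alternative helps only when the quadrat actually contains two
  color populations.
- The prism fallback is biased high on multi-layer surfaces (it counts
  walls and undersides as canopy); it exists for surfaces the closure
  cannot seal and its use is always recorded.
- Recovered sample correlations under the zero-inflated, heteroscedastic
  biomass model sit slightly above the calibrated population value at
  n = 40 (≈ +0.02 at r = 0.8); this is a small-sample property of the
  Pearson estimator under that mixture, not a calibration error.
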