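# Methods

## The measurement model

The package measures transmural left-atrial wall thickness from
contrast-enhanced cardiac CT and displays it on a 2D coplanar map. Its
assumptions, in order of importance:

* the chamber lumen is uniformly contrast-enhanced and much brighter than
  the wall, which is in turn brighter than the immediately surrounding
  tissue (bright-lumen contrast assumption);
* the LA body is star-shaped about an interior isocentre in every axial
  slice, so each slice's inner contour is a single closed ring that a
  boundary tracer can walk;
* the pulmonary veins and the mitral annulus can be separated from the
  body by planes (four PV cut planes, one basal plane), supplied in a YAML
  config for clinical data or derived analytically for phantoms;
* thickness is the shortest Euclidean distance from the chamber-side inner
  boundary to the outer wall boundary, voxel centre to voxel centre, with
  anisotropic spacing in mm. No half-voxel surface correction is added;
  with the chamber-side inner-boundary convention the centre-to-centre
  distance is an unbiased estimate of the geometric wall thickness (the
  half-voxel insets on the two sides cancel).

## Pipeline stages and their tunable parameters

| parameter | default | meaning |
|---|---|---|
| lumen threshold | 3-class Otsu, upper | region-growing acceptance (HU) |
| `sobel_refine` | off | snap the grown surface to the Sobel gradient ridge |
| `r_max` | 10 mm | outward search cap for the outer boundary |
| band Otsu bins | 128 | HU histogram resolution in the outer search band |
| reference direction | +x | map seam/centre-column anchor ray |

**Inner boundary.** Region growing is a 6-connected component of the
thresholded volume containing the isocentre; growth to the volume border
raises a "chamber leak" error rather than returning garbage. The Sobel
snap (one pass, ±1 voxel along the dominant outward direction, ties keep
the current boundary) is implemented and tested but disabled by default:
on a thin wall the partial-volume effect displaces the composite
lumen→wall→background gradient ridge *outward into the wall* (~0.1 mm for
a 1.0 mm wall under a 0.8 mm FWHM kernel), so ridge-snapping inflates the
chamber at exactly the structures this tool exists to measure. The
threshold-based boundary also reproduces the chamber-underestimation
behaviour observed with physical phantoms.

**Outer boundary.** The band at iteration *k* is every unclipped
non-chamber voxel within *k* 6-connected dilations of the inner boundary
and within `r_max`; a two-class Otsu threshold over the band HU histogram
defines candidate wall voxels, which must stay 6-connected to the inner
boundary; iteration stops at a fixed point of the wall set. A band with a
single HU value postpones thresholding until the band reaches a second
tissue class; if that never happens the procedure reports
"wall/background not separable".

**Unwrap.** The tracer uses the fixed weight matrix
`[[7,8,1],[6,0,2],[5,4,3]]` over the eight in-slice neighbours. A static
weight matrix cannot by itself avoid immediate backtracking, so already
visited voxels are excluded and dead ends backtrack to the most recent
voxel with an unvisited neighbour — this makes the trace total (every
contour voxel exactly once) and deterministic on any 8-connected contour;
weight entries are distinct so no tie-break is ever needed among occupied
neighbours. Rows are native CT slices; the start voxel of each row is the
contour voxel nearest the fixed reference ray and sits at the centre
column, which realises vertically coherent columns without any dependence
on a summation convention for the initial column offset. Whether to trace
the inner or outer boundary was an open choice; the inner boundary is
used, since thickness is indexed on it.

**Map geometry.** Pixel arc weights are Freeman–Kulpa corrected chain-code
steps (0.948·in-plane spacing axial, 1.340·diagonal). The raw 1/√2 weights
overestimate a digitised smooth contour's length by ~4–5% — a bias that
does not vanish with resolution — which would break the closed-form
cylinder check (row arc sums vs 2πr) and bias CCL/BCL; the corrected
estimator is standard in digital geometry. The correction is a uniform
factor, so arc-weighted *means* (thickness summaries) are unchanged by it.
Where the trace had to backtrack, the step to the non-adjacent successor
is not a wall step and receives a neutral one-pixel weight.

**Holes.** The ostium region of each PV is the cylinder of the vein's
inner radius around the cut-plane axis (extended slightly behind the plane
because the opening straddles a tilted surface); contour voxels inside it
become HOLE pixels. Membership is geometric, so image noise cannot
fragment an ostium. Hole components are grouped per PV by nearest cut
plane when a delineation is available (robust to ostia that nearly touch
in map space near the roof); otherwise by 8-connected components with
horizontal wraparound across the map seam.

**Metrics.** Height is the slice span of the segmented chamber times the
slice increment. CCL is the arc sum of the mid-height row and BCL of the
last row above the basal plane (the slice rule is a package choice; no
published convention exists). PV ostium areas are Σ(arc weight × row
spacing) over each hole. "Heterogeneity" has no published definition; the
arc-weighted standard deviation of map thickness is used and isolated in
one function so alternatives (IQR, coefficient of variation) are
pluggable. Error tables use the overestimation-positive convention
(absolute = measurement − gold; relative = absolute/gold × 100).

## The digital phantom and CT simulator

The phantom emulates an average adult LA envelope: a superellipse-of-
revolution dome (default exponent 2 — an elliptical dome) of height 30 mm
and basal diameter 30 mm, with the wall defined as all points within half
the local design thickness of the mid-surface along its normal — so
transmural thickness equals the design profile by construction. The roof
cap tops out at z = 0 and the base is an open disc at z = height (mitral
annulus; no wall cap). Three study configurations: homogeneous 1.0 mm,
homogeneous 2.0 mm, and a linear 0.5 mm (roof) → 1.6 mm (base) gradient.
Four PV tubes (inner diameter 8 mm, wall 1 mm, length 10 mm) attach
horizontally at azimuths 45°/135°/225°/315°, the superior pair at 0.75 and
the inferior pair at 0.55 of the height above the base — the published
figures show two left and two right superior–inferior pairs but no exact
angles, so these are package defaults. Voxel labels are decided by centre
point against the analytic surfaces (no anti-aliasing); voxel centres sit
at half-integer grid positions so analytic surfaces generically fall
between slice planes. Rasterisation is refused when the grid spacing
exceeds half the thinnest wall.

The CT simulator maps labels to HU (lumen and PV lumen 350, walls 50,
background −50 — clinical-like contrast values, configurable), convolves
with an isotropic Gaussian PSF (default FWHM 0.8 mm) to generate the
partial-volume effect, and adds seeded Gaussian noise (default σ 15 HU).
With zero PSF and zero noise the output is bit-exact the label lookup,
which the oracle-equivalence tests exploit.

What the phantom does **not** emulate: cardiac motion and gating, beam
hardening, scanner reconstruction kernels, anatomical wall-thickness
texture, trabeculation, the left-atrial appendage, or the acryl/water
materials of a physical phantom. Passing phantom tests therefore validates
the geometry and algorithmic chain, not clinical segmentation robustness.

## Study-scale choices and numerical notes

Validation phantoms are rasterised at 0.25 mm isotropic spacing (grids of
roughly 230×230×130 voxels), matching sub-voxel sampling of the thinnest
0.5 mm wall; unit tests use 0.5 mm where the property under test is
resolution-independent. The simulated-CT accuracy check runs five noise
seeds. The mid-surface distance field is evaluated through a 0.05 mm
(r, z) lookup grid (the body is a surface of revolution), with bilinear
interpolation error far below voxel size. Degenerate partial rings at the
first/last two chamber slices (roof apex, basal rim — where blur and noise
can leave only an arc) are dropped from the map with a warning rather than
aborting the run.

## Known limitations

* With the default HU model, a 1.0 mm wall under a 0.8 mm PSF never
  reaches full wall contrast and falls to ~0 HU at its true outer surface;
  any positive band-Otsu threshold then truncates the outer half of the
  wall, and the measured wall volume underestimates truth by ~20% (the
  thickness map underestimates correspondingly). Thicker walls behave much
  better (the 2.0 mm phantom's wall volume is within ~5%). A physical
  acryl-in-water phantom does not show this failure because its wall/
  background contrast survives blurring; reproducing that regime requires
  setting `CTParams` to the corresponding material HUs. This is the single
  deliberately failing check in the acceptance suite.
* Plane-based PV clipping only approximates the tilted LA/PV junction:
  the measured chamber includes a small vein-mouth vestibule before the
  cut plane, and ostium areas measured on the CT map run ~10–20% above the
  gold standard (the published comparison also shows systematic ostium
  overestimation, at smaller magnitude).
* The gold-standard roof row of the gradient phantom reads ~0.38 mm for a
  0.5 mm design (within the one-voxel tolerance): at high surface
  curvature the discrete minimum distance to the outer voxel shell is
  biased low by up to half a voxel diagonal.
* The tracer requires one main closed ring per slice; multi-ring
  cross-sections (which a strongly lobed appendage would create) are
  reduced to the largest ring with a warning.
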