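# Methods

## Coordinate system and projective model

A treatment beam is modelled as a point source with the axis +Z running
from source toward patient; X and Y are the collimator axes.  Every
planar shape (jaw rectangle, MLC aperture, block outline) is stored in
millimetres at the 100 cm reference plane and moved to any other plane by
central projection: vertices scale by z/z_ref about the central axis, so
lengths scale linearly and areas quadratically.  This single rule is what
"divergent" means everywhere in the package.

Distances from the source are kept in centimetres (reference 100 cm, tray
default 55.4 cm, clearance 8.2 cm); in-plane coordinates and the meshes
are millimetres.  Unit conversions happen only at module boundaries.

The source-to-tray distance is not a physical constant of the method but
a machine configuration; 55.4 cm is used as the default working plane
(consistent with printing a 1:1 verification transparency at that
distance) and is overridable per field and per shell spec.

## Cavity and mass model

Each island block becomes a cavity lofted between the tray plane and the
plane 8 cm closer to the source.  Because both faces are central
projections of the same outline, every intermediate cross-section is a
linearly scaled copy, and the exact volume is the frustum form
V = (h/3)(A_top + √(A_top A_bottom) + A_bottom) with the face areas from
the shoelace formula.  This identity is also the oracle used in tests:
the closed form must agree with numerical integration of
((1−t)√A_top + t√A_bottom)² h over t ∈ [0, 1] and with the
divergence-theorem volume of the generated mesh.

The fill mass is M = η·ρ·ΣVᵢ with packing fraction η = 0.6 (random close
packing of equal spheres; the FCC bound π/√18 ≈ 0.7405 is enforced as a
validity ceiling) and BB alloy density ρ = 17.6 g/cc.  A calibrated
effective density can replace the product: the calibration is the
least-squares slope through the origin of measured mass vs cavity volume,
Σmv/Σv², reported with the RMS residual.  Its standard error is
σ/√(Σv²), which the recovery tests use as the 3-sigma acceptance band.

The percent difference is reported as 100·(calculated − measured)/
calculated, signed so that overfill is negative.  The default verdict
tolerance is ±2 %; the overfill bound may be set looser than the
underfill bound, since modest extra attenuation is clinically benign
while under-attenuation is not.  The precise values are a commissioning
choice.

## Shell meshing without CSG

The printable assembly is built analytically as volume-disjoint closed
bodies rather than by boolean solid modelling:

* per block, a *tub*: outer frustum side walls (the outline offset
  outward by the 1.2 mm wall at the tray plane, then lofted), an outer
  top cap, inner cavity walls and ceiling, and a flat bottom annulus
  where the tub meets the baseplate.  One closed genus-0 surface whose
  volume is exactly outer-frustum minus cavity-frustum;
* the baseplate: a prismatic extrusion (1.6 mm) of the projected jaw
  rectangle plus the projected 1 cm margin, with bolt holes, one fill
  hole per cavity and an optional checkerboard lattice as true interior
  holes (plate genus equals the hole count).

Bodies abut exactly but never overlap, so the concatenated mesh is
watertight and its volume is the sum of closed-form component volumes;
the builder verifies both and fails loudly otherwise (0.1 % guard).

Planar caps — including the holed plate faces and the tub's bottom
annulus — are triangulated by ear clipping after eliminating holes with
visibility bridges.  Bridge visibility is established by brute-force
segment obstruction tests against every boundary edge; loops are a few
hundred vertices, so robustness was preferred over asymptotic cleverness.
No Steiner points are introduced: cap vertices are bit-for-bit the wall
loop vertices, which is the invariant that keeps the solids watertight.
Polygon offsetting uses mitred joins with a bevel fallback (limit 5×) so
sharp outline vertices cannot produce unprintable spikes.

Because the outer wall outline is offset at the tray plane and then
projected, the physical wall is 1.2 mm at the tray and proportionally
thinner toward the source (≈ 1.03 mm at the top of an 8 cm cavity with
the default geometry).  The walls are a mechanical container only; they
are deliberately excluded from any dose bookkeeping.

Default bolt positions are the projected jaw-rectangle corners inset by
9 mm — shielded territory for any field whose MLC conforms around a
target — and every bolt position, default or user-supplied, is validated
to lie outside the CIAO.  For fields without MLC data the CIAO is
unknowable, so validation downgrades to a warning.  The checkerboard
lattice reproduces a cosmetic/weight-saving plate feature; it is off by
default and carries no dosimetric claim.

STL output is binary little-endian with the patient and field identifiers
embedded in the 80-byte header (the writer is local code because the
header content is part of the contract; reading and auditing go through
trimesh).  Coordinates are float32 in the file, which bounds round-trip
volume error at ~1e-4 relative.

## Field-geometry comparison

Masks live on a deterministic common raster covering the jaw rectangle
plus a 20 mm margin, default 0.5 mm pitch, with the pixel-center-in-region
rule used identically for planned outlines, CIAO and thresholded images.
The CIAO is the union over control points of the open leaf-pair strips
clipped to the jaws; membership is interior-of-union (a pixel center on a
shared strip edge counts, the outer boundary does not), and the tests
check this against a per-pixel brute-force oracle.

Binarization marks low-signal pixels as blocked.  The default threshold
is the midpoint of the low and high modal intensities, estimated as the
1st/99th percentile pair — exact on two-level images and robust to
moderate noise; Otsu's method and explicit values are alternatives.
Masks are not morphologically cleaned by default; any cleaning would be
an explicit, flagged choice.  Image grids are rescaled from the imager to
the reference plane by similar triangles before comparison.

The Jaccard distance is computed by direct pixel counting; an independent
library implementation serves as a cross-check in the tests, and the
metric axioms (symmetry, identity, triangle inequality) are property-
tested on random masks.  Comparisons intersect both masks with the CIAO
first, which is what makes deliberately enlarged out-of-field block
extensions invisible to the statistic.  Group summaries report means to
3 decimals and per-case ratios as integer percentages.

## Synthetic fixtures

The three archetypes emulate the clinically motivated cases the method
targets: two quasi-circular lung blocks in a large mantle field, two
small ovary blocks in a pelvis field, and two long thin lung blocks in a
tall mantle field.  Outlines are harmonic-wobbled ellipses (24 vertices,
≤4 % radial modulation) sized so default cavity volumes fall inside the
50–92 cc per-shell range observed for such blocks: ≈72, ≈54 and ≈87 cc
respectively.  The MLC is a single control point conforming to the jaws,
fully open at mid-field and pulled to 75 % at the Y extremes, so field
corners stay shielded (bolt territory).  All outputs are bit-for-bit
deterministic per seed.

Portal images are ideal fluence maps — 1.0 in the open CIAO, 0.05
transmission under a block, 0.0 outside — optionally shifted, rotated,
edge-noised, Gaussian-blurred (penumbra) and Gaussian-noised.  The 0.05
transmission is a fixture parameter consistent with near-total attenuation
by ~8 cm of packed high-Z material, not a physics claim.  What passing
end-to-end tests therefore demonstrate is the *geometry* chain (plan →
raster → image → mask → statistic), not detector physics: no scatter,
no EPID response model, no gantry sag, no registration error beyond the
injected perturbations.

## Numerical choices

* Polygon validity (simplicity, nonzero area) is judged on coordinates
  snapped to a 1 µm grid, so TPS float noise cannot flag a clean outline
  and sub-µm slivers are rejected; stored coordinates are never snapped.
* Ear-clip orientation/containment tests use an epsilon scaled by the
  squared coordinate magnitude; zero-area ears are clipped without
  emitting triangles.
* Winding: outlines are normalized clockwise on ingestion; all area
  computation is winding-invariant by absolute value.
* Plan files are canonical JSON (sorted keys, 2-space indent, trailing
  newline), making write∘read the identity byte-for-byte — the round-trip
  is a test oracle, not a convenience.
* Grids are anchored to the jaw rectangle, so planned and synthetic-image
  rasters align exactly; external images are resampled nearest-neighbour
  onto the comparison grid.

## Problem sizes in tests

Property suites run at sizes chosen to finish in seconds on one core:
1000 random polygons for the shoelace/triangulation cross-check, 1000
random mask triples for the metric axioms, all three archetype assemblies
(~1000 triangles each) for watertightness and volume agreement, and
12-shell calibration sets.  These sizes are comfortably past the point
where the checked properties are size-independent.

## Known limitations

* No CSG: bodies may abut but must not interpenetrate; exotic specs
  (e.g. a fill hole wider than its cavity) are rejected rather than
  resolved by boolean subtraction.
* The fill hole pierces the baseplate only; the shell's bottom annulus is
  sealed by the plate, so the printed part needs the plate mounted before
  filling (matching the intended workflow, where the plug is clamped
  between plate and tray).
* Bolt-position validation tests the bolt center, not the full hole
  footprint, against the CIAO.
* Multi-isocenter beams and DICOM writing are out of scope; the RT Plan
  importer reads standard jaw/MLC/block tags only.
* Dose is entirely out of scope: no attenuation, scatter or TPS coupling
  is modelled anywhere.
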