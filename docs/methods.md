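# Methods

This note documents the models, conventions and numerical choices behind
`limbmorph`, and what validation on the synthetic phantom does and does
not establish about real data.

## Distance analysis (method 1)

**Definition.** The directed nearest-vertex distance field assigns to
every vertex of a source surface the Euclidean distance to the closest
*vertex* of a target surface. Vertex-to-vertex (rather than
point-to-triangle) distance is the primary mode because the protocol it
implements is defined on mesh vertices; on meshes whose edge length is
small against the tissue depths of interest the difference is bounded by
about half an edge length. The relation is deliberately directional:
d(hard→skin) is a tissue-depth proxy, d(skin→hard) is not its inverse.

**Exactness.** The KD-tree accelerated path re-resolves each query
within an inflated radius using the same arithmetic as the exhaustive
O(N·M) oracle, so the two are bit-identical, including the tie rule
(equal-distance ties collapse to the lowest target index). This keeps
results independent of spatial-index internals.

**Trimming.** Both surfaces are cut by one plane placed `offset_mm`
(default 50) proximal to the most distal point of the reference
hard-tissue surface along a caller-supplied distal direction (default
−z, the usual axial-stack convention; the scanner frame's
proximal–distal axis is data-dependent and therefore an explicit input,
never inferred). Crossing triangles are split at exact edge–plane
intersections (via `trimesh`), so skin and hard tissue are cut at
exactly the same plane; the cut is left open — capping would add
fictitious skin area to the histogram. Output vertices satisfy
signed-distance ≥ −1e−9 mm (stragglers within tolerance are snapped onto
the plane).

**Histogram.** 100 equal-width bins (configurable) over
[0, max distance] per condition, or an explicit shared range for
overlays (recommended when comparing conditions). Counts are normalised
to percent of source vertices, correcting for different segmentation
densities. Values on an interior bin edge belong to the upper bin and
the maximum to the last bin (numpy convention); a supplied range must
cover the data so percents always sum to 100. The summary reports min,
max, the modal bin and the fraction below a shallow-tissue threshold
(default: the upper edge of the first three bins; where the geometry has
no near-zero depths — as on the phantom — a data-driven threshold such
as the pooled lower decile is the meaningful choice).

## Registration and comparison (method 2)

**Landmark fit.** Orthogonal-Procrustes/Kabsch solution (scipy's
`Rotation.align_vectors`) over ≥ 3 index-paired points, constrained to a
proper rotation — anatomy must never mirror. Collinear source points
leave an axis unconstrained and are rejected. Per-pair residuals and RMS
are returned so landmark quality is visible.

**ICP.** Point-to-point on vertices: iterate nearest-correspondence
(KD-tree), Kabsch fit, update, from the landmark initialisation.
Defaults: ≤ 100 iterations, stop when the correspondence RMS changes by
< 1e−6 mm, optional correspondence-distance gate, at most 5000 source
vertices drawn once with a seeded generator (drawing once, not per
iteration, keeps the RMS trace provably non-increasing). The returned
transform composes the refinement with the initialisation; the contract
is convergence and recovery of applied motions, not bit-matching any
particular GUI tool's variant.

**Hausdorff metrics.** `absolute_bidirectional` is the classic Hausdorff
distance (larger of the two directed nearest-distance maxima);
`average_bidirectional` is the mean of all nearest distances pooled over
both directions — the common symmetric mean-surface-distance convention,
adopted because "average Hausdorff" has no single canonical definition.

**Signed comparison.** With both skins in one frame, each
reference vertex's offset to its nearest other-skin vertex is projected
on the reference's outward area-weighted vertex normal:
`signed = (w − v)·n(v)`, so |signed| ≤ ‖w − v‖ by construction and
negative means the other interface is more compressive at that point.
The unsigned distance is retained alongside, since a heat map of pure
nearest distances cannot encode the direction of the difference. Running
the comparison both ways, the second map's sign is inverted so "negative
= condition B more compressive" holds on both. Vertices within one
median edge length of an open (trim) boundary are flagged — nearest
matches across an open edge are unreliable — and excluded from summary
statistics but kept in heat maps. A reference with > 1 % undefined
normals is rejected as unoriented.

## The synthetic phantom

**Geometry.** Skin: a surface of revolution tapering linearly from 50 mm
radius at the open proximal end (z = 160 mm) to 40 mm at z = 0, closed
by a distal hemisphere (pole at z = −40) and a flat proximal disk;
cross-sections carry a low-order angular modulation
(1.2 mm·cos 2θ ellipticity plus 0.8 mm·cos 3θ "tibial crest") because a
perfectly circular section would put entire vertex rings at identical
distances and produce delta-spike histograms no real limb shows. Bone: a
capsule of radius 15 mm along z ∈ [10, 140]. Both meshes are watertight,
outward-oriented and byte-deterministic for a given spec. In the shaft
region the clearance has the closed form
`r_skin(z)·(1 + m(θ)) − r_bone`, which every distance computation is
tested against (within one skin edge length at the default resolution;
converging with refinement on the axisymmetric variant, where the
closed form is the exact continuum distance).

**Interface conditions.** Deformations move skin vertices inward along
their local radial direction (cylindrical on the shaft, spherical on the
distal cap) by a uniform term plus Gaussian patches in (axial,
circumferential-arc) coordinates; the exact per-vertex displacement is
returned as ground truth and the deformed skin is checked against bone
intersection. Presets:

- *hands-off* (pressure-cast): uniform 2 mm radial compression — the
  hydrostatic, evenly distributed fit.
- *hands-on* (rectified PTB): uniform 3 mm plus a patellar-bar patch
  (5 mm, sd 10 mm), two supracondylar patches (4.5 mm, sd 10 mm) near
  the proximal brim of the analysed region, and an axisymmetric
  total-contact distal cup (8 mm at the distal pole, sd 20 mm axially).
  Rectified sockets remove more cast volume overall than pressure
  casting and grip the distal end; the cup amplitude is scaled to take
  up most of the ~10 mm distal clearance excess that the bone-tip
  offset creates, emulating an evenly loaded distal cushion. Patch
  widths follow the anatomical scale of the features they mimic (a
  patellar-tendon bar is a few centimetres across).

With these presets the phantom reproduces the clinically reported
histogram contrast — the hands-on condition's modal bin is taller and at
smaller depth, with more tissue below a shallow-depth threshold, while
distance maxima stay similar between conditions — and the comparison
maps localise each rectification feature.

**What the phantom does not model.** Tissue mechanics (displacements are
kinematic, volume is not conserved), multi-bone anatomy with realistic
shapes (a multi-part hard-tissue variant exists for compile/merge
testing but has no closed-form truth), segmentation noise and MRI
partial-volume artefacts, liner geometry, and dynamic loading. Passing
the phantom suite therefore demonstrates correctness of the geometric
computations and conventions, not clinical validity of any particular
interface comparison.

## File handling and reproducibility

STL (binary and ASCII, auto-detected) is read through `trimesh`; facet
soup is welded into shared-vertex topology with a 1e−6 mm grid snap —
far below voxel scale, order-independent — and file normals are ignored
in favour of winding. Binary STL stores float32, so writing quantizes
coordinates at ~1e−7 relative. Per-vertex scalar fields travel as ASCII
PLY with a named vertex property; landmarks as CSV
(`src_x..dst_z`, row-paired, ≥ 3 rows); summaries and transforms
(4×4 row-major homogeneous) as JSON. Every CLI run writes a provenance
record (inputs, parameters, seed, version, timestamp); with a fixed seed
all data products are bit-reproducible, timestamps aside. All lengths
are millimetres throughout.

Default problem sizes (64 angular × 48 axial skin rings, ≈ 4k skin and
5k bone vertices) keep the full validation suite and the acceptance
script in the seconds-to-minutes range while holding discretisation
error to a fraction of the tissue-depth scales under study.
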