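# Methods

This note records the geometric model, its operationalisations, the
numerical choices, and what the synthetic data can and cannot show.

## Coordinate conventions

All geometry is in millimetres in a right-handed frame. The canonical pose
is a right knee in full extension: +X lateral, +Y anterior, +Z proximal,
with the transepicondylar axis (TEA) along X through the origin. Left knees
are mirrored across the sagittal plane on entry and the flag recorded; every
landmark and drilling operation assumes the canonical frame (or an
explicitly supplied body frame).

## Mesh primitives

`SurfaceMesh` wraps `trimesh.Trimesh` and enforces the contract on
construction: duplicate vertices merged, degenerate faces removed, winding
fixed so the signed volume is positive, and watertightness required (an open
mesh raises an error naming the open-edge count). Two query paths exist:

- **Arbitrary-direction ray casting** (Möller–Trumbore over all faces,
  vectorised): returns sorted crossings with entering/exiting labels from
  the sign of the ray·normal determinant. Duplicate hits on shared edges
  (equal `t` within 1e-9) are merged and tangential grazes (repeated kind)
  dropped, so the crossing list always alternates.
- **Axis-parallel batch casting**: triangles are bucketed on a uniform 2D
  grid in the plane perpendicular to the axis, so parity (point-in-mesh)
  queries over tens of thousands of points — the breakage classifier's hot
  path — inspect only a handful of candidate triangles each. Containment for
  points within 1e-6 mm of the surface is documented as undefined.

Rotations use `scipy.spatial.transform.Rotation` (Rodrigues); distances are
preserved to 1e-9 relative, which the tests assert.

## Synthetic knee generator

Each subject is built from an implicit composition surfaced by marching
cubes (scikit-image) at a configurable voxel pitch (default 1.0 mm; halved
once on the rare surfacing failure):

- **Femur** = union of two condylar ellipsoids, a flared shaft, and an
  anterior trochlear bridge, minus an intercondylar notch box (open
  posteriorly and distally). The condyles are egg-shaped — the superior
  semi-axis is 0.5× the inferior one — because real condyles hang below the
  epicondyles but the bone narrows quickly above them; without this the
  supracondylar region carries unrealistically much bone and steep
  low-flexion drill paths come out far too long. The trochlear bridge merges
  the condyles anterior of the notch apex, as the patellar surface does;
  it also makes "the most anterior edge of the intercondylar notch" a real
  boundary (without it the corridor is open anteriorly).
- **Tibia** = plateau slab (rounded box) + shaft, with the plateau top
  2 mm below the lowest condyle point (extension joint-space gap) and the
  TEA parallel to the plateau ML axis.

The only population-anchored dimension is the transepicondylar distance,
drawn per subject from N(82.1, 5.7²) mm and clamped to [60, 110]. Every
other default is an invented plausible proportion of it (condyle radii
0.27×, notch width 0.22×, notch height 0.20×, shaft radius 0.17×, plateau
ML width 0.95×, AP depth 0.62×), all overridable. A per-subject seed adds
shape variation beyond size: ±2% condylar asymmetry, AP elongation
1.10 ± 0.04, posterior condylar offset −2 ± 1 mm, notch apex position
6.5 ± 0.8 mm. Region labels (lateral-condyle medial wall, medial-condyle
articular surface, tibial plateau, external cortex) are assigned from the
generating primitive nearest each face; "cartilage of the medial femoral
condyle" is approximated by the labelled articular bone surface, since the
models are bone-only.

**What the generator does not emulate:** real cortical/trabecular
distinction, the posterior femoral cortex concavity, menisci and soft
tissue, per-patient footprint variability, and statistical shape learned
from real anatomy. Passing trend tests on this cohort therefore shows that
the pipeline's geometry and logic produce the expected directional effects
under hinge kinematics — not that the absolute magnitudes transfer to
patient anatomy.

## Landmarks and footprints

- **Epicondyles/TEA**: extreme ±X surface points within the distal half of
  the femur; the TEA runs through their midpoint, directed medial→lateral.
- **Notch roof (Blumensaat-line proxy)**: in the true-lateral projection
  (viewing along the TEA), a grid of TEA-parallel rays classifies each
  (anterior, proximal) station as "corridor-open" when bone exists on both
  sides of the mid-epicondylar plane but not at the plane itself. Per
  anterior station the roof is the top of the lowest contiguous open run
  (runs shorter than two samples are noise and skipped); roof points must
  lie distal to the epicondylar level. The notch apex is the most anterior
  roof point; the proxy direction is the principal axis of the traced roof,
  oriented posterior→anterior. Sampling: 121 × 101 stations over the
  projected extent — ranges come from projected vertices so the trace is
  equivariant under rigid transforms applied jointly to mesh and frame.
- **Quadrant grid**: on the medial-wall submesh's lateral-projection
  silhouette, `extent_along` = silhouette span along the proxy direction,
  `extent_perp` = span from the proxy line toward distal (the Bernard
  convention of full condyle depth/height; the perpendicular 100% end is
  taken toward the distal articular margin — the convention is stated, not
  guessed silently). The femoral footprint centre sits at fractions 0.284
  (from the posterior border) and 0.357 (from the proxy line), lifted onto
  the wall by a ray along the viewing axis from the medial side. Because the
  projection is along the TEA, posing the knee at 90° before projecting
  would not change the grid; it is computed in the extension pose.
- **Tibial footprint**: fractions 0.357 (AP, from anterior) and 0.515 (ML,
  from medial) of the plateau outline's bounding box in the least-squares
  plateau plane, lifted by a proximal→distal ray.

## Kinematics

Flexion is a pure hinge of the tibia about the fixed TEA (femur, footprint
and tunnel stay world-fixed), with the sign chosen so the tibial shaft's
distal end moves posteriorly. Roll-back and screw-home motion are
deliberately not modelled. The tibial footprint used for the bending angle
is the extension-pose one, matching the full-extension measurement
convention.

## Drilling

- **Portal line**: parallel to the posed plateau ML axis, 10 mm above the
  plateau along its posed normal, 15 mm anterior to the posed plateau's
  anterior-most point (configurable; see Limitations for its sensitivity).
  The parameter `s` increases medially.
- **Transverse angle**: between the portal→footprint direction projected
  into the posed plateau plane and the plateau AP axis (0° = sagittal,
  90° = fully transverse). Only angle *differences* (−10°, −20°) matter
  downstream, which this datum preserves.
- **MTA search**: bisection on `s` (tolerance 0.02 mm) for the most medial
  portal whose full cylinder (radius 4 mm about the portal→exit segment)
  keeps non-negative clearance from the medial-condyle articular region;
  feasibility monotonicity is validated on a 17-point bracket first and a
  non-monotone pattern is an error. The bracket is the plateau ML extent
  ± 20 mm, with the lateral end clamped where the drill direction crosses
  the sagittal plane — lateral of that the drill would point medially, which
  is not a transportal geometry and breaks both monotonicity assumptions.
  If the constraint never binds, the medial end is returned and flagged.
- **Tunnel**: axis from the footprint centre `F` along `unit(F − portal)`;
  the exit is the *last* inside→outside crossing with the femur, so notch
  re-entries do not truncate the tunnel. A grazing axis with no real chord
  yields a zero-length (short) tunnel rather than an error.
- **Breakage classification** (an operationalisation of a verbal
  definition): 72 wall generators at radius 4 mm are sampled every 0.25 mm
  over the first min(length, 25) mm. *Entrance* breakage: some generator has
  no in-bone sample within the first 8 mm (the oblique-aperture allowance —
  on an oblique entry the far wall starts several mm in). Otherwise
  *mid-tunnel* breakage: some generator leaves bone again between its first
  in-bone sample (+0.5 mm) and the window end (−0.5 mm). All five constants
  are configurable; a resolution-stability test (halved step, doubled
  generators) guards the defaults on constructed defect fixtures. An
  alternative operationalisation via the topology of the cylinder/surface
  intersection curve would avoid the sampling constants but is substantially
  harder to make robust on surfaced meshes.

## Statistics

One-way within-subject ANOVA: F = MS_condition / MS_(condition×subject),
df = (k−1, (k−1)(n−1)), sphericity assumed. A Greenhouse–Geisser correction
is not applied by default because the analysis this mirrors reports none;
the framework flags degenerate inputs (zero error variance) rather than
failing. Post hoc: all k(k−1)/2 two-sided paired t-tests with Bonferroni
adjustment within one family (m = 6 for four flexion levels, m = 3 for three
drill angles). Cochran's Q uses the closed form with a chi-square(k−1)
reference; the all-rows-constant case returns Q = 0, p = 1, flagged. Tests
verify the paired-t identity (F = t² at k = 2), the McNemar identity
(k = 2), calibration of the type-I error under a simulated null, agreement
with statsmodels' independent implementations, and — for one enumerable
4×3 instance — closeness to the exact within-row permutation null. At n = 4
the chi-square approximation is rough for most instances; the test documents
this and uses an instance where it is usable.

## Problem sizes and determinism

The default test/acceptance cohort is 10 subjects (seed 42) at 1.0 mm voxel
pitch — a full 4×3 grid takes ~4 s/subject end to end, and the whole suite
runs in well under two minutes. The many-draw generator invariant sweep uses
100 subjects at 2.0 mm pitch, where surfacing is ~10× cheaper and the
invariants under test (watertightness, labels, epicondylar separation) are
pitch-insensitive. Everything is deterministic given seeds: cohort draws use
`numpy.random.default_rng`, per-subject seeds derive from the master seed,
and reruns produce identical tables.

## Known limitations

- **Portal kinematics**: the portal line is rigidly attached to the posed
  tibial plateau, so under pure hinge flexion the portal swings up and
  behind the femur; at surgical flexion (≥110°) it lies posterior to the
  femoral footprint and the drill elevation *decreases* with flexion. Two
  consequences: (i) the graft bending angle grows from MTA to MTA−20° at
  high flexion (a physical portal held at the anterior joint line gives the
  opposite ordering); (ii) the MTA-column tunnel length saturates between
  120° and 130° — its mean rises ~2 mm from 100° to 120° and is flat to
  marginally lower at 130° on the default cohort. The portal AP offset
  controls this saturation (larger offsets restore monotonic growth); the
  default stays at 15 mm.
- Bone-only models: "cartilage" clearance is bone-surface clearance.
- The quadrant grid spans the silhouette bounding extents; real quadrant
  measurements are made on radiograph-like projections with observer
  judgement.
- Breakage is a sampled-generator criterion; pathological sub-sample-width
  defects would be missed (the stability test bounds this at the defaults).
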