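# Methods

## Model and assumptions

The grid-cutting crop treats a dental scan as a shared-vertex triangle
mesh in millimetres and operates purely per-vertex: no vertex is created,
moved or smoothed, and connectivity is consulted only at the end, when
faces touching a removed vertex are dropped. Consequently the method is
indifferent to mesh quality — non-manifold geometry, disconnected flaps
(cheek, lip) and degenerate slivers are all accepted — which is what makes
it workable on scans taken directly in the mouth.

Two assumptions matter:

* **Orientation is declared, not detected.** The user states maxilla or
  mandible; the maxilla is flipped by a rigid 180° rotation about the
  x-axis through the centroid. A rotation rather than a z-mirror preserves
  chirality (a mirror would swap left/right anatomy). The rotation axis
  (x vs y) is a free choice recorded in the run report; nothing downstream
  depends on it because the occlusal fit and grid are both recomputed in
  the oriented frame.
* **The occlusal surfaces are the local height maxima.** Both the
  R-exclusion and the inclusion threshold measure "tooth-ness" by height
  relative to the approximated occlusal plane. Structures that violate the
  assumption — a partly erupted third molar far below the plane — are
  removed as if they were soft tissue; this is inherent to the method, and
  the test suite reproduces it rather than patching it.

## Occlusal-plane approximation

"Least squares" is ordinary least squares of z on (x, y) (minimising mean
squared z-residuals), not total least squares: the scan is oriented z-up
and every comparison in the pipeline ("below the plane", "largest z") is
z-based, so the z-residual fit is the internally consistent reading. The
same routine fits both the initial fitting plane (all vertices) and the
occlusal plane (four points).

Free choices fixed here:

* Section planes sit at 1/3 and 2/3 of the x-extent and 1/2 of the
  y-extent of the *surviving* vertices' bounding box (the vertices on or
  above the fitting plane), giving six roughly equal sections over the
  arch. Bins are half-open with the last bin closed, so membership is
  unambiguous.
* "Below the fitting plane" is a strict signed-perpendicular-distance
  test; vertices exactly on the plane survive.
* A section representative maximises perpendicular distance above the
  fitting plane; among the ≤ 6 representatives the four with largest z are
  fitted. All ties break toward the lowest vertex index, making the result
  order-stable and bit-reproducible.
* If only four or five sections are populated, the largest-z rule applies
  to what is available; below four the operation fails with an error
  naming the empty sections, since a two- or three-point "plane" would be
  arbitrary.

## Square analysis

The evaluation point E_p of a square is its highest vertex — a fast proxy
for the vertex closest to the occlusal plane. Two rules follow:

* **R-exclusion.** d(E_p), the perpendicular distance of E_p *below* the
  occlusal plane (clamped conceptually: on/above the plane d ≤ 0 and the
  square always passes), is compared against R × z-range, where the
  z-range is computed once over the whole oriented scan before any
  removal. The comparison is strict (excluded when larger). Perpendicular
  rather than vertical distance is used because the quantity is a distance
  to a plane; for near-horizontal occlusal planes the difference is
  negligible.
* **Inclusion threshold.** The threshold point is T = E_p − I·N_o with N_o
  the upward unit normal of the occlusal plane. The displacement runs
  *away* from the occlusal plane: E_p is the square's top and the retained
  band extends I mm downward from it — the sign convention that makes
  "vertices with z above the threshold are kept" coherent. The keep rule
  compares z-values non-strictly (z ≥ z(T)), so E_p itself survives even
  at I = 0.

Monotonicity follows from the construction: the occlusal plane and the
exclusion verdicts do not depend on I, and enlarging R can only turn
excluded squares into cropped ones, so the kept set is nested in both I
and R. The test suite asserts this, along with translation equivariance
(the grid is anchored at the bounding-box minimum) and vertex-for-vertex
agreement with an independent brute-force reimplementation.

## Mesh I/O

STL stores an unindexed triangle soup; reading welds coincident corners
into shared vertices by exact coordinate match at a tolerance of 1e-6 mm
(scanner exports repeat shared corners bit-identically; a larger tolerance
risks fusing fine occlusal detail). File normals are ignored. Degenerate
triangles are dropped on read with a logged count. Binary STL stores
float32, so a write/read round-trip preserves coordinates to ~5e-6 mm at
scan scale; ASCII output is full precision. Welding orders vertices by
face traversal, so round-trips are the identity up to vertex reindexing.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| G (grid size) | mm | 1 | granularity of the per-square crop; smaller follows the dentition more closely |
| I (inclusion criterion) | mm | 7 | depth of surface retained below each square's top; roughly a clinical crown height plus a gingival collar |
| R (ratio of inclusion) | — | 0.33 | fraction of the scan's z-range used to discard toothless squares |
| retry setting | | G=5, I=5, R=0.4 | coarser, more permissive variant for arches where the defaults clip a tooth |

## The synthetic arch generator

`gridcut.synth` emulates the conditions the method must handle, not dental
anatomy. The surface is a band following a parabolic arch midline
(width 50 mm, depth 40 mm, half-width 5 mm — typical adult-arch
dimensions), with a gingival skirt falling 5 mm (default) below the dental
ridge and truncated-Gaussian crowns of height 8 mm (default) at up to 16
tooth positions; optional features are missing teeth, a low ectopic molar
(height = eruption_fraction × tooth height, laterally displaced by the
tilt), and a retromolar flap (a broader soft bump at one distal end).
Vertex z receives seeded Gaussian jitter (σ = 0.02 mm) emulating scanner
noise; everything else is deterministic in the seed.

The tooth label is crown-only: a vertex belongs to a tooth when that
tooth's bump contributes at least half the crown height *and* the vertex
lies in the upper half of the crown. The success criterion of the method
is tooth preservation, not gingival-margin accuracy, so a conservative
label avoids penalising legitimate cropping near the margin. With the
default geometry this puts the lowest tooth-labeled vertex 4 mm below the
cusp level while the R-exclusion boundary sits at ≈ 4.3 mm below the
occlusal plane — a deliberate ≈ 0.3 mm margin, an order of magnitude above
the jitter, so tooth preservation on standard arches is a property of the
method, not of a lucky seed.

What the generator does **not** emulate: real crown morphology (fissures,
marginal ridges), malocclusion, scan holes and boundary noise, reflective
artefacts, and partially captured cheeks in arbitrary positions. Passing
tests therefore demonstrate the geometric contracts of the algorithm and
its behaviour under the study-like conditions above — they do not certify
performance on clinical scans.

## Numerical choices and degenerate inputs

* Plane fits use a dense least-squares solve; rank-deficient xy
  configurations (collinear points) raise a degenerate-fit error.
* Grid bins are half-open, the last column/row closed; a vertex exactly on
  an interior grid line belongs to the higher-indexed square.
* An all-excluded crop returns an empty mesh with a warning flag rather
  than an error — an empty result is a legitimate outcome, e.g. under a
  tiny R.
* The cropped mesh is returned in the oriented frame (a maxilla stays
  flipped) so downstream scan-to-scan comparison sees a uniform frame; the
  CLI's `--restore-frame` un-flips for visual comparison against the
  input.
* There is no randomness anywhere in the pipeline; identical input and
  parameters give byte-identical output.

## Problem sizes

Tests and the acceptance script use arches of ≈ 2 000–4 200 vertices
(0.5–0.75 mm resolution) and random relief meshes of ≈ 320 vertices; the
brute-force equivalence check runs on 25 meshes ≤ 2 000 vertices. These
sizes exercise hundreds to thousands of grid squares per scan — the same
regime as a clinical scan at a coarser sampling — and keep the full suite
in the seconds range. The pipeline itself is vectorised and handles
larger meshes linearly in vertex count.

## Known limitations

* Partly erupted or ectopic third molars below the R-exclusion boundary
  are removed; the retry parameters rescue moderate cases only.
* A tall retromolar flap can enter the section representatives and tilt
  the approximated occlusal plane (reproduced in the tests).
* The method never traces the tooth/gingiva boundary; gingiva within I mm
  of each square's top is always retained.
* No automatic jaw-side detection and no automatic parameter tuning.
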