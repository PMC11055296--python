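# Methods

This note documents the measurement model, the synthetic validation
surfaces, the numerical choices, and the limits of what the test suite
demonstrates.

## Anatomical frame

All measurements are expressed in a world frame constructed from the seven
landmarks and nothing else, so any rigid motion of the input leaves every
radius unchanged (verified to < 1e-6 mm in the tests).

* **Transverse plane α** — through the anterior medial border extreme, the
  posterior medial border extreme and the anterior lateral border extreme.
* **Coronal plane β** — perpendicular to α, through midpoint(ant-medial,
  post-medial border extremes) and midpoint(ant-lateral border extreme,
  posterolateral corner edge). This definition is intrinsically slightly
  asymmetric (one endpoint is a border extreme, the other a corner edge),
  so β is typically tilted a fraction of a degree from the "ideal" coronal
  orientation; all downstream constructions inherit the frame consistently,
  so the tilt does not bias radii (demonstrated by the synthetic recovery
  tests).
* **Origin** — the fitted talar centerpoint: circumcenter of point 1 =
  midpoint(AM, AL edges), point 2 = midpoint(PM, PL edges) and point 3 =
  the superior surface projection of midpoint(point 1, point 2). The
  projection direction is the α normal oriented toward the trochlear side;
  that side is identified from the corner edges' offset from α, falling
  back to the mesh's mean side for degenerate patches whose corners lie on
  α (e.g. a pure cylinder patch).
* **Axes** — +Z = superior α normal, +Y = β normal toward the anterior
  landmarks, +X = Y × Z. Left-side specimens are mirrored about the
  sagittal plane after the rigid alignment; radii are mirror-invariant, so
  no further correction is needed.

Two deliberate resolutions of under-determined constructions: the fitted
centerpoint (not the triple-plane intersection) is *the* origin, and the
sagittal plane passes through it. If the centerpoint circle is nearly
collinear — a trochlea whose dome barely rises above the corner-chord
plane — the fitted center can lie arbitrarily far away and the
medial/lateral split at X = 0 becomes meaningless; the frame builder
therefore rejects specimens whose fitted centerpoint lies more than 50
corner-quad diagonals from the trochlea as degenerate rather than
silently producing garbage.

## Regional radii

Six coronal station planes (normal +Y) pass through the anteroposterior
positions of the four corner edges and the two per-side midpoints. The
*top point* of each station is the maximal-Z polyline point of its section
curve within the requested half (X < 0 medial, X > 0 lateral); exact ties
are broken toward the groove (smaller |X|), which makes the measurement
deterministic on exactly symmetric surfaces. The duplicate-position
degeneracy check for stations is applied within each side's triple, since a
symmetric trochlea legitimately places medial and lateral stations at the
same Y.

Each crest section plane passes through two adjacent tops and the superior
surface projection of their chord midpoint; if those three points are
collinear (e.g. both tops on a cylinder at the same Y), the vertical plane
through the chord is used instead. The radius is the circumcircle through
the two tops — snapped onto the section curve by orthogonal projection
onto its segments — and the point halfway between them by cumulative arc
length. Snapping tolerance is 0.5 mm (configurable); endpoints further
from the curve than that indicate an upstream failure and raise an error.
The midsagittal radii use the same three-point rule on the X = 0 profile
restricted to the anteroposterior span of the corner edges, with extremes
anterior = max Y, superior = max Z, posterior = min Y.

Sensitivity note: a three-point circle on a shallow arc amplifies
out-of-plane error roughly by c²/(8h²) (chord c, sagitta h); for a
posteromedial radius of ~34 mm sampled over ~12 mm the factor is ~60. The
measurement is nevertheless stable because the three points are taken *on*
the section curve itself, so their error is bounded by the mesh chordal
sag (~r·Δθ²/8), not by the top-detection error.

## Cylinder fit

The trochlear patch is separated as the vertices whose (X, Y) fall inside
the corner-edge quadrilateral (inflated by a configurable margin, default
0 mm) and whose outward normal points superior. The fit minimizes
Σ (dᵢ − r)² over five parameters: two axis-direction components about the
mediolateral initialization, two axis-point offsets in the plane through
the centroid perpendicular to the axis, and the radius. The problem is
internally centered and scaled by the mean centroid distance;
Levenberg–Marquardt is followed by a short Gauss–Newton polish
(central-difference Jacobian, stop at step < 1e-13) because LM's relative
stopping rules alone leave the radius reproducible only to ~rms·1e-7,
which would fail the 1e-9 scale-equivariance contract. On an exact
cylinder the fit returns the radius to machine precision; on a sphere it
converges to a finite underfit (reported with its rms) rather than erroring.

## Synthetic trochlea generator

The generator emulates the features of the articular surface that the
measurement chain actually exercises:

* two anteroposterior crests at x = ±x_c whose sagittal profiles are two
  circular arcs tangent at the apex (independent anterior/posterior radii
  per crest); the apex sits at the midpoint of the articular
  anteroposterior extent, so arc-length midpoints stay on a single arc and
  ground truth is exact;
* mediolateral radius interpolation by smoothstep with knots at the two
  crests and the midline, optionally with independent mid-station radii
  (default: crest means). The zero derivative at the knots keeps the crest
  lines stationary in x, so discretized top points carry only second-order
  error — with a kinked crest the same measurement shows ~3–5 % bias,
  which is why the surface is built smooth;
* a central groove of depth g with a squared-parabolic transverse profile
  (again zero slope at the crests), quadratic shoulder ramps descending to
  a flat rim (the "thin skirt"), and a linearly widening anterior border so
  the border extremes are unique landmark points;
* exact landmark coordinates: corner edges at the crest arc termini, border
  extremes on the rim (all rim points share one height, which puts the
  generated specimen exactly in standard pose for the α plane);
* optional Gaussian vertex noise applied along z (keeps the parametric grid
  single-valued), seeded and bit-reproducible; left-side specimens are
  mirrored about the sagittal plane.

Default dimensions (mm): crest half-separation x_c = 13, articular AP
extent 24 (+1 margin so stations cut interior mesh), groove depth 2.5,
anterior widening 2, grid 200×200 — proportions of an adult talus with the
default crest radii set to the reference cohort's regional means.

**Feasibility envelope.** Two parameter combinations are rejected at
generation time: (i) a mid radius so much larger than a crest radius that
the groove center would rise above the crest at the corner stations
(arc-drop difference > groove depth − 0.25 mm) — the crest top points
would migrate into the groove; (ii) a dome whose mean corner arc-drop
exceeds the groove depth by less than 0.5 mm — the centerpoint circle
would be nearly collinear. The cohort generator draws per-region radii
independently (normal, truncated at the constructible minimum) and redraws
the six-tuple until it admits a feasible groove depth, which it then
assigns per specimen; this truncates the joint tails while leaving the
per-region means close to their targets.

**What the generator does not emulate:** real cortical-surface roughness
and segmentation artifacts, the inferior talar body (only the superior
patch plus skirt is generated), non-circular crest profiles, and
digitization error in the landmarks (landmarks are exact unless the user
perturbs them). Passing the recovery tests therefore demonstrates the
correctness of the geometric chain, not robustness to every artifact of
clinical CT meshes; the landmark–surface tolerance (2 mm) and the snap
tolerance (0.5 mm) are the knobs that would absorb such noise.

## Cohort statistics

Pooled-variance (Student) t is used for two-group comparisons — the choice
is confirmed by recomputing the reference cohort's printed fitted-radius t
statistics (6.894 and 0.783) from its printed summaries, which match the
pooled formula to well within print rounding. The six regions are treated
as independent groups in the one-way ANOVA (the same recomputation check:
F = 54.905 emerges from the printed Table of six n=91 summaries only under
that model, even though 30 subjects contribute both sides). Fisher's LSD
deliberately applies no multiplicity correction. p-values are two-sided;
reports format p to three decimals with "< 0.001" below that.

The bundled `data/reference_summaries.json` carries the published
reference cohort's printed per-region and fitted-radius summaries and
statistics; `check-reference` recomputes the latter from the former. The
residual deviations (≤ ~1 %) are attributable to the 2-decimal rounding of
the printed summaries.

## Study sizes used by the tests and the acceptance script

Parameter-recovery runs use noise-free 200×200 trochleae (crest radii
within 2 %, midsagittal within 5 %; observed ≲ 0.2 %) and 257×257 cylinder
patches (all radii within 1e-4 relative; observed ≲ 7e-5). The cohort
ordering study uses the default demographics — 61 subjects (28 male, 33
female), 30 bilateral, 91 tali — at a 96×96 grid, where per-specimen
measurement error (≲ 0.4 %) is negligible against the between-specimen
SDs (3–5 mm). The ordering profile separates adjacent regional means by
4 mm: with the reference cohort's own printed means, the MP–AL (0.38 mm)
and MA–AM (1.0 mm) gaps are not population-detectable at n = 91, so a
cohort that preserves the anatomical ordering with detectable adjacent
separations is the appropriate positive control for the ordering property.
Statistical calibration uses 1000 null replicates per test at the
reference sample sizes.

## Known limitations

* The mid-station radii of the default (linear-field) generator are tied
  to the crest means; reproducing orderings in which MP falls below both
  posterior crest radii requires the independent mid-radius fields, which
  the `ordered` and `reference` presets use.
* Landmark placement is an input; no automatic landmark detection is
  provided or planned.
* The β-plane definition leaves a small frame tilt (< 1°) intrinsic to the
  landmark geometry; radii are unaffected but exported standardized meshes
  inherit it.
* The records pipeline treats each talus as one observation; bilateral
  correlation is addressed only by the matched paired-t comparison, not by
  mixed-effects modeling.
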