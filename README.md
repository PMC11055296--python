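# talusmorph

Landmark-driven morphometry of the **talar trochlea** — the pulley-shaped
superior articular surface of the talus that the tibia rides on. The shape
of this surface, and in particular how its radius of curvature varies
between regions, drives the design of talar components for total ankle
replacement: current prostheses are often symmetric cylinders, while real
trochleae have distinctly different anterior and posterior radii on the
medial and lateral crests.

`talusmorph` measures, from a triangulated surface mesh (STL, mm) plus
seven digitized anatomical landmarks:

* the **six regional radii of curvature** — anteromedial (AM),
  anterolateral (AL), posteromedial (PM), posterolateral (PL) along the two
  crests, and mid-anterior (MA) / mid-posterior (MP) on the midsagittal
  profile;
* the **cylinder-fit radius** — the radius of the least-squares right
  circular cylinder fitted to the separated trochlear patch;
* the **cohort statistics** used to compare regions, sexes, sides and age
  groups, operating both on raw per-specimen records and directly on
  published (n, mean, SD) summaries.

## Method

Every specimen is first standardized into an anatomical world frame built
from the landmarks alone (so the result is independent of scanner pose):
the transverse plane α passes through the three border-extreme landmarks,
the coronal plane β is perpendicular to α through two landmark midpoints,
and the origin is the **fitted talar centerpoint** — the circumcenter of
the two corner-chord midpoints and the superior surface projection of their
own midpoint. Axes: +Z superior, +Y anterior, +X lateral; left tali are
mirrored so the medial crest always lies at X < 0.

Each regional radius is a **three-point circumcircle** on a section curve:
six coronal station planes (through the AM/PM/AL/PL corner landmarks and
the two mid-stations) locate the crest *top points* (maximal-Z points of
the section curves per medial/lateral half); a nearly sagittal plane
through each pair of adjacent tops and the surface projection of their
chord midpoint cuts the crest profile; the radius is

    r = |AB| · |BC| · |CA| / (4 · area(ABC))

for A, B the two tops (snapped onto the curve) and C the point halfway
between them by cumulative arc length. The MA/MP radii apply the same
three-point rule to the (anterior, superior) and (superior, posterior)
extremes of the midsagittal profile. The cylinder fit minimizes
Σᵢ (dᵢ − r)² over the axis line (direction + in-plane offset) and radius,
where dᵢ is the distance of patch vertex i to the axis.

The statistics layer implements the pooled-variance (Student) two-sample t,
the paired t, one-way independent-groups ANOVA, Fisher's LSD post-hoc
comparisons, and Pearson correlation — all available directly from
(n, mean, SD) summaries, which makes published summary tables exactly
recomputable.

Because no real cohort is distributed with the package, validation rests on
a **synthetic trochlea generator** with exact analytic ground truth: two
anteroposteriorly running crests whose sagittal profiles are pairs of
circular arcs tangent at the apex (independent anterior/posterior radii per
crest), a central groove, anterior widening, and exactly placed landmarks.
The full pipeline recovers the generator's crest radii to ≲ 0.2 % and an
exact cylinder patch to < 1e-4 relative. See `docs/methods.md` for the
model details, parameter defaults and known limitations.

## Worked example

Generate a synthetic trochlea with known radii and measure it back:

```sh
$ talusmorph synth --preset asymmetric --out demo --grid 200
wrote asymmetric.stl, asymmetric_landmarks.json, asymmetric_truth.json in demo

$ talusmorph measure --mesh demo/asymmetric.stl --landmarks demo/asymmetric_landmarks.json
{
  "specimen": "asymmetric.stl",
  "side": "right",
  "radii_mm": {
    "r_am": 16.0042,
    "r_al": 22.0094,
    "r_pm": 34.0258,
    "r_pl": 28.0251,
    "r_ma": 18.9967,
    "r_mp": 31.0169,
    "r_cyl": 21.7503,
    "cyl_rms": 0.8288
  }
}
```

The generator's true crest radii were (AM, AL, PM, PL) = (16, 22, 34, 28) mm
and the mid radii their crest means (19, 31): every measured radius lands
within ~0.1 % of truth. `r_cyl` is the single-cylinder compromise across a
surface whose true radii range from 16 to 34 mm, with the misfit reported
as `cyl_rms` (0.83 mm here) — exactly the compromise a cylindrical
prosthesis component makes.

The statistics layer reproduces published reference-cohort results from
their printed summaries:

```sh
$ talusmorph check-reference
anova_regions_F: observed 54.904  printed 54.905  (relative deviation 0.0000)
fitted_t_male_vs_female: observed 6.884  printed 6.894  (relative deviation 0.0014)
fitted_t_right_vs_left: observed 0.776  printed 0.783  (relative deviation 0.0085)
pooled_fitted_mean_by_sex: observed 20.517  printed 20.520  (relative deviation 0.0001)
```

Batch measurement of a cohort (`talusmorph batch --manifest …`) writes one
CSV row per talus; `talusmorph stats --records …` then produces per-region
summaries, sex/side/age-group t tests, matched bilateral paired t tests and
age correlations.

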