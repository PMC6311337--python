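# Methods

This note documents the geometric model behind `pubicorridor`, the
numerical choices, what the synthetic phantoms emulate (and do not),
and the known limitations. Angles are degrees, lengths millimetres
throughout.

## The measurement model

The unit of analysis is one hemipelvis, represented by a watertight
triangulated surface in mm with outward normals, plus a set of named
landmarks: the pelvic-brim polyline ordered medial→lateral, the outer
tubercle edge curve *m*, the lowest symphysis point *O*, the upper and
lower symphysis boundary points, the closed obturator-foramen loop and
the tubercle apex (optionally also the contralateral apex, which lives
on the opposite hemipelvis and is exempt from the on-surface check).
Landmarks are snapped to the nearest surface point on load and rejected
beyond 1 mm: they originate from clicks on a rendered surface, not from
the mesh itself.

### Plate placement

The insertion curve is the brim offset 5 mm onto the superior pubic
surface. Offsetting is geodesic: from each brim station the curve
marches perpendicular to the brim within the local tangent plane in
sub-steps (default 0.5 mm), re-projecting onto the surface after each
sub-step; on a planar face this reduces to the exact Euclidean offset.
At the brim the superior surface meets the posterior cortical wall in
an edge, so the marching normal is taken only from faces the point
touches that are roughly parallel to the travel direction (and, at end
corners, to the brim tangent); which sheet to march on is seeded from
the side of the tubercle-edge curve and then propagated by direction
continuity. "5 mm from the boundary" is thus a surface distance — the
measurement convention is not standardised, and users comparing against
calliper (chordal) measurements should expect sub-0.1 mm differences on
gently curved bone.

S is the most medial close approach (within 1 mm) of the offset curve
to the tubercle-edge curve, refined by 0.01 mm arc resampling; M and L
lie 6.5 mm and 6.5 + 13 = 19.5 mm lateral of S in chord-accumulated arc
length (the plate's first-hole offset and hole pitch; both overridable
via `PlateSpec` to model other implants).

### Containment

A screw is a cylinder (default diameter 3.5) from an on-surface entry
point. Containment samples the lateral surface on axial rings (24 rings
at the accurate profile, never sparser than one ring per 2.5 mm — sparse
rings alias grazing tangencies) with 32 points per ring, plus tip-cap
points, and requires every sample to lie inside the mesh within
`contain_tol` (0.01). Three deliberate conventions:

* **Circumscribed sampling.** Ring samples sit at `r / cos(pi/n_circ)`
  so the sampled polygon never under-covers the true cylinder; combined
  with the small positive tolerance, sampling and tolerance errors
  partially cancel (net angular bias ≤ ~0.05° at the defaults).
* **Countersunk head.** A cylinder entering at the surface necessarily
  protrudes near its head once tilted. Samples above the entry tangent
  plane are exempt, with the plane lowered 0.3 mm below the entry: on a
  gently convex faceted cortex the exact tangent plane would retain
  samples protruding by the faceting sagitta (~0.05 mm), making verdicts
  orientation-dependent. A cylinder whose samples are *all* exempt
  (pointing out of the bone) counts as not contained.
* **Inside test.** Point-in-mesh is the generalized winding number
  (robust for watertight meshes, no ray/edge degeneracies), with exact
  point–triangle distances for near-boundary points; both are
  JIT-compiled with numba when available, with a vectorised numpy
  fallback.

### Angle and length searches

All maxima are bisections between a contained and a violating bracket
located by a coarse sweep (3° steps at the accurate profile), to an
angular tolerance of 0.02° and a length tolerance of 0.01 mm; the
searches are deterministic, so results are reproducible bit-for-bit for
fixed inputs and config. Tilt searches cap at 89°: beyond that a screw
lies on the surface and the tangency concept degenerates.

Two length policies define feasibility of a tilt:

* **fixed** (posterior default): the shortest implantable screw (14 mm)
  is contained. MPIA is the supremum posterior tilt under this policy —
  the short screw shown at maximal retroversion.
* **max-tangent** (anterior default): a screw spanning the corridor —
  reaching the far cortex — is contained. The test length is the
  centreline's far exit chord minus `r/cos(incidence)` at the exit face
  (so oblique and grazing exits are handled), never stopping more than
  `crossing_margin_mm` (14) short of the exit. MAIA is the supremum
  anteversion at which the full-length screw still clears the anterior
  cortex; at that tilt the screw is tangential to it, and L1/L2 are its
  maximal tangent length, measured 0.4° inside the supremum because at
  the exact tangency the tangent length is numerically bistable (stop
  at the contact vs run past it).

On a parallel-walled strip both policies coincide with the closed 2D
rectangle-in-strip solution; the package carries that closed form *and*
an independent 0.01° dense-sweep oracle, and the test suite holds the
mesh search to 0.1° / 0.1 mm of the sweep over 20 configurations with
wall separations 8–20 mm and entry clearances up to 11.5 mm — the
clinically occurring tilt range. Beyond ~60° tilt the tangency condition
is ill-conditioned (clearance changes < 0.05 mm per degree), and no
0.1°-level comparison is meaningful there; the certificates therefore
use a 0.15° epsilon, the documented angular uncertainty.

### Tangential-obturator screw

Directions from L are parametrised by medial inclination α (from the
inward surface normal toward the symphysis) and A/P tilt β. The search
returns the minimal α at which any β admits a contained
corridor-spanning screw, by bisection on α over a β grid (±18°, 2°
steps, lazily scanned from the last success, with the feasible-interval
edges refined to 0.05°); β is the midpoint of the feasible interval at
α*. The returned screw is tangent to the obturator-side inner cortex;
if α = 0 is already feasible (no foramen constraint binds, e.g. a
phantom without a hole) the result is flagged unconstrained. MIA and
APIA are the axis angles against the in-plane perpendiculars to the
cortical tangent, measured in the two cross-section planes at L.

### Cross sections and reference lines

Plane 1 at L is spanned by the L→brim perpendicular and the tangential
screw axis; plane 2 is orthogonal to it through the axis. Plane 3 — the
inner screw's insertion plane — is spanned by the M→brim perpendicular
and the MO direction (it contains both M and O); plane 4 is orthogonal
to plane 3 through O and M, and hosts the insertion-plane MIA: the
angle between OM and the in-plane perpendicular to the cortical tangent
at M. The outer screw is measured in the plane through L parallel to
plane 3. Reference lines are in-plane projections of the inward surface
normal, the normal being area-averaged over a 2 mm patch. Anterior/
posterior and medial senses are derived from the landmarks themselves
(offset-curve direction and the direction toward O), never from global
axes, which is what makes every measurement mirror- and rigid-motion
invariant (verified to 0.1°/0.1 mm in the suite).

### Safe region

Faces nearly parallel to the tangential axis (|n·axis| < 0.35) with an
anterior (resp. posterior) outward component are projected along the
axis; the endosteal envelopes of the two projected sheets are binned
polylines whose least-squares lines classify the pattern: crossing
inside the silhouette (or pinching below one screw diameter at its
edge) with apex ≥ 90° is a blunt V, < 90° a sharp V, otherwise the
boundaries are disjoint. The 90° split is a package choice — the three
patterns are described qualitatively in the literature without a
numeric criterion — and is exposed in the config.

## Statistics

Intersex comparisons use the pooled-variance Student *t* from group
summaries (for the equal-n tables the statistic equals Welch's; only
the df differ), two-sided p, significance at 0.05, no multiplicity
correction. Pooled "Total" rows use exact two-group pooling of means
and variances (identical to concatenating raw samples). The normality
screen is a one-sample Kolmogorov–Smirnov test against a normal with
the sample's own mean and sd; estimating the parameters from the data
makes the p-value conservative (the Lilliefors caveat), which is
documented rather than corrected, matching common practice in the
source literature of such studies. The audit utility recomputes every
externally reported *t* from its own printed summaries and flags
deviations above 0.5 as not reproducible (probable errata); deviations
within 0.02 count as exact under input rounding. Flagged entries are
reported, never silently corrected.

## Synthetic phantoms

**Strip phantom** — a closed slab with planar cortical walls exactly
`T` apart; the analytic acceptance surface. Its ground truth is the 2D
oracle above.

**Hemipubis phantom** — a watertight idealisation built from a 2D bone
silhouette (symphyseal face at the x = 0 midline, superior edge, deep
inferior body, through-hole for the obturator foramen) embedded with
varying wall separation: a flat plateau (13.5 × thickness scale) across
the entry zone thinning to 9 laterally (the medial-thick /
lateral-thin gradient), an **anterior waist** — the cortex narrows by
`anterior_waist` (default 3) at ~12 mm depth, the thin supra-obturator
shell — and a deep **anterior flare** below 15 mm depth (the thick
inferomedial body). The waist is what makes the maximally anteverted
screw tangent at shallow depth and then run the full corridor, so
L1/L2 are long and bone-size-coupled, as in real anatomy. Per-subject
wall slopes give the within-sex variance of MPIA/MAIA. A tubercle bump
(Gaussian, 4 mm) sits at x = intertubercular/2; a 2 mm posterior bow
curves the ramus. All landmarks are emitted exactly on the surface, and
generation is deterministic for a fixed spec.

Two scaling laws tie the phantom to the sampled morphometrics: the
corridor obliquity is predicted as `atan((IT/2 + 11.5)/symphysis
height)` (the OM line), and (a) the inferior extent of the body is laid
out *along* that oblique corridor — the inferior-ramus direction — with
chord `depth_ratio × ramus_length`, so the attainable outer-screw
length inherits the ramus-length distribution rather than being
confounded by obliquity; (b) the waist depth is scaled by the cosine of
the predicted obliquity so the anterior tangency angle depends on waist
amplitude and entry clearance, not on pelvis obliquity — making MAIA
sex-null by construction, as the study conditions require.

**Cohort sampler** — per-subject parameters drawn from per-sex normals
(intertubercular 58.40 ± 6.03 / 61.98 ± 9.04; symphysis height
41.82 ± 4.65 / 39.85 ± 3.26; ramus length 55 ± 6.36 / 48 ± 8.65,
mirroring the outer-screw-length dimorphism; thickness scale
1.0 ± 0.10; wall slopes 0.04 ± 0.03; anterior waist 3.0 ± 1.2), with
hard clips keeping tail draws constructible (e.g. intertubercular
44–88, thickness scale 0.85–1.25). Subject *i* uses RNG substream
`seed + i`, so cohorts are reproducible end to end from one integer.

What the phantoms do **not** emulate: cortical/trabecular density, real
cortical thickness maps, surface roughness, anatomical shape variation
beyond the sampled parameters, and realistic spread of the tangential
MIA (the foramen sits at a fixed offset from the entry, so its
between-subject sd is far smaller than in vivo). Passing tests
therefore demonstrate correctness of the geometric searches and the
statistical machinery under controlled conditions — not anatomical
accuracy of any particular mean value. Cohort-level anatomical means
from CT data are not reproducible from phantoms and are not asserted.

## Problem sizes and profiles

The accurate profile (defaults above) measures one hemipelvis in ~10 s
on one CPU at the default mesh resolution (~1 800 faces). Cohort-scale
studies use the documented `PipelineConfig.fast()` profile (12 × 10
sampling, 0.04 tolerance, 0.1° bisection, 4 mm ring spacing) on
~1 000-face phantoms, ≈ 0.15 s per subject; the replicate power study
in the test suite runs 50 cohorts of 40 + 40 subjects with the
outer-screw fast path in about ten minutes. Subjects whose sampled
geometry admits no corridor are recorded as failures and excluded from
the tables rather than aborting the run (none occur at the default
distributions).

## Known limitations

* Geodesic offsetting by tangent-plane stepping accumulates projection
  error on strongly curved or noisy surfaces; it is exact on planes and
  validated to ±0.2 mm on the phantom. Real segmentations should be
  smoothed/repaired upstream (mesh repair is out of scope).
* The tangential search assumes the feasible β set at fixed α is a
  single interval; pathological multi-pocket corridors would be
  reported from the pocket found first.
* Near-grazing maxima (> ~60° tilt) are ill-conditioned by geometry,
  not by implementation; reported values there carry > 0.1° uncertainty.
* The safe-region classifier fits straight boundaries; strongly curved
  cortical silhouettes would need the binned polylines themselves
  (which are returned) rather than the fitted apex angle.

## The replicate sex-comparison study

The detection-rate study simulates fifty independent 40 + 40 cohorts
(replicate *r* seeds its cohort with `base + 1000 r`; per-subject
substreams are `seed + index`), measures the outer screw with a
2 mm-ring-spacing profile — sparser rings alias the near-tangent
contact zone against screw length and would leak a spurious bone-size
signal into the angles — and records the intersex pooled-*t* of the
screw length and of MAIA per replicate. Under the configured
distributions the length test is expected significant in essentially
every replicate (paired effect ≈ +7 mm at ~7.5 mm within-sex sd) and
MAIA, which the generator constructs to be sex-null, should stay
non-significant at the nominal ~5% false-positive rate.

Because a *fixed* seed family draws its nuisance parameters once, the
count of false positives across 50 replicates is binomial and a family
can land in its tail: a verification probe for this is part of the API
(`paired_sex_shift`), which maps identical random draws through the
male and female parameter tables so the male–female measurement
difference isolates the generator's systematic sex effect with ~30×
less variance than independent cohorts. On the shipped configuration
it reports a MAIA shift statistically indistinguishable from zero
alongside the full configured length gap — the direct evidence that
an occasional significant MAIA replicate reflects sampling luck of
sex-neutral parameters (wall thickness, waist, slopes), not a
constructed effect. The phantom's MAIA within-sex spread (~5°) is
still narrower than in vivo (~9–10°), which makes the intersex *t*
more sensitive to such luck than a real cohort would be; this is a
known fidelity limit of the phantom.
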