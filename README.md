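# pubicorridor

Virtual planning of the two obliquely inserted screws that anchor a
3.5 mm reconstruction plate on the pubic body, computed on triangulated
hemipelvis surface meshes.

When the plate is laid along the pelvic brim starting at the outer edge
of the pubic tubercle, its two innermost screws enter the superior
pubic surface about 5 mm medial of the brim, at 6.5 mm (inner screw,
site M) and 19.5 mm (outer screw, site L) from the plate tip. Both
screws must be angled medially into the pubic body: laterally the bone
is a thin shell over the obturator foramen, medially it is the thick
symphyseal body. This package computes, for one hemipelvis:

* the **insertion sites** S, M, L on the brim-offset curve;
* the **obturator-tangential screw** from L — the most laterally
  inclined contained screw, tangent to the obturator-side inner cortex —
  with its length L0, medial inclination angle (MIA) and
  anterior/posterior inclination angle (APIA);
* for the inner and outer screws, the **maximum anterior and posterior
  inclination angles** (MAIA ≥ 0 ≥ MPIA, measured from the in-plane
  perpendicular to the local cortical tangent) and the screw lengths L1,
  L2 at maximal anteversion, where the screw lies tangential to the
  anterior cortex;
* the **safe-region pattern** — blunt V, sharp V or disjoint — formed by
  the projected anterior and posterior cortical boundaries seen along
  the tangential screw axis;
* the **cohort statistics** of a sex-comparison study: per-sex
  mean ± sd tables with pooled totals and two-independent-samples
  Student *t* tests (pooled variance), a Kolmogorov–Smirnov normality
  screen, and a consistency audit that recomputes externally reported
  *t* values from their own printed summaries.

A screw is *contained* when every sample of its lateral surface and tip
cap lies inside the watertight bone surface within a 0.01 mm tolerance
(samples above the entry cortex — the countersunk head — are exempt);
maximal angles and lengths are found by bisection between a contained
and a violating bracket. Because no public CT cohort accompanies the
technique, the package ships parametric **bone phantoms**: an analytic
strip phantom whose tangency angles have closed 2D solutions (the
acceptance oracle for every search), a watertight hemipubis phantom
with obturator foramen, tubercle and symphyseal face, and a cohort
sampler that draws per-subject phantom parameters from per-sex normal
distributions (intertubercular distance 58.40 ± 6.03 mm male /
61.98 ± 9.04 mm female; symphysis height 41.82 ± 4.65 / 39.85 ± 3.26 mm).

Intended users: orthopaedic/anatomy researchers replicating or
extending digital screw-corridor measurements, and developers needing a
tested cylinder-in-mesh containment search.

## Worked example

```python
from pubicorridor import (PipelineConfig, PubisPhantomSpec,
                          analyze_hemipelvis, generate_pubis_phantom)

mesh, landmarks = generate_pubis_phantom(PubisPhantomSpec())
result = analyze_hemipelvis(mesh, landmarks, PipelineConfig())
print(result.to_flat_dict())
```

On the default phantom this prints (angles in degrees, lengths in mm):

```
inner screw  : plane MIA 37.66, MAIA +13.43, MPIA -14.47, L1 56.42
outer screw  : MAIA +12.29, MPIA -16.44, L2 54.78
tangential   : MIA 20.45, APIA -11.03, L0 42.37
safe region  : disjoint
```

Reading: from site M the screw may be tilted up to 13.4° anteriorly
before breaching the anterior cortex (at that tilt a 56 mm screw runs
tangent to it down the pubic body) and up to 14.5° posteriorly with the
shortest (14 mm) screw; any screw from L inclined less than 20.5°
medially would enter the obturator foramen (MIA 20.5°). The same measurements on
real CT-derived meshes take an STL plus a landmark JSON (pelvic brim
polyline, tubercle edge, symphysis points, obturator loop — see
`docs/methods.md`):

```bash
pubicorridor measure hemipelvis.stl hemipelvis_landmarks.json --out-dir results/
pubicorridor simulate --n-male 5 --n-female 5 --seed 7 --out-dir cohort/
pubicorridor run-cohort --n-male 10 --n-female 10 --seed 1 --out-dir results/
```

The `examples/` directory holds short narrative scripts, one per
capability (`strip_oracle_demo.py`, `plan_single_hemipelvis.py`,
`cohort_tables_demo.py`, `audit_published_tables.py`).

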