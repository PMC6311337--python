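"""Simulate a small virtual cohort and print the three summary tables.

Samples 8 male and 8 female phantoms from the configured per-sex
morphometric distributions, measures every corridor parameter with the
coarse (cohort-speed) profile, and prints per-sex mean±sd, pooled
totals and the intersex pooled-t tests, one table per screw.
"""

from pubicorridor import CohortSpec, PipelineConfig, render_tables
from pubicorridor.cohort import cohort_report, run_cohort

spec = CohortSpec(n_male=8, n_female=8, seed=11, resolution=0.45)
results = run_cohort(spec, PipelineConfig.fast(), measure="full")
print(f"measured {int((results['error'] == '').sum())}/{len(results)} subjects")
print(render_tables(cohort_report(results)))
print("With n=8 per sex only large effects reach significance; the outer")
print("and tangential screw lengths inherit the configured male-female")
print("ramus-length gap, the angles are sex-null by construction.")
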