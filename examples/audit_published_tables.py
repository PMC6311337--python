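"""Consistency audit of externally reported summary tables.

Feeds the published per-sex (mean, sd, n) summaries of the plate-screw
technique back through the pooled two-sample t test and compares the
recomputed statistics with the t values printed alongside them. Seven
of nine entries reproduce to within input rounding; the tangential
screw length and APIA rows do not follow from their own summaries
(probable transcription errata), and the audit flags exactly those.
"""

from pubicorridor import audit_printed_tables

PRINTED = {
    "inner_L1": {"male": (47.07, 4.08, 40), "female": (45.95, 3.93, 40),
                 "t": 1.261},
    "inner_MAIA": {"male": (14.06, 8.91, 40), "female": (10.74, 9.95, 40),
                   "t": 1.573},
    "inner_MPIA": {"male": (-13.30, 10.72, 40), "female": (-10.25, 9.60, 40),
                   "t": -1.341},
    "outer_L2": {"male": (55.71, 6.36, 40), "female": (48.68, 8.65, 40),
                 "t": 4.139},
    "outer_MAIA": {"male": (9.77, 10.53, 40), "female": (10.94, 8.33, 40),
                   "t": -0.553},
    "outer_MPIA": {"male": (-11.80, 11.00, 40), "female": (-6.23, 7.91, 40),
                   "t": -2.599},
    "tangential_L0": {"male": (53.16, 8.70, 40), "female": (45.07, 10.91, 40),
                      "t": 5.026},
    "tangential_MIA": {"male": (30.42, 7.95, 40), "female": (32.88, 10.65, 40),
                       "t": -1.167},
    "tangential_APIA": {"male": (9.32, 9.57, 40), "female": (5.74, 10.58, 40),
                        "t": 0.117},
}

audit = audit_printed_tables(PRINTED)
print(audit.to_string())
print()
flagged = list(audit.index[~audit.consistent])
print(f"not reproducible from their own summaries: {flagged}")
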