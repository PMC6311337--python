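"""Summary-statistic t tests, pooling, KS screen, report tables, audit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pubicorridor import (GroupSummary, audit_printed_tables, ks_normality,
                          make_tables, pool_groups, render_tables,
                          two_sample_t_from_summaries)
from pubicorridor.stats import DegenerateSampleError, StratificationError

# published per-sex summaries (mean, sd, n=40) for this plate-screw
# technique, with the t values the original report printed
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


def test_pooled_t_matches_published_outer_length():
    res = two_sample_t_from_summaries(GroupSummary(55.71, 6.36, 40),
                                      GroupSummary(48.68, 8.65, 40))
    assert res.t == pytest.approx(4.139, abs=0.02)
    assert res.df == 78
    assert res.p < 0.001


def test_identical_groups_give_null_t():
    g = GroupSummary(10.0, 2.0, 30)
    res = two_sample_t_from_summaries(g, GroupSummary(10.0, 2.0, 30))
    assert res.t == 0.0 and res.p == pytest.approx(1.0)


def test_degenerate_equal_constants_raise():
    with pytest.raises(DegenerateSampleError):
        two_sample_t_from_summaries(GroupSummary(5.0, 0.0, 10),
                                    GroupSummary(5.0, 0.0, 10))


def test_summary_t_equals_raw_t(rng):
    a = rng.normal(10, 3, 37)
    b = rng.normal(12, 4, 45)
    res = two_sample_t_from_summaries(GroupSummary.from_sample(a),
                                      GroupSummary.from_sample(b))
    t_raw, p_raw = sps.ttest_ind(a, b, equal_var=True)
    assert res.t == pytest.approx(t_raw, abs=1e-9)
    assert res.p == pytest.approx(p_raw, abs=1e-9)


def test_pooled_equals_welch_statistic_for_equal_n():
    g1, g2 = GroupSummary(20.0, 5.0, 40), GroupSummary(17.0, 9.0, 40)
    pooled = two_sample_t_from_summaries(g1, g2)
    t_w, _ = sps.ttest_ind_from_stats(*vars(g1).values(), *vars(g2).values(),
                                      equal_var=False)
    assert pooled.t == pytest.approx(float(t_w), abs=1e-12)


def test_pooling_consistent_with_concatenation(rng):
    a = rng.normal(30, 6, 25)
    b = rng.normal(45, 2, 55)
    pooled = pool_groups(GroupSummary.from_sample(a),
                         GroupSummary.from_sample(b))
    both = np.concatenate([a, b])
    assert pooled.mean == pytest.approx(both.mean(), abs=1e-9)
    assert pooled.sd == pytest.approx(both.std(ddof=1), abs=1e-9)
    sym = pool_groups(GroupSummary.from_sample(b),
                      GroupSummary.from_sample(a))
    assert sym.mean == pytest.approx(pooled.mean) and \
        sym.sd == pytest.approx(pooled.sd)


def test_pooling_a_group_with_itself_closed_form():
    g = GroupSummary(8.0, 3.0, 20)
    p = pool_groups(g, g)
    assert p.mean == 8.0
    assert p.sd == pytest.approx(3.0 * np.sqrt((2 * 20 - 2) / (2 * 20 - 1)))


def test_ks_screen_calibrated_under_the_null():
    hits = 0
    for seed in range(100):
        x = np.random.default_rng(seed).normal(5, 2, 1000)
        if ks_normality(x)["p"] > 0.05:
            hits += 1
    assert hits >= 95


def test_ks_screen_detects_gross_non_normality():
    hits = 0
    for seed in range(40):
        x = np.random.default_rng(seed).uniform(0, 1, 1000)
        if ks_normality(x)["p"] < 0.05:
            hits += 1
    assert hits >= 38


def test_ks_degenerate_inputs():
    with pytest.raises(DegenerateSampleError):
        ks_normality([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateSampleError):
        ks_normality([2.0] * 50)


def _fake_cohort(n=6, jitter=0.0, rng=None):
    rows = []
    for k in range(2 * n):
        sex = "male" if k < n else "female"
        i = k % n  # same within-sex pattern for both sexes
        eps = 0.0 if rng is None else rng.normal(0, jitter)
        rows.append({"sex": sex, "inner_L1_mm": 46.0 + eps + (i % 3) * 0.5,
                     "inner_MAIA_deg": 12.0 + (i % 4) * 0.3,
                     "inner_MPIA_deg": -11.0 - (i % 3) * 0.2,
                     "outer_L2_mm": 52.0 + (i % 5) * 0.4,
                     "outer_MAIA_deg": 10.0 + (i % 4) * 0.2,
                     "outer_MPIA_deg": -9.0 - (i % 2) * 0.3,
                     "tangential_L0_mm": 50.0 + (i % 3) * 0.6,
                     "tangential_MIA_deg": 31.0 + (i % 4) * 0.4,
                     "tangential_APIA_deg": 7.0 + (i % 3) * 0.5})
    return pd.DataFrame(rows)


def test_make_tables_layout_and_null_cohort():
    tables = make_tables(_fake_cohort())
    assert set(tables) == {"inner", "outer", "tangential"}
    inner = tables["inner"]
    assert list(inner.columns) == ["Screw Length, L1 (mm)", "MAIA (deg)",
                                   "MPIA (deg)"]
    assert {"Male (n=6)", "Female (n=6)", "Total (n=12)", "t value",
            "P value"} == set(inner.index)
    # identical per-sex patterns -> every t is 0
    for tab in tables.values():
        assert all(float(t) == pytest.approx(0.0, abs=1e-9)
                   for t in tab.loc["t value"])
    text = render_tables(tables)
    assert "Inner screw" in text and "tangential" in text


def test_make_tables_requires_both_sexes():
    df = _fake_cohort()
    with pytest.raises(StratificationError):
        make_tables(df[df.sex == "male"])


def test_audit_reproduces_the_consistency_partition():
    """Recomputing every published t from its own summaries flags exactly
    the tangential screw length and APIA entries as non-reproducible."""
    audit = audit_printed_tables(PRINTED)
    flagged = set(audit.index[~audit.consistent])
    assert flagged == {"tangential_L0", "tangential_APIA"}
    exact = audit[audit.consistent]
    assert (exact.abs_deviation <= 0.02).all()
    assert (audit.loc[list(flagged), "abs_deviation"] > 0.5).all()
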