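"""Cohort statistics: normality screen, pooled two-sample t, report tables.

Reproduces the statistical stage of a sex-comparison morphometry study:
per-sex mean +- sd summaries, pooled "Total" rows, two-independent-
samples Student t tests (pooled variance, the SPSS default), a
one-sample Kolmogorov-Smirnov normality screen, and a consistency audit
that recomputes every printed t value from its own printed summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateSampleError(ValueError):
    pass


@dataclass
class GroupSummary:
    """(mean, sd, n) of one measurement in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("a group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @classmethod
    def from_sample(cls, x) -> "GroupSummary":
        x = np.asarray(x, float)
        x = x[~np.isnan(x)]
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


@dataclass
class TestResult:
    t: float
    df: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def two_sample_t_from_summaries(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Pooled-variance Student t test from group summaries.

    sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2),
    t = (m1 - m2) / sqrt(sp^2 (1/n1 + 1/n2)), df = n1 + n2 - 2,
    two-sided p. The sign follows m1 - m2 (group 1 = male by the
    reporting convention). For equal group sizes the statistic equals
    the Welch statistic; only the degrees of freedom differ.
    """
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            raise DegenerateSampleError(
                "t undefined: both groups constant and equal")
    t, p = sps.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                    g2.mean, g2.sd, g2.n, equal_var=True)
    return TestResult(t=float(t), df=g1.n + g2.n - 2, p=float(p))


def pool_groups(g1: GroupSummary, g2: GroupSummary) -> GroupSummary:
    """Exact two-group pooling of mean and sd (the "Total" row).

    The pooled variance combines within-group and between-group parts:
    [(n1-1) s1^2 + (n2-1) s2^2 + n1 (m1 - m)^2 + n2 (m2 - m)^2] / (n-1).
    Symmetric in its arguments and identical to concatenating the raw
    samples.
    """
    n = g1.n + g2.n
    m = (g1.n * g1.mean + g2.n * g2.mean) / n
    ss = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2
          + g1.n * (g1.mean - m) ** 2 + g2.n * (g2.mean - m) ** 2)
    return GroupSummary(mean=m, sd=math.sqrt(ss / (n - 1)), n=n)


def ks_normality(sample) -> dict:
    """One-sample Kolmogorov-Smirnov test against a fitted normal.

    The reference normal uses the sample's own mean and sd, so the
    p-value is conservative (the Lilliefors caveat): estimating the
    parameters from the data makes large D values rarer under the null
    than the classical KS distribution assumes.
    """
    x = np.asarray(sample, float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise DegenerateSampleError("KS normality screen needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateSampleError("constant sample: sd = 0")
    d, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return {"D": float(d), "p": float(p)}


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

#: measurement columns of the three report tables, in display order
TABLE_LAYOUT = {
    "inner": [("inner_L1_mm", "Screw Length, L1 (mm)"),
              ("inner_MAIA_deg", "MAIA (deg)"),
              ("inner_MPIA_deg", "MPIA (deg)")],
    "outer": [("outer_L2_mm", "Screw Length, L2 (mm)"),
              ("outer_MAIA_deg", "MAIA (deg)"),
              ("outer_MPIA_deg", "MPIA (deg)")],
    "tangential": [("tangential_L0_mm", "Screw Length, L0 (mm)"),
                   ("tangential_MIA_deg", "MIA (deg)"),
                   ("tangential_APIA_deg", "APIA (deg)")],
}


class StratificationError(ValueError):
    pass


def make_tables(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-sex summary tables with pooled totals and intersex t tests.

    ``results`` holds one row per hemipelvis with a ``sex`` column
    ('male'/'female') and the flat measurement columns of
    :meth:`CorridorResult.to_flat_dict`. Returns one DataFrame per screw
    (inner/outer/tangential) with rows Male, Female, Total (mean +- sd),
    t value and two-sided P value (pooled Student t; significance at
    0.05). Means and sds are rendered to 2 decimals, t to 3.
    """
    for sex in ("male", "female"):
        if (results["sex"] == sex).sum() < 2:
            raise StratificationError(f"need >= 2 subjects of sex {sex!r}")
    out = {}
    for table, cols in TABLE_LAYOUT.items():
        present = [(k, label) for k, label in cols if k in results.columns]
        if not present:
            continue
        data = {}
        for key, label in present:
            gm = GroupSummary.from_sample(
                results.loc[results.sex == "male", key])
            gf = GroupSummary.from_sample(
                results.loc[results.sex == "female", key])
            tot = pool_groups(gm, gf)
            tt = two_sample_t_from_summaries(gm, gf)
            data[label] = {
                f"Male (n={gm.n})": f"{gm.mean:.2f}±{gm.sd:.2f}",
                f"Female (n={gf.n})": f"{gf.mean:.2f}±{gf.sd:.2f}",
                f"Total (n={tot.n})": f"{tot.mean:.2f}±{tot.sd:.2f}",
                "t value": f"{tt.t:.3f}",
                "P value": ("<0.05" if tt.significant else ">0.05")
                           + f" ({tt.p:.3f})",
            }
        out[table] = pd.DataFrame(data)
    return out


def render_tables(tables: dict[str, pd.DataFrame]) -> str:
    """Plain-text rendering of the three report tables."""
    parts = []
    titles = {"inner": "Inner screw", "outer": "Outer screw",
              "tangential": "Screw at the line tangential to the obturator"}
    for name, df in tables.items():
        parts.append(f"== {titles.get(name, name)} (mean±sd) ==")
        parts.append(df.to_string())
        parts.append("")
    return "\n".join(parts)


def audit_printed_tables(printed: dict, flag_threshold: float = 0.5,
                         agree_threshold: float = 0.02) -> pd.DataFrame:
    """Recompute every printed t value from its own printed summaries.

    ``printed`` maps parameter names to
    ``{"male": (mean, sd, n), "female": (mean, sd, n), "t": printed_t}``.
    Returns a DataFrame with the recomputed t, the deviation and a
    ``consistent`` verdict: deviations above ``flag_threshold`` are
    flagged as not reproducible from their own summaries (probable
    errata); deviations at most ``agree_threshold`` count as exact
    agreement (within input rounding). Intermediate deviations are
    reported unflagged for the reader to judge.
    """
    rows = []
    for name, entry in printed.items():
        gm = GroupSummary(*entry["male"])
        gf = GroupSummary(*entry["female"])
        res = two_sample_t_from_summaries(gm, gf)
        dev = abs(res.t - entry["t"])
        rows.append({
            "parameter": name,
            "printed_t": entry["t"],
            "recomputed_t": round(res.t, 3),
            "abs_deviation": round(dev, 3),
            "consistent": bool(dev <= flag_threshold),
            "exact": bool(dev <= agree_threshold),
        })
    return pd.DataFrame(rows).set_index("parameter")
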