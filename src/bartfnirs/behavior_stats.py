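"""Group behavioral statistics: adjusted-score comparisons, the two-way
ANOVA screen, and group comparisons of fitted model parameters.

The default two-sample test is Welch's unequal-variance t (the pooled-variance
variant is available behind a flag); the sign convention is group1 - group2
with patients first, so a lower-scoring patient group yields a negative t.
Welch degrees of freedom follow Welch-Satterthwaite; reports print them next
to the naive n1 + n2 - 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .bart_core import CONTROL, PATIENT, SubjectDataset, adjusted_score_or_nan

__all__ = [
    "GroupSummary",
    "TestResult",
    "welch_t",
    "two_way_anova",
    "compare_parameters",
    "score_table",
    "group_summaries",
    "compare_adjusted_scores",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group's scores on one measure."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 per group")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class TestResult:
    label: str
    statistic: float
    df: float
    p: float
    family: str  # "welch_t", "pooled_t", "anova_f"

    def __post_init__(self) -> None:
        if not math.isnan(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _summarize(sample) -> tuple[int, float, float]:
    if isinstance(sample, GroupSummary):
        return sample.n, sample.mean, sample.sd
    if isinstance(sample, tuple) and len(sample) == 3:
        n, mean, sd = sample
        return int(n), float(mean), float(sd)
    arr = np.asarray(sample, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 observations per group")
    return int(arr.size), float(arr.mean()), float(arr.std(ddof=1))


def welch_t(group1, group2, label: str = "", pooled: bool = False) -> TestResult:
    """Two-tailed two-sample t from raw vectors, ``(n, mean, sd)`` tuples or
    :class:`GroupSummary` objects; Welch by default.

    Degenerate case: both variances zero with equal means gives t = 0, p = 1.
    """
    n1, m1, s1 = _summarize(group1)
    n2, m2, s2 = _summarize(group2)
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return TestResult(label, 0.0, float(n1 + n2 - 2), 1.0, "welch_t")
        return TestResult(label, math.copysign(math.inf, m1 - m2), float(n1 + n2 - 2), 0.0, "welch_t")

    v1, v2 = s1**2 / n1, s2**2 / n2
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
        family = "pooled_t"
    else:
        t = (m1 - m2) / math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        family = "welch_t"
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(label, float(t), float(df), float(p), family)


def two_way_anova(scores: pd.DataFrame) -> list[TestResult]:
    """Two-way ANOVA (group x condition) on a complete long-format table with
    columns ``subject_id``, ``group``, ``condition``, ``score``.

    Used as the screen before per-condition t-tests.  Incomplete designs
    (any subject missing a condition cell) are refused.
    """
    required = {"subject_id", "group", "condition", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"need columns {sorted(required)}")
    cells = scores.groupby(["subject_id", "condition"]).size()
    n_conditions = scores["condition"].nunique()
    per_subject = cells.groupby("subject_id").size()
    if scores["score"].isna().any() or (per_subject != n_conditions).any():
        raise ValueError("incomplete subject x condition table; no unbalanced-design handling")

    if scores["score"].nunique() == 1:  # degenerate: no variance anywhere
        return [
            TestResult(label, 0.0, float("nan"), 1.0, "anova_f")
            for label in ("condition", "group", "interaction")
        ]
    model = ols("score ~ C(group) * C(condition)", data=scores).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = []
    for label, term in [
        ("condition", "C(condition)"),
        ("group", "C(group)"),
        ("interaction", "C(group):C(condition)"),
    ]:
        row = table.loc[term]
        f = float(row["F"])
        p = float(row["PR(>F)"])
        if math.isnan(f):  # zero between-group variance: no effect at all
            f, p = 0.0, 1.0
        out.append(TestResult(label, f, float(row["df"]), p, "anova_f"))
    return out


def compare_parameters(
    estimates: pd.DataFrame,
    patient_group: str = PATIENT,
    pooled: bool = False,
) -> pd.DataFrame:
    """One Welch t per model parameter between the two groups.

    ``estimates`` is the per-subject posterior-mean table from
    :func:`bartfnirs.inference.subject_estimates` (columns ``subject_id``,
    ``group``, then one column per parameter).  No multiplicity correction is
    applied: the parameter tests are reported raw, FDR being reserved for the
    channel-wise optical contrasts.
    """
    params = [c for c in estimates.columns if c not in ("subject_id", "group")]
    pat = estimates[estimates["group"] == patient_group]
    ctl = estimates[estimates["group"] != patient_group]
    rows = []
    for p in params:
        res = welch_t(pat[p].to_numpy(), ctl[p].to_numpy(), label=p, pooled=pooled)
        rows.append(
            {
                "parameter": p,
                "n1": len(pat),
                "mean1": pat[p].mean(),
                "sd1": pat[p].std(ddof=1),
                "n2": len(ctl),
                "mean2": ctl[p].mean(),
                "sd2": ctl[p].std(ddof=1),
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Adjusted-score tables


def score_table(datasets: list[SubjectDataset]) -> pd.DataFrame:
    """Per-subject adjusted score per condition (NaN where every balloon of a
    condition burst)."""
    conditions: list[str] = []
    for d in datasets:
        for c in d.conditions:
            if c not in conditions:
                conditions.append(c)
    rows = []
    for d in datasets:
        for c in conditions:
            rows.append(
                {
                    "subject_id": d.subject_id,
                    "group": d.group,
                    "condition": c,
                    "score": adjusted_score_or_nan(d, c),
                }
            )
    return pd.DataFrame(rows)


def group_summaries(
    scores: pd.DataFrame, patient_group: str = PATIENT
) -> pd.DataFrame:
    out = (
        scores.groupby(["condition", "group"])["score"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return out


def compare_adjusted_scores(
    scores: pd.DataFrame, patient_group: str = PATIENT, pooled: bool = False
) -> pd.DataFrame:
    """Per-condition two-sample t on adjusted scores (patients - controls)."""
    rows = []
    for cond, sub in scores.groupby("condition", sort=False):
        pat = sub.loc[sub["group"] == patient_group, "score"].dropna().to_numpy()
        ctl = sub.loc[sub["group"] != patient_group, "score"].dropna().to_numpy()
        if len(pat) < 2 or len(ctl) < 2:
            # too many missing scores (every balloon burst): report, don't test
            nan = float("nan")
            res = TestResult(cond, nan, nan, nan, "welch_t")
        else:
            res = welch_t(pat, ctl, label=cond, pooled=pooled)
        rows.append(
            {
                "condition": cond,
                "n1": len(pat),
                "mean1": pat.mean(),
                "sd1": pat.std(ddof=1),
                "n2": len(ctl),
                "mean2": ctl.mean(),
                "sd2": ctl.std(ddof=1),
                "t": res.statistic,
                "df_welch": res.df,
                "df_naive": len(pat) + len(ctl) - 2,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
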