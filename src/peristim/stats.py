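"""Group-level statistics over classification summaries.

The battery mirrors a standard parametric workflow at significance level
alpha = 0.05: two-proportion z-tests for comparing type proportions between
groups (with a Fisher-exact fallback when expected cells are small),
Student's t for two-sample rate comparisons with Cohen's d as effect size,
one-way ANOVA followed by Tukey's HSD for more than two groups, and
Shapiro-Wilk / Levene assumption checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "StatResult",
    "proportion_test",
    "students_t",
    "cohens_d",
    "one_way_anova",
    "tukey_hsd",
    "assumption_checks",
]


@dataclass(frozen=True)
class StatResult:
    """A test outcome: statistic, p-value, optional df and effect size."""

    method: str
    statistic: float
    p_value: float
    df: float | tuple[float, float] | None = None
    effect_size: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isnan(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        """True when p < 0.05 (the fixed study-wide alpha)."""
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "effect_size": self.effect_size,
            "flags": list(self.flags),
            "significant": self.significant,
        }


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> StatResult:
    """Two-sided two-proportion z-test with pooled variance.

    Falls back to Fisher's exact test (flagged ``exact_fallback``) whenever
    any expected cell count under the pooled proportion is below 5, where
    the normal approximation is unreliable.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n")
    p_pool = (k1 + k2) / (n1 + n2)
    expected = [n1 * p_pool, n1 * (1 - p_pool), n2 * p_pool, n2 * (1 - p_pool)]
    if min(expected) < 5:
        odds, p = sps.fisher_exact(
            [[k1, n1 - k1], [k2, n2 - k2]], alternative="two-sided"
        )
        return StatResult(
            method="fisher_exact",
            statistic=float(odds),
            p_value=float(p),
            flags=("exact_fallback",),
        )
    p1, p2 = k1 / n1, k2 / n2
    if p_pool in (0.0, 1.0) or p1 == p2:
        return StatResult(method="two_proportion_z", statistic=0.0, p_value=1.0)
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return StatResult(method="two_proportion_z", statistic=float(z), p_value=float(p))


def cohens_d(x1: Sequence[float], x2: Sequence[float]) -> float:
    """Standardized mean difference (mean1 - mean2) / pooled SD.

    The pooled SD weights the sample variances by their degrees of freedom.
    Interpretation guide: 0.2 small, 0.5 medium, 0.8 large.  Returns NaN
    when the pooled SD is zero.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("cohens_d requires at least 2 observations per sample")
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if sp2 == 0:
        return math.nan
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


def students_t(
    x1: Sequence[float], x2: Sequence[float], welch: bool = False
) -> StatResult:
    """Two-sided two-sample t-test, equal-variance by default.

    ``welch=True`` drops the equal-variance assumption.  Cohen's d (pooled)
    is attached as the effect size.  Degenerate case: both samples constant
    and equal means gives t = 0, p = 1, flagged.
    """
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult(
                method="student_t",
                statistic=0.0,
                p_value=1.0,
                df=float(a.size + b.size - 2),
                effect_size=math.nan,
                flags=("degenerate_variance",),
            )
        return StatResult(
            method="student_t",
            statistic=math.inf if a.mean() > b.mean() else -math.inf,
            p_value=0.0,
            df=float(a.size + b.size - 2),
            effect_size=math.nan,
            flags=("degenerate_variance",),
        )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    return StatResult(
        method="welch_t" if welch else "student_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
        effect_size=cohens_d(a, b),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """Classic one-way fixed-effects ANOVA over two or more groups."""
    if len(groups) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    n_total = sum(a.size for a in arrs)
    df = (float(len(arrs) - 1), float(n_total - len(arrs)))
    if all(a.var(ddof=1) == 0 for a in arrs) and len({a.mean() for a in arrs}) == 1:
        return StatResult(
            method="one_way_anova",
            statistic=math.nan,
            p_value=math.nan,
            df=df,
            flags=("degenerate_variance",),
        )
    res = sps.f_oneway(*arrs)
    return StatResult(
        method="one_way_anova",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=df,
    )


def tukey_hsd(groups: Sequence[Sequence[float]]) -> dict[tuple[int, int], StatResult]:
    """Tukey's honestly-significant-difference pairwise comparisons.

    Returns a mapping (i, j) -> result for every unordered pair of group
    indices; the statistic is the mean difference group_i - group_j and the
    p-value comes from the studentized-range distribution.
    """
    if len(groups) < 2:
        raise ValueError("tukey_hsd requires at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    res = sps.tukey_hsd(*arrs)
    out: dict[tuple[int, int], StatResult] = {}
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            out[(i, j)] = StatResult(
                method="tukey_hsd",
                statistic=float(res.statistic[i, j]),
                p_value=float(min(max(res.pvalue[i, j], 0.0), 1.0)),
                effect_size=cohens_d(arrs[i], arrs[j]),
            )
    return out


def assumption_checks(groups: Sequence[Sequence[float]]) -> dict:
    """Shapiro-Wilk normality per group and mean-centered Levene across groups.

    Groups with fewer than 3 observations skip the normality check (None,
    flagged).  Levene requires at least two usable groups.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    normality: list[StatResult | None] = []
    flags: list[str] = []
    for k, a in enumerate(arrs):
        if a.size < 3:
            normality.append(None)
            flags.append(f"normality_skipped_group_{k}")
            continue
        res = sps.shapiro(a)
        normality.append(
            StatResult(
                method="shapiro_wilk",
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
            )
        )
    if len(arrs) >= 2 and all(a.size >= 2 for a in arrs):
        lev = sps.levene(*arrs, center="mean")
        variance = StatResult(
            method="levene_mean_centered",
            statistic=float(lev.statistic),
            p_value=float(lev.pvalue),
        )
    else:
        variance = None
        flags.append("levene_skipped")
    return {"normality": normality, "variance_homogeneity": variance, "flags": flags}
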