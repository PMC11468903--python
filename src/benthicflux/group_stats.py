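"""Replicate-chamber group comparisons: one-way ANOVA with Tukey HSD.

The F statistic is computed from the classical between/within
sums-of-squares decomposition (written out here rather than delegated,
so tests can check it against independent oracles); p-values come from
scipy's F and studentized-range distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ValidationError

__all__ = [
    "GroupTable",
    "PairwiseComparison",
    "AnovaResult",
    "normality_check",
    "one_way_anova",
    "posthoc_pairwise",
]


@dataclass
class GroupTable:
    """Labeled groups of replicate values sharing one unit."""

    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValidationError("need >= 2 groups")
        for label, values in self.groups.items():
            if len(values) < 2:
                raise ValidationError(
                    f"group {label!r} needs >= 2 values for a variance estimate"
                )

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())


@dataclass(frozen=True)
class PairwiseComparison:
    label_a: str
    label_b: str
    mean_difference: float
    p_adjusted: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: list[PairwiseComparison]


def normality_check(
    values: list[float], alpha: float = 0.05
) -> tuple[float, float, str]:
    """Shapiro-Wilk test with an optional log rescue.

    Returns ``(statistic, p_value, transform_applied)`` where the
    transform is ``"log"`` when normality was rejected at ``alpha`` and
    all values are positive (the returned statistic then refers to the
    log-transformed data), else ``"none"``. Nonpositive values make the
    log transform unavailable; a warning is issued instead.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValidationError("normality check needs >= 3 values")
    if np.ptp(arr) == 0.0:
        raise ValidationError("normality check is degenerate for constant values")
    stat, p = stats.shapiro(arr)
    if p >= alpha:
        return float(stat), float(p), "none"
    if np.any(arr <= 0):
        warnings.warn(
            "normality rejected but data contain nonpositive values; "
            "log transform unavailable",
            stacklevel=2,
        )
        return float(stat), float(p), "none"
    stat_log, p_log = stats.shapiro(np.log(arr))
    return float(stat_log), float(p_log), "log"


def one_way_anova(table: GroupTable, with_posthoc: bool = True) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across the table's groups."""
    groups = [np.asarray(v, dtype=float) for v in table.groups.values()]
    k = len(groups)
    n_total = table.n_total
    grand_mean = sum(g.sum() for g in groups) / n_total

    ss_between = sum(len(g) * (g.mean() - grand_mean) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        raise ValidationError("zero within-group variance everywhere; F is undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    pairwise = posthoc_pairwise(table) if with_posthoc else []
    return AnovaResult(
        f_statistic=float(f),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        pairwise=pairwise,
    )


def posthoc_pairwise(table: GroupTable) -> list[PairwiseComparison]:
    """All-pairs mean differences with Tukey HSD adjusted p-values."""
    labels = list(table.groups)
    samples = [np.asarray(table.groups[lbl], dtype=float) for lbl in labels]
    if all(s.var(ddof=1) == 0.0 for s in samples):
        raise ValidationError("zero within-group variance everywhere")
    res = stats.tukey_hsd(*samples)
    out: list[PairwiseComparison] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            diff = float(samples[i].mean() - samples[j].mean())
            p = float(res.pvalue[i, j])
            if math.isnan(p):
                p = 1.0
            out.append(
                PairwiseComparison(
                    label_a=labels[i],
                    label_b=labels[j],
                    mean_difference=diff,
                    p_adjusted=min(max(p, 0.0), 1.0),
                )
            )
    return out
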