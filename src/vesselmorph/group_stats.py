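"""Group comparisons: one-way ANOVA and pairwise tests against references.

Reporting follows the source study's conventions: values as mean +/- sample
SD, an omnibus one-way ANOVA across groups, and per-group two-sided
comparisons against each reference group (normal, model, positive control)
with significance tiers at p < 0.05 and p < 0.01.  The default post-hoc
method is Fisher's LSD on the pooled ANOVA variance; no multiplicity
correction is applied across factors, matching the original reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "AnovaResult",
    "ComparisonResult",
    "one_way_anova",
    "tier_for",
    "pairwise_vs_reference",
]

TIERS = ("ns", "p<0.05", "p<0.01")
METHODS = ("lsd", "welch")


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    degenerate: bool = False  # all values identical across all groups
    zero_within: bool = False  # separated groups with zero within-group variance


@dataclass(frozen=True)
class ComparisonResult:
    factor: str
    group: str
    reference: str
    p_value: float
    tier: str


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Standard one-way ANOVA over ``k`` groups of animal-level values.

    Degenerate inputs are flagged rather than raised: all values identical
    across every group gives an undefined F (NaN, ``degenerate=True``);
    separated groups with zero within-group variance give ``F = inf`` and
    ``p = 0`` with ``zero_within=True``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    all_values = np.concatenate(arrays)
    n_total = len(all_values)
    k = len(arrays)
    grand = all_values.mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        if ms_between == 0:
            return AnovaResult(np.nan, np.nan, df_between, df_within, 0.0, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_between, df_within, 0.0, zero_within=True)
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within, float(ms_within))


def tier_for(p_value: float) -> str:
    """Map a p-value to the two-tier star convention."""
    if np.isnan(p_value):
        return "ns"
    if p_value < 0.01:
        return "p<0.01"
    if p_value < 0.05:
        return "p<0.05"
    return "ns"


def pairwise_vs_reference(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    method: str = "lsd",
    factor: str = "",
) -> list[ComparisonResult]:
    """Two-sided comparison of every group against one reference group.

    ``lsd`` (default) uses Fisher's least-significant-difference t-test on
    the pooled within-group variance of the omnibus ANOVA, with ``N - k``
    degrees of freedom.  ``welch`` uses per-pair Welch t-tests.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present")
    ref = np.asarray(groups[reference], dtype=float)
    results = []
    if method == "lsd":
        anova = one_way_anova(list(groups.values()))
    for label, values in groups.items():
        if label == reference:
            continue
        values = np.asarray(values, dtype=float)
        if method == "lsd":
            diff = values.mean() - ref.mean()
            if anova.ms_within == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(anova.ms_within * (1 / len(values) + 1 / len(ref)))
                t = diff / se
                p = float(2 * stats.t.sf(abs(t), anova.df_within))
        else:
            p = float(stats.ttest_ind(values, ref, equal_var=False).pvalue)
        results.append(
            ComparisonResult(
                factor=factor, group=label, reference=reference, p_value=p, tier=tier_for(p)
            )
        )
    return results
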