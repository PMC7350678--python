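"""Group-comparison statistics shown on plots.

Two tests are offered: the two-sample t test assuming equal variances
(pooled variance) and the Wilcoxon rank-sum (Mann-Whitney) test for
independent groups, the latter with the exact null distribution for small
samples without ties and the normal approximation with continuity correction
otherwise. Comparisons are either all pairwise or each condition against one
reference condition. Raw two-sided p-values are reported; no multiple-testing
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

SYMBOL_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class StatResult:
    compound: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    display: str


def compare_groups(values_a, values_b, test: str = "t_equal_var",
                   compound: str = "", group_a: str = "", group_b: str = "",
                   display_style: str = "symbols") -> StatResult | None:
    """Compare two groups of intensities; returns None (skip, warn upstream)
    when either group has fewer than two non-missing values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return None
    if test == "t_equal_var":
        if np.ptp(np.concatenate([a, b])) == 0:
            statistic, p_value = 0.0, 1.0  # all values identical
        else:
            statistic, p_value = sps.ttest_ind(a, b, equal_var=True)
    elif test == "wilcoxon":
        exact = max(len(a), len(b)) <= 8 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        statistic, p_value = res.statistic, res.pvalue
    else:
        raise ValidationError(f"unknown test {test!r}; use t_equal_var or wilcoxon")
    p_value = float(min(p_value, 1.0))
    return StatResult(
        compound, group_a, group_b, test, float(statistic), p_value,
        len(a), len(b), format_significance(p_value, display_style),
    )


def comparison_plan(conditions, mode: str = "all_pairwise",
                    reference: str | None = None) -> list[tuple[str, str]]:
    """Which condition pairs to test: all n(n-1)/2 unordered pairs, or each
    non-reference condition against the reference."""
    conditions = list(conditions)
    if mode == "all_pairwise":
        return list(combinations(conditions, 2))
    if mode == "vs_reference":
        if reference not in conditions:
            raise ValidationError(
                f"reference condition {reference!r} is not among {conditions}"
            )
        return [(reference, c) for c in conditions if c != reference]
    raise ValidationError(f"unknown comparison mode {mode!r}")


def format_significance(p: float, style: str = "symbols") -> str:
    """Render a p-value as the conventional star symbols or as numeric text
    (three significant figures, with a ``"<0.001"`` display floor)."""
    if not 0 <= p <= 1:
        raise ValidationError(f"p-value {p} outside [0, 1]")
    if style == "symbols":
        for threshold, symbol in SYMBOL_THRESHOLDS:
            if p <= threshold:
                return symbol
        return "ns"
    if style == "numeric":
        if p < 0.001:
            return "<0.001"
        return f"{p:.3g}"
    raise ValidationError(f"unknown significance style {style!r}")
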