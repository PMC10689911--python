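"""Cohort summaries and group comparisons of repeat sizes."""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class NumericSummary:
    n: int
    mean: float          # 1 dp
    sd: float            # sample SD (n-1 denominator), 1 dp
    min: float
    max: float

    def __str__(self) -> str:
        return (f"{self.mean} +/- {self.sd} "
                f"({self.min:g}-{self.max:g}), n={self.n}")


def summarize_numeric(values: Sequence[float]) -> NumericSummary:
    """Mean +/- sample SD and range, rounded to 1 decimal.

    The SD uses the n-1 denominator (sample SD), the convention under which
    clinical tables of this kind are reported.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value list")
    if x.size < 2:
        raise ValueError("need at least 2 values for a sample SD")
    return NumericSummary(
        n=int(x.size),
        mean=round(float(x.mean()), 1),
        sd=round(float(x.std(ddof=1)), 1),
        min=float(x.min()),
        max=float(x.max()),
    )


def compare_sizes(group_a: Sequence[float], group_b: Sequence[float],
                  method: str = "mannwhitney") -> tuple[float, float]:
    """Two-sided comparison of repeat-size distributions.

    ``mannwhitney`` is the rank-sum test with normal approximation and tie
    correction (the default: size distributions are skewed); ``welch`` is
    the unequal-variance t-test, falling back to the rank-sum test with a
    warning when both groups have zero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "welch":
        if a.std() == 0 and b.std() == 0:
            warnings.warn("degenerate variance: falling back to rank-sum",
                          stacklevel=2)
            return compare_sizes(a, b, method="mannwhitney")
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
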