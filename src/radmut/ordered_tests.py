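"""Ordered chi-square forward selection over pooled mutation classes.

The six pooled mutation-class proportions of a spectrum sum to one, so their
counts cannot be tested independently: if one class rises, the others must
fall.  The forward-selection procedure handles this dependency by testing
classes sequentially.  First every class is tested against the pool of the
other five ("unordered" tests) and classes are ranked by these p-values.
Then rank 1 keeps its unordered p; rank r (2..5) is retested against the
pool of the classes ranked below it only; and the last class is tested
against the rank-5 class alone — an identical 2x2 table to the rank-5 test,
so the two last ranks always share a p-value.  Habitat counts enter summed
over the species of each exposure group.  A Holm step-down correction with
an externally fixed family size k is provided for combining these tests with
a parallel family of regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class DegenerateTableError(ValueError):
    """A 2x2 table with a zero margin; the chi-square test is undefined."""


def chisq_vs_rest(
    counts_low,
    counts_high,
    target_class: int,
    rest_classes,
    yates: bool = False,
) -> tuple[float, int, float]:
    """Pearson chi-square of one class against a pool of others.

    Builds the 2x2 table (habitat x {target, sum of rest}) and returns
    ``(statistic, df, p)`` with df = 1 and the upper-tail p-value.  No
    continuity correction unless ``yates`` is set.
    """
    low = np.asarray(counts_low, dtype=float)
    high = np.asarray(counts_high, dtype=float)
    rest = list(rest_classes)
    if not rest:
        raise ValueError("rest_classes must be nonempty")
    if (low < 0).any() or (high < 0).any():
        raise ValueError("counts must be nonnegative")
    table = np.array(
        [
            [low[target_class], low[rest].sum()],
            [high[target_class], high[rest].sum()],
        ]
    )
    for axis, name in ((0, "habitat row"), (1, "class column")):
        margins = table.sum(axis=1 - axis)
        if (margins == 0).any():
            raise DegenerateTableError(
                f"zero {name} margin in 2x2 table for class {target_class}"
            )
    stat, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return float(stat), int(df), float(p)


@dataclass
class OrderedResult:
    """Outcome of the ordered forward chi-square procedure."""

    classes: list[str]
    counts_low: np.ndarray
    counts_high: np.ndarray
    unordered_p: np.ndarray
    rank: np.ndarray              # 1..6, permutation ordered by unordered_p
    ordered_p: np.ndarray         # NaN where a sub-table was degenerate
    statistics: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mutation_class": self.classes,
                "counts_low": self.counts_low.astype(int),
                "counts_high": self.counts_high.astype(int),
                "unordered_p": self.unordered_p,
                "rank": self.rank,
                "ordered_p": self.ordered_p,
                "statistic": self.statistics,
            }
        )


def ordered_forward(
    counts_low,
    counts_high,
    classes: list[str] | None = None,
    yates: bool = False,
) -> OrderedResult:
    """Run the full ordered chi-square forward selection.

    Ties in the unordered p-values are broken by descending total count and
    then class name, so the ranking is deterministic.  A degenerate
    sub-table yields NaN for that rank's ordered p with a warning recorded.
    """
    low = np.asarray(counts_low, dtype=float)
    high = np.asarray(counts_high, dtype=float)
    if low.shape != high.shape or low.ndim != 1:
        raise ValueError("counts_low and counts_high must be 1-d of equal length")
    m = len(low)
    if classes is None:
        classes = [f"class{i}" for i in range(m)]
    if low.sum() == 0 or high.sum() == 0:
        raise DegenerateTableError("a habitat has zero total count")

    unordered_p = np.full(m, np.nan)
    unordered_stat = np.full(m, np.nan)
    warnings: list[str] = []
    for c in range(m):
        rest = [i for i in range(m) if i != c]
        try:
            unordered_stat[c], _, unordered_p[c] = chisq_vs_rest(
                low, high, c, rest, yates=yates
            )
        except DegenerateTableError as exc:
            warnings.append(f"unordered test for {classes[c]}: {exc}")
    # deterministic ranking: p ascending, then total count descending, then name
    total = low + high
    order = sorted(
        range(m),
        key=lambda c: (
            np.inf if np.isnan(unordered_p[c]) else unordered_p[c],
            -total[c],
            classes[c],
        ),
    )
    rank = np.empty(m, dtype=int)
    for r, c in enumerate(order, start=1):
        rank[c] = r

    ordered_p = np.full(m, np.nan)
    statistics = np.full(m, np.nan)
    for r, c in enumerate(order, start=1):
        if r == 1:
            ordered_p[c] = unordered_p[c]
            statistics[c] = unordered_stat[c]
            continue
        if r < m:
            rest = order[r:]          # classes ranked strictly below m_r
        else:
            rest = [order[m - 2]]     # last class vs the rank-(m-1) class
        try:
            statistics[c], _, ordered_p[c] = chisq_vs_rest(low, high, c, rest, yates=yates)
        except DegenerateTableError as exc:
            warnings.append(f"ordered test rank {r} ({classes[c]}): {exc}")
    return OrderedResult(
        classes=list(classes),
        counts_low=low,
        counts_high=high,
        unordered_p=unordered_p,
        rank=rank,
        ordered_p=ordered_p,
        statistics=statistics,
        warnings=warnings,
    )


def holm_adjust(p_values, k: int) -> np.ndarray:
    """Holm step-down adjustment with an external family size k.

    k may exceed the number of supplied p-values when the family includes
    tests adjusted elsewhere: adjusted(r) = min(1, max_{r'<=r} (k - r' + 1) p_(r')),
    returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if k < len(p):
        raise ValueError(f"k={k} smaller than the number of p-values ({len(p)})")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty_like(p)
    running = 0.0
    for r, idx in enumerate(order, start=1):
        running = max(running, (k - r + 1) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
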