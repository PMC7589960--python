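"""Student-Newman-Keuls stepwise multiple comparisons.

Cell means are ordered and ranges tested with studentized-range critical
values q(alpha, p, df) where p is the span of the range. The procedure
is stepwise: a range is tested only if the range containing it was
significant; once a span is declared non-significant, every pair inside
it is declared non-significant without testing. Homogeneous groups are
the maximal non-significant spans (the familiar "underlining" display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import studentized_range


@dataclass
class SnkResult:
    ordered_labels: tuple
    ordered_means: tuple[float, ...]
    #: (label_low, label_high) -> True if significantly different
    decisions: dict[tuple, bool]
    homogeneous_groups: list[tuple]
    alpha: float

    def significant_pairs(self) -> list[tuple]:
        return sorted(k for k, v in self.decisions.items() if v)


def snk_posthoc(
    means: dict,
    n_per_group: int,
    mse: float,
    df_error: int,
    alpha: float = 0.05,
) -> SnkResult:
    """Run the SNK procedure on a set of equal-n cell means.

    ``means`` maps cell label to mean; ``mse`` and ``df_error`` come from
    the preceding ANOVA. Requires df_error >= 1 and alpha in (0, 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if mse < 0:
        raise ValueError("mse must be >= 0")

    labels = sorted(means, key=lambda k: (means[k], str(k)))
    m = np.array([means[k] for k in labels])
    k = len(labels)
    se = np.sqrt(mse / n_per_group)
    decided: dict[tuple[int, int], bool] = {}

    def declare_span_ns(i: int, j: int) -> None:
        for u in range(i, j + 1):
            for v in range(u + 1, j + 1):
                decided.setdefault((u, v), False)

    def test(i: int, j: int) -> None:
        if (i, j) in decided or j <= i:
            return
        span = j - i + 1
        if se == 0.0:
            significant = m[j] > m[i]
        else:
            q_obs = (m[j] - m[i]) / se
            q_crit = studentized_range.ppf(1.0 - alpha, span, df_error)
            significant = q_obs > q_crit
        if significant:
            decided[(i, j)] = True
            test(i, j - 1)
            test(i + 1, j)
        else:
            declare_span_ns(i, j)

    if k >= 2:
        test(0, k - 1)

    # maximal non-significant spans -> homogeneous groups
    groups: list[tuple] = []
    for i in range(k):
        j = i
        while j + 1 < k and not any(
            decided.get((u, v), False) for u in range(i, j + 2) for v in range(u + 1, j + 2)
        ):
            j += 1
        span = tuple(labels[i : j + 1])
        if not any(set(span) <= set(gr) for gr in groups):
            groups.append(span)

    decisions = {
        (labels[i], labels[j]): sig for (i, j), sig in decided.items()
    }
    # pairs never reached (k < 2) default to non-significant
    for i in range(k):
        for j in range(i + 1, k):
            decisions.setdefault((labels[i], labels[j]), False)
    return SnkResult(tuple(labels), tuple(m), decisions, groups, alpha)
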