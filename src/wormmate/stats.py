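"""Group comparisons used throughout the behavioral analyses.

Categorical outcomes (potent vs. not potent, protracted vs. not) are
compared with Fisher's exact test; non-Gaussian metrics with the
Mann-Whitney rank test; Gaussian metrics across more than two groups with
one-way ANOVA followed by Tukey's HSD post-test.  No multiple-testing
correction is applied beyond Tukey within an ANOVA family — comparisons
are reported per test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``: rows are groups, columns yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")
        self.a, self.b, self.c, self.d = (
            int(self.a),
            int(self.b),
            int(self.c),
            int(self.d),
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool = False  # a zero margin: p defined as 1, no information


@dataclass
class MannWhitneyResult:
    u_statistic: float  # U for the first sample
    p_value: float
    method: str  # "exact" or "asymptotic"
    n_x: int
    n_y: int


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_1, group_2, mean_diff, p_adj, reject
    zero_variance: bool = False


def fisher_exact(table: ContingencyTable2x2) -> FisherResult:
    """Two-sided Fisher's exact test by the probability-mass rule.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed (within float
    tolerance) that of the observed table.  A table with a zero margin
    carries no information; p is defined as 1 and flagged.
    """
    if table.has_zero_margin:
        return FisherResult(p_value=1.0, odds_ratio=float("nan"), degenerate=True)
    odds, p = sps.fisher_exact(table.as_array(), alternative="two-sided")
    return FisherResult(p_value=float(p), odds_ratio=float(odds))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    The exact null distribution is enumerated when the combined sample size
    is at most 20 and the data are tie-free; otherwise the normal
    approximation with tie-corrected variance and continuity correction is
    used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not len(x) or not len(y):
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return MannWhitneyResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method=method,
        n_x=len(x),
        n_y=len(y),
    )


def anova_tukey(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey's HSD post-test.

    ``groups`` maps group labels to observation lists.  When every group is
    a constant with identical values the F statistic is undefined
    (zero variance); the result is flagged and pairwise decisions are all
    non-rejections.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, arr in zip(labels, arrays):
        if not len(arr):
            raise ValueError(f"group {k!r} is empty")
    n_total = sum(len(a) for a in arrays)
    if n_total <= len(arrays):
        raise ValueError("total n must exceed the number of groups")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        pairs = [
            {
                "group_1": labels[i],
                "group_2": labels[j],
                "mean_diff": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return AnovaTukeyResult(
            f_statistic=float("nan"),
            p_value=float("nan"),
            pairwise=pd.DataFrame(pairs),
            zero_variance=True,
        )

    f_stat, p_val = sps.f_oneway(*arrays)
    hsd = sps.tukey_hsd(*arrays)
    pairs = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            p_adj = float(hsd.pvalue[i, j])
            pairs.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": p_adj,
                    "reject": p_adj < alpha,
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        pairwise=pd.DataFrame(pairs),
    )
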