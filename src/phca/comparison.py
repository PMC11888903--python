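"""Rank-based classifier comparison: Friedman omnibus + Nemenyi post hoc.

Classifiers are compared on blocks of performance values (by default the
five metric values of a single trial, so k classifiers x N = 5 blocks).
Within each block the classifiers are ranked with "higher value is better"
(ties share the mean rank).  The Friedman test asks whether the average
ranks could come from equivalent classifiers; when it rejects, the Nemenyi
test compares every pair: the difference of average ranks is referred to
the Studentized range distribution (infinite degrees of freedom), and two
classifiers differ significantly when their average ranks differ by at
least the critical difference

    CD = q_alpha * sqrt(k (k + 1) / (6 N)),

with q_alpha the alpha-level Studentized-range quantile divided by sqrt(2).
Pairwise p-values are reported capped to [0.001, 0.900], the range of the
standard tabulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PerformanceBlockMatrix",
    "ComparisonResult",
    "friedman_test",
    "nemenyi_pairwise",
    "critical_difference",
    "average_ranks",
    "compare_classifiers",
    "significance_table",
    "metric_block_matrix",
]

P_FLOOR = 0.001
P_CAP = 0.900


@dataclass(frozen=True)
class PerformanceBlockMatrix:
    """N blocks x k classifiers of performance values in [0, 1]."""

    values: np.ndarray
    classifiers: tuple

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("block matrix must be 2-d (blocks x classifiers)")
        n, k = vals.shape
        if k < 2 or k != len(self.classifiers):
            raise ValueError("need k >= 2 classifiers matching the column names")
        if n < 2:
            raise ValueError("need N >= 2 blocks")
        if not np.isfinite(vals).all():
            raise ValueError("block matrix has missing entries")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "classifiers", tuple(self.classifiers))

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    @property
    def n_classifiers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ComparisonResult:
    friedman_statistic: float
    friedman_p: float
    average_ranks: pd.Series
    nemenyi_p: pd.DataFrame
    cd: float
    alpha: float


def _within_block_ranks(matrix: PerformanceBlockMatrix) -> np.ndarray:
    """Rank classifiers within each block, rank 1 = best (highest value)."""
    return np.vstack([stats.rankdata(-row, method="average")
                      for row in matrix.values])


def average_ranks(matrix: PerformanceBlockMatrix) -> pd.Series:
    ranks = _within_block_ranks(matrix).mean(axis=0)
    return pd.Series(ranks, index=list(matrix.classifiers), name="average_rank")


def friedman_test(matrix: PerformanceBlockMatrix):
    """Tie-corrected Friedman statistic and chi-square p-value.

    With r_ij the within-block ranks and R_j the rank sums, the statistic is
    (k-1) * sum_j (R_j - N(k+1)/2)^2 / (A - C), where A is the sum of
    squared ranks and C = N k (k+1)^2 / 4.  When every block is fully tied
    (A = C) the statistic is 0 and p = 1.
    """
    ranks = _within_block_ranks(matrix)
    n, k = ranks.shape
    rank_sums = ranks.sum(axis=0)
    a = float(np.sum(ranks ** 2))
    c = n * k * (k + 1) ** 2 / 4.0
    if np.isclose(a, c):
        return 0.0, 1.0
    statistic = (k - 1) * float(np.sum((rank_sums - n * (k + 1) / 2.0) ** 2)) / (a - c)
    p = float(stats.chi2.sf(statistic, k - 1))
    return float(statistic), min(max(p, np.finfo(float).tiny), 1.0)


def nemenyi_pairwise(matrix: PerformanceBlockMatrix) -> pd.DataFrame:
    """Symmetric k x k matrix of Nemenyi p-values (diagonal 1).

    p_ij = P[Q >= |Rbar_i - Rbar_j| / sqrt(k(k+1)/(12 N))] under the
    Studentized range distribution with infinite degrees of freedom;
    off-diagonal values are capped to [0.001, 0.900].
    """
    ranks = _within_block_ranks(matrix)
    n, k = ranks.shape
    avg = ranks.mean(axis=0)
    scale = np.sqrt(k * (k + 1) / (12.0 * n))
    diff = np.abs(avg[:, None] - avg[None, :])
    q = diff / scale
    p = stats.studentized_range.sf(q, k, np.inf)
    p = np.clip(p, P_FLOOR, P_CAP)
    np.fill_diagonal(p, 1.0)
    return pd.DataFrame(p, index=list(matrix.classifiers), columns=list(matrix.classifiers))


def critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """CD = q_alpha * sqrt(k(k+1) / (6N)) with q_alpha from the Studentized
    range at infinite degrees of freedom, divided by sqrt(2)."""
    if alpha not in (0.05, 0.10):
        raise ValueError(f"alpha must be 0.05 or 0.10, got {alpha}")
    if k < 2 or n < 1:
        raise ValueError("need k >= 2 classifiers and N >= 1 blocks")
    q_alpha = stats.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q_alpha * np.sqrt(k * (k + 1) / (6.0 * n)))


def compare_classifiers(matrix: PerformanceBlockMatrix, alpha: float = 0.05) -> ComparisonResult:
    statistic, p = friedman_test(matrix)
    return ComparisonResult(
        friedman_statistic=statistic,
        friedman_p=p,
        average_ranks=average_ranks(matrix),
        nemenyi_p=nemenyi_pairwise(matrix),
        cd=critical_difference(matrix.n_classifiers, matrix.n_blocks, alpha),
        alpha=alpha,
    )


def metric_block_matrix(metrics_by_classifier: dict,
                        roster: Optional[Sequence[str]] = None) -> PerformanceBlockMatrix:
    """Blocks = the five metric values of one trial, columns = classifiers.

    ``metrics_by_classifier`` maps classifier id to a
    :class:`~phca.evaluation.MetricsReport` (or a metric-name -> value dict).
    """
    from .evaluation import METRIC_NAMES

    roster = list(roster) if roster is not None else list(metrics_by_classifier)
    rows = []
    for name in METRIC_NAMES:
        row = []
        for cid in roster:
            m = metrics_by_classifier[cid]
            row.append(m[name] if isinstance(m, dict) else m.metric(name))
        rows.append(row)
    return PerformanceBlockMatrix(np.array(rows), tuple(roster))


def significance_table(per_trial_metrics: Sequence[dict], alpha: float = 0.05,
                       reference: str = "PHCA",
                       roster: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Per-trial Nemenyi p-values of the reference classifier vs the others.

    One row per trial; columns ``<reference>-<other>``; a pair with
    p > alpha is flagged "no significant difference" (standard reading:
    small p means significantly different).
    """
    rows = []
    columns = None
    for t, metrics in enumerate(per_trial_metrics):
        matrix = metric_block_matrix(metrics, roster)
        if reference not in matrix.classifiers:
            raise KeyError(f"reference classifier {reference!r} missing from roster")
        nem = nemenyi_pairwise(matrix)
        others = [c for c in matrix.classifiers if c != reference]
        if columns is None:
            columns = [f"{reference}-{o}" for o in others]
        row = {"trial": t}
        for o in others:
            p = float(nem.loc[reference, o])
            row[f"{reference}-{o}"] = p
            row[f"{reference}-{o} significant"] = bool(p <= alpha)
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial")
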