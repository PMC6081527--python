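"""Summary-statistics ANOVA, Tukey-Kramer post hoc, Spearman and RMSD/CV.

The bench study reports per-group means, SDs and n = 3 rather than raw
replicates, so the one-way ANOVA and the Tukey-Kramer test are computed
directly from summary statistics:

    SS_between = sum n_i (m_i - grand mean)^2,   df_between = k - 1
    SS_within  = sum (n_i - 1) s_i^2,            df_within  = sum (n_i - 1)
    F = MS_between / MS_within,  p = upper tail of F(df_b, df_w)

    q_ij = |m_i - m_j| / sqrt(MSE (1/n_i + 1/n_j) / 2)
    adjusted p = upper tail of the studentized range with k groups, df_w

This is algebraically identical to the classical raw-data ANOVA applied
to any per-group samples with those means and SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "ANOVAResult",
    "TukeyResult",
    "ReproducibilityResult",
    "anova_from_summary",
    "tukey_kramer_from_summary",
    "anova_from_replicates",
    "summarize_replicates",
    "spearman_correlation",
    "rmsd_cv",
]


@dataclass
class SummaryStats:
    """Per-group (mean, SD, n) table, e.g. one printed table row."""

    group_labels: Sequence[str]
    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        k = len(self.group_labels)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("group_labels, means, sds and ns must have equal length")
        if np.any(self.sds < 0):
            raise ValueError("standard deviations must be non-negative")
        if np.any(self.ns < 2):
            raise ValueError("every group needs n >= 2 for a within-group variance")

    def index(self, label: str) -> int:
        return list(self.group_labels).index(label)


@dataclass
class ANOVAResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TukeyResult:
    pair: tuple[str, str]
    mean_difference: float
    q_statistic: float
    adjusted_p: float


@dataclass
class ReproducibilityResult:
    """Replicate scatter of AUC values at one integration time."""

    integration_time: float
    rmsd: float  # gray value units (root mean replicate variance)
    cv_pct: float  # 100 * rmsd / grand mean AUC


def _sums_of_squares(stats: SummaryStats) -> tuple[float, int, float, int]:
    ns = stats.ns.astype(float)
    grand = float(np.sum(ns * stats.means) / ns.sum())
    ss_b = float(np.sum(ns * (stats.means - grand) ** 2))
    ss_w = float(np.sum((ns - 1) * stats.sds**2))
    return ss_b, len(stats.means) - 1, ss_w, int(np.sum(ns - 1))


def anova_from_summary(stats: SummaryStats) -> ANOVAResult:
    """One-way ANOVA computed from per-group means, SDs and sizes."""
    if len(stats.means) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ss_b, df_b, ss_w, df_w = _sums_of_squares(stats)
    if ss_w == 0.0:
        if ss_b == 0.0:
            raise ValueError("degenerate input: no variance between or within groups")
        warnings.warn(
            "zero within-group variance with unequal means; F is infinite and p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return ANOVAResult(np.inf, df_b, df_w, 0.0)
    f = (ss_b / df_b) / (ss_w / df_w)
    return ANOVAResult(f, df_b, df_w, float(sps.f.sf(f, df_b, df_w)))


def tukey_kramer_from_summary(stats: SummaryStats, pair: tuple[str, str]) -> TukeyResult:
    """Tukey-Kramer adjusted comparison of two groups after ANOVA."""
    i, j = stats.index(pair[0]), stats.index(pair[1])
    if i == j:
        raise ValueError("pair labels must name two distinct groups")
    _, _, ss_w, df_w = _sums_of_squares(stats)
    if ss_w == 0.0:
        raise ValueError("zero within-group variance; Tukey-Kramer undefined")
    mse = ss_w / df_w
    diff = float(stats.means[i] - stats.means[j])
    se = np.sqrt(mse * (1.0 / stats.ns[i] + 1.0 / stats.ns[j]) / 2.0)
    q = abs(diff) / se
    if q == 0.0:
        p = 1.0
    else:
        p = float(sps.studentized_range.sf(q, len(stats.means), df_w))
    return TukeyResult(pair=(pair[0], pair[1]), mean_difference=diff, q_statistic=q, adjusted_p=p)


def summarize_replicates(groups: dict[str, Sequence[float]]) -> SummaryStats:
    """Collapse raw per-group replicate values to a SummaryStats table."""
    labels = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in labels]
    return SummaryStats(
        group_labels=labels,
        means=np.array([v.mean() for v in values]),
        sds=np.array([v.std(ddof=1) for v in values]),
        ns=np.array([len(v) for v in values]),
    )


def anova_from_replicates(groups: dict[str, Sequence[float]]) -> ANOVAResult:
    """Classical one-way ANOVA on raw replicates.

    Exactly equals :func:`anova_from_summary` applied to the groups' own
    means and SDs (the summary statistics are sufficient).
    """
    return anova_from_summary(summarize_replicates(groups))


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho (average-rank ties) with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def rmsd_cv(
    auc_by_condition: dict[str, Sequence[float]], integration_time: float
) -> ReproducibilityResult:
    """Replicate reproducibility of AUC values at one integration time.

    RMSD is the square root of the mean (over conditions, i.e. stenosis
    model x ROI cells) of the replicate variance; CV expresses it as a
    percentage of the grand mean AUC.
    """
    variances = []
    all_values = []
    for cond, values in auc_by_condition.items():
        v = np.asarray(values, dtype=float)
        if len(v) < 2:
            raise ValueError(f"condition {cond!r} has a single replicate; need >= 2")
        variances.append(v.var(ddof=1))
        all_values.append(v)
    if not variances:
        raise ValueError("no conditions supplied")
    rmsd = float(np.sqrt(np.mean(variances)))
    grand = float(np.mean(np.concatenate(all_values)))
    if grand == 0.0:
        raise ValueError("grand mean AUC is zero; CV undefined")
    return ReproducibilityResult(
        integration_time=integration_time, rmsd=rmsd, cv_pct=100.0 * rmsd / abs(grand)
    )
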