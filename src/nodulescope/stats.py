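"""Nonparametric group-comparison and ordered-trend statistics.

Omnibus Kruskal-Wallis with Dunn's post-hoc (Bonferroni by default),
histogram binning of grouped metric values into ordered contingency tables,
the Mantel-Haenszel linear-by-linear association chi-squared test for trend
(chi2 = (N-1) r^2 on row/column scores), Goodman-Kruskal's gamma as the
ordinal effect measure, Haberman-adjusted standardised residuals to locate
the cells driving a difference, and the 2^-ddCq qPCR fold-change helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedValues",
    "ContingencyTable",
    "TrendResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "bin_values",
    "linear_by_linear_trend",
    "goodman_kruskal_gamma",
    "adjusted_residuals",
    "ddct_fold_change",
]


@dataclass
class GroupedValues:
    """Metric values keyed by (ordered) group name."""

    values: Mapping[str, Sequence[float]]
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = {k: np.asarray(v, float) for k, v in self.values.items()}
        for name, v in self.values.items():
            if v.size < 1:
                raise ValueError(f"group {name!r} is empty")

    @property
    def groups(self) -> List[str]:
        return list(self.values)

    @property
    def n_total(self) -> int:
        return int(sum(v.size for v in self.values.values()))


@dataclass
class ContingencyTable:
    """Groups x ordered-bins count matrix with monotone numeric scores."""

    counts: np.ndarray
    row_scores: Optional[Sequence[float]] = None
    col_scores: Optional[Sequence[float]] = None
    row_labels: Optional[Sequence[str]] = None
    col_labels: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0) or not np.all(
            self.counts == np.round(self.counts)
        ):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        if self.counts.sum() < 2:
            raise ValueError("need at least 2 observations")
        r, c = self.counts.shape
        self.row_scores = (
            np.arange(1.0, r + 1.0)
            if self.row_scores is None
            else np.asarray(self.row_scores, float)
        )
        self.col_scores = (
            np.arange(1.0, c + 1.0)
            if self.col_scores is None
            else np.asarray(self.col_scores, float)
        )
        for scores, m in ((self.row_scores, r), (self.col_scores, c)):
            if scores.size != m:
                raise ValueError("score length does not match table shape")
            if scores.size >= 2 and not (
                np.all(np.diff(scores) > 0) or np.all(np.diff(scores) < 0)
            ):
                raise ValueError("scores must be strictly monotone")


@dataclass
class TrendResult:
    chi2: float
    p_value: float
    gamma: float
    adjusted_residuals: np.ndarray = field(repr=False)
    n: int = 0
    df: int = 1


def kruskal_wallis(g: GroupedValues) -> Tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value.

    All-identical data are a defined degenerate case: H = 0, p = 1.
    """
    samples = list(g.values.values())
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if g.n_total < 3:
        raise ValueError("need at least 3 observations")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def dunn_posthoc(g: GroupedValues, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks after a Kruskal-Wallis omnibus.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - T/(12(N-1))] (1/n_i + 1/n_j))
    with the tie term T = sum(t^3 - t) over tied value multiplicities.
    ``adjust`` is "bonferroni" (over all pairs) or "none"; both raw and
    adjusted p-values are returned.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    names = g.groups
    samples = [g.values[name] for name in names]
    sizes = np.array([s.size for s in samples])
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)
    mean_ranks = [
        ranks[lo:hi].mean() for lo, hi in zip(np.r_[0, bounds[:-1]], bounds)
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, n_pairs * p_raw) if adjust == "bonferroni" else p_raw
        rows.append(
            {"group_a": a, "group_b": b, "z": float(z),
             "p_raw": float(p_raw), "p_adj": float(p_adj)}
        )
    return pd.DataFrame(rows)


def bin_values(g: GroupedValues, edges: Sequence[float]) -> ContingencyTable:
    """Histogram each group into ordered bins.

    Bins are half-open lower-inclusive [lo, hi), final bin closed.
    Out-of-range values are clamped into the end bins (logged policy).
    """
    edges = np.asarray(edges, float)
    if edges.size < 2:
        raise ValueError("need at least 2 bin edges")
    if not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be strictly increasing")
    n_bins = edges.size - 1
    names = g.groups
    counts = np.zeros((len(names), n_bins), dtype=np.int64)
    for i, name in enumerate(names):
        v = np.asarray(g.values[name], float)
        idx = np.searchsorted(edges, v, side="right") - 1
        idx = np.clip(idx, 0, n_bins - 1)  # clamp + final-bin-closed
        counts[i] = np.bincount(idx, minlength=n_bins)
    col_labels = [
        f"[{edges[i]:g},{edges[i+1]:g}{')' if i < n_bins - 1 else ']'}"
        for i in range(n_bins)
    ]
    return ContingencyTable(counts, row_labels=list(names), col_labels=col_labels)


def linear_by_linear_trend(t: ContingencyTable) -> TrendResult:
    """Mantel-Haenszel linear-by-linear association test for trend.

    chi2 = (N - 1) * r^2 with r the Pearson correlation of the row/column
    scores over the N expanded observations; df = 1. Gamma and adjusted
    residuals are attached for the full ordered-table report.
    """
    counts = t.counts
    n = int(counts.sum())
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("both table dimensions must be >= 2")
    r_sc = np.asarray(t.row_scores, float)
    c_sc = np.asarray(t.col_scores, float)
    row_marg = counts.sum(axis=1)
    col_marg = counts.sum(axis=0)
    mean_r = float(np.dot(row_marg, r_sc)) / n
    mean_c = float(np.dot(col_marg, c_sc)) / n
    var_r = float(np.dot(row_marg, (r_sc - mean_r) ** 2))
    var_c = float(np.dot(col_marg, (c_sc - mean_c) ** 2))
    if var_r == 0 or var_c == 0:
        raise ValueError("zero variance in row or column scores")
    cov = float(
        np.sum(counts * np.outer(r_sc - mean_r, c_sc - mean_c))
    )
    r = cov / np.sqrt(var_r * var_c)
    chi2 = (n - 1) * r * r
    p = float(sps.chi2.sf(chi2, df=1))
    return TrendResult(
        chi2=float(chi2),
        p_value=p,
        gamma=goodman_kruskal_gamma(t),
        adjusted_residuals=adjusted_residuals(t),
        n=n,
    )


def goodman_kruskal_gamma(t: ContingencyTable) -> float:
    """Goodman-Kruskal's gamma = (C - D)/(C + D) over concordant and
    discordant pairs of the ordered table."""
    counts = t.counts.astype(float)
    r, c = counts.shape
    concordant = discordant = 0.0
    for i in range(r):
        for j in range(c):
            nij = counts[i, j]
            if nij == 0:
                continue
            concordant += nij * counts[i + 1 :, j + 1 :].sum()
            discordant += nij * counts[i + 1 :, :j].sum()
    if concordant + discordant == 0:
        raise ValueError("gamma undefined: no concordant or discordant pairs")
    return float((concordant - discordant) / (concordant + discordant))


def adjusted_residuals(t: ContingencyTable, adjusted: bool = True) -> np.ndarray:
    """Standardised residuals of the independence model.

    Haberman adjusted form by default:
    SR_ij = (O - E) / sqrt(E (1 - row_i/N)(1 - col_j/N));
    ``adjusted=False`` gives raw Pearson residuals (O - E)/sqrt(E).
    """
    counts = t.counts.astype(float)
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal row or column")
    expected = np.outer(row, col) / n
    resid = counts - expected
    denom = np.sqrt(expected)
    if adjusted:
        denom = denom * np.sqrt(np.outer(1.0 - row / n, 1.0 - col / n))
    return resid / denom


def ddct_fold_change(
    cq_target_treated: float,
    cq_ref_treated: float,
    cq_target_control: float,
    cq_ref_control: float,
) -> float:
    """Relative expression fold change 2^-ddCq.

    ddCq = (Cq_target - Cq_ref)_treated - (Cq_target - Cq_ref)_control.
    """
    vals = (cq_target_treated, cq_ref_treated, cq_target_control, cq_ref_control)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Cq values must be finite")
    ddcq = (cq_target_treated - cq_ref_treated) - (
        cq_target_control - cq_ref_control
    )
    return float(2.0 ** (-ddcq))
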