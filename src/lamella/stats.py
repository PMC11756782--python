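"""Paired k-group nonparametric comparison stack.

The analysis design for comparing plan-quality metrics across calculation-
setting groups, all on the same lesions (paired):

* Friedman test (within-subject ranks, tie-corrected chi-square) as the
  k-group omnibus;
* Scheffé-type simultaneous post hoc comparison on the Friedman rank sums
  for all pairs;
* a conditional rule: pairs the post hoc test leaves non-significant but
  with p < 0.9 are re-examined with the paired Wilcoxon signed-rank test
  (the post hoc construction is conservative; the gate recovers power on
  borderline pairs without touching clearly null ones);
* Jonckheere-Terpstra trend test across the a-priori group ordering;
* strict significance tiers p < 0.05 (*), < 0.01 (**), < 0.001 (***).

Wilcoxon uses the classical zero-drop convention and an exact null
distribution (dynamic program over signed ranks, ties included) up to
n = 25, a tie-corrected normal approximation with continuity correction
above. Box-and-whisker summaries use linearly interpolated quartiles and
1.5*IQR whisker fences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "PairedPanel", "GroupComparison", "friedman", "scheffe_posthoc",
    "wilcoxon_signed_rank", "jonckheere_terpstra", "conditional_wsrt_rule",
    "stars", "bwp_summary", "compare_groups",
]

WSRT_EXACT_MAX_N = 25


@dataclass
class PairedPanel:
    """n subjects x k groups of one metric; groups carry the a-priori order
    (worst-quality settings first) used by the trend test."""

    values: np.ndarray
    group_order: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("panel must be 2-D (subjects x groups)")
        n, k = self.values.shape
        if k < 2:
            raise ValueError("need at least two groups")
        if len(self.group_order) != k:
            raise ValueError("group_order length must match the number of columns")
        if not self.subject_ids:
            self.subject_ids = tuple(f"s{i}" for i in range(n))
        if np.isnan(self.values).any():
            raise ValueError("panel has missing cells; drop subjects listwise first")
        self.group_order = tuple(self.group_order)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_columns(cls, columns: dict[str, Sequence[float]],
                     group_order: Sequence[str],
                     subject_ids: Sequence[str] | None = None,
                     dropna: bool = True) -> "PairedPanel":
        """Assemble a panel from per-group columns, dropping incomplete
        subjects listwise (mirrors per-metric eligibility censoring)."""
        mat = np.column_stack([np.asarray(columns[g], float) for g in group_order])
        ids = tuple(subject_ids) if subject_ids else tuple(f"s{i}" for i in range(len(mat)))
        if dropna:
            keep = ~np.isnan(mat).any(axis=1)
            mat = mat[keep]
            ids = tuple(s for s, k_ in zip(ids, keep) if k_)
        return cls(mat, tuple(group_order), ids)


def _within_subject_ranks(values: np.ndarray) -> np.ndarray:
    return _sps.rankdata(values, axis=1)


def friedman(panel: PairedPanel) -> tuple[float, float]:
    """Friedman omnibus test with the standard tie correction.

    Returns ``(chi2_statistic, p)``; p from the chi-square distribution with
    k-1 degrees of freedom. Fully tied panels give statistic 0, p = 1.
    """
    n, k = panel.n, panel.k
    if n < 2 or k < 3:
        raise ValueError("Friedman needs n >= 2 subjects and k >= 3 groups")
    r = _within_subject_ranks(panel.values)
    rank_sums = r.sum(axis=0)
    a = float((r**2).sum())
    c = n * k * (k + 1) ** 2 / 4.0
    if a == c:  # every subject fully tied
        return 0.0, 1.0
    stat = (k - 1) * float(((rank_sums - n * (k + 1) / 2.0) ** 2).sum()) / (a - c)
    p = float(_sps.chi2.sf(stat, k - 1))
    return stat, p


def scheffe_posthoc(panel: PairedPanel) -> np.ndarray:
    """Scheffé-type simultaneous pairwise comparison on Friedman rank sums.

    For each pair (i, j): S_ij = (R_i - R_j)^2 / (n*k*(k+1)/6) referred to
    chi-square with k-1 df — simultaneous over all contrasts, hence
    conservative pairwise. Returns the symmetric k x k p matrix (unit
    diagonal).
    """
    n, k = panel.n, panel.k
    if n < 2 or k < 3:
        raise ValueError("post hoc needs n >= 2 subjects and k >= 3 groups")
    rank_sums = _within_subject_ranks(panel.values).sum(axis=0)
    denom = n * k * (k + 1) / 6.0
    diff2 = (rank_sums[:, None] - rank_sums[None, :]) ** 2
    p = _sps.chi2.sf(diff2 / denom, k - 1)
    np.fill_diagonal(p, 1.0)
    return p


def _wsrt_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by dynamic program over all 2^n sign patterns.

    Works with mid-ranks: doubling makes every rank an integer, and the
    distribution of 2*W+ is built by convolution.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    lower = counts[: w2 + 1].sum()
    upper = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (classical convention); ties in |d| get
    mid-ranks. Exact enumeration for n <= 25 after zero removal, else the
    tie-corrected normal approximation with continuity correction. All
    differences zero returns p = 1.
    """
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = _sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= WSRT_EXACT_MAX_N:
        return _wsrt_exact_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    return float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))


def jonckheere_terpstra(panel: PairedPanel) -> tuple[float, float, str]:
    """Jonckheere-Terpstra test for a monotone trend across ordered groups.

    The statistic sums Mann-Whitney counts over all ordered group pairs
    (ties count one half); the p-value uses the tie-corrected normal
    approximation. Applied to the group columns as independent samples —
    the test has no paired form. Returns ``(z, p, trend)`` with trend
    ``"increasing"``, ``"decreasing"`` or ``"none"`` in the group order.
    """
    if panel.k < 3:
        raise ValueError("trend test needs k >= 3 ordered groups")
    groups = [panel.values[:, j] for j in range(panel.k)]
    jt = 0.0
    for i in range(panel.k):
        for j in range(i + 1, panel.k):
            a, b = groups[i][:, None], groups[j][None, :]
            jt += float((a < b).sum()) + 0.5 * float((a == b).sum())
    sizes = np.array([g.size for g in groups], float)
    big_n = sizes.sum()
    pooled = np.concatenate(groups)
    tie_counts = np.unique(pooled, return_counts=True)[1].astype(float)
    mean = (big_n**2 - (sizes**2).sum()) / 4.0
    t1 = (big_n * (big_n - 1) * (2 * big_n + 5)
          - (sizes * (sizes - 1) * (2 * sizes + 5)).sum()
          - (tie_counts * (tie_counts - 1) * (2 * tie_counts + 5)).sum()) / 72.0
    t2 = ((sizes * (sizes - 1) * (sizes - 2)).sum()
          * (tie_counts * (tie_counts - 1) * (tie_counts - 2)).sum()
          ) / (36.0 * big_n * (big_n - 1) * (big_n - 2))
    t3 = ((sizes * (sizes - 1)).sum() * (tie_counts * (tie_counts - 1)).sum()
          ) / (8.0 * big_n * (big_n - 1))
    var = t1 + t2 + t3
    if var <= 0:  # all observations identical
        return 0.0, 1.0, "none"
    z = (jt - mean) / np.sqrt(var)
    p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    trend = "increasing" if jt > mean else ("decreasing" if jt < mean else "none")
    return float(z), p, trend


def conditional_wsrt_rule(scheffe_p: np.ndarray, alpha: float = 0.05,
                          gate: float = 0.9) -> list[tuple[int, int]]:
    """Pairs to re-test with the paired Wilcoxon signed-rank test.

    Exactly the pairs the post hoc test left non-significant
    (p >= ``alpha``) but short of clearly null (p < ``gate``).
    """
    p = np.asarray(scheffe_p, float)
    out = []
    k = p.shape[0]
    for i in range(k):
        for j in range(i + 1, k):
            if alpha <= p[i, j] < gate:
                out.append((i, j))
    return out


def stars(p: float) -> str:
    """Strict significance tiers: p < 0.05 (*), < 0.01 (**), < 0.001 (***)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value {p:g} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def bwp_summary(values: Sequence[float]) -> dict:
    """Box-and-whisker summary: linearly interpolated quartiles, whiskers at
    the nearest data within 1.5*IQR of the box, outliers beyond."""
    v = np.sort(np.asarray(values, float))
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "q1": float(q1), "median": float(q2), "q3": float(q3),
        "whisker_low": float(inside[0]), "whisker_high": float(inside[-1]),
        "outliers": [float(x) for x in v[(v < lo_fence) | (v > hi_fence)]],
        "n": int(v.size),
    }


@dataclass
class GroupComparison:
    """The full comparison record for one metric panel."""

    group_order: tuple[str, ...]
    friedman_stat: float
    friedman_p: float
    scheffe_p: np.ndarray  # k x k, symmetric, unit diagonal
    wsrt_p: dict[tuple[int, int], float]  # only pairs selected by the gate
    jt_z: float
    jt_p: float
    jt_trend: str

    def pair_label(self, i: int, j: int) -> str:
        return f"{self.group_order[i]} vs {self.group_order[j]}"

    def pair_report(self, i: int, j: int) -> str:
        """'0.475 (NS) [0.003**]'-style cell: post hoc p, stars, and the
        bracketed conditional Wilcoxon result when it was run."""
        sp = self.scheffe_p[i, j]
        cell = f"{sp:.3f}" if stars(sp) == "NS" else f"{sp:.3f} {stars(sp)}"
        if stars(sp) == "NS":
            cell = f"{sp:.3f} (NS)"
        key = (min(i, j), max(i, j))
        if key in self.wsrt_p:
            wp = self.wsrt_p[key]
            tag = "(NS)" if stars(wp) == "NS" else stars(wp)
            cell += f" [{wp:.3f} {tag}]"
        return cell


def compare_groups(panel: PairedPanel, alpha: float = 0.05,
                   gate: float = 0.9) -> GroupComparison:
    """Run the full stack on one metric panel (k >= 3 groups)."""
    stat, fp = friedman(panel)
    sp = scheffe_posthoc(panel)
    wsrt: dict[tuple[int, int], float] = {}
    for i, j in conditional_wsrt_rule(sp, alpha=alpha, gate=gate):
        wsrt[(i, j)] = wilcoxon_signed_rank(panel.values[:, i], panel.values[:, j])
    z, jp, trend = jonckheere_terpstra(panel)
    return GroupComparison(
        group_order=panel.group_order,
        friedman_stat=stat, friedman_p=fp,
        scheffe_p=sp, wsrt_p=wsrt,
        jt_z=z, jt_p=jp, jt_trend=trend,
    )
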