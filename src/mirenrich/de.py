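"""Directional differential expression by Wilcoxon rank-sum with BH control.

Each gene is tested between the relapse+ (R+) and relapse- (R-) outcome
groups with the two-sided Wilcoxon rank-sum test; p-values are adjusted with
the Benjamini-Hochberg step-up procedure across all genes of a dataset, and
genes with adjusted p strictly below ``alpha`` (default 0.05) are split into
separate up- and down-regulated lists by the sign of the median difference
(R+ minus R-).  A directional list qualifies for downstream enrichment only
when it contains at least ``min_genes`` genes (default 30).

The rank-sum test is exact (full enumeration of rank assignments) when the
combined sample size is at most 20 and there are no ties, and otherwise uses
the normal approximation with midranks, tie-corrected variance and a
continuity correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset_io import ExpressionDataset, OutcomeLabels, RELAPSE_POS, RELAPSE_NEG

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "DirectionalGeneLists",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "derive_de_lists",
    "list_qualifies",
    "write_de_table",
]

_EXACT_MAX_N = 20  # combined size up to which the exact null is enumerated


@dataclass(frozen=True)
class DEResult:
    """One gene's rank-sum test: statistic is the R+ group's rank sum (midranks)."""

    gene_id: str
    rank_sum_statistic: float
    p_nominal: float
    p_adjusted: float
    direction: str  # "up" | "down" | "none" (zero median difference)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nominal <= 1.0 or not 0.0 <= self.p_adjusted <= 1.0:
            raise ValueError(f"{self.gene_id}: p-values must lie in [0, 1]")


@dataclass(frozen=True)
class DirectionalGeneLists:
    """Per-dataset up/down gene lists with the tested universe.

    ``up`` and ``down`` are ordered by (adjusted p, nominal p, gene id) and
    are always disjoint; ``qualifies_up``/``qualifies_down`` apply the
    >= ``min_genes`` dataset-qualification rule.
    """

    up: tuple[str, ...]
    down: tuple[str, ...]
    universe: tuple[str, ...]
    alpha: float
    min_genes: int
    qualifies_up: bool
    qualifies_down: bool
    results: tuple[DEResult, ...] = ()

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down lists must be disjoint")
        if not (set(self.up) | set(self.down)) <= set(self.universe):
            raise ValueError("up/down lists must be subsets of the universe")


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two samples.

    Returns ``(rank_sum_statistic, p_nominal)`` where the statistic is the
    sum of (mid)ranks of ``a`` in the pooled sample.  Exact by enumeration
    for combined n <= 20 without ties, else the tie-corrected,
    continuity-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if a.size < 2:
        raise ValueError(f"group a has {a.size} observations; at least 2 required")
    if b.size < 2:
        raise ValueError(f"group b has {b.size} observations; at least 2 required")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    rank_sum = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return rank_sum, float(min(res.pvalue, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p(i) by m/i, take the cumulative minimum from
    the largest rank downward, cap at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    bad = np.where(~((p >= 0.0) & (p <= 1.0)))[0]
    if bad.size:
        raise ValueError(f"p-value at index {bad[0]} ({p[bad[0]]!r}) is outside [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted


def list_qualifies(gene_list, min_genes: int = 30) -> bool:
    """Dataset-qualification rule: a list counts only with >= min_genes genes."""
    return len(tuple(gene_list)) >= min_genes


def derive_de_lists(
    dataset: ExpressionDataset,
    labels: OutcomeLabels,
    alpha: float = 0.05,
    min_genes: int = 30,
) -> DirectionalGeneLists:
    """Per-gene rank-sum tests -> BH -> directional significant gene lists.

    A gene enters a list iff its adjusted p is strictly below ``alpha``;
    direction is the sign of (median R+ - median R-).  Significant genes
    with a zero median difference have no defensible direction and are
    excluded (their count is logged).  Samples without a label are dropped
    with a logged count.
    """
    pos = [s for s in dataset.sample_ids if labels.status.get(s) == RELAPSE_POS]
    neg = [s for s in dataset.sample_ids if labels.status.get(s) == RELAPSE_NEG]
    n_unlabeled = dataset.n_samples - len(pos) - len(neg)
    if n_unlabeled:
        logger.info("dropping %d unlabeled samples", n_unlabeled)
    if len(pos) < 2:
        raise ValueError(f"relapse+ group has {len(pos)} samples; at least 2 required")
    if len(neg) < 2:
        raise ValueError(f"relapse- group has {len(neg)} samples; at least 2 required")

    frame = dataset.frame
    A = frame.loc[:, pos].to_numpy(dtype=float)
    B = frame.loc[:, neg].to_numpy(dtype=float)

    stats_out = np.empty(dataset.n_genes)
    p_nominal = np.empty(dataset.n_genes)
    for i in range(dataset.n_genes):
        stats_out[i], p_nominal[i] = wilcoxon_rank_sum(A[i], B[i])
    p_adjusted = bh_adjust(p_nominal)
    median_diff = np.median(A, axis=1) - np.median(B, axis=1)

    results: list[DEResult] = []
    up: list[tuple[float, float, str]] = []
    down: list[tuple[float, float, str]] = []
    n_zero_direction = 0
    for i, gene in enumerate(dataset.gene_ids):
        if median_diff[i] > 0:
            direction = "up"
        elif median_diff[i] < 0:
            direction = "down"
        else:
            direction = "none"
        results.append(
            DEResult(gene, stats_out[i], p_nominal[i], p_adjusted[i], direction)
        )
        if p_adjusted[i] < alpha:
            key = (p_adjusted[i], p_nominal[i], gene)
            if direction == "up":
                up.append(key)
            elif direction == "down":
                down.append(key)
            else:
                n_zero_direction += 1
    if n_zero_direction:
        logger.info(
            "excluded %d significant genes with zero median difference",
            n_zero_direction,
        )
    up_genes = tuple(g for _, _, g in sorted(up))
    down_genes = tuple(g for _, _, g in sorted(down))
    return DirectionalGeneLists(
        up=up_genes,
        down=down_genes,
        universe=dataset.gene_ids,
        alpha=alpha,
        min_genes=min_genes,
        qualifies_up=list_qualifies(up_genes, min_genes),
        qualifies_down=list_qualifies(down_genes, min_genes),
        results=tuple(results),
    )


def write_de_table(lists: DirectionalGeneLists, path) -> None:
    """TSV of per-gene results: statistic, p-values, direction, significance."""
    significant = set(lists.up) | set(lists.down)
    with open(path, "w") as fh:
        fh.write("gene_id\tstatistic\tp_nominal\tp_adjusted\tdirection\tsignificant\n")
        for r in lists.results:
            fh.write(
                f"{r.gene_id}\t{r.rank_sum_statistic!r}\t{r.p_nominal!r}\t"
                f"{r.p_adjusted!r}\t{r.direction}\t{1 if r.gene_id in significant else 0}\n"
            )
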