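"""Target-reverse-expression verification via t-statistics and KS tests.

This is the alternative screening arm: instead of testing the overlap of a
target set with a thresholded gene list, it asks whether the predicted
targets of a miRNA are *distributionally* shifted relative to the rest of
the transcriptome.  Per gene, a classical pooled-variance two-sample
t-statistic (R+ minus R-) is computed over genes passing a presence filter
(detected in at least ``min_fraction`` of samples, default 60%); per
(miRNA, algorithm), a two-sided two-sample Kolmogorov-Smirnov test compares
the t-value distribution of the retained target genes against that of the
retained non-targets.  P-values are BH-adjusted within each
(algorithm, dataset) family; adjusted p strictly below 0.05 is significant.

Presence calls from negative-control probes are not reproducible without
probe-level data, so the default presence rule is a synthetic stand-in: a
value counts as "present" when it exceeds the dataset-wide expression
quantile (default 0.25).  Externally computed 0/1 presence calls can be
supplied instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import distributions

from .dataset_io import ExpressionDataset, OutcomeLabels, RELAPSE_POS, RELAPSE_NEG
from .dataset_io import TargetPredictionTable
from .de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceRule",
    "GeneTStats",
    "KSRecord",
    "presence_filter",
    "gene_t_statistics",
    "ks_two_sample",
    "ks_target_enrichment",
    "write_ks_table",
]


@dataclass(frozen=True)
class PresenceRule:
    """How to call a gene 'present' in a sample.

    ``quantile_threshold`` mode calls a value present when it exceeds the
    dataset-wide ``quantile`` of all expression values; ``external_calls``
    mode consumes a user-supplied 0/1 matrix (same shape as the dataset).
    A gene is retained when present in at least ``min_fraction`` of samples.
    """

    mode: str = "quantile_threshold"
    quantile: float = 0.25
    min_fraction: float = 0.6
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("quantile_threshold", "external_calls"):
            raise ValueError(f"unknown presence mode {self.mode!r}")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"quantile ({self.quantile}) must lie in (0, 1)")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError(f"min_fraction ({self.min_fraction}) must lie in (0, 1]")


@dataclass(frozen=True)
class GeneTStats:
    """Per-gene pooled-variance two-sample t (R+ minus R-) on retained genes."""

    t: Mapping[str, float]
    retained: frozenset[str]

    def values_for(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self.t[g] for g in genes if g in self.t])


@dataclass(frozen=True)
class KSRecord:
    """One (miRNA, algorithm, dataset) KS comparison of target vs non-target t."""

    mirna: str
    algorithm: str
    dataset: str
    n_targets: int
    n_background: int
    D: float
    p_nominal: float
    p_adjusted: float
    significant: bool
    skipped: bool = False

    def __post_init__(self) -> None:
        if not self.skipped and not 0.0 <= self.D <= 1.0:
            raise ValueError("KS statistic D must lie in [0, 1]")


def presence_filter(dataset: ExpressionDataset, rule: PresenceRule) -> frozenset[str]:
    """Genes called present in at least ``rule.min_fraction`` of samples."""
    if rule.mode == "quantile_threshold":
        threshold = float(np.quantile(dataset.values, rule.quantile))
        present = dataset.values > threshold
    else:
        calls = rule.calls
        if calls is None:
            raise ValueError("external_calls mode requires a calls matrix")
        if calls.shape != dataset.frame.shape or not (
            list(calls.index) == list(dataset.gene_ids)
            and list(calls.columns) == list(dataset.sample_ids)
        ):
            raise ValueError(
                "presence-calls matrix does not match the dataset's genes/samples"
            )
        present = calls.to_numpy() > 0
    counts = present.sum(axis=1)
    # tolerance so 'exactly 60% of samples' passes despite float representation
    needed = rule.min_fraction * dataset.n_samples - 1e-9
    retained = frozenset(
        g for g, c in zip(dataset.gene_ids, counts) if c >= needed
    )
    if not retained:
        raise ValueError(
            "presence filter retained no genes; the dataset may be degenerate "
            "(constant values) or the rule too strict"
        )
    return retained


def gene_t_statistics(
    dataset: ExpressionDataset,
    labels: OutcomeLabels,
    retained: Iterable[str],
) -> GeneTStats:
    """Classical pooled-variance two-sample t for each retained gene.

    Genes with zero pooled variance have no finite t and are dropped with
    their ids logged.
    """
    pos = [s for s in dataset.sample_ids if labels.status.get(s) == RELAPSE_POS]
    neg = [s for s in dataset.sample_ids if labels.status.get(s) == RELAPSE_NEG]
    if len(pos) < 2:
        raise ValueError(f"relapse+ group has {len(pos)} samples; at least 2 required")
    if len(neg) < 2:
        raise ValueError(f"relapse- group has {len(neg)} samples; at least 2 required")
    retained = [g for g in dataset.gene_ids if g in frozenset(retained)]
    frame = dataset.frame.loc[retained]
    A = frame.loc[:, pos].to_numpy(dtype=float)
    B = frame.loc[:, neg].to_numpy(dtype=float)
    n1, n2 = A.shape[1], B.shape[1]
    var1 = A.var(axis=1, ddof=1)
    var2 = B.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    finite = np.isfinite(t)
    dropped = [g for g, ok in zip(retained, finite) if not ok]
    if dropped:
        logger.info("dropped %d zero-variance genes: %s", len(dropped), dropped[:5])
    stats_map = {g: float(v) for g, v, ok in zip(retained, t, finite) if ok}
    return GeneTStats(t=stats_map, retained=frozenset(stats_map))


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    ``D`` is the supremum over observed values of the absolute ECDF
    difference; the p-value uses the asymptotic KS distribution with
    effective size ``|x||y| / (|x| + |y|)``.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    if x.size == 0:
        raise ValueError("first sample is empty")
    if y.size == 0:
        raise ValueError("second sample is empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_eff = x.size * y.size / (x.size + y.size)
    p = float(distributions.kstwobign.sf(np.sqrt(n_eff) * d))
    return d, min(max(p, 0.0), 1.0)


def ks_target_enrichment(
    tstats: GeneTStats,
    predictions: TargetPredictionTable,
    expressed_mirnas: Iterable[str],
    dataset_id: str,
    min_targets: int = 10,
    alpha: float = 0.05,
) -> list[KSRecord]:
    """Per (expressed miRNA, algorithm): KS of target vs non-target t-values.

    A miRNA whose retained target overlap is below ``min_targets`` yields a
    record flagged ``skipped`` (p-values NaN) rather than being silently
    dropped; BH runs within each (algorithm, dataset) family over the
    non-skipped records, and significance uses adjusted p strictly below
    ``alpha``.
    """
    expressed = frozenset(expressed_mirnas)
    roster = set(predictions.mirnas())
    retained = tstats.retained
    records: list[KSRecord] = []
    for algorithm in predictions.algorithms:
        tested: list[tuple[str, int, int, float, float]] = []
        skipped: list[tuple[str, int, int]] = []
        for mirna in sorted(expressed & roster):
            target_set = predictions.get(algorithm, mirna)
            if not target_set:
                continue
            targets = sorted(target_set & retained)
            background = sorted(retained - target_set)
            if len(targets) < min_targets or not background:
                skipped.append((mirna, len(targets), len(background)))
                continue
            d, p = ks_two_sample(
                tstats.values_for(targets), tstats.values_for(background)
            )
            tested.append((mirna, len(targets), len(background), d, p))
        adjusted = bh_adjust(np.array([p for *_, p in tested])) if tested else []
        for (mirna, n_t, n_b, d, p), adj in zip(tested, adjusted):
            records.append(
                KSRecord(
                    mirna=mirna,
                    algorithm=algorithm,
                    dataset=dataset_id,
                    n_targets=n_t,
                    n_background=n_b,
                    D=d,
                    p_nominal=p,
                    p_adjusted=float(adj),
                    significant=bool(adj < alpha),
                )
            )
        for mirna, n_t, n_b in skipped:
            records.append(
                KSRecord(
                    mirna=mirna,
                    algorithm=algorithm,
                    dataset=dataset_id,
                    n_targets=n_t,
                    n_background=n_b,
                    D=float("nan"),
                    p_nominal=float("nan"),
                    p_adjusted=float("nan"),
                    significant=False,
                    skipped=True,
                )
            )
    records.sort(key=lambda r: (r.algorithm, r.mirna))
    return records


def write_ks_table(records: Sequence[KSRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "mirna\talgorithm\tdataset\tn_targets\tn_background\tD\t"
            "p_nominal\tp_adjusted\tsignificant\tskipped\n"
        )
        for r in records:
            fh.write(
                f"{r.mirna}\t{r.algorithm}\t{r.dataset}\t{r.n_targets}\t"
                f"{r.n_background}\t{r.D!r}\t{r.p_nominal!r}\t{r.p_adjusted!r}\t"
                f"{int(r.significant)}\t{int(r.skipped)}\n"
            )
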