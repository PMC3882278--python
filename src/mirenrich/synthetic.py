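"""Synthetic case-control expression studies with planted miRNA regulons.

The generator emulates the structure of the public breast-cancer cohorts the
pipeline is designed for: a normalized log-expression matrix over two outcome
groups (relapse within five years, R+, versus no relapse, R-), per-algorithm
miRNA target-prediction sets, and a list of miRNAs expressed in the tissue.

A subset of miRNAs is "planted": their target genes (the regulon) are shifted
by ``effect_size`` within-group standard deviations in the R+ group.  The
default sign convention is *down* in R+, mirroring miRNA repression — an
active miRNA pushes its targets' transcript levels down.  Each prediction
algorithm reports a random fraction (``algorithm_sensitivity``) of every true
regulon plus a proportion of false-positive genes, so that downstream
enrichment sees realistically overlapping, imperfect prediction sets.

Everything is deterministic given ``seed``.  Sub-streams for the expression
matrix, regulon assignment and each algorithm's predictions are derived from
fixed offsets of the seed, so e.g. changing ``n_algorithms`` never perturbs
the expression draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .dataset_io import (
    RELAPSE_POS,
    RELAPSE_NEG,
    ExpressionDataset,
    OutcomeLabels,
    TargetPredictionTable,
    read_expression_matrix,
    read_mirna_list,
    read_sample_labels,
    read_target_predictions,
    write_expression_matrix,
    write_mirna_list,
    write_sample_labels,
    write_target_predictions,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "generate_study",
    "generate_null_study",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic case-control study.

    ``effect_size`` is expressed in units of the within-group standard
    deviation ``noise_sd``; planted regulons are shifted by
    ``-effect_size * noise_sd`` in the R+ group when ``direction == "down"``
    (the default, mirroring repression by an active miRNA).
    """

    n_genes: int = 2000
    n_samples_pos: int = 30
    n_samples_neg: int = 30
    n_mirnas: int = 60
    n_planted: int = 5
    regulon_size: int = 40
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_algorithms: int = 3
    algorithm_sensitivity: float = 0.7
    algorithm_fp_rate: float = 0.1
    baseline_mean: float = 8.0
    seed: int = 0
    direction: str = "down"
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        def positive(name: str) -> None:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} ({getattr(self, name)}) must be positive")

        for name in (
            "n_genes",
            "n_samples_pos",
            "n_samples_neg",
            "n_mirnas",
            "regulon_size",
            "noise_sd",
        ):
            positive(name)
        if self.n_planted < 0:
            raise ValueError(f"n_planted ({self.n_planted}) must be >= 0")
        if self.effect_size < 0:
            raise ValueError(f"effect_size ({self.effect_size}) must be >= 0")
        if self.n_algorithms < 2:
            raise ValueError(f"n_algorithms ({self.n_algorithms}) must be >= 2")
        if self.n_planted > self.n_mirnas:
            raise ValueError(
                f"n_planted ({self.n_planted}) must not exceed n_mirnas "
                f"({self.n_mirnas})"
            )
        if self.regulon_size * self.n_planted > self.n_genes:
            raise ValueError(
                f"regulon_size x n_planted ({self.regulon_size * self.n_planted}) "
                f"must not exceed n_genes ({self.n_genes})"
            )
        if not 0 < self.algorithm_sensitivity <= 1:
            raise ValueError(
                f"algorithm_sensitivity ({self.algorithm_sensitivity}) must be "
                f"in (0, 1]"
            )
        if not 0 <= self.algorithm_fp_rate < 1:
            raise ValueError(
                f"algorithm_fp_rate ({self.algorithm_fp_rate}) must be in [0, 1)"
            )
        if self.seed < 0:
            raise ValueError(f"seed ({self.seed}) must be >= 0")
        if self.direction not in ("down", "up"):
            raise ValueError(f"direction ({self.direction!r}) must be 'down' or 'up'")


@dataclass(frozen=True)
class SyntheticStudy:
    """One generated study plus its ground truth.

    ``truth`` maps every miRNA to its true regulon (empty for unplanted
    miRNAs); ``expressed_mirnas`` defaults to the full miRNA roster.
    """

    expression: ExpressionDataset
    labels: OutcomeLabels
    predictions: TargetPredictionTable
    expressed_mirnas: frozenset[str]
    truth: Mapping[str, frozenset[str]]

    @property
    def planted_mirnas(self) -> frozenset[str]:
        return frozenset(m for m, genes in self.truth.items() if genes)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(1, n + 1)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:03d}" for i in range(1, n + 1)]


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one study from ``config``; fully deterministic given its seed.

    Non-target genes are i.i.d. Normal(baseline_mean, noise_sd) in both
    groups; planted-regulon genes have their mean shifted by
    ``effect_size * noise_sd`` in the R+ group only (sign per
    ``config.direction``).  Each algorithm reports
    ``round(sensitivity * |regulon|)`` true targets per planted miRNA plus
    ``round(fp_rate * that)`` random non-targets; unplanted miRNAs receive
    random sets of ``regulon_size`` genes.
    """
    cfg = config
    genes = _gene_ids(cfg.n_genes)
    mirnas = _mirna_ids(cfg.n_mirnas)
    sample_pos = [f"RP{i:03d}" for i in range(1, cfg.n_samples_pos + 1)]
    sample_neg = [f"RN{i:03d}" for i in range(1, cfg.n_samples_neg + 1)]
    algorithms = tuple(f"alg{i}" for i in range(1, cfg.n_algorithms + 1))

    # fixed-offset sub-streams: (seed, 0) matrix, (seed, 1) regulons,
    # (seed, 2, a) per algorithm — so n_algorithms never perturbs the matrix
    rng_expr = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
    rng_truth = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))

    planted_idx = sorted(
        rng_truth.choice(cfg.n_mirnas, size=cfg.n_planted, replace=False).tolist()
    )
    truth: dict[str, frozenset[str]] = {m: frozenset() for m in mirnas}
    regulons_idx: dict[str, np.ndarray] = {}
    if cfg.n_planted:
        if cfg.allow_overlap:
            for mi in planted_idx:
                regulons_idx[mirnas[mi]] = rng_truth.choice(
                    cfg.n_genes, size=cfg.regulon_size, replace=False
                )
        else:
            pool = rng_truth.choice(
                cfg.n_genes, size=cfg.regulon_size * cfg.n_planted, replace=False
            )
            for j, mi in enumerate(planted_idx):
                regulons_idx[mirnas[mi]] = pool[
                    j * cfg.regulon_size : (j + 1) * cfg.regulon_size
                ]
        for mirna, idx in regulons_idx.items():
            truth[mirna] = frozenset(genes[i] for i in idx)

    n_samples = cfg.n_samples_pos + cfg.n_samples_neg
    values = cfg.baseline_mean + cfg.noise_sd * rng_expr.standard_normal(
        (cfg.n_genes, n_samples)
    )
    shift = cfg.effect_size * cfg.noise_sd
    if cfg.direction == "down":
        shift = -shift
    for idx in regulons_idx.values():
        values[np.asarray(idx), : cfg.n_samples_pos] += shift

    frame = pd.DataFrame(values, index=genes, columns=sample_pos + sample_neg)
    expression = ExpressionDataset(frame)
    labels = OutcomeLabels(
        {**{s: RELAPSE_POS for s in sample_pos}, **{s: RELAPSE_NEG for s in sample_neg}}
    )

    all_genes = frozenset(genes)
    sets: dict[tuple[str, str], frozenset[str]] = {}
    for ai, algorithm in enumerate(algorithms):
        rng_alg = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2, ai)))
        for mirna in mirnas:
            regulon = truth[mirna]
            if regulon:
                true_sorted = sorted(regulon)
                n_true = int(round(cfg.algorithm_sensitivity * len(true_sorted)))
                reported = set(
                    rng_alg.choice(true_sorted, size=n_true, replace=False).tolist()
                )
                n_fp = int(round(cfg.algorithm_fp_rate * n_true))
                if n_fp:
                    non_targets = sorted(all_genes - regulon)
                    reported.update(
                        rng_alg.choice(non_targets, size=n_fp, replace=False).tolist()
                    )
            else:
                idx = rng_alg.choice(cfg.n_genes, size=cfg.regulon_size, replace=False)
                reported = {genes[i] for i in idx}
            sets[(algorithm, mirna)] = frozenset(reported)

    predictions = TargetPredictionTable(
        algorithms, sets, explicit_universe={a: all_genes for a in algorithms}
    )
    return SyntheticStudy(
        expression=expression,
        labels=labels,
        predictions=predictions,
        expressed_mirnas=frozenset(mirnas),
        truth=truth,
    )


def generate_null_study(config: SimulationConfig) -> SyntheticStudy:
    """A pure-null study: no planted miRNAs, zero effect size."""
    return generate_study(replace(config, n_planted=0, effect_size=0.0))


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Serialize a study into ``directory`` in the pipeline's file formats.

    Emits ``expression.tsv``, ``labels.tsv``, ``predictions.tsv``,
    ``expressed_mirnas.txt`` and ``truth.json``; :func:`read_study`
    round-trips the result exactly.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create study directory {directory}: {exc}") from exc
    paths = {
        "expression": write_expression_matrix(
            study.expression, directory / "expression.tsv"
        ),
        "labels": write_sample_labels(study.labels, directory / "labels.tsv"),
        "predictions": write_target_predictions(
            study.predictions, directory / "predictions.tsv"
        ),
        "expressed": write_mirna_list(
            study.expressed_mirnas, directory / "expressed_mirnas.txt"
        ),
    }
    truth_path = directory / "truth.json"
    truth_obj = {m: sorted(genes) for m, genes in sorted(study.truth.items())}
    truth_path.write_text(json.dumps(truth_obj, indent=0, sort_keys=True) + "\n")
    paths["truth"] = truth_path
    return paths


def read_study(directory: str | Path) -> SyntheticStudy:
    """Load a study written by :func:`write_study`.

    The predictions' explicit universe is reattached as the full expression
    gene roster — the convention the generator uses.
    """
    directory = Path(directory)
    expression = read_expression_matrix(directory / "expression.tsv")
    labels = read_sample_labels(directory / "labels.tsv")
    table = read_target_predictions(directory / "predictions.tsv")
    all_genes = frozenset(expression.gene_ids)
    predictions = TargetPredictionTable(
        table.algorithms,
        table.sets,
        explicit_universe={a: all_genes for a in table.algorithms},
    )
    expressed = read_mirna_list(directory / "expressed_mirnas.txt")
    truth_obj = json.loads((directory / "truth.json").read_text())
    truth = {m: frozenset(genes) for m, genes in truth_obj.items()}
    return SyntheticStudy(expression, labels, predictions, expressed, truth)
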