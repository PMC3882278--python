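"""Readers, writers and containers for the pipeline's tabular formats.

The pipeline consumes four kinds of input:

* a normalized, log-scale expression matrix (genes x samples, TSV);
* per-sample binary 5-year disease-free-survival labels (TSV, 1 = relapse
  within five years, 0 = no relapse);
* miRNA -> predicted-target gene sets from one or more prediction
  algorithms (long-form TSV or GMT);
* a plain-text list of miRNAs known to be expressed in the tissue.

Probe-level matrices can be collapsed to gene level with
:func:`collapse_probes`: when several probes map to the same gene, the probe
with the highest median expression across all samples wins.

All readers validate and *reject* malformed input (naming the offending line)
rather than silently repairing it; all writers emit files that their readers
round-trip exactly.  Identifiers are opaque strings; no assumption is made
about Entrez vs Ensembl namespaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RELAPSE_POS = "relapse_pos"
RELAPSE_NEG = "relapse_neg"

__all__ = [
    "RELAPSE_POS",
    "RELAPSE_NEG",
    "ParseError",
    "ExpressionDataset",
    "OutcomeLabels",
    "ProbeAnnotation",
    "TargetPredictionTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_labels",
    "write_sample_labels",
    "read_probe_annotation",
    "collapse_probes",
    "read_target_predictions",
    "write_target_predictions",
    "read_mirna_list",
    "write_mirna_list",
]


class ParseError(ValueError):
    """A file does not conform to its declared tabular format."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """A genes x samples matrix of normalized log-scale expression.

    Wraps a :class:`pandas.DataFrame` whose index holds gene (or probe)
    identifiers and whose columns hold sample identifiers.  Identifiers must
    be unique and every value finite; normalization itself is out of scope —
    this container holds its output.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if f.columns.has_duplicates:
            dup = f.columns[f.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup[:5]}")
        values = f.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.frame.loc[:, list(sample_ids)])


@dataclass(frozen=True)
class OutcomeLabels:
    """Sample -> 5-year disease-free-survival status (relapse_pos/relapse_neg)."""

    status: Mapping[str, str]

    def __post_init__(self) -> None:
        for sample, value in self.status.items():
            if value not in (RELAPSE_POS, RELAPSE_NEG):
                raise ValueError(
                    f"sample {sample!r} has unknown status {value!r}; "
                    f"expected {RELAPSE_POS!r} or {RELAPSE_NEG!r}"
                )

    @property
    def positives(self) -> tuple[str, ...]:
        return tuple(s for s, v in self.status.items() if v == RELAPSE_POS)

    @property
    def negatives(self) -> tuple[str, ...]:
        return tuple(s for s, v in self.status.items() if v == RELAPSE_NEG)

    def __len__(self) -> int:
        return len(self.status)


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe -> gene mapping; probes without an unambiguous gene carry None."""

    gene_for: Mapping[str, str | None]

    def mapped_probes(self) -> tuple[str, ...]:
        return tuple(p for p, g in self.gene_for.items() if g is not None)


@dataclass(frozen=True)
class TargetPredictionTable:
    """Per-algorithm miRNA -> predicted-target gene sets.

    ``explicit_universe`` optionally supplies each algorithm's prediction
    universe (e.g. the full platform gene roster); when absent, the universe
    of an algorithm is the union of its prediction sets.
    """

    algorithms: tuple[str, ...]
    sets: Mapping[tuple[str, str], frozenset[str]]
    explicit_universe: Mapping[str, frozenset[str]] | None = None

    def __post_init__(self) -> None:
        known = set(self.algorithms)
        for (algorithm, mirna), genes in self.sets.items():
            if algorithm not in known:
                raise ValueError(
                    f"prediction set for {mirna!r} references unknown algorithm "
                    f"{algorithm!r}"
                )
        if self.explicit_universe is not None:
            for (algorithm, mirna), genes in self.sets.items():
                universe = self.explicit_universe.get(algorithm)
                if universe is not None and not genes <= universe:
                    extra = sorted(genes - universe)
                    raise ValueError(
                        f"({algorithm}, {mirna}) predicts genes outside the "
                        f"declared universe: {extra[:5]}"
                    )

    def universe(self, algorithm: str) -> frozenset[str]:
        """The algorithm's prediction universe."""
        if algorithm not in self.algorithms:
            raise KeyError(f"unknown algorithm {algorithm!r}")
        if self.explicit_universe is not None and algorithm in self.explicit_universe:
            return self.explicit_universe[algorithm]
        union: set[str] = set()
        for (alg, _), genes in self.sets.items():
            if alg == algorithm:
                union |= genes
        return frozenset(union)

    def mirnas(self) -> tuple[str, ...]:
        """Sorted roster of all miRNA identifiers across algorithms."""
        return tuple(sorted({m for (_, m) in self.sets}))

    def mirnas_for(self, algorithm: str) -> tuple[str, ...]:
        return tuple(sorted({m for (a, m) in self.sets if a == algorithm}))

    def get(self, algorithm: str, mirna: str) -> frozenset[str]:
        return self.sets.get((algorithm, mirna), frozenset())


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionDataset:
    """Read a gene-by-sample TSV (header ``gene_id<TAB>s1<TAB>...``)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: header must name at least one sample")
    sample_ids = header[1:]
    n_fields = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != n_fields:
            raise ParseError(
                f"{path}: line {lineno}: expected {n_fields} fields, "
                f"got {len(parts)}"
            )
        gene = parts[0]
        if gene in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate gene id {gene!r}")
        seen.add(gene)
        try:
            values = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell: {exc}") from exc
        gene_ids.append(gene)
        rows.append(values)
    frame = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionDataset(frame)


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    dataset.frame.to_csv(path, sep="\t", index_label="gene_id")
    return path


# ---------------------------------------------------------------------------
# Outcome labels
# ---------------------------------------------------------------------------

_STATUS_TOKEN = {"1": RELAPSE_POS, "0": RELAPSE_NEG}


def read_sample_labels(path: str | Path) -> OutcomeLabels:
    """Read a two-column TSV ``sample_id<TAB>relapse_5yr`` with values 1/0."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty labels file")
    status: dict[str, str] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
        sample, token = parts
        if sample in status:
            raise ParseError(f"{path}: line {lineno}: duplicate sample id {sample!r}")
        if token not in _STATUS_TOKEN:
            raise ParseError(
                f"{path}: line {lineno}: unknown status token {token!r} (expected 1 or 0)"
            )
        status[sample] = _STATUS_TOKEN[token]
    return OutcomeLabels(status)


def write_sample_labels(labels: OutcomeLabels, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\trelapse_5yr\n")
        for sample, value in labels.status.items():
            fh.write(f"{sample}\t{1 if value == RELAPSE_POS else 0}\n")
    return path


# ---------------------------------------------------------------------------
# Probe annotation and collapse
# ---------------------------------------------------------------------------


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a two-column TSV ``probe_id<TAB>gene_id``.

    An empty, ``-`` or ``NA`` gene field marks an unmapped probe.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty annotation file")
    gene_for: dict[str, str | None] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 fields, got {len(parts)}")
        probe, gene = parts
        if probe in gene_for:
            raise ParseError(f"{path}: line {lineno}: duplicate probe id {probe!r}")
        gene_for[probe] = None if gene in ("", "-", "NA") else gene
    return ProbeAnnotation(gene_for)


def collapse_probes(
    dataset: ExpressionDataset, annotation: ProbeAnnotation
) -> ExpressionDataset:
    """Collapse a probe-level matrix to gene level.

    For each gene with several mapped probes, keep the row of the probe with
    the highest median expression across all samples; ties break on the
    lexicographically smallest probe id.  Unmapped probes are dropped.
    """
    medians = np.median(dataset.values, axis=1)
    best: dict[str, tuple[float, str]] = {}
    for i, probe in enumerate(dataset.gene_ids):
        gene = annotation.gene_for.get(probe)
        if gene is None:
            continue
        # key orders by (median desc, probe id asc): higher median wins,
        # lexicographically smaller probe id wins ties
        candidate = (-medians[i], probe)
        if gene not in best or candidate < best[gene]:
            best[gene] = candidate
    if not best:
        raise ValueError("probe collapse produced no genes: no probe maps to a gene")
    genes = sorted(best)
    probes = [best[g][1] for g in genes]
    frame = dataset.frame.loc[probes].copy()
    frame.index = pd.Index(genes)
    n_dropped = dataset.n_genes - len(
        [p for p in dataset.gene_ids if annotation.gene_for.get(p) is not None]
    )
    logger.info(
        "collapsed %d probes to %d genes (%d unmapped probes dropped)",
        dataset.n_genes,
        len(genes),
        n_dropped,
    )
    return ExpressionDataset(frame)


# ---------------------------------------------------------------------------
# Target predictions
# ---------------------------------------------------------------------------


def read_target_predictions(
    path: str | Path, format: str = "long_tsv"
) -> TargetPredictionTable:
    """Read miRNA target predictions.

    ``long_tsv``: header ``algorithm<TAB>mirna<TAB>gene``, one prediction per
    row (duplicates collapse).  ``gmt``: standard GMT lines whose set names
    are ``algorithm|mirna``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    sets: dict[tuple[str, str], set[str]] = {}
    algorithms: list[str] = []
    if format == "long_tsv":
        if not lines:
            raise ParseError(f"{path}: empty predictions file")
        for lineno, line in enumerate(lines[1:], start=2):
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected 3 fields, got {len(parts)}"
                )
            algorithm, mirna, gene = parts
            if algorithm not in algorithms:
                algorithms.append(algorithm)
            sets.setdefault((algorithm, mirna), set()).add(gene)
    elif format == "gmt":
        for lineno, line in enumerate(lines, start=1):
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs name, description "
                    f"and at least one gene"
                )
            name = parts[0]
            if name.count("|") != 1:
                raise ParseError(
                    f"{path}: line {lineno}: GMT set name {name!r} does not "
                    f"match 'algorithm|mirna'"
                )
            algorithm, mirna = name.split("|")
            if algorithm not in algorithms:
                algorithms.append(algorithm)
            sets.setdefault((algorithm, mirna), set()).update(parts[2:])
    else:
        raise ValueError(f"unknown predictions format {format!r}")
    frozen = {key: frozenset(genes) for key, genes in sets.items()}
    return TargetPredictionTable(tuple(algorithms), frozen)


def write_target_predictions(table: TargetPredictionTable, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("algorithm\tmirna\tgene\n")
        for (algorithm, mirna) in sorted(table.sets):
            for gene in sorted(table.sets[(algorithm, mirna)]):
                fh.write(f"{algorithm}\t{mirna}\t{gene}\n")
    return path


# ---------------------------------------------------------------------------
# Expressed-miRNA list
# ---------------------------------------------------------------------------


def read_mirna_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text miRNA list (one id per line, ``#`` comments allowed)."""
    path = Path(path)
    mirnas: set[str] = set()
    for line in path.read_text().splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        mirnas.add(stripped)
    if not mirnas:
        raise ParseError(
            f"{path}: no miRNA identifiers found; an empty expressed set makes "
            f"the analysis vacuous"
        )
    return frozenset(mirnas)


def write_mirna_list(mirnas: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for mirna in sorted(mirnas):
            fh.write(f"{mirna}\n")
    return path
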