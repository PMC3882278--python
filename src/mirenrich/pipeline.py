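"""End-to-end orchestration: DE -> calibrated enrichment -> KS arm -> consensus.

The pipeline runs, per dataset: optional probe collapse, Wilcoxon/BH
differential expression, the >= ``min_genes`` list-qualification rule,
Fisher target-set enrichment with permutation calibration on every
qualifying directional list, and (optionally) the KS verification arm.
miRNA candidates are then called by multi-algorithm consensus: a miRNA is a
candidate when it is in the expressed set and is flagged by at least
``min_algorithms`` distinct algorithms within one (dataset, direction) list
(the default ``list`` scope; ``dataset`` and ``global`` scopes pool supports
more broadly).

Results are summarized in an occurrence matrix (rows = datasets, columns =
miRNAs, cells ``x(a)`` with ``a`` supporting algorithms, ``-`` otherwise)
and a JSON run report that echoes every threshold and seed, so a run is
reproducible byte-for-byte from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset_io import (
    collapse_probes,
    read_expression_matrix,
    read_mirna_list,
    read_probe_annotation,
    read_sample_labels,
    read_target_predictions,
)
from .de import derive_de_lists, write_de_table
from .enrichment import (
    EnrichmentRecord,
    calibrate_null_threshold,
    enrich_gene_list,
    filter_by_calibration,
    write_enrichment_table,
)
from .reverse_ks import (
    KSRecord,
    PresenceRule,
    gene_t_statistics,
    ks_target_enrichment,
    presence_filter,
    write_ks_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateCall",
    "RunReport",
    "PipelineError",
    "consensus_candidates",
    "occurrence_table",
    "run_pipeline",
]

NOT_PREDICTED = "-"


class PipelineError(RuntimeError):
    """The pipeline cannot proceed (e.g. no qualifying gene list)."""


@dataclass(frozen=True)
class CandidateCall:
    """A miRNA's consensus status under one approach (fisher or ks).

    ``supports`` maps (dataset, direction) — direction is ``""`` for the
    KS arm, which has no directional lists — to the set of algorithms that
    flagged the miRNA there.
    """

    mirna: str
    approach: str
    supports: Mapping[tuple[str, str], frozenset[str]]
    consensus: bool
    min_algorithms: int

    def support_count(self, dataset: str) -> int:
        """Max number of supporting algorithms over directions in a dataset."""
        return max(
            (len(a) for (d, _), a in self.supports.items() if d == dataset),
            default=0,
        )


@dataclass(frozen=True)
class RunReport:
    """The JSON-serializable manifest of one pipeline run."""

    data: Mapping

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True) + "\n"


def _normalize_records(
    records: Iterable[EnrichmentRecord | KSRecord],
) -> list[tuple[str, str, str, str, bool]]:
    """-> (mirna, dataset, direction, algorithm, flagged) tuples."""
    out = []
    for r in records:
        if isinstance(r, EnrichmentRecord):
            if r.passes_calibration is None:
                raise ValueError(
                    f"enrichment record ({r.mirna}, {r.algorithm}) has no "
                    f"calibration verdict; run filter_by_calibration first"
                )
            out.append(
                (r.mirna, r.list_id[0], r.list_id[1], r.algorithm,
                 bool(r.passes_calibration))
            )
        elif isinstance(r, KSRecord):
            out.append(
                (r.mirna, r.dataset, "", r.algorithm,
                 bool(r.significant and not r.skipped))
            )
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
    return out


def consensus_candidates(
    records: Sequence[EnrichmentRecord | KSRecord],
    expressed_mirnas: Iterable[str],
    min_algorithms: int = 2,
    scope: str = "list",
    approach: str | None = None,
    algorithm_roster: Iterable[str] | None = None,
) -> list[CandidateCall]:
    """Call candidate miRNAs by multi-algorithm consensus.

    A miRNA is a candidate iff it belongs to the expressed set and, within
    the chosen scope (one (dataset, direction) list by default), it is
    flagged by at least ``min_algorithms`` distinct algorithms.
    """
    if scope not in ("list", "dataset", "global"):
        raise ValueError(f"unknown consensus scope {scope!r}")
    normalized = _normalize_records(records)
    if approach is None:
        approach = (
            "ks"
            if records and isinstance(records[0], KSRecord)
            else "fisher"
        )
    expressed = frozenset(expressed_mirnas)
    if algorithm_roster is not None:
        roster = frozenset(algorithm_roster)
        unknown = {a for _, _, _, a, _ in normalized if a not in roster}
        if unknown:
            raise ValueError(
                f"records reference algorithms outside the roster: "
                f"{sorted(unknown)}"
            )
    supports: dict[str, dict[tuple[str, str], set[str]]] = {}
    for mirna, dataset, direction, algorithm, flagged in normalized:
        per = supports.setdefault(mirna, {})
        algs = per.setdefault((dataset, direction), set())
        if flagged:
            algs.add(algorithm)
    calls: list[CandidateCall] = []
    for mirna in sorted(supports):
        per = {
            key: frozenset(algs) for key, algs in supports[mirna].items() if algs
        }
        if scope == "list":
            reached = any(len(algs) >= min_algorithms for algs in per.values())
        elif scope == "dataset":
            by_ds: dict[str, set[str]] = {}
            for (dataset, _), algs in per.items():
                by_ds.setdefault(dataset, set()).update(algs)
            reached = any(len(algs) >= min_algorithms for algs in by_ds.values())
        else:
            union: set[str] = set()
            for algs in per.values():
                union.update(algs)
            reached = len(union) >= min_algorithms
        calls.append(
            CandidateCall(
                mirna=mirna,
                approach=approach,
                supports=per,
                consensus=bool(reached and mirna in expressed),
                min_algorithms=min_algorithms,
            )
        )
    return calls


def occurrence_table(
    calls: Sequence[CandidateCall],
    datasets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Occurrence matrix: rows = datasets, columns = miRNAs, cells x(a)/-.

    ``a`` is the number of supporting algorithms for that (dataset, miRNA),
    maximized over directions; miRNAs with no support anywhere are omitted.
    """
    mirnas = sorted(
        {c.mirna for c in calls if any(c.supports.values())}
    )
    if datasets is None:
        datasets = sorted({d for c in calls for (d, _) in c.supports})
    by_mirna = {c.mirna: c for c in calls}
    rows = {}
    for dataset in datasets:
        cells = []
        for mirna in mirnas:
            call = by_mirna.get(mirna)
            a = call.support_count(dataset) if call else 0
            cells.append(f"x({a})" if a else NOT_PREDICTED)
        rows[dataset] = cells
    return pd.DataFrame.from_dict(rows, orient="index", columns=mirnas)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "seed": 0,
    "alpha": 0.05,
    "min_genes": 30,
    "min_algorithms": 2,
    "consensus_scope": "list",
    "n_perm": 1000,
    "null_quantile": 0.01,
    "run_ks": True,
    "targets_format": "long_tsv",
}

_KS_DEFAULTS = {
    "presence_quantile": 0.25,
    "presence_fraction": 0.6,
    "min_targets": 10,
    "alpha": 0.05,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sub_seed(base_seed: int, *offsets: int) -> int:
    """A stable 31-bit sub-seed for one calibration stream."""
    state = np.random.SeedSequence((base_seed, *offsets)).generate_state(1)[0]
    return int(state % (2**31))


def load_config(path: str | Path) -> dict:
    """Load and normalize a pipeline TOML config; paths resolve relative to it."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    cfg = {**_DEFAULTS, **{k: v for k, v in raw.items() if k not in ("datasets", "ks")}}
    cfg["ks"] = {**_KS_DEFAULTS, **raw.get("ks", {})}
    datasets = raw.get("datasets", [])
    if not datasets:
        raise PipelineError(f"{path}: config lists no datasets")
    base = path.parent
    for required in ("targets", "expressed"):
        if required not in cfg:
            raise PipelineError(f"{path}: config is missing {required!r}")
    cfg["targets"] = str(base / cfg["targets"])
    cfg["expressed"] = str(base / cfg["expressed"])
    cfg["datasets"] = []
    for entry in datasets:
        ds = dict(entry)
        for key in ("expression", "labels", "annotation"):
            if key in ds:
                ds[key] = str(base / ds[key])
        if "id" not in ds or "expression" not in ds or "labels" not in ds:
            raise PipelineError(
                f"{path}: each dataset needs 'id', 'expression' and 'labels'"
            )
        cfg["datasets"].append(ds)
    return cfg


def run_pipeline(config: str | Path | Mapping, out_dir: str | Path) -> RunReport:
    """Run the full pipeline from a TOML config (or pre-loaded mapping).

    Writes all stage outputs plus ``report.json`` into ``out_dir`` and
    returns the report.  Re-running with the same config reproduces all
    outputs byte-identically.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = {**_DEFAULTS, **dict(config)}
        cfg["ks"] = {**_KS_DEFAULTS, **cfg.get("ks", {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(cfg["seed"])
    predictions = read_target_predictions(cfg["targets"], cfg["targets_format"])
    expressed = read_mirna_list(cfg["expressed"])

    inputs_digest = {
        Path(cfg["targets"]).name: _sha256(Path(cfg["targets"])),
        Path(cfg["expressed"]).name: _sha256(Path(cfg["expressed"])),
    }

    dataset_summaries: dict[str, dict] = {}
    calibration_report: dict[str, dict] = {}
    fisher_records: list[EnrichmentRecord] = []
    ks_records: list[KSRecord] = []
    n_qualifying = 0

    for di, entry in enumerate(cfg["datasets"]):
        ds_id = entry["id"]
        expression = read_expression_matrix(entry["expression"])
        labels = read_sample_labels(entry["labels"])
        inputs_digest[Path(entry["expression"]).name] = _sha256(
            Path(entry["expression"])
        )
        inputs_digest[Path(entry["labels"]).name] = _sha256(Path(entry["labels"]))
        if "annotation" in entry:
            annotation = read_probe_annotation(entry["annotation"])
            inputs_digest[Path(entry["annotation"]).name] = _sha256(
                Path(entry["annotation"])
            )
            expression = collapse_probes(expression, annotation)

        lists = derive_de_lists(
            expression, labels, alpha=cfg["alpha"], min_genes=cfg["min_genes"]
        )
        write_de_table(lists, out_dir / f"de_{ds_id}.tsv")
        for direction, genes in (("up", lists.up), ("down", lists.down)):
            (out_dir / f"{ds_id}.{direction}.txt").write_text(
                "".join(f"{g}\n" for g in genes)
            )
        summary = {
            "n_genes": expression.n_genes,
            "n_samples_pos": len(
                [s for s in expression.sample_ids if labels.status.get(s) == "relapse_pos"]
            ),
            "n_samples_neg": len(
                [s for s in expression.sample_ids if labels.status.get(s) == "relapse_neg"]
            ),
            "n_up": len(lists.up),
            "n_down": len(lists.down),
            "qualifies_up": lists.qualifies_up,
            "qualifies_down": lists.qualifies_down,
        }
        dataset_summaries[ds_id] = summary

        universe = frozenset(expression.gene_ids)
        for li, (direction, genes, qualifies) in enumerate(
            (
                ("up", lists.up, lists.qualifies_up),
                ("down", lists.down, lists.qualifies_down),
            )
        ):
            if not qualifies:
                continue
            n_qualifying += 1
            list_id = (ds_id, direction)
            records = enrich_gene_list(
                genes, predictions, universe, expressed, list_id
            )
            calibrations = calibrate_null_threshold(
                genes,
                predictions,
                universe,
                expressed,
                n_perm=int(cfg["n_perm"]),
                null_quantile=float(cfg["null_quantile"]),
                seed=_sub_seed(seed, di, li),
                list_id=list_id,
            )
            records = filter_by_calibration(records, calibrations)
            fisher_records.extend(records)
            calibration_report.setdefault(ds_id, {})[direction] = {
                alg: {
                    "threshold_nominal": cal.threshold_nominal,
                    "threshold_adjusted": cal.threshold_adjusted,
                    "max_retained_nominal": cal.max_retained_nominal,
                    "n_permutations": cal.n_permutations,
                    "null_quantile": cal.null_quantile,
                    "seed": cal.seed,
                }
                for alg, cal in sorted(calibrations.items())
            }

        if cfg["run_ks"]:
            ks_cfg = cfg["ks"]
            rule = PresenceRule(
                mode="quantile_threshold",
                quantile=float(ks_cfg["presence_quantile"]),
                min_fraction=float(ks_cfg["presence_fraction"]),
            )
            retained = presence_filter(expression, rule)
            tstats = gene_t_statistics(expression, labels, retained)
            ds_ks = ks_target_enrichment(
                tstats,
                predictions,
                expressed,
                ds_id,
                min_targets=int(ks_cfg["min_targets"]),
                alpha=float(ks_cfg["alpha"]),
            )
            ks_records.extend(ds_ks)
            summary["ks_n_retained"] = len(tstats.retained)

    if n_qualifying == 0:
        raise PipelineError(
            f"no directional gene list qualified: every list has fewer than "
            f"min_genes = {cfg['min_genes']} differentially expressed genes"
        )

    write_enrichment_table(fisher_records, out_dir / "enrichment.tsv")
    (out_dir / "calibration.json").write_text(
        json.dumps(calibration_report, indent=2, sort_keys=True) + "\n"
    )
    fisher_calls = consensus_candidates(
        fisher_records,
        expressed,
        min_algorithms=int(cfg["min_algorithms"]),
        scope=cfg["consensus_scope"],
        approach="fisher",
        algorithm_roster=predictions.algorithms,
    )
    dataset_ids = [d["id"] for d in cfg["datasets"]]
    fisher_occurrence = occurrence_table(fisher_calls, datasets=dataset_ids)
    fisher_occurrence.to_csv(out_dir / "occurrence_fisher.tsv", sep="\t")

    ks_calls: list[CandidateCall] = []
    if cfg["run_ks"]:
        write_ks_table(ks_records, out_dir / "ks.tsv")
        if ks_records:
            ks_calls = consensus_candidates(
                ks_records,
                expressed,
                min_algorithms=int(cfg["min_algorithms"]),
                scope=cfg["consensus_scope"],
                approach="ks",
                algorithm_roster=predictions.algorithms,
            )
            occurrence_table(ks_calls, datasets=dataset_ids).to_csv(
                out_dir / "occurrence_ks.tsv", sep="\t"
            )

    def _call_obj(call: CandidateCall) -> dict:
        return {
            "mirna": call.mirna,
            "consensus": call.consensus,
            "supports": {
                f"{d}:{direction}" if direction else d: sorted(algs)
                for (d, direction), algs in sorted(call.supports.items())
            },
        }

    config_echo = {
        k: (Path(v).name if k in ("targets", "expressed") else v)
        for k, v in cfg.items()
        if k != "datasets"
    }
    config_echo["datasets"] = [
        {
            k: (Path(v).name if k in ("expression", "labels", "annotation") else v)
            for k, v in entry.items()
        }
        for entry in cfg["datasets"]
    ]

    report = RunReport(
        {
            "config": config_echo,
            "inputs_sha256": inputs_digest,
            "datasets": dataset_summaries,
            "calibration": calibration_report,
            "candidates": {
                "fisher": [_call_obj(c) for c in fisher_calls if c.consensus],
                "ks": [_call_obj(c) for c in ks_calls if c.consensus],
            },
            "occurrence": {
                "fisher": {
                    ds: dict(zip(fisher_occurrence.columns, row))
                    for ds, row in fisher_occurrence.iterrows()
                },
                "ks": (
                    {
                        ds: {
                            c.mirna: f"x({c.support_count(ds)})"
                            for c in ks_calls
                            if c.support_count(ds)
                        }
                        for ds in dataset_ids
                    }
                    if ks_calls
                    else {}
                ),
            },
            "versions": {
                "mirenrich": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
    )
    (out_dir / "report.json").write_text(report.to_json())
    return report
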