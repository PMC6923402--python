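"""Readers and writers for the tool's tabular formats.

Formats are deliberately plain:

* typed edge list, TSV ``source<TAB>target<TAB>edge_type`` or SIF
  ``source<TAB>edge_type<TAB>target``, edge_type in
  {TF_gene, TF_miRNA, miRNA_gene};
* expression table, TSV with header ``id  lfc  padj`` ('.' decimal separator;
  lfc may be empty for miRNAs);
* annotation lists, one identifier per line, ``#`` comments allowed;
* the ranked priority table, TSV mirroring the published score-table layout
  ``gene  D  hub  mds  mcds  score  LFC  layer  rank`` (absent LFC rendered
  as an em-dash).
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import TYPE_CHECKING, Union

import pandas as pd

from .model import (
    DiseaseAnnotation,
    EdgeType,
    ExpressionRecord,
    ExpressionTable,
    InteractionCatalog,
    RegulatoryEdge,
    RegulatoryNetwork,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .prioritize import PriorityTable

__all__ = [
    "read_network",
    "read_catalog",
    "write_network",
    "read_expression_table",
    "write_expression_table",
    "read_annotation",
    "write_annotation",
    "write_priority_table",
    "ABSENT_LFC",
]

PathLike = Union[str, Path]

#: rendering of a missing log2 fold change in the ranked table
ABSENT_LFC = "—"

_EDGE_TYPES = {e.value for e in EdgeType}


def _parse_edge_rows(path: PathLike, dialect: str) -> list[RegulatoryEdge]:
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")
    edges: list[RegulatoryEdge] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            if len(cols) < 3:
                raise ValidationError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(cols)}")
            if dialect == "sif":
                source, etype, target = cols[0], cols[1], cols[2]
            else:
                source, target, etype = cols[0], cols[1], cols[2]
            if lineno == 1 and etype not in _EDGE_TYPES and {source.lower(), target.lower(), etype.lower()} & {
                "source", "target", "edge_type", "type", "interaction",
            }:
                continue  # tolerated header row
            if etype not in _EDGE_TYPES:
                raise ValidationError(
                    f"{path}:{lineno}: unknown edge type {etype!r} (expected one of {sorted(_EDGE_TYPES)})"
                )
            try:
                edges.append(RegulatoryEdge(source, target, EdgeType(etype)))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return edges


def read_network(path: PathLike, dialect: str = "tsv") -> RegulatoryNetwork:
    """Read a typed edge list into a validated network.

    Duplicate rows collapse to one edge; node kinds are inferred from edge
    types (with the mir/let naming convention breaking gene-vs-miRNA ties).
    Contradictory kind evidence raises :class:`ValidationError`.
    """
    return RegulatoryNetwork(_parse_edge_rows(path, dialect))


def read_catalog(path: PathLike, dialect: str = "tsv") -> InteractionCatalog:
    """Read a background interaction catalog (must be non-empty)."""
    return InteractionCatalog(_parse_edge_rows(path, dialect))


def write_network(network: RegulatoryNetwork, path: PathLike, dialect: str = "tsv") -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for e in network.edges():
            if dialect == "sif":
                fh.write(f"{e.source}\t{e.edge_type.value}\t{e.target}\n")
            else:
                fh.write(f"{e.source}\t{e.target}\t{e.edge_type.value}\n")


def read_expression_table(path: PathLike) -> ExpressionTable:
    """Read a TSV of per-gene log2 fold changes and adjusted p-values.

    Header must name ``id``, ``lfc`` and ``padj`` columns.  Empty lfc cells
    are stored as absent; duplicate ids and non-numeric padj are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "lfc", "padj"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: expression table header must contain {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        node = row.id.strip()
        lfc_raw = row.lfc.strip()
        try:
            lfc = float(lfc_raw) if lfc_raw and lfc_raw != ABSENT_LFC else None
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric lfc {lfc_raw!r} for {node!r}") from exc
        try:
            padj = float(row.padj)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric padj {row.padj!r} for {node!r}") from exc
        records.append(ExpressionRecord(node, lfc, padj))
    return ExpressionTable.from_records(records)


def write_expression_table(table: ExpressionTable, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "lfc", "padj"])
        for node in sorted(table.records):
            rec = table.records[node]
            lfc = "" if rec.lfc is None else repr(rec.lfc)
            writer.writerow([node, lfc, repr(rec.padj)])


def read_annotation(path: PathLike, disease_name: str) -> DiseaseAnnotation:
    """Read a one-id-per-line disease annotation list (DisGeNET/HMDD export
    style).  Blank lines and ``#`` comments are skipped; duplicates collapse."""
    members = set()
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return DiseaseAnnotation(disease_name, frozenset(members))


def write_annotation(annotation: DiseaseAnnotation, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {annotation.disease_name}\n")
        for node in sorted(annotation.members):
            fh.write(node + "\n")


def write_priority_table(table: "PriorityTable", path: PathLike) -> None:
    """Write the ranked candidate table as TSV.

    Column order mirrors the published score tables; LFC is formatted with
    an em-dash for nodes lacking expression data (miRNAs).
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "D", "hub", "mds", "mcds", "score", "LFC", "layer", "rank"])
        for row in table.rows:
            lfc = ABSENT_LFC if row.lfc is None else _fmt_lfc(row.lfc)
            writer.writerow(
                [row.node, row.degree, row.hub_flag, row.mds_flag, row.mcds_flag,
                 row.score, lfc, row.layer, row.rank]
            )


def _fmt_lfc(value: float) -> str:
    if math.isfinite(value) and value == int(value):
        return str(int(value))
    return f"{value:g}"
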