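"""Differential co-regulatory network construction.

Given a background catalog of validated regulations and a differential-
expression table, this module (1) restricts to significantly differentially
expressed (DE) genes, (2) selects the miRNAs whose interaction partners are
over-represented among the DE genes (hypergeometric test, BH-adjusted,
cutoff 0.001), and (3) assembles the differential network from the catalog
edges whose endpoints survive both filters — the "complete network" of the
co-regulatory layer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from .evaluate import bh_adjust, hypergeom_upper_tail
from .model import (
    DiseaseAnnotation,
    EdgeType,
    ExpressionTable,
    InteractionCatalog,
    NodeKind,
    RegulatoryNetwork,
)

__all__ = [
    "DEGeneSet",
    "MiRNAEnrichmentResult",
    "filter_de_genes",
    "enrich_mirnas",
    "build_differential_network",
    "write_enrichment_results",
]


@dataclass(frozen=True)
class DEGeneSet:
    """Genes/TFs with adjusted p-value strictly below ``alpha``."""

    members: frozenset[str]
    alpha: float

    def __contains__(self, node: str) -> bool:
        return node in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MiRNAEnrichmentResult:
    """Over-representation of one miRNA's partner set among the DE genes."""

    mirna: str
    overlap_k: int
    partner_set_size: int
    raw_p: float
    adj_p: float
    selected: bool


def filter_de_genes(table: ExpressionTable, alpha: float = 0.05) -> DEGeneSet:
    """Select nodes with padj strictly below ``alpha`` (DE genes)."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    members = frozenset(n for n, rec in table.records.items() if rec.padj < alpha)
    return DEGeneSet(members, alpha)


def _partners(catalog: InteractionCatalog, mirna: str) -> set[str]:
    """Gene targets (miRNA_gene out-edges) union TF regulators (TF_miRNA
    in-edges) of a miRNA."""
    g = catalog.graph
    targets = {v for _, v, k in g.out_edges(mirna, keys=True) if k == EdgeType.MIRNA_GENE.value}
    regulators = {u for u, _, k in g.in_edges(mirna, keys=True) if k == EdgeType.TF_MIRNA.value}
    return targets | regulators


def enrich_mirnas(
    catalog: InteractionCatalog,
    de: DEGeneSet,
    cutoff: float = 0.001,
    mode: str = "union",
) -> list[MiRNAEnrichmentResult]:
    """Test each catalog miRNA for over-representation of its partners among
    the DE genes.

    For miRNA *m* let P(m) be the union of its gene targets and its TF
    regulators.  With universe U = all gene/TF nodes of the catalog, the raw
    p-value is the inclusive upper tail P(X >= |P(m) ∩ DE|) of the
    hypergeometric distribution with population |U|, |DE ∩ U| successes and
    |P(m)| draws.  P-values are BH-adjusted across all tested miRNAs and a
    miRNA is selected when its adjusted p falls below ``cutoff``.

    ``mode="separate"`` instead tests targets and regulators in two separate
    hypergeometric tests (BH-adjusted jointly) and requires both to pass.
    Results are sorted by adjusted p ascending, then miRNA id.
    """
    if mode not in ("union", "separate"):
        raise ValueError(f"mode must be 'union' or 'separate', got {mode!r}")
    universe = catalog.universe()
    mirnas = sorted(catalog.mirnas())
    if not mirnas:
        raise ValueError("catalog contains no miRNA-incident edges")
    de_in_universe = de.members & universe

    if mode == "union":
        partner_sets = {m: [_partners(catalog, m)] for m in mirnas}
    else:
        g = catalog.graph
        partner_sets = {
            m: [
                {v for _, v, k in g.out_edges(m, keys=True) if k == EdgeType.MIRNA_GENE.value},
                {u for u, _, k in g.in_edges(m, keys=True) if k == EdgeType.TF_MIRNA.value},
            ]
            for m in mirnas
        }

    raw: list[float] = []
    meta: list[tuple[str, int, int]] = []  # (mirna, overlap, partners) per test
    for m in mirnas:
        for pset in partner_sets[m]:
            pset &= universe
            k = len(pset & de_in_universe)
            raw.append(hypergeom_upper_tail(k, len(universe), len(de_in_universe), len(pset)))
            meta.append((m, k, len(pset)))
    adj = bh_adjust(raw)

    results: list[MiRNAEnrichmentResult] = []
    i = 0
    for m in mirnas:
        n_tests = len(partner_sets[m])
        chunk = list(range(i, i + n_tests))
        i += n_tests
        selected = all(adj[j] < cutoff for j in chunk)
        # report the union-set bookkeeping; for separate mode the displayed
        # p-values are the worse (max) of the two tests
        overlap = sum(meta[j][1] for j in chunk) if n_tests == 1 else len(
            set.union(*partner_sets[m]) & de_in_universe
        )
        partners = meta[chunk[0]][2] if n_tests == 1 else len(set.union(*partner_sets[m]) & universe)
        results.append(
            MiRNAEnrichmentResult(
                mirna=m,
                overlap_k=overlap,
                partner_set_size=partners,
                raw_p=max(raw[j] for j in chunk),
                adj_p=max(adj[j] for j in chunk),
                selected=selected,
            )
        )
    results.sort(key=lambda r: (r.adj_p, r.mirna))
    return results


def build_differential_network(
    catalog: InteractionCatalog,
    de: DEGeneSet,
    selected_mirnas: Iterable[str],
) -> RegulatoryNetwork:
    """Assemble the differential co-regulatory network.

    A catalog edge is retained when every gene/TF endpoint is DE and every
    miRNA endpoint is among the selected miRNAs.  Nodes are exactly the
    endpoints of retained edges — isolated nodes are dropped.
    """
    selected = set(selected_mirnas)
    unknown = selected - catalog.mirnas()
    if unknown:
        raise ValueError(f"selected miRNAs not in catalog: {sorted(unknown)}")

    def endpoint_ok(node: str) -> bool:
        if catalog.kind(node) is NodeKind.MIRNA:
            return node in selected
        return node in de

    retained = [e for e in catalog.edges() if endpoint_ok(e.source) and endpoint_ok(e.target)]
    return RegulatoryNetwork(retained)


def write_enrichment_results(
    results: Iterable[MiRNAEnrichmentResult],
    path: Union[str, Path],
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["mirna", "partners", "overlap", "raw_p", "adj_p", "selected"])
        for r in results:
            writer.writerow(
                [r.mirna, r.partner_set_size, r.overlap_k, f"{r.raw_p:.6g}", f"{r.adj_p:.6g}", int(r.selected)]
            )
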