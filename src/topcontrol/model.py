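"""Domain types for TF–miRNA co-regulatory networks.

The central object is :class:`RegulatoryNetwork`, a typed directed graph whose
nodes are transcription factors (TFs), protein-coding genes, or miRNAs, and
whose edges carry one of three regulation types: ``TF_gene``, ``TF_miRNA`` or
``miRNA_gene``.  Node kind is a per-network property derived solely from the
edges supplied — there is no external oracle of which symbols are TFs.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "NodeKind",
    "EdgeType",
    "RegulatoryEdge",
    "RegulatoryNetwork",
    "ExpressionRecord",
    "ExpressionTable",
    "InteractionCatalog",
    "DiseaseAnnotation",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class NodeKind(str, enum.Enum):
    TF = "TF"
    GENE = "gene"
    MIRNA = "miRNA"


class EdgeType(str, enum.Enum):
    TF_GENE = "TF_gene"
    TF_MIRNA = "TF_miRNA"
    MIRNA_GENE = "miRNA_gene"

    @property
    def source_kind(self) -> NodeKind:
        return NodeKind.TF if self in (EdgeType.TF_GENE, EdgeType.TF_MIRNA) else NodeKind.MIRNA

    @property
    def target_kind(self) -> NodeKind:
        return NodeKind.MIRNA if self is EdgeType.TF_MIRNA else NodeKind.GENE


#: miRNA name convention (hsa-mir-21, hsa-let-7b, ...) used only to break a
#: gene-vs-miRNA evidence tie during kind inference.
_MIRNA_NAME = re.compile(r"(^|-)(mir|let)(-|\d|$)", re.IGNORECASE)


def looks_like_mirna(name: str) -> bool:
    return bool(_MIRNA_NAME.search(name))


@dataclass(frozen=True, order=True)
class RegulatoryEdge:
    """One experimentally validated regulation: ``source --edge_type--> target``."""

    source: str
    target: str
    edge_type: EdgeType

    def __post_init__(self) -> None:
        for endpoint in (self.source, self.target):
            if not endpoint or endpoint != endpoint.strip() or any(c.isspace() for c in endpoint):
                raise ValidationError(f"invalid node identifier {endpoint!r}")


def infer_kinds(edges: Iterable[RegulatoryEdge]) -> dict[str, NodeKind]:
    """Derive each node's kind from the typed edges it participates in.

    A node sourcing a TF_gene/TF_miRNA edge is a TF; a node sourcing a
    miRNA_gene edge or targeted by a TF_miRNA edge is a miRNA; a node targeted
    by a TF_gene or miRNA_gene edge is (at least) a gene.  TF evidence
    dominates gene evidence (TFs are themselves regulated genes).  A node with
    both TF and miRNA evidence is contradictory.  A gene-vs-miRNA conflict is
    resolved by the miRNA naming convention; otherwise it is an error.
    """
    tf_ev: set[str] = set()
    mirna_ev: set[str] = set()
    gene_ev: set[str] = set()
    for e in edges:
        if e.edge_type in (EdgeType.TF_GENE, EdgeType.TF_MIRNA):
            tf_ev.add(e.source)
        else:
            mirna_ev.add(e.source)
        if e.edge_type is EdgeType.TF_MIRNA:
            mirna_ev.add(e.target)
        else:
            gene_ev.add(e.target)

    kinds: dict[str, NodeKind] = {}
    for node in tf_ev | mirna_ev | gene_ev:
        is_tf, is_mirna, is_gene = node in tf_ev, node in mirna_ev, node in gene_ev
        if is_tf and is_mirna:
            raise ValidationError(
                f"node {node!r} acts both as a TF (TF_* edge source) and as a "
                "miRNA (miRNA_gene source or TF_miRNA target)"
            )
        if is_tf:
            kinds[node] = NodeKind.TF
        elif is_mirna and is_gene:
            if looks_like_mirna(node):
                kinds[node] = NodeKind.MIRNA
            else:
                raise ValidationError(
                    f"node {node!r} has both miRNA and gene edge evidence and no "
                    "miRNA-style name to break the tie"
                )
        elif is_mirna:
            kinds[node] = NodeKind.MIRNA
        else:
            kinds[node] = NodeKind.GENE
    return kinds


class RegulatoryNetwork:
    """Typed directed graph of TFs, genes and miRNAs.

    Duplicate ``(source, target)`` pairs with different edge types are kept as
    distinct edges, but degree counts each interaction partner once.
    Self-loops are permitted; a node always dominates itself regardless.
    """

    def __init__(
        self,
        edges: Iterable[RegulatoryEdge] = (),
        kinds: Optional[dict[str, NodeKind]] = None,
    ) -> None:
        edges = sorted(set(edges))
        inferred = infer_kinds(edges)
        if kinds is not None:
            # edge-derived kinds are authoritative; declared kinds only add
            # isolated nodes (kind is a per-network property of the edges)
            merged = {n: k for n, k in kinds.items() if n not in inferred}
            merged.update(inferred)
            kinds = merged
        else:
            kinds = inferred

        self._g = nx.MultiDiGraph()
        for node in sorted(kinds):
            self._g.add_node(node, kind=kinds[node])
        for e in edges:
            self._g.add_edge(e.source, e.target, key=e.edge_type.value, edge_type=e.edge_type)

    # -- container protocol -------------------------------------------------
    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self.node_kinds() == other.node_kinds() and set(self.edges()) == set(other.edges())

    # -- views ---------------------------------------------------------------
    @property
    def graph(self) -> nx.MultiDiGraph:
        return self._g

    def nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def node_kinds(self) -> dict[str, NodeKind]:
        return {n: self._g.nodes[n]["kind"] for n in self._g.nodes}

    def kind(self, node: str) -> NodeKind:
        return self._g.nodes[node]["kind"]

    def nodes_of_kind(self, kind: NodeKind) -> set[str]:
        return {n for n, d in self._g.nodes(data=True) if d["kind"] is kind}

    def edges(self) -> Iterator[RegulatoryEdge]:
        for u, v, k in sorted(self._g.edges(keys=True)):
            yield RegulatoryEdge(u, v, EdgeType(k))

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def pair_digraph(self) -> nx.DiGraph:
        """Simple digraph over distinct (source, target) pairs.

        Degree and domination are defined on this graph: multi-type duplicate
        regulations contribute once.
        """
        return nx.DiGraph(self._g)

    def out_neighbors(self, node: str) -> set[str]:
        if node not in self._g:
            raise KeyError(f"unknown node {node!r}")
        return set(self._g.successors(node))

    def subnetwork(self, nodes: Iterable[str]) -> "RegulatoryNetwork":
        keep = set(nodes)
        edges = [e for e in self.edges() if e.source in keep and e.target in keep]
        kinds = {n: self.kind(n) for n in keep}
        return RegulatoryNetwork(edges, kinds=kinds)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-node differential-expression summary.

    ``lfc`` is the log2 fold change between the two conditions; it may be
    absent for miRNAs (expression is typically measured on the gene panel
    only).  ``padj`` is the multiple-testing-adjusted p-value.
    """

    node: str
    lfc: Optional[float]
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0):
            raise ValidationError(f"padj {self.padj} for {self.node!r} outside [0, 1]")


@dataclass
class ExpressionTable:
    records: dict[str, ExpressionRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[ExpressionRecord]) -> "ExpressionTable":
        table = cls()
        for rec in records:
            if rec.node in table.records:
                raise ValidationError(f"duplicate expression record for {rec.node!r}")
            table.records[rec.node] = rec
        return table

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, node: str) -> bool:
        return node in self.records

    def lfc(self, node: str) -> Optional[float]:
        rec = self.records.get(node)
        return rec.lfc if rec is not None else None

    def ids(self) -> set[str]:
        return set(self.records)


class InteractionCatalog(RegulatoryNetwork):
    """Background catalog of validated regulations (the universe before
    differential restriction).  The enrichment universe is its gene/TF node
    set."""

    def __init__(self, edges: Iterable[RegulatoryEdge], kinds=None) -> None:
        edges = list(edges)
        if not edges:
            raise ValidationError("interaction catalog must be non-empty")
        super().__init__(edges, kinds=kinds)

    def universe(self) -> set[str]:
        return self.nodes_of_kind(NodeKind.GENE) | self.nodes_of_kind(NodeKind.TF)

    def mirnas(self) -> set[str]:
        return self.nodes_of_kind(NodeKind.MIRNA)


@dataclass(frozen=True)
class DiseaseAnnotation:
    """A named set of disease-associated gene/miRNA identifiers (DisGeNET /
    HMDD style exports).  Membership is exact string match after trimming."""

    disease_name: str
    members: frozenset[str]

    def __contains__(self, node: str) -> bool:
        return node in self.members

    def __len__(self) -> int:
        return len(self.members)
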