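"""Composite scoring and ranking of candidate nodes.

Each node of the differential network receives one point for each topological
role it plays — hub, minimum-dominating-set member, minimum-connected-
dominating-set member — giving a score of 0–3.  The layered candidate model:

* layer 3 — every node of the differential network;
* layer 4 — nodes with score >= 1 (the union of the three role sets);
* layer 5 — nodes with the maximum score of 3 (selected by all criteria).

Within equal score, candidates are ordered by |log2 fold change| descending;
nodes without an LFC (miRNAs) follow the LFC-bearing nodes of their score
block; residual ties break by degree descending, then id.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .control import NodeSetResult, degrees
from .model import ExpressionTable, RegulatoryNetwork

__all__ = ["PriorityRow", "PriorityTable", "assign_scores", "rank_candidates", "layer_members"]


@dataclass(frozen=True)
class PriorityRow:
    node: str
    degree: int
    hub_flag: int
    mds_flag: int
    mcds_flag: int
    score: int
    lfc: Optional[float]
    layer: int
    rank: Optional[int] = None


@dataclass
class PriorityTable:
    rows: list[PriorityRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, node: str) -> PriorityRow:
        for r in self.rows:
            if r.node == node:
                return r
        raise KeyError(node)

    def is_ranked(self) -> bool:
        return bool(self.rows) and all(r.rank is not None for r in self.rows)


def _layer_of(score: int) -> int:
    if score == 3:
        return 5
    if score >= 1:
        return 4
    return 3


def assign_scores(
    network: RegulatoryNetwork,
    hub_set: NodeSetResult,
    mds: NodeSetResult,
    mcds: NodeSetResult,
    expr: ExpressionTable,
) -> PriorityTable:
    """Build one unranked row per network node from the three role sets.

    The score is the number of roles; the layer follows from the score.  LFC
    is looked up in the expression table and left absent where missing.
    """
    node_set = set(network.nodes())
    for result in (hub_set, mds, mcds):
        stray = set(result.members) - node_set
        if stray:
            raise ValueError(
                f"{result.method} members not in network: {sorted(stray)[:5]}"
            )
    deg = {r.node: r.degree for r in degrees(network)}
    rows = []
    for node in network.nodes():
        flags = (int(node in hub_set), int(node in mds), int(node in mcds))
        score = sum(flags)
        rows.append(
            PriorityRow(
                node=node,
                degree=deg[node],
                hub_flag=flags[0],
                mds_flag=flags[1],
                mcds_flag=flags[2],
                score=score,
                lfc=expr.lfc(node),
                layer=_layer_of(score),
            )
        )
    return PriorityTable(rows)


def _sort_key(row: PriorityRow):
    # score desc; LFC-bearing before absent; |LFC| desc; degree desc; id asc
    return (
        -row.score,
        row.lfc is None,
        -(abs(row.lfc) if row.lfc is not None else 0.0),
        -row.degree,
        row.node,
    )


def rank_candidates(table: PriorityTable) -> PriorityTable:
    """Apply the normative ordering and assign 1-based contiguous ranks."""
    ordered = sorted(table.rows, key=_sort_key)
    return PriorityTable([replace(r, rank=i) for i, r in enumerate(ordered, start=1)])


def layer_members(
    table: PriorityTable,
    layer: int,
    expr: Optional[ExpressionTable] = None,
    de_alpha: float = 0.05,
) -> set[str]:
    """Candidate ids of a given layer.

    Layers 1 and 2 live upstream of the network and require the expression
    table: layer 1 is every profiled id, layer 2 the significantly DE ids.
    Layer 3 is the whole network; layer 4 is score >= 1; layer 5 is score 3.
    """
    if not 1 <= layer <= 5:
        raise ValueError(f"layer must be in 1..5, got {layer}")
    if layer <= 2:
        if expr is None:
            raise ValueError("layers 1-2 require the expression table")
        if layer == 1:
            return expr.ids()
        return {n for n, rec in expr.records.items() if rec.padj < de_alpha}
    if layer == 3:
        return {r.node for r in table.rows}
    if layer == 4:
        return {r.node for r in table.rows if r.score >= 1}
    return {r.node for r in table.rows if r.score == 3}
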