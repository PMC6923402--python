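"""Topological controllability features of a regulatory network.

Three node sets proxy control over a directed regulatory network:

* **hubs** — the top 10% highest-degree nodes;
* **MDS** — a minimum dominating set: the fewest nodes such that every node
  either belongs to the set or is directly regulated (out-edge) by a member;
* **MCDS** — a minimum connected dominating set of the largest (weakly)
  connected component: a dominating set whose members additionally induce a
  connected subgraph of the underlying undirected graph (a "dominating
  pathway").

Domination is directed: a node covers itself and its out-neighbors, matching
the controllability reading that a regulator controls its targets.  Degree
and domination are computed over distinct (source, target) pairs, so a
regulation recorded with several edge types counts once.

Minimum dominating sets are found exactly with the integer linear program

    minimize   sum_v x_v
    subject to x_v + sum_{u in pred(v)} x_u >= 1   for every node v,
               x binary,

solved by HiGHS through :func:`scipy.optimize.milp`; a deterministic greedy
set-cover fallback handles networks above a configurable size.  MCDS uses a
grow-and-prune heuristic (exact minimum connected domination is not attempted;
validity — domination plus connectivity — is asserted on every run).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .model import RegulatoryNetwork

__all__ = [
    "DegreeRecord",
    "NodeSetResult",
    "degrees",
    "hubs",
    "dominated_by",
    "compute_mds",
    "largest_connected_component",
    "compute_mcds",
]

#: largest network the automatic mode still solves exactly
DEFAULT_EXACT_SIZE_LIMIT = 500


@dataclass(frozen=True)
class DegreeRecord:
    node: str
    degree: int  # in-degree + out-degree over distinct (source, target) pairs


@dataclass(frozen=True)
class NodeSetResult:
    """A hub/MDS/MCDS node set with provenance.

    ``domain`` records the node set over which domination was required (the
    full network for MDS, the largest connected component for MCDS).
    """

    members: frozenset[str]
    method: str       # "hub" | "MDS" | "MCDS"
    exactness: str    # "exact" | "heuristic"
    domain: frozenset[str]

    def __contains__(self, node: str) -> bool:
        return node in self.members

    def __len__(self) -> int:
        return len(self.members)


def degrees(network: RegulatoryNetwork) -> list[DegreeRecord]:
    """Per-node degree over distinct interaction partners (self-loop adds 2)."""
    g = network.pair_digraph()
    return [DegreeRecord(n, g.in_degree(n) + g.out_degree(n)) for n in sorted(g.nodes)]


def hubs(network: RegulatoryNetwork, fraction: float = 0.10) -> NodeSetResult:
    """The top ``ceil(fraction * N)`` highest-degree nodes.

    Ties at the boundary degree are broken lexicographically (smallest id
    kept) so exactly k nodes are returned, deterministically.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"hub fraction must be in (0, 1], got {fraction}")
    recs = degrees(network)
    k = math.ceil(fraction * len(recs))
    ordered = sorted(recs, key=lambda r: (-r.degree, r.node))
    members = frozenset(r.node for r in ordered[:k])
    return NodeSetResult(members, "hub", "exact", frozenset(network.nodes()))


def dominated_by(network: RegulatoryNetwork, node: str) -> set[str]:
    """Closed out-neighborhood: the node itself plus everything it regulates."""
    if node not in network:
        raise KeyError(f"unknown node {node!r}")
    return {node} | network.out_neighbors(node)


def _closed_out_neighborhoods(g: nx.DiGraph) -> dict[str, set[str]]:
    return {n: {n} | set(g.successors(n)) for n in g.nodes}


def _forced_nodes(g: nx.DiGraph) -> set[str]:
    """Nodes with no incoming edge can only be dominated by themselves."""
    return {n for n in g.nodes if g.in_degree(n) == 0}


def _greedy_mds(g: nx.DiGraph) -> set[str]:
    """Deterministic greedy set cover over closed out-neighborhoods.

    Tie cascade: max newly covered nodes, then max total degree, then
    lexicographically smallest id.
    """
    cover = _closed_out_neighborhoods(g)
    total_degree = {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}
    chosen = set(_forced_nodes(g))
    uncovered = set(g.nodes) - set().union(*(cover[n] for n in chosen)) if chosen else set(g.nodes)
    while uncovered:
        best = max(
            g.nodes,
            key=lambda n: (len(cover[n] & uncovered), total_degree[n], _RevStr(n)),
        )
        chosen.add(best)
        uncovered -= cover[best]
    return chosen


class _RevStr(str):
    """String with reversed ordering, so max() picks the lexicographically
    smallest id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _exact_mds(g: nx.DiGraph) -> set[str]:
    """Provably minimum dominating set via the domination ILP (HiGHS)."""
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols = [], []
    for v in nodes:
        i = index[v]
        rows.append(i)
        cols.append(i)
        for u in g.predecessors(v):
            if u != v:
                rows.append(i)
                cols.append(index[u])
    a = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    lb = np.zeros(n)
    for f in _forced_nodes(g):
        lb[index[f]] = 1.0
    res = milp(
        c=np.ones(n),
        constraints=LinearConstraint(a, lb=np.ones(n)),
        integrality=np.ones(n),
        bounds=(lb, np.ones(n)),
    )
    if res.status != 0:  # pragma: no cover - domination ILP is always feasible
        raise RuntimeError(f"MDS ILP failed: {res.message}")
    return {nodes[i] for i in range(n) if res.x[i] > 0.5}


def _assert_dominating(g: nx.DiGraph, members: set[str], domain: set[str]) -> None:
    cover = set(members)
    for m in members:
        cover |= set(g.successors(m))
    missing = domain - cover
    if missing:  # pragma: no cover - internal invariant
        raise AssertionError(f"dominating-set invariant violated; uncovered: {sorted(missing)[:5]}")


def compute_mds(
    network: RegulatoryNetwork,
    mode: str = "auto",
    size_limit: int = DEFAULT_EXACT_SIZE_LIMIT,
) -> NodeSetResult:
    """Minimum dominating set of the whole network under directed domination.

    ``mode="exact"`` solves the ILP to proven optimality; ``"greedy"`` runs
    the deterministic greedy cover; ``"auto"`` solves exactly up to
    ``size_limit`` nodes and falls back to greedy beyond.  In every mode,
    in-degree-0 nodes are forced into the set and validity is asserted on the
    result.
    """
    if mode not in ("exact", "greedy", "auto"):
        raise ValueError(f"mode must be exact, greedy or auto, got {mode!r}")
    g = network.pair_digraph()
    if g.number_of_nodes() == 0:
        raise ValueError("cannot compute an MDS of an empty network")
    if mode == "auto":
        mode = "exact" if g.number_of_nodes() <= size_limit else "greedy"
    members = _exact_mds(g) if mode == "exact" else _greedy_mds(g)
    _assert_dominating(g, members, set(g.nodes))
    return NodeSetResult(frozenset(members), "MDS", mode if mode == "exact" else "heuristic",
                         frozenset(g.nodes))


def largest_connected_component(network: RegulatoryNetwork) -> RegulatoryNetwork:
    """Induced subnetwork on the largest weakly connected component.

    Size ties are broken by the component containing the lexicographically
    smallest node.
    """
    if len(network) == 0:
        return network
    g = network.pair_digraph()
    components = [sorted(c) for c in nx.weakly_connected_components(g)]
    best = max(components, key=lambda c: (len(c), _RevStr(c[0])))
    return network.subnetwork(best)


def compute_mcds(network: RegulatoryNetwork) -> NodeSetResult:
    """Connected dominating set of the largest connected component (LCC).

    Grow-and-prune heuristic: seed with the LCC node of maximum out-degree
    (ties: max total degree, then smallest id); repeatedly add the node
    undirected-adjacent to the current set that covers the most undominated
    nodes (same tie cascade), bridging via a shortest undirected path when no
    adjacent node makes progress; finally prune members, in ascending
    coverage order, whose removal preserves both domination and connectivity.
    The result is a valid connected dominating set, not necessarily minimum.
    """
    lcc = largest_connected_component(network)
    if len(lcc) == 0:
        raise ValueError("cannot compute an MCDS of an empty network")
    g = lcc.pair_digraph()
    und = g.to_undirected(as_view=False)
    domain = set(g.nodes)
    cover = _closed_out_neighborhoods(g)
    total_degree = {n: g.in_degree(n) + g.out_degree(n) for n in g.nodes}

    seed = max(g.nodes, key=lambda n: (g.out_degree(n), total_degree[n], _RevStr(n)))
    members: set[str] = {seed}
    dominated = set(cover[seed])

    while dominated != domain:
        frontier = {v for m in members for v in und.neighbors(m)} - members
        undominated = domain - dominated
        best, best_gain = None, 0
        for cand in frontier:
            gain = len(cover[cand] & undominated)
            if best is None or (gain, total_degree[cand], _RevStr(cand)) > (
                best_gain, total_degree[best], _RevStr(best)
            ):
                best, best_gain = cand, gain
        if best is not None and best_gain > 0:
            members.add(best)
            dominated |= cover[best]
        else:
            # bridge: first step of a shortest undirected path from the set
            # towards the nearest undominated node
            members.add(_bridge_step(und, members, undominated))
            # recompute below; the bridge node may or may not cover anything
            dominated = set().union(*(cover[m] for m in members))

    # prune in ascending coverage (then id) order until a fixed point
    changed = True
    while changed:
        changed = False
        for m in sorted(members, key=lambda n: (len(cover[n] & domain), n)):
            trial = members - {m}
            if not trial:
                continue
            still_dominating = domain <= set().union(*(cover[t] for t in trial))
            if still_dominating and nx.is_connected(und.subgraph(trial)):
                members = trial
                changed = True
                break

    _assert_dominating(g, members, domain)
    if len(members) > 1 and not nx.is_connected(und.subgraph(members)):  # pragma: no cover
        raise AssertionError("MCDS connectivity invariant violated")
    return NodeSetResult(frozenset(members), "MCDS", "heuristic", frozenset(domain))


def _bridge_step(und: nx.Graph, members: set[str], undominated: set[str]) -> str:
    """First node after the member set on a deterministic shortest undirected
    path to the nearest undominated node."""
    parents: dict[str, Optional[str]] = {m: None for m in sorted(members)}
    queue = deque(sorted(members))
    target = None
    found_at = None
    while queue:
        node = queue.popleft()
        if node in undominated and node not in members:
            depth = _depth(parents, node)
            if found_at is not None and depth > found_at:
                break
            if target is None or node < target:
                target, found_at = node, depth
            continue
        for nb in sorted(und.neighbors(node)):
            if nb not in parents:
                parents[nb] = node
                queue.append(nb)
    if target is None:  # pragma: no cover - LCC is connected by construction
        raise AssertionError("no path from the connected set to an undominated node")
    node = target
    while parents[node] not in members and parents[node] is not None:
        node = parents[node]
    return node if parents[node] is not None else node


def _depth(parents: dict[str, Optional[str]], node: str) -> int:
    depth = 0
    while parents[node] is not None:
        node = parents[node]
        depth += 1
    return depth
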