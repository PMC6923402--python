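"""Deterministic synthetic fixtures with known ground truth.

The generator emulates the inputs of a differential co-regulatory analysis at
desk scale: a background catalog of typed TF/miRNA regulations with a
right-skewed out-degree distribution (few master regulators targeting many
genes), an expression table with a planted set of differentially expressed
(DE) genes, miRNAs whose partner sets are constructed so that a known subset
passes the enrichment cutoff, and a disease annotation that preferentially
covers the high-degree nodes of the resulting differential network.  Every
draw flows through a single :class:`numpy.random.Generator` seeded from the
spec, so identical specs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    DiseaseAnnotation,
    EdgeType,
    ExpressionRecord,
    ExpressionTable,
    InteractionCatalog,
    NodeKind,
    RegulatoryEdge,
    RegulatoryNetwork,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_toy_network"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are a scaled-down cancer-transcriptome setting: a few hundred
    genes under a few dozen TFs and a dozen miRNAs, roughly a third of the
    genes differentially expressed, log2 fold changes on an exponential scale
    of 1.5, and 60% of the top differential-network nodes annotated as
    disease-associated.
    """

    n_tfs: int = 40
    n_genes: int = 360
    n_mirnas: int = 12
    attachment_exponent: float = 1.2  # Pareto tail index of TF out-degrees
    de_fraction: float = 0.30
    lfc_scale: float = 1.5
    planted_disease_overlap: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tfs, self.n_genes, self.n_mirnas) <= 0:
            raise ValueError("node counts must be positive")
        if not (0.0 < self.de_fraction < 1.0):
            raise ValueError("de_fraction must be in (0, 1)")
        if not (0.0 <= self.planted_disease_overlap <= 1.0):
            raise ValueError("planted_disease_overlap must be in [0, 1]")
        if self.attachment_exponent <= 0 or self.lfc_scale <= 0:
            raise ValueError("attachment_exponent and lfc_scale must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for recovery tests."""

    de_members: frozenset[str]
    enriched_mirnas: frozenset[str]
    planted_subnetwork: RegulatoryNetwork
    annotated: frozenset[str]


def _names(spec: SyntheticSpec) -> tuple[list[str], list[str], list[str]]:
    tfs = [f"TF{i:03d}" for i in range(1, spec.n_tfs + 1)]
    genes = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    mirnas = [f"hsa-mir-{100 + i}" for i in range(1, spec.n_mirnas + 1)]
    return tfs, genes, mirnas


def generate(
    spec: SyntheticSpec,
) -> tuple[InteractionCatalog, ExpressionTable, DiseaseAnnotation, GroundTruth]:
    """Draw one dataset: catalog, expression table, annotation, ground truth."""
    rng = np.random.default_rng(spec.seed)
    tfs, genes, mirnas = _names(spec)
    regulable = tfs + genes  # gene-kind targets (TFs are themselves genes)

    # --- TF -> gene/TF edges with Pareto-tailed out-degrees and
    #     preferential attachment on the target side -----------------------
    edges: set[RegulatoryEdge] = set()
    max_out = max(10, spec.n_genes // 6)
    target_weight = np.ones(len(regulable))
    for i, tf in enumerate(tfs):
        out_deg = 1 + int(min(rng.pareto(spec.attachment_exponent) * 3, max_out))
        p = target_weight / target_weight.sum()
        picks = rng.choice(len(regulable), size=min(out_deg, len(regulable)), replace=False, p=p)
        for j in picks:
            if regulable[j] != tf:
                edges.add(RegulatoryEdge(tf, regulable[j], EdgeType.TF_GENE))
                target_weight[j] += 1.0

    # --- planted DE membership (decided before miRNA wiring so partner
    #     sets can be tilted towards it) ----------------------------------
    n_de = int(round(spec.de_fraction * len(regulable)))
    de_members = set(rng.choice(regulable, size=n_de, replace=False).tolist())

    # --- miRNA partner sets: a planted third is drawn almost entirely from
    #     the DE set (enriched); the rest are background draws -------------
    n_enriched = max(1, spec.n_mirnas // 3)
    enriched = set(mirnas[:n_enriched])
    de_list = sorted(de_members)
    background = sorted(set(regulable) - de_members)
    for m in mirnas:
        n_partners = int(rng.integers(12, 25))
        if m in enriched:
            n_from_de = max(1, int(round(n_partners * 0.9)))
            part = list(rng.choice(de_list, size=min(n_from_de, len(de_list)), replace=False))
            part += list(rng.choice(background, size=n_partners - len(part), replace=False))
        else:
            part = list(rng.choice(sorted(regulable), size=n_partners, replace=False))
        # roughly a quarter of partners regulate the miRNA (must be TF-kind
        # sources), the rest are its targets
        for partner in part:
            if partner in tfs and rng.random() < 0.25:
                edges.add(RegulatoryEdge(partner, m, EdgeType.TF_MIRNA))
            else:
                edges.add(RegulatoryEdge(m, partner, EdgeType.MIRNA_GENE))

    catalog = InteractionCatalog(sorted(edges))
    # kind inference may discover no TF evidence for a planned TF that only
    # appears as a target; the DE bookkeeping is unaffected

    # --- expression table: planted DE genes significant with exponential
    #     fold changes, the rest null ---------------------------------------
    records = []
    for node in sorted(regulable):
        if node in de_members:
            # kept strictly below the 0.05 threshold after rounding
            padj = min(round(float(rng.uniform(0.0, 0.05)), 6), 0.049999)
            lfc = float(rng.choice([-1.0, 1.0]) * (0.25 + rng.exponential(spec.lfc_scale)))
        else:
            padj = min(round(float(rng.uniform(0.05, 1.0)), 6), 1.0)
            lfc = float(rng.normal(0.0, 0.3))
        records.append(ExpressionRecord(node, round(lfc, 4), padj))
    expr = ExpressionTable.from_records(records)

    # --- planted differential subnetwork: catalog edges whose gene/TF
    #     endpoints are DE and miRNA endpoints enriched ---------------------
    def keep(e: RegulatoryEdge) -> bool:
        def ok(node: str) -> bool:
            if catalog.kind(node) is NodeKind.MIRNA:
                return node in enriched
            return node in de_members
        return ok(e.source) and ok(e.target)

    planted = RegulatoryNetwork([e for e in catalog.edges() if keep(e)])

    # --- disease annotation: cover the planted network's likely high-score
    #     nodes — the top-degree decile plus unregulated nodes (which are
    #     necessarily dominators) — at the configured rate, plus matched
    #     background noise -------------------------------------------------
    g = planted.pair_digraph()
    ordered = sorted(g.nodes, key=lambda n: (-(g.in_degree(n) + g.out_degree(n)), n))
    pool = sorted(
        set(ordered[: max(1, len(ordered) // 10)])
        | {n for n in g.nodes if g.in_degree(n) == 0}
    )
    n_hit = int(round(spec.planted_disease_overlap * len(pool)))
    hits = set(rng.choice(pool, size=n_hit, replace=False).tolist()) if n_hit else set()
    rest = sorted(set(ordered) - set(pool))
    n_noise = min(len(rest), max(1, n_hit))
    noise = set(rng.choice(rest, size=n_noise, replace=False).tolist()) if n_noise else set()
    annotation = DiseaseAnnotation("synthetic-disease", frozenset(hits | noise))

    truth = GroundTruth(
        de_members=frozenset(de_members),
        enriched_mirnas=frozenset(enriched),
        planted_subnetwork=planted,
        annotated=annotation.members,
    )
    return catalog, expr, annotation, truth


#: hand-laid 20-node typed network used as a stable regression fixture: one
#: master-regulator TF, a secondary TF cascade, two miRNAs and a short tail
#: reachable only through the cascade.
_TOY_EDGES: tuple[tuple[str, str, EdgeType], ...] = (
    ("TFA", "GGA", EdgeType.TF_GENE),
    ("TFA", "GGB", EdgeType.TF_GENE),
    ("TFA", "GGC", EdgeType.TF_GENE),
    ("TFA", "GGD", EdgeType.TF_GENE),
    ("TFA", "TFB", EdgeType.TF_GENE),
    ("TFA", "hsa-mir-1", EdgeType.TF_MIRNA),
    ("TFB", "GGE", EdgeType.TF_GENE),
    ("TFB", "GGF", EdgeType.TF_GENE),
    ("TFB", "hsa-mir-2", EdgeType.TF_MIRNA),
    ("TFC", "GGA", EdgeType.TF_GENE),
    ("TFC", "GGG", EdgeType.TF_GENE),
    ("TFC", "GGH", EdgeType.TF_GENE),
    ("hsa-mir-1", "GGB", EdgeType.MIRNA_GENE),
    ("hsa-mir-1", "GGE", EdgeType.MIRNA_GENE),
    ("hsa-mir-1", "GGI", EdgeType.MIRNA_GENE),
    ("hsa-mir-2", "GGC", EdgeType.MIRNA_GENE),
    ("hsa-mir-2", "GGJ", EdgeType.MIRNA_GENE),
    ("hsa-mir-2", "TFC", EdgeType.MIRNA_GENE),
    ("GGJ", "GGK", EdgeType.TF_GENE),
    ("GGK", "GGL", EdgeType.TF_GENE),
    ("GGL", "GGM", EdgeType.TF_GENE),
    ("TFD", "GGN", EdgeType.TF_GENE),
    ("TFD", "GGA", EdgeType.TF_GENE),
)


def generate_toy_network() -> RegulatoryNetwork:
    """A fixed ~20-node typed network for regression tests.

    Its hub, MDS and MCDS sets are computed by the solvers and frozen as
    fixtures; the network itself is hand-laid to exercise a master regulator,
    a regulatory cascade, miRNA feedback onto a TF, and a linear tail.
    """
    return RegulatoryNetwork(RegulatoryEdge(s, t, et) for s, t, et in _TOY_EDGES)
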