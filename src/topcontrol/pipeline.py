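"""End-to-end orchestration: catalog + expression table in, ranked candidate
table (and optional evaluation against a disease annotation) out.

Every stage is also available as a standalone function so a pre-built
network — e.g. one exported from a web server — can be injected directly at
the topology stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from . import io as tc_io
from .construction import build_differential_network, enrich_mirnas, filter_de_genes, write_enrichment_results
from .control import DEFAULT_EXACT_SIZE_LIMIT, compute_mcds, compute_mds, hubs
from .evaluate import EvaluationReport, evaluate_candidates
from .model import DiseaseAnnotation, ExpressionTable, RegulatoryNetwork
from .prioritize import PriorityTable, assign_scores, layer_members, rank_candidates

__all__ = ["RunConfig", "PipelineResult", "run", "run_pipeline"]

logger = logging.getLogger("topcontrol")


@dataclass
class RunConfig:
    """Every tunable of a run; serializable so a run log can echo it."""

    de_alpha: float = 0.05
    mirna_cutoff: float = 0.001
    enrichment_mode: str = "union"
    hub_fraction: float = 0.10
    mds_mode: str = "auto"
    size_limit: int = DEFAULT_EXACT_SIZE_LIMIT
    seed: int = 0
    catalog: Optional[str] = None
    expression: Optional[str] = None
    network: Optional[str] = None      # pre-built differential network, skips construction
    annotation: Optional[str] = None
    disease_name: str = "disease"
    out_dir: Optional[str] = None

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    network: RegulatoryNetwork
    hubs: "frozenset[str]"
    mds: "frozenset[str]"
    mcds: "frozenset[str]"
    table: PriorityTable
    evaluation: Optional[EvaluationReport]
    stage_counts: dict


def run(
    config: RunConfig,
    catalog=None,
    expression: Optional[ExpressionTable] = None,
    network: Optional[RegulatoryNetwork] = None,
    annotation: Optional[DiseaseAnnotation] = None,
) -> PipelineResult:
    """Run the full prioritization on in-memory inputs.

    Either a catalog + expression table (the network is constructed) or a
    pre-built network + expression table must be given.
    """
    if expression is None:
        raise ValueError("an expression table is required")
    enrichment = None
    if network is None:
        if catalog is None:
            raise ValueError("either a catalog or a pre-built network is required")
        de = filter_de_genes(expression, config.de_alpha)
        enrichment = enrich_mirnas(catalog, de, cutoff=config.mirna_cutoff, mode=config.enrichment_mode)
        selected = {r.mirna for r in enrichment if r.selected}
        network = build_differential_network(catalog, de, selected)
        logger.info("constructed differential network: %d nodes, %d edges", len(network), network.n_edges())
    if len(network) == 0:
        raise ValueError("differential network is empty; nothing to prioritize")

    hub_set = hubs(network, config.hub_fraction)
    mds = compute_mds(network, mode=config.mds_mode, size_limit=config.size_limit)
    mcds = compute_mcds(network)
    table = rank_candidates(assign_scores(network, hub_set, mds, mcds, expression))

    evaluation = None
    if annotation is not None:
        candidates = layer_members(table, 4)
        evaluation = evaluate_candidates(candidates, annotation, set(network.nodes()))

    counts = {
        "n_nodes": len(network),
        "n_edges": network.n_edges(),
        "n_hubs": len(hub_set),
        "n_mds": len(mds),
        "n_mcds": len(mcds),
        "n_layer4": len(layer_members(table, 4)),
        "n_layer5": len(layer_members(table, 5)),
    }
    result = PipelineResult(
        network=network,
        hubs=hub_set.members,
        mds=mds.members,
        mcds=mcds.members,
        table=table,
        evaluation=evaluation,
        stage_counts=counts,
    )
    result.enrichment = enrichment  # type: ignore[attr-defined]
    return result


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based wrapper around :func:`run`; writes all artifacts under
    ``config.out_dir`` and a run log echoing the configuration."""
    catalog = tc_io.read_catalog(config.catalog) if config.catalog else None
    expression = tc_io.read_expression_table(config.expression) if config.expression else None
    network = tc_io.read_network(config.network) if config.network else None
    annotation = (
        tc_io.read_annotation(config.annotation, config.disease_name) if config.annotation else None
    )
    result = run(config, catalog=catalog, expression=expression, network=network, annotation=annotation)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tc_io.write_network(result.network, out / "network.tsv")
        tc_io.write_priority_table(result.table, out / "ranked_candidates.tsv")
        for name, members in (("hubs", result.hubs), ("mds", result.mds), ("mcds", result.mcds)):
            with open(out / f"{name}.txt", "w", encoding="utf-8") as fh:
                for node in sorted(members):
                    fh.write(node + "\n")
        enrichment = getattr(result, "enrichment", None)
        if enrichment is not None:
            write_enrichment_results(enrichment, out / "mirna_enrichment.tsv")
        if result.evaluation is not None:
            payload = result.evaluation.as_dict()
            payload["percent"] = result.evaluation.percentages()
            (out / "evaluation.json").write_text(json.dumps(payload, indent=2) + "\n")
        log = {
            "config": dataclasses.asdict(config),
            "stage_counts": result.stage_counts,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return result
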