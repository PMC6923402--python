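"""DE filtering, miRNA enrichment and differential-network assembly."""

import math

import pytest

from topcontrol.construction import (
    build_differential_network,
    enrich_mirnas,
    filter_de_genes,
)
from topcontrol.model import (
    EdgeType,
    ExpressionRecord,
    ExpressionTable,
    InteractionCatalog,
    RegulatoryEdge,
)
from topcontrol.synthetic import SyntheticSpec, generate


def edge(s, t, et):
    return RegulatoryEdge(s, t, EdgeType(et))


def expr_table(**padj):
    return ExpressionTable.from_records(
        ExpressionRecord(node, None, p) for node, p in padj.items()
    )


class TestFilterDEGenes:
    def test_threshold_is_strict(self):
        table = expr_table(a=0.01, b=0.05, c=0.049)
        assert filter_de_genes(table, 0.05).members == {"a", "c"}

    def test_nothing_significant_gives_empty_set(self):
        assert len(filter_de_genes(expr_table(a=0.5, b=0.05), 0.05)) == 0

    def test_planted_de_genes_recovered_exactly(self):
        _, expr, _, truth = generate(SyntheticSpec(seed=3))
        assert filter_de_genes(expr, 0.05).members == truth.de_members

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            filter_de_genes(expr_table(a=0.1), 0.0)


def catalog_with_mirna(n_universe=100, n_partners=5):
    """One miRNA whose partners are genes G1..Gk inside a 100-gene universe."""
    edges = [edge("T0", f"G{i}", "TF_gene") for i in range(1, n_universe)]
    edges += [edge("m1", f"G{i}", "miRNA_gene") for i in range(1, n_partners + 1)]
    return InteractionCatalog(edges)  # universe: T0 + G1..G99 = 100 nodes


class TestEnrichMirnas:
    def test_raw_p_matches_combinatorial_formula(self):
        # 5 partners, all DE; universe of 100 with 10 DE
        cat = catalog_with_mirna()
        de = filter_de_genes(
            expr_table(**{f"G{i}": 0.01 for i in range(1, 11)},
                       **{f"G{i}": 0.5 for i in range(11, 100)}, T0=0.5),
            0.05,
        )
        assert len(de) == 10
        (res,) = enrich_mirnas(cat, de, cutoff=0.001)
        expected = math.comb(10, 5) * math.comb(90, 0) / math.comb(100, 5)
        assert res.raw_p == pytest.approx(expected, rel=1e-12)
        assert res.selected  # single test: adj_p == raw_p ~ 3.3e-6 < 0.001

    def test_zero_overlap_gives_p_one(self):
        cat = catalog_with_mirna()
        de = filter_de_genes(
            expr_table(**{f"G{i}": 0.01 for i in range(50, 60)},
                       **{f"G{i}": 0.5 for i in list(range(1, 50)) + list(range(60, 100))},
                       T0=0.5),
            0.05,
        )
        (res,) = enrich_mirnas(cat, de)
        assert res.overlap_k == 0 and res.raw_p == 1.0 and not res.selected

    def test_empty_de_intersection_is_not_an_error(self):
        cat = catalog_with_mirna()
        de = filter_de_genes(expr_table(ZZZ=0.01), 0.05)  # disjoint from universe
        (res,) = enrich_mirnas(cat, de)
        assert res.raw_p == 1.0 and not res.selected

    def test_identical_partner_sets_get_identical_p(self):
        edges = [edge("T0", f"G{i}", "TF_gene") for i in range(1, 40)]
        for m in ("hsa-mir-1", "hsa-mir-2"):
            edges += [edge(m, f"G{i}", "miRNA_gene") for i in range(1, 6)]
        cat = InteractionCatalog(edges)
        de = filter_de_genes(
            expr_table(**{f"G{i}": 0.01 for i in range(1, 6)},
                       **{f"G{i}": 0.5 for i in range(6, 40)}, T0=0.5),
            0.05,
        )
        r1, r2 = enrich_mirnas(cat, de)
        assert r1.raw_p == r2.raw_p and r1.adj_p == r2.adj_p

    def test_adjusted_never_below_raw_and_order_preserved(self):
        _, expr, _, _ = generate(SyntheticSpec(seed=5))
        cat = generate(SyntheticSpec(seed=5))[0]
        de = filter_de_genes(expr, 0.05)
        results = enrich_mirnas(cat, de)
        for r in results:
            assert r.adj_p >= r.raw_p - 1e-15
        by_raw = sorted(results, key=lambda r: r.raw_p)
        assert [r.adj_p for r in by_raw] == sorted(r.adj_p for r in results)

    def test_separate_mode_requires_both_tests(self):
        # targets all DE, but the sole TF regulator is not DE: union passes,
        # separate does not
        edges = [edge("T0", f"G{i}", "TF_gene") for i in range(1, 60)]
        edges += [edge("m1", f"G{i}", "miRNA_gene") for i in range(1, 7)]
        edges += [edge("T0", "m1", "TF_miRNA")]
        cat = InteractionCatalog(edges)
        de = filter_de_genes(
            expr_table(**{f"G{i}": 0.01 for i in range(1, 7)},
                       **{f"G{i}": 0.5 for i in range(7, 60)}, T0=0.5),
            0.05,
        )
        (union_res,) = enrich_mirnas(cat, de, mode="union")
        (sep_res,) = enrich_mirnas(cat, de, mode="separate")
        assert union_res.selected and not sep_res.selected


class TestBuildDifferentialNetwork:
    def test_endpoint_filtering(self):
        cat = InteractionCatalog([edge("A", "B", "TF_gene"), edge("A", "C", "TF_gene")])
        net = build_differential_network(cat, filter_de_genes(expr_table(A=0.01, B=0.01, C=0.9)), set())
        assert set(net.nodes()) == {"A", "B"} and net.n_edges() == 1

    def test_mirna_edges_need_selection(self):
        cat = InteractionCatalog([
            edge("T", "hsa-mir-1", "TF_miRNA"),
            edge("hsa-mir-1", "G", "miRNA_gene"),
        ])
        de = filter_de_genes(expr_table(T=0.01, G=0.01))
        net = build_differential_network(cat, de, {"hsa-mir-1"})
        assert len(net) == 3 and net.n_edges() == 2
        empty = build_differential_network(cat, de, set())
        assert len(empty) == 0

    def test_monotone_in_de_set(self):
        cat, expr, _, _ = generate(SyntheticSpec(seed=2))
        small = filter_de_genes(expr, 0.01)
        large = filter_de_genes(expr, 0.05)
        assert small.members <= large.members
        mirnas = cat.mirnas()
        net_small = build_differential_network(cat, small, mirnas)
        net_large = build_differential_network(cat, large, mirnas)
        assert set(net_small.edges()) <= set(net_large.edges())

    def test_no_isolated_nodes(self):
        cat, expr, _, _ = generate(SyntheticSpec(seed=4))
        net = build_differential_network(cat, filter_de_genes(expr), cat.mirnas())
        g = net.pair_digraph()
        assert all(g.degree(n) > 0 for n in g.nodes)

    def test_planted_subnetwork_reconstructed_exactly(self):
        cat, expr, _, truth = generate(SyntheticSpec(seed=1))
        de = filter_de_genes(expr, 0.05)
        selected = {r.mirna for r in enrich_mirnas(cat, de) if r.selected}
        assert selected == set(truth.enriched_mirnas)
        assert build_differential_network(cat, de, selected) == truth.planted_subnetwork

    def test_unknown_selected_mirna_rejected(self):
        cat = InteractionCatalog([edge("A", "B", "TF_gene")])
        with pytest.raises(ValueError):
            build_differential_network(cat, filter_de_genes(expr_table(A=0.01, B=0.01)), {"hsa-mir-99"})
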