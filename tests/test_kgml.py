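import pytest

from pathphylo.errors import MappingError, ParseError
from pathphylo.kgml import NamespaceMap, parse_kgml, relabel_members
from pathphylo.synthetic import emit_kgml

from conftest import make_graph, random_pathway_graph


def kgml_doc(entries, relations, org="tst"):
    """Assemble a minimal KGML document from (id, name, type) and (e1, e2[, subtype])."""
    parts = [f'<pathway name="path:{org}00001" org="{org}">']
    for eid, name, etype, *comp in entries:
        if comp:
            comps = "".join(f'<component id="{c}"/>' for c in comp[0])
            parts.append(f'<entry id="{eid}" name="{name}" type="{etype}">{comps}</entry>')
        else:
            parts.append(f'<entry id="{eid}" name="{name}" type="{etype}"/>')
    for rel in relations:
        e1, e2 = rel[0], rel[1]
        sub = f'<subtype name="{rel[2]}" value=""/>' if len(rel) > 2 else ""
        rtype = rel[3] if len(rel) > 3 else "PPrel"
        parts.append(
            f'<relation entry1="{e1}" entry2="{e2}" type="{rtype}">{sub}</relation>'
        )
    parts.append("</pathway>")
    return "".join(parts)


class TestParseKgml:
    def test_three_genes_two_relations(self):
        doc = kgml_doc(
            [(1, "tst:g1", "gene"), (2, "tst:g2", "gene"), (3, "tst:g3", "gene")],
            [(1, 2), (2, 3)],
        )
        g = parse_kgml(doc)
        assert len(g) == 3 and g.g.number_of_edges() == 2
        assert g.species_code == "tst"
        assert g.member_ids(1) == frozenset({"g1"})

    def test_duplicate_relations_collapse_to_one_edge(self):
        doc = kgml_doc(
            [(1, "tst:g1", "gene"), (2, "tst:g2", "gene")],
            [(1, 2, "activation"), (1, 2, "expression", "GErel")],
        )
        g = parse_kgml(doc)
        assert g.g.number_of_edges() == 1

    def test_group_expansion_clique_and_reattachment(self):
        doc = kgml_doc(
            [
                (1, "tst:e1", "gene"),
                (2, "tst:e2", "gene"),
                (3, "tst:e3", "gene"),
                (4, "", "group", [1, 2]),
            ],
            [(4, 3)],
        )
        g = parse_kgml(doc)
        assert g.edge_set() == {
            frozenset({1, 2}),
            frozenset({1, 3}),
            frozenset({2, 3}),
        }

    def test_compound_nodes_opt_in(self):
        doc = kgml_doc(
            [(1, "tst:g1", "gene"), (2, "cpd:C00001", "compound")], [(1, 2)]
        )
        assert len(parse_kgml(doc)) == 1
        g = parse_kgml(doc, include_compounds=True)
        assert len(g) == 2 and g.node_class(2) == "compound"

    def test_map_entries_and_maplink_dropped(self):
        doc = kgml_doc(
            [(1, "tst:g1", "gene"), (2, "path:tst00002", "map")],
            [(1, 2, "link", "maplink")],
        )
        g = parse_kgml(doc)
        assert len(g) == 1 and g.g.number_of_edges() == 0

    def test_multiple_name_tokens_all_become_members(self):
        doc = kgml_doc([(1, "tst:a tst:b", "gene")], [])
        assert parse_kgml(doc).member_ids(1) == frozenset({"a", "b"})

    def test_malformed_document_raises(self):
        with pytest.raises(ParseError):
            parse_kgml("<pathway><entry id='x' type='gene'/></pathway>")
        with pytest.raises(ParseError):
            parse_kgml("<notapathway/>")

    def test_unknown_relation_endpoint_strict_vs_lax(self):
        doc = kgml_doc([(1, "tst:g1", "gene")], [(1, 99)])
        with pytest.raises(ParseError):
            parse_kgml(doc, strict=True)
        g = parse_kgml(doc, strict=False)
        assert g.g.number_of_edges() == 0

    def test_order_independence(self):
        entries = [(1, "tst:g1", "gene"), (2, "tst:g2", "gene"), (3, "tst:g3", "gene")]
        rels = [(1, 2), (2, 3), (1, 3)]
        a = parse_kgml(kgml_doc(entries, rels))
        b = parse_kgml(kgml_doc(entries[::-1], rels[::-1]))
        assert a.edge_set() == b.edge_set()
        assert all(a.member_ids(n) == b.member_ids(n) for n in a.node_ids)


class TestNamespace:
    def test_mapping_applied(self):
        doc = kgml_doc([(1, "hsa:1", "gene")], [])
        ns = NamespaceMap({"hsa:1": "K001"})
        g = parse_kgml(doc, namespace=ns)
        assert g.member_ids(1) == frozenset({"K001"})

    def test_strict_mapping_gap_raises(self):
        doc = kgml_doc([(1, "hsa:1 hsa:2", "gene")], [])
        with pytest.raises(MappingError, match="hsa:2"):
            parse_kgml(doc, namespace=NamespaceMap({"hsa:1": "K001"}))

    def test_from_tsv(self, tmp_path):
        p = tmp_path / "ns.tsv"
        p.write_text("# comment\nhsa:1\tK001\nhsa:2\tK002\n")
        ns = NamespaceMap.from_tsv(p)
        assert ns.mapping == {"hsa:1": "K001", "hsa:2": "K002"}

    def test_relabel_identity_and_shared_target(self):
        g = make_graph("x", [(0, 1)], members={0: "a", 1: "b"})
        ident = relabel_members(g, NamespaceMap({"a": "a", "b": "b"}))
        assert all(ident.member_ids(n) == g.member_ids(n) for n in g.node_ids)
        shared = relabel_members(g, NamespaceMap({"a": "K1", "b": "K1"}))
        # both relabeled, no node merging
        assert len(shared) == 2
        assert shared.member_ids(0) == shared.member_ids(1) == frozenset({"K1"})

    def test_relabel_strict_gap(self):
        g = make_graph("x", [(0, 1)], members={0: "a", 1: "b"})
        with pytest.raises(MappingError, match="b"):
            relabel_members(g, NamespaceMap({"a": "K1"}))


@pytest.mark.parametrize("seed", range(5))
def test_emit_parse_round_trip(seed):
    g = random_pathway_graph(12, 0.25, seed, species="rtx")
    g2 = parse_kgml(emit_kgml(g))
    assert g2.node_ids == g.node_ids
    assert g2.edge_set() == g.edge_set()
    assert all(g2.member_ids(n) == g.member_ids(n) for n in g.node_ids)
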