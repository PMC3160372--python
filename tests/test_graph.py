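"""Causal-graph data model, serialization, census and traversal."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcrnet import (CausalGraph, Evidence, augment_with_orthologs, census,
                    downstream_mrna_targets, load_graph, save_graph,
                    subgraph_by_tag)
from rcrnet.errors import (ContractError, ReferentialError, UnknownNodeError,
                           VocabularyError)
from rcrnet.graph import AMBIGUOUS, EntityNode

from conftest import make_node


# -- construction invariants ----------------------------------------------


def test_entity_class_vocabulary_is_closed():
    with pytest.raises(VocabularyError):
        EntityNode(node_id="x", entity_class="gene-ish")


def test_modification_required_exactly_for_modified_protein():
    with pytest.raises(VocabularyError):
        EntityNode(node_id="x", entity_class="modified-protein")
    with pytest.raises(VocabularyError):
        EntityNode(node_id="x", entity_class="protein", modification="P@S1")


def test_activity_kind_required_exactly_for_activity():
    with pytest.raises(VocabularyError):
        EntityNode(node_id="x", entity_class="activity")


def test_edges_require_declared_endpoints(toy_graph):
    with pytest.raises(ReferentialError):
        toy_graph.add_causal_edge("TF1", "missing", 1,
                                  Evidence(citation_id="PMID:9"))
    with pytest.raises(ReferentialError):
        toy_graph.add_noncausal_edge("missing", "TF1", "has-activity")


def test_self_causation_rejected(toy_graph):
    with pytest.raises(ContractError):
        toy_graph.add_causal_edge("TF1", "TF1", 1, Evidence(citation_id="x"))


def test_duplicate_assertion_merges_evidence(toy_graph):
    before = len(toy_graph.causal_edges)
    toy_graph.add_causal_edge("TF1", "m1", 1, Evidence(citation_id="PMID:99"))
    assert len(toy_graph.causal_edges) == before
    assert len(toy_graph.causal_edges[("TF1", "m1", 1)].evidence) == 2
    # re-adding identical evidence is a no-op
    toy_graph.add_causal_edge("TF1", "m1", 1, Evidence(citation_id="PMID:99"))
    assert len(toy_graph.causal_edges[("TF1", "m1", 1)].evidence) == 2


# -- census ----------------------------------------------------------------


def test_census_counts(toy_graph):
    c = census(toy_graph)
    assert c.total_nodes == 9
    assert c.causal_edge_count == 9
    assert c.noncausal_edge_count == 1
    assert c.total_edges == 10
    # PMIDs 1-4 across all causal evidences
    assert c.unique_citation_count == 4
    assert sum(c.class_counts.values()) == c.total_nodes


def test_census_empty_graph():
    c = census(CausalGraph())
    assert c.total_nodes == 0 and c.total_edges == 0
    assert c.unique_citation_count == 0


def test_census_shared_citation_counted_once():
    g = CausalGraph()
    for nid in "abc":
        g.add_node(make_node(nid, "protein"))
    g.add_causal_edge("a", "b", 1, Evidence(citation_id="PMID:7"))
    g.add_causal_edge("a", "c", -1, Evidence(citation_id="PMID:7"))
    assert census(g).unique_citation_count == 1


# -- serialization round-trips --------------------------------------------


@pytest.mark.parametrize("dialect", ["native-tsv", "native-json"])
def test_round_trip_identity(toy_graph, dialect, tmp_path):
    path = tmp_path / ("g.json" if dialect == "native-json" else "g.tsv")
    save_graph(toy_graph, path, dialect)
    assert load_graph(path, dialect) == toy_graph


def test_round_trip_preserves_unicode_tissue(tmp_path):
    g = CausalGraph()
    g.add_node(make_node("a"))
    g.add_node(make_node("b"))
    g.add_causal_edge("a", "b", 1, Evidence(
        citation_id="PMID:1", tissue="poumon fœtal, 肺"))
    path = tmp_path / "g.json"
    save_graph(g, path, "native-json")
    loaded = load_graph(path, "native-json")
    ev = loaded.causal_edges[("a", "b", 1)].evidence[0]
    assert ev.tissue == "poumon fœtal, 肺"


def test_merged_graph_is_round_trip_fixed_point(toy_graph, tmp_path):
    toy_graph.add_causal_edge("TF1", "m1", 1, Evidence(citation_id="PMID:50"))
    path = tmp_path / "g.tsv"
    save_graph(toy_graph, path, "native-tsv")
    once = load_graph(path, "native-tsv")
    save_graph(once, path, "native-tsv")
    assert load_graph(path, "native-tsv") == once


@st.composite
def random_graphs(draw):
    n = draw(st.integers(2, 8))
    classes = ["protein", "mRNA", "activity", "complex", "other"]
    g = CausalGraph(name="rnd")
    ids = [f"n{i}" for i in range(n)]
    for i, nid in enumerate(ids):
        g.add_node(make_node(nid, classes[draw(st.integers(0, 4))]))
    n_edges = draw(st.integers(0, 12))
    for _ in range(n_edges):
        s = draw(st.sampled_from(ids))
        t = draw(st.sampled_from(ids))
        if s == t:
            continue
        sign = draw(st.sampled_from([1, -1]))
        g.add_causal_edge(s, t, sign, Evidence(
            citation_id=f"PMID:{draw(st.integers(1, 5))}",
            quote=draw(st.text(
                alphabet=st.characters(blacklist_categories=("Cs", "Cc")),
                max_size=12)),
        ))
    return g


@settings(max_examples=40, deadline=None, derandomize=True)
@given(g=random_graphs(), dialect=st.sampled_from(["native-tsv", "native-json"]))
def test_round_trip_property(g, dialect, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "g.dat"
    save_graph(g, path, dialect)
    assert load_graph(path, dialect) == g


@settings(max_examples=30, deadline=None, derandomize=True)
@given(g=random_graphs())
def test_census_conservation_property(g):
    c = census(g)
    assert sum(c.class_counts.values()) == c.total_nodes
    assert c.total_edges == c.causal_edge_count + c.noncausal_edge_count


# -- load errors -----------------------------------------------------------


def test_empty_tsv_file_gives_empty_graph(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    g = load_graph(path, "native-tsv")
    assert census(g).total_nodes == 0


def test_unknown_relation_names_row(tmp_path, toy_graph):
    path = tmp_path / "g.tsv"
    save_graph(toy_graph, path, "native-tsv")
    text = path.read_text() + "TF1\tfrobnicates\tm1\t\t\t\t\t\n"
    path.write_text(text)
    with pytest.raises(VocabularyError) as exc:
        load_graph(path, "native-tsv")
    assert "row" in str(exc.value)


def test_dangling_endpoint_raises_referential_error(tmp_path, toy_graph):
    path = tmp_path / "g.tsv"
    save_graph(toy_graph, path, "native-tsv")
    path.write_text(path.read_text() +
                    "TF1\tincreases\tghost\t1\tPMID:1\thuman\t\t\n")
    with pytest.raises(ReferentialError):
        load_graph(path, "native-tsv")


def test_malformed_row_reports_row_number(tmp_path, toy_graph):
    path = tmp_path / "g.tsv"
    save_graph(toy_graph, path, "native-tsv")
    lines = path.read_text().splitlines()
    lines.append("a\tb\tc\td\te\tf\tg\th\ti\tj")  # too many cells
    path.write_text("\n".join(lines))
    with pytest.raises(Exception) as exc:
        load_graph(path, "native-tsv")
    assert f"row {len(lines)}" in str(exc.value)


# -- supplementary-table importer -----------------------------------------


def _write_xlsx(path, node_rows, edge_rows):
    import openpyxl
    book = openpyxl.Workbook()
    ws1 = book.active
    ws1.title = "Nodes"
    ws1.append(["Node ID", "Node Class"])
    for row in node_rows:
        ws1.append(row)
    ws2 = book.create_sheet("Edges")
    ws2.append(["Source", "Relationship", "Target", "PMID",
                "Species", "Tissue", "Evidence Text"])
    for row in edge_rows:
        ws2.append(row)
    book.save(path)


def test_supplementary_importer_maps_known_relations(tmp_path):
    from rcrnet.graph import load_supplementary_table
    path = tmp_path / "supp.xlsx"
    _write_xlsx(
        path,
        [["A", "protein"], ["B", "mRNA"], ["C", "activity"]],
        [["C", "increases", "B", "12345", "human", "lung", "quote text"],
         ["A", "directlyDecreases", "B", "12346", "mouse", "", ""],
         ["A", "hasActivity", "C", "", "", "", ""]],
    )
    g, report = load_supplementary_table(path)
    c = census(g)
    assert c.total_nodes == 3
    assert c.causal_edge_count == 2
    assert c.noncausal_edge_count == 1
    assert c.unique_citation_count == 2
    assert not report.unmapped_relations


def test_supplementary_importer_reports_unmapped_relations(tmp_path):
    from rcrnet.graph import load_supplementary_table
    path = tmp_path / "supp.xlsx"
    _write_xlsx(path, [["A", "protein"], ["B", "mRNA"]],
                [["A", "correlatesWith", "B", "1", "", "", ""]])
    g, report = load_supplementary_table(path)
    assert report.unmapped_relations == {"correlatesWith": 1}
    assert census(g).causal_edge_count == 0


# -- ortholog augmentation -------------------------------------------------


def _donor_pair():
    base = CausalGraph(species="human")
    donor = CausalGraph(species="mouse")
    for nid in ("A'", "B'"):
        base.add_node(make_node(nid))
    for nid in ("A", "B"):
        donor.add_node(make_node(nid))
    donor.add_causal_edge("A", "B", 1, Evidence(citation_id="PMID:m1",
                                                species="mouse"))
    return base, donor


def test_augment_translates_edge_with_donor_evidence():
    base, donor = _donor_pair()
    out, report = augment_with_orthologs(base, donor,
                                         [("A", "A'"), ("B", "B'")])
    assert ("A'", "B'", 1) in out.causal_edges
    assert out.causal_edges[("A'", "B'", 1)].evidence[0].species == "mouse"
    assert report.n_translated == 1 and report.n_skipped_unmapped == 0


def test_augment_merges_existing_edge_without_count_change():
    base, donor = _donor_pair()
    base.add_causal_edge("A'", "B'", 1, Evidence(citation_id="PMID:h1",
                                                 species="human"))
    out, report = augment_with_orthologs(base, donor,
                                         [("A", "A'"), ("B", "B'")])
    assert len(out.causal_edges) == len(base.causal_edges)
    assert len(out.causal_edges[("A'", "B'", 1)].evidence) == 2
    assert report.n_merged == 1


def test_augment_skips_and_counts_unmapped_endpoints():
    base, donor = _donor_pair()
    out, report = augment_with_orthologs(base, donor, [("A", "A'")])
    assert report.n_skipped_unmapped == 1
    assert len(out.causal_edges) == 0


def test_augment_is_idempotent():
    base, donor = _donor_pair()
    pairs = [("A", "A'"), ("B", "B'")]
    once, _ = augment_with_orthologs(base, donor, pairs)
    twice, report = augment_with_orthologs(once, donor, pairs)
    assert twice == once
    assert report.n_translated == 0


def test_augment_many_to_many_policies():
    base, donor = _donor_pair()
    base.add_node(make_node("A2'"))
    pairs = [("A", "A'"), ("A", "A2'"), ("B", "B'")]
    out, report = augment_with_orthologs(base, donor, pairs)
    assert {("A'", "B'", 1), ("A2'", "B'", 1)} <= set(out.causal_edges)
    skipped, report2 = augment_with_orthologs(base, donor, pairs,
                                              policy="skip-ambiguous")
    assert len(skipped.causal_edges) == 0
    assert report2.n_skipped_ambiguous == 1
    with pytest.raises(ContractError):
        augment_with_orthologs(base, donor, pairs, policy="error")


# -- downstream targets ----------------------------------------------------


def test_depth1_targets_signed(toy_graph):
    targets = downstream_mrna_targets(toy_graph, "TF1")
    assert targets == {"g1": 1, "g2": -1, "g3": 1, "g4": 1, "g5": -1}


def test_opposite_sign_edges_flag_ambiguous(toy_graph):
    targets = downstream_mrna_targets(toy_graph, "K1")
    assert targets["g1"] == AMBIGUOUS
    assert targets["g2"] == 1


def test_depth1_matches_brute_force_edge_scan(toy_graph):
    for node_id in toy_graph.nodes:
        expected_signs = {}
        for e in toy_graph.causal_edges.values():
            if e.source != node_id:
                continue
            node = toy_graph.nodes[e.target]
            if node.entity_class != "mRNA":
                continue
            expected_signs.setdefault(node.gene_symbol, set()).add(e.sign)
        own = toy_graph.nodes[node_id].gene_symbol
        expected = {g: (s.pop() if len(s) == 1 else AMBIGUOUS)
                    for g, s in expected_signs.items() if g != own}
        assert downstream_mrna_targets(toy_graph, node_id) == expected


def test_depth2_sign_is_product_along_path():
    # U -(-)-> V -(+)-> m  gives m an implied sign of -1 at depth 2
    g = CausalGraph()
    g.add_node(make_node("U", "activity"))
    g.add_node(make_node("V", "activity"))
    g.add_node(make_node("m", "mRNA", base_entity="gm"))
    g.add_causal_edge("U", "V", -1, Evidence(citation_id="x"))
    g.add_causal_edge("V", "m", 1, Evidence(citation_id="y"))
    assert downstream_mrna_targets(g, "U", depth=1) == {}
    assert downstream_mrna_targets(g, "U", depth=2) == {"gm": -1}
    # conflicting two-step paths -> ambiguous
    g.add_node(make_node("W", "activity"))
    g.add_causal_edge("U", "W", 1, Evidence(citation_id="z"))
    g.add_causal_edge("W", "m", 1, Evidence(citation_id="w"))
    assert downstream_mrna_targets(g, "U", depth=2) == {"gm": AMBIGUOUS}


def test_unknown_node_raises(toy_graph):
    with pytest.raises(UnknownNodeError):
        downstream_mrna_targets(toy_graph, "nope")


# -- subgraph by tag -------------------------------------------------------


def test_subgraph_by_tag_keeps_internal_edges():
    g = CausalGraph()
    for nid, tags in [("a", {"CellCycle"}), ("b", {"CellCycle"}),
                      ("c", set()), ("d", {"Growth"})]:
        g.add_node(make_node(nid, tags=frozenset(tags)))
    g.add_causal_edge("a", "b", 1, Evidence(citation_id="1"))
    g.add_causal_edge("a", "c", 1, Evidence(citation_id="2"))
    sub = subgraph_by_tag(g, "CellCycle")
    assert set(sub.nodes) == {"a", "b"}
    assert set(sub.causal_edges) == {("a", "b", 1)}
    # tag present on some node but selecting none of the edges
    assert len(subgraph_by_tag(g, "Growth").causal_edges) == 0
    with pytest.raises(UnknownNodeError):
        subgraph_by_tag(g, "NoSuchBlock")


def test_subgraph_all_tagged_is_identity(toy_graph):
    tagged = CausalGraph(name=toy_graph.name)
    for nid, node in toy_graph.nodes.items():
        tagged.add_node(EntityNode(
            node_id=node.node_id, label=node.label,
            entity_class=node.entity_class, base_entity=node.base_entity,
            modification=node.modification, activity_kind=node.activity_kind,
            species_scope=node.species_scope, tags=frozenset({"All"}),
        ))
    for e in toy_graph.causal_edges.values():
        tagged.add_causal_edge(e.source, e.target, e.sign, e.evidence)
    for e in toy_graph.noncausal_edges:
        tagged.add_noncausal_edge(e.source, e.target, e.relation)
    sub = subgraph_by_tag(tagged, "All")
    assert set(sub.nodes) == set(tagged.nodes)
    assert set(sub.causal_edges) == set(tagged.causal_edges)
    assert sub.noncausal_edges == tagged.noncausal_edges
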