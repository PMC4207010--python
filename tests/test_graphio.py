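"""Network/gene-set IO, identifier mapping and merging."""

import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from procmod import graphio
from procmod.errors import ContractError, ParseError
from procmod.graphio import IdMapping


class TestReadInteractionTable:
    def test_empty_file_gives_empty_network(self, edge_file):
        g = graphio.read_interaction_table(edge_file([]))
        assert g.number_of_nodes() == 0 and g.number_of_edges() == 0

    def test_reciprocal_rows_collapse_to_one_undirected_edge(self, edge_file):
        g = graphio.read_interaction_table(edge_file(["A\tB", "B\tA"]))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        assert g.has_edge("A", "B")

    def test_parse_report_counts_loops_and_duplicates(self, edge_file):
        # 10 rows: 7 distinct edges, 2 duplicates of them, 1 self-loop
        rows = [
            "a\tb", "b\tc", "c\td", "d\te", "e\tf", "f\tg", "g\ta",
            "a\tb",        # duplicate
            "c\tb",        # duplicate after orientation normalization
            "h\th",        # self-loop
        ]
        g = graphio.read_interaction_table(edge_file(rows))
        assert g.number_of_edges() == 7
        assert g.graph["parse_report"] == {
            "rows": 10, "loops_dropped": 1, "duplicates_collapsed": 2,
        }

    def test_psimitab_strips_namespace_prefix(self, edge_file):
        rows = ["uniprotkb:P1\tuniprotkb:P2\textra\tcolumns"]
        g = graphio.read_interaction_table(edge_file(rows), format="psimitab")
        assert g.has_edge("P1", "P2")

    def test_comment_lines_ignored(self, edge_file):
        g = graphio.read_interaction_table(edge_file(["# header", "A\tB"]))
        assert g.number_of_edges() == 1

    @pytest.mark.parametrize("row", ["single_column", "A\t ", " \tB"])
    def test_malformed_row_raises_with_line_number(self, edge_file, row):
        with pytest.raises(ParseError, match=":2:"):
            graphio.read_interaction_table(edge_file(["A\tB", row]))


class TestGmt:
    def test_within_line_duplicates_collapse(self, edge_file):
        (pw,) = graphio.read_gmt(edge_file(["P1\tdesc\tg1\tg2\tg2"], name="x.gmt"))
        assert pw.pathway_id == "P1" and pw.genes == {"g1", "g2"}

    def test_empty_file_gives_empty_collection(self, edge_file):
        assert graphio.read_gmt(edge_file([], name="x.gmt")) == []

    def test_disjoint_sets_hand_count(self, edge_file):
        rows = ["P1\td\ta1\ta2", "P2\td\tb1\tb2\tb3", "P3\td\tc1\tc2\tc3\tc4"]
        pws = graphio.read_gmt(edge_file(rows, name="x.gmt"))
        assert len(pws) == 3
        assert len(set().union(*(p.genes for p in pws))) == 9

    def test_short_line_and_duplicate_id_rejected(self, edge_file):
        with pytest.raises(ParseError):
            graphio.read_gmt(edge_file(["P1\tonly_two_fields"], name="a.gmt"))
        with pytest.raises(ParseError, match="P1"):
            graphio.read_gmt(edge_file(["P1\td\tg1", "P1\td\tg2"], name="b.gmt"))

    def test_round_trip(self, tmp_path):
        pws = [graphio.PathwayAnnotation("P1", "one", frozenset({"a", "b"})),
               graphio.PathwayAnnotation("P2", "two", frozenset({"c"}))]
        graphio.write_gmt(pws, tmp_path / "x.gmt")
        assert graphio.read_gmt(tmp_path / "x.gmt") == pws


def path_graph(*nodes):
    g = graphio.new_network()
    g.add_nodes_from(nodes)
    for u, v in zip(nodes, nodes[1:]):
        g.add_edge(u, v)
    return g


class TestMapIds:
    def test_identity_mapping_leaves_network_unchanged(self):
        g = path_graph("a", "b", "c")
        mapping = IdMapping.identity(g.nodes())
        out = graphio.map_ids(g, mapping, policy="expand")
        assert graphio.graph_equal(out, g)

    def test_collapsing_two_path_nodes_drops_the_self_loop(self):
        # a-b-c-d-e with b,c -> X: edge b-c becomes a dropped self-loop
        g = path_graph("a", "b", "c", "d", "e")
        pairs = [("a", "a"), ("b", "X"), ("c", "X"), ("d", "d"), ("e", "e")]
        mapping = IdMapping.from_pairs(pairs, "ensembl_gene", "ensembl_gene")
        out = graphio.map_ids(g, mapping)
        assert set(out.nodes()) == {"a", "X", "d", "e"}
        assert {frozenset(e) for e in out.edges()} == {
            frozenset({"a", "X"}), frozenset({"X", "d"}), frozenset({"d", "e"}),
        }

    def test_unmapped_gene_removed_under_drop_ambiguous(self):
        mapping = IdMapping.from_pairs([("b", "b1")], "ensembl_gene", "other")
        mapped, report = graphio.map_ids(frozenset({"a", "b"}), mapping,
                                         policy="drop_ambiguous")
        assert mapped == {"b1"}
        assert report == {"mapped": 1, "dropped": 1, "expanded": 0}

    def test_ambiguous_source_dropped_vs_expanded(self):
        mapping = IdMapping.from_pairs(
            [("a", "a1"), ("a", "a2")], "ensembl_gene", "other")
        expanded, _ = graphio.map_ids(frozenset({"a"}), mapping, policy="expand")
        dropped, _ = graphio.map_ids(frozenset({"a"}), mapping, policy="drop_ambiguous")
        assert expanded == {"a1", "a2"} and dropped == frozenset()

    def test_namespace_mismatch_rejected(self):
        g = path_graph("a", "b")
        mapping = IdMapping.from_pairs([("a", "x")], "unigene_rat", "ensembl_gene")
        with pytest.raises(ContractError):
            graphio.map_ids(g, mapping)

    @settings(max_examples=30, derandomize=True)
    @given(st.data())
    def test_expand_matches_brute_force_rewiring_oracle(self, data):
        """Expansion re-wires edges to all target combinations, minus self-loops."""
        n = data.draw(st.integers(4, 20))
        edges = data.draw(st.sets(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)).filter(lambda e: e[0] != e[1]),
            max_size=30))
        g = graphio.new_network()
        g.add_nodes_from(f"n{i}" for i in range(n))
        g.add_edges_from((f"n{a}", f"n{b}") for a, b in edges)
        fanout = {f"n{i}": data.draw(st.integers(0, 2)) for i in range(n)}
        pairs = [(s, f"{s}_t{j}") for s, k in fanout.items() for j in range(k)]
        mapping = IdMapping.from_pairs(pairs, "ensembl_gene", "other")
        out = graphio.map_ids(g, mapping)

        expected_edges = set()
        for u, v in g.edges():
            for a, b in itertools.product(mapping.targets(u), mapping.targets(v)):
                if a != b:
                    expected_edges.add(frozenset({a, b}))
        assert {frozenset(e) for e in out.edges()} == expected_edges
        assert not any(u == v for u, v in out.edges())


class TestMergeNetworks:
    def test_self_merge_is_idempotent(self, k4_bridge_k4):
        merged = graphio.merge_networks([k4_bridge_k4, k4_bridge_k4])
        assert graphio.graph_equal(merged, k4_bridge_k4)

    def test_edge_union_hand_count(self):
        n1 = path_graph("a", "b", "c", "d")     # 3 edges
        n2 = path_graph("c", "d", "e", "f")     # 3 edges, shares c-d
        merged = graphio.merge_networks([n1, n2])
        assert merged.number_of_edges() == 5

    def test_merge_of_empty_list_is_empty_network(self):
        merged = graphio.merge_networks([])
        assert merged.number_of_nodes() == 0

    def test_mixed_namespaces_rejected(self):
        n1 = graphio.new_network(namespace="ensembl_gene")
        n2 = graphio.new_network(namespace="unigene_rat")
        with pytest.raises(ContractError):
            graphio.merge_networks([n1, n2])

    def test_merge_order_invariant(self, k4_bridge_k4, three_cliques):
        nets = [k4_bridge_k4, three_cliques[0], path_graph("a3", "zz")]
        reference = graphio.merge_networks(nets)
        for perm in itertools.permutations(nets):
            assert graphio.graph_equal(graphio.merge_networks(list(perm)), reference)
        # associativity up to graph equality
        left = graphio.merge_networks([graphio.merge_networks(nets[:2]), nets[2]])
        right = graphio.merge_networks([nets[0], graphio.merge_networks(nets[1:])])
        assert graphio.graph_equal(left, right)


class TestRoundTrip:
    def test_tsv_round_trip(self, tmp_path, k4_bridge_k4):
        graphio.write_interaction_table(k4_bridge_k4, tmp_path / "net.tsv")
        back = graphio.read_interaction_table(tmp_path / "net.tsv")
        assert graphio.graph_equal(back, k4_bridge_k4)

    def test_graphml_round_trip(self, tmp_path, k4_bridge_k4):
        graphio.write_graphml(k4_bridge_k4, tmp_path / "net.graphml")
        back = graphio.read_graphml(tmp_path / "net.graphml")
        assert graphio.graph_equal(back, k4_bridge_k4)

    def test_outputs_stay_simple_graphs(self, edge_file):
        rows = ["a\tb", "b\ta", "a\ta", "a\tc"]
        g = graphio.read_interaction_table(edge_file(rows))
        assert graphio.graph_equal(g, graphio.simplified(g))

    def test_mapping_table_round_trip(self, tmp_path):
        mapping = IdMapping.from_pairs(
            [("r1", "h1"), ("r1", "h2"), ("r2", "h3")], "unigene_rat", "ensembl_gene")
        graphio.write_mapping_table(mapping, tmp_path / "map.tsv")
        back = graphio.read_mapping_table(tmp_path / "map.tsv", "unigene_rat", "ensembl_gene")
        assert back.pairs == mapping.pairs
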