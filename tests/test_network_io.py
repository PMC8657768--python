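"""Graph and gene-list I/O: parsing rules, invariants, round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppirank.network_io import (
    GeneLabelSet,
    Graph,
    graph_from_edges,
    induced_largest_component,
    load_edge_list,
    load_gene_scores,
    write_edge_list,
)


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadEdgeList:
    def test_empty_file_gives_empty_graph(self, tmp_path):
        g = load_edge_list(write(tmp_path, "e.tsv", ""))
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_duplicates_and_self_loops_collapse(self, tmp_path):
        g = load_edge_list(write(tmp_path, "e.tsv", "A B\nB A\nC C\n"))
        assert g.n_nodes == 3  # C enters as an isolated node
        assert g.n_edges == 1
        assert g.node_ids == ("A", "B", "C")

    def test_comments_and_extra_columns_ignored(self, tmp_path):
        g = load_edge_list(write(tmp_path, "e.tsv", "# header\nA\tB\t0.9\nB\tC\t0.1\n"))
        assert g.n_nodes == 3 and g.n_edges == 2

    def test_short_line_reports_line_number(self, tmp_path):
        with pytest.raises(ValueError, match=":2:"):
            load_edge_list(write(tmp_path, "e.tsv", "A B\nlonely\n"))

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(OSError):
            load_edge_list(tmp_path / "nope.tsv")

    def test_first_appearance_node_order(self, tmp_path):
        g = load_edge_list(write(tmp_path, "e.tsv", "X Y\nA X\n"))
        assert g.node_ids == ("X", "Y", "A")


class TestGeneScores:
    def test_threshold_is_inclusive(self, tmp_path):
        p = write(tmp_path, "s.tsv", "gene_id\tscore\ng1\t0.05\ng2\t0.10\ng3\t0.30\n")
        labels = load_gene_scores(p, threshold=0.1)
        assert labels.positive_ids == {"g2", "g3"}

    def test_zero_threshold_keeps_all(self, tmp_path):
        p = write(tmp_path, "s.tsv", "gene_id\tscore\ng1\t0.05\ng2\t0.9\n")
        assert load_gene_scores(p, threshold=0.0).positive_ids == {"g1", "g2"}

    def test_duplicates_keep_max_score(self, tmp_path):
        p = write(tmp_path, "s.tsv", "gene_id\tscore\ng1\t0.2\ng1\t0.6\n")
        labels = load_gene_scores(p, threshold=0.1)
        assert labels.positive_ids == {"g1"}
        assert labels.scores["g1"] == pytest.approx(0.6)

    def test_non_numeric_score_names_line(self, tmp_path):
        p = write(tmp_path, "s.tsv", "gene_id\tscore\ng1\thigh\n")
        with pytest.raises(ValueError, match=":2:"):
            load_gene_scores(p)

    def test_intersect_graph_drops_missing_with_warning(self, caplog):
        g = graph_from_edges([("A", "B")])
        labels = GeneLabelSet(frozenset({"A", "Z"}), {"A": 0.5, "Z": 0.9})
        with caplog.at_level("WARNING"):
            kept = labels.intersect_graph(g)
        assert kept.positive_ids == {"A"}
        assert "dropped" in caplog.text


class TestLargestComponent:
    def test_larger_of_two_components(self):
        g = graph_from_edges([("A", "B"), ("C", "D"), ("D", "E")])
        sub = induced_largest_component(g, {"A", "B", "C", "D", "E"})
        assert set(sub.node_ids) == {"C", "D", "E"}
        assert sub.n_edges == 2

    def test_no_internal_edges_gives_single_node(self):
        g = graph_from_edges([("A", "B"), ("C", "D")])
        sub = induced_largest_component(g, {"A", "C"})  # no A-C edge
        # all candidates are size-1 components; smallest index wins
        assert sub.node_ids == ("A",)

    def test_empty_keep_gives_empty_graph(self):
        g = graph_from_edges([("A", "B")])
        sub = induced_largest_component(g, set())
        assert sub.n_nodes == 0 and sub.n_edges == 0

    def test_matches_networkx_on_random_graph(self, small_sbm):
        nx = pytest.importorskip("networkx")
        rng = np.random.Generator(np.random.PCG64(5))
        keep = set(
            np.array(small_sbm.node_ids)[
                rng.choice(small_sbm.n_nodes, size=30, replace=False)
            ]
        )
        sub = induced_largest_component(small_sbm, keep)
        G = nx.Graph()
        G.add_nodes_from(keep)
        G.add_edges_from(
            (small_sbm.node_ids[i], small_sbm.node_ids[j])
            for i, j in small_sbm.edges()
            if small_sbm.node_ids[i] in keep and small_sbm.node_ids[j] in keep
        )
        best = max(nx.connected_components(G), key=len)
        assert sub.n_nodes == len(best)


edge_lists = st.lists(
    st.tuples(st.integers(0, 12), st.integers(0, 12)), min_size=0, max_size=60
)


@given(edges=edge_lists)
@settings(max_examples=60, deadline=None)
def test_graph_invariants_hold_for_arbitrary_edge_streams(edges):
    """Self-loops and duplicate/reversed lines never violate Graph invariants."""
    g = graph_from_edges([(f"n{u}", f"n{v}") for u, v in edges])
    g.validate()
    assert g.n_edges == sum(len(a) for a in g.adjacency) // 2


@given(edges=edge_lists)
@settings(max_examples=30, deadline=None)
def test_edge_list_round_trip(tmp_path_factory, edges):
    g = graph_from_edges([(f"n{u}", f"n{v}") for u, v in edges])
    path = tmp_path_factory.mktemp("rt") / "edges.tsv"
    write_edge_list(g, path)
    g2 = load_edge_list(path)
    edge_ids = {
        frozenset((g.node_ids[i], g.node_ids[j])) for i, j in g.edges()
    }
    edge_ids2 = {
        frozenset((g2.node_ids[i], g2.node_ids[j])) for i, j in g2.edges()
    }
    assert edge_ids == edge_ids2
    # isolated nodes are not representable in a pure edge list
    non_isolated = {g.node_ids[i] for i in range(g.n_nodes) if g.degree(i)}
    assert set(g2.node_ids) == non_isolated
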