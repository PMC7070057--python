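"""Graph container, edge-list I/O, adjacency, negative sampling, splitting."""

import itertools

import numpy as np
import pytest

from mangf.man_graph import (
    EdgeListParseError,
    InsufficientNegativesError,
    MANGraph,
    ValidationError,
    load_edge_list,
    sample_negatives,
    split_folds,
    subsample_edges,
    to_adjacency,
    write_edge_list,
)


def _write(tmp_path, rows, name="edges.tsv"):
    path = tmp_path / name
    path.write_text("\n".join(rows) + "\n")
    return path


class TestLoadEdgeList:
    def test_duplicates_are_dropped(self, tmp_path):
        path = _write(tmp_path, [
            "m1\td1\tmiRNA-disease",
            "m2\td1\tmiRNA-disease",
            "m1\td1\tmiRNA-disease",
        ])
        g = load_edge_list(path)
        assert g.n_edges == 2

    def test_edges_are_canonicalized_by_global_index(self, tmp_path):
        # indices: m1=0, d1=1, m2=2 -> the second edge stores d1 first
        path = _write(tmp_path, [
            "m1\td1\tmiRNA-disease",
            "m2\td1\tmiRNA-disease",
        ])
        g = load_edge_list(path)
        pairs = {(e.head_id, e.tail_id) for e in g.positive_edges}
        assert pairs == {("m1", "d1"), ("d1", "m2")}

    def test_loader_accepts_either_endpoint_column_order(self, tmp_path):
        path = _write(tmp_path, [
            "m1\td1\tmiRNA-disease",
            "d1\tm2\tmiRNA-disease",  # disease written in the head column
        ])
        g = load_edge_list(path)
        assert g.node("m2").node_type == "miRNA"
        assert g.n_edges == 2

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = _write(tmp_path, [
            "# a comment",
            "",
            "m1\td1\tmiRNA-disease",
        ])
        assert load_edge_list(path).n_edges == 1

    def test_unknown_relation_reports_line_number(self, tmp_path):
        path = _write(tmp_path, [
            "m1\td1\tmiRNA-disease",
            "m1\td1\tmiRNA-gene",
        ])
        with pytest.raises(EdgeListParseError) as err:
            load_edge_list(path)
        assert err.value.line == 2

    def test_endpoint_type_mismatch_rejected(self, tmp_path):
        # m1 is a miRNA from row 1 but row 2 uses it as a protein endpoint
        path = _write(tmp_path, [
            "m1\td1\tmiRNA-disease",
            "m1\tp1\tprotein-protein",
        ])
        with pytest.raises(EdgeListParseError):
            load_edge_list(path)

    def test_round_trip_preserves_edge_multiset(self, tmp_path, tiny_dataset):
        g = tiny_dataset.graph
        out = tmp_path / "rt.tsv"
        write_edge_list(g, out)
        # as undirected typed pairs, the multiset survives any reload
        g2 = load_edge_list(out)
        ukey = lambda e: (frozenset((e.head_id, e.tail_id)), e.relation_type)
        assert sorted(map(hash, map(ukey, g.positive_edges))) == sorted(
            map(hash, map(ukey, g2.positive_edges))
        )
        # with node metadata the global indices (hence the canonical
        # orientation) are reproduced exactly
        meta = tmp_path / "nodes.tsv"
        meta.write_text(
            "".join(f"{n.node_id}\t{n.node_type}\n" for n in g.nodes)
        )
        g3 = load_edge_list(out, node_meta=meta)
        key = lambda e: (e.head_id, e.tail_id, e.relation_type)
        assert sorted(map(key, g.positive_edges)) == sorted(
            map(key, g3.positive_edges)
        )


class TestAdjacency:
    def test_single_edge(self):
        g = MANGraph()
        g.add_node("m1", "miRNA")
        g.add_node("d1", "disease")
        g.add_edge("m1", "d1", "miRNA-disease")
        assert to_adjacency(g).tolist() == [[0, 1], [1, 0]]

    def test_empty_edge_set_gives_zero_matrix(self):
        g = MANGraph()
        g.add_node("m1", "miRNA")
        g.add_node("d1", "disease")
        assert not to_adjacency(g).any()

    def test_triangle_row_sums(self):
        g = MANGraph()
        for i in range(3):
            g.add_node(f"p{i}", "protein")
        for a, b in itertools.combinations(range(3), 2):
            g.add_edge(f"p{a}", f"p{b}", "protein-protein")
        Y = to_adjacency(g)
        assert Y.sum(axis=0).tolist() == [2, 2, 2]

    def test_symmetric_zero_diagonal_and_edge_count(self, tiny_dataset):
        g = tiny_dataset.graph
        Y = to_adjacency(g)
        assert (Y == Y.T).all()
        assert np.trace(Y) == 0
        assert np.triu(Y).sum() == len(g.positive_pairs())

    def test_self_loops_rejected(self):
        g = MANGraph()
        g.add_node("p1", "protein")
        g.add_node("p2", "protein")
        with pytest.raises(ValidationError):
            g.add_edge("p1", "p1", "protein-protein")


class TestSampleNegatives:
    def test_balanced_sample_disjoint_from_positives(self, tiny_dataset):
        g = tiny_dataset.graph
        negs = sample_negatives(g, g.n_edges, seed=1)
        assert len(negs) == g.n_edges
        for e in negs:
            assert not g.has_pair(e.head_id, e.tail_id)
            assert e.label == "negative"

    def test_disjointness_against_bruteforce_nonedge_enumeration(self, toy_graph):
        g = toy_graph
        negs = sample_negatives(g, 4, seed=0)
        nonedges = set()
        nodes = g.nodes
        for a, b in itertools.combinations(nodes, 2):
            if not g.has_pair(a.node_id, b.node_id):
                nonedges.add(frozenset((a.node_id, b.node_id)))
        for e in negs:
            assert frozenset((e.head_id, e.tail_id)) in nonedges

    def test_stratified_counts_match_positive_proportions(self, tiny_dataset):
        g = tiny_dataset.graph
        negs = sample_negatives(g, g.n_edges, seed=2)
        for rel in {e.relation_type for e in g.positive_edges}:
            n_pos = len(g.edges_of_type(rel))
            n_neg = sum(1 for e in negs if e.relation_type == rel)
            assert abs(n_neg - n_pos) <= 1

    def test_same_seed_reproduces_sample(self, tiny_dataset):
        g = tiny_dataset.graph
        a = sample_negatives(g, 50, seed=7)
        b = sample_negatives(g, 50, seed=7)
        assert a == b

    def test_saturated_relation_type_raises(self):
        g = MANGraph()
        g.add_node("m1", "miRNA")
        g.add_node("d1", "disease")
        g.add_edge("m1", "d1", "miRNA-disease")  # complete bipartite 1x1
        with pytest.raises(InsufficientNegativesError) as err:
            sample_negatives(g, 1, seed=0)
        assert err.value.relation_type == "miRNA-disease"

    def test_endpoint_types_always_legal(self, tiny_dataset):
        g = tiny_dataset.graph
        from mangf.man_graph import RELATION_ENDPOINTS

        for e in sample_negatives(g, 60, seed=3):
            types = {g.node(e.head_id).node_type, g.node(e.tail_id).node_type}
            assert types == set(RELATION_ENDPOINTS[e.relation_type])


class TestSplitFolds:
    def test_even_split(self, tiny_dataset):
        edges = tiny_dataset.graph.positive_edges[:10]
        fs = split_folds(edges, 5, seed=0)
        assert fs.sizes == [2, 2, 2, 2, 2]

    def test_remainder_rule(self, tiny_dataset):
        edges = tiny_dataset.graph.positive_edges[:11]
        fs = split_folds(edges, 5, seed=0)
        assert sorted(fs.sizes, reverse=True) == [3, 2, 2, 2, 2]

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    def test_partition_invariants(self, tiny_dataset, k):
        g = tiny_dataset.graph
        edges = g.positive_edges + sample_negatives(g, g.n_edges, seed=4)
        fs = split_folds(edges, k, seed=1)
        folds = [set(fs.fold_edges(f)) for f in range(k)]
        assert set().union(*folds) == set(edges)
        for a, b in itertools.combinations(folds, 2):
            assert not (a & b)
        assert max(fs.sizes) - min(fs.sizes) <= 1
        # labels near-even within each fold too
        for f in folds:
            n_pos = sum(1 for e in f if e.label == "positive")
            assert abs(2 * n_pos - len(f)) <= 2

    def test_k_larger_than_edges_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            split_folds(toy_graph.positive_edges, 10, seed=0)


class TestSubsampleEdges:
    @pytest.mark.parametrize("fraction,expect", [(0.8, 8), (0.2, 2)])
    def test_train_counts(self, tiny_dataset, fraction, expect):
        g = tiny_dataset.graph.copy_with_edges(
            tiny_dataset.graph.positive_edges[:10]
        )
        train, held = subsample_edges(g, fraction, seed=0)
        assert train.n_edges == expect
        assert len(held) == 10 - expect

    def test_complement_and_node_set_preserved(self, tiny_dataset):
        g = tiny_dataset.graph
        train, held = subsample_edges(g, 0.6, seed=5)
        assert train.n_nodes == g.n_nodes
        assert set(train.positive_edges) | set(held) == set(g.positive_edges)
        assert not set(train.positive_edges) & set(held)

    def test_same_seed_same_split(self, tiny_dataset):
        g = tiny_dataset.graph
        t1, h1 = subsample_edges(g, 0.4, seed=9)
        t2, h2 = subsample_edges(g, 0.4, seed=9)
        assert h1 == h2 and set(t1.positive_edges) == set(t2.positive_edges)

    @pytest.mark.parametrize("fraction", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_bounds(self, toy_graph, fraction):
        with pytest.raises(ValueError):
            subsample_edges(toy_graph, fraction, seed=0)
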