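"""Synthetic generator: densities, determinism, signal knobs."""

import numpy as np
import pytest

from mangf import synthetic as syn
from mangf.attr_features import (
    build_disease_dag,
    contribution_map,
    disease_similarity,
    encode_rna_kmer,
)
from mangf.man_graph import RELATION_ENDPOINTS


class TestGenerateNetwork:
    def test_density_matches_binomial_expectation(self):
        spec = syn.SyntheticSpec(
            n_mirna=100, n_lncrna=100, n_protein=10, n_drug=10, n_disease=10,
            density=0.01, edge_signal=1.0, seed=0,
        )
        g, _ = syn.generate_network(spec)
        n_ml = len(g.edges_of_type("miRNA-lncRNA"))
        # 10000 pairs at p=0.01 -> ~100 +/- 3 sigma
        sigma = np.sqrt(10000 * 0.01 * 0.99)
        assert abs(n_ml - 100) <= 3 * sigma

    def test_same_seed_identical_graph(self):
        spec = syn.SyntheticSpec(n_mirna=30, n_lncrna=20, n_protein=30,
                                 n_drug=10, n_disease=15, seed=3)
        g1, l1 = syn.generate_network(spec)
        g2, l2 = syn.generate_network(spec)
        assert set(g1.positive_edges) == set(g2.positive_edges)
        for nid in l1:
            np.testing.assert_array_equal(l1[nid], l2[nid])

    def test_all_nine_relation_types_present(self, default_dataset):
        rels = {e.relation_type for e in default_dataset.graph.positive_edges}
        assert rels == set(RELATION_ENDPOINTS)

    def test_zero_signal_edges_independent_of_latents(self):
        spec = syn.SyntheticSpec(n_mirna=80, n_lncrna=80, n_protein=10,
                                 n_drug=10, n_disease=10, edge_signal=0.0,
                                 density=0.05, seed=1)
        g, lat = syn.generate_network(spec)
        idx = g.node_index()
        edges = g.edges_of_type("miRNA-lncRNA")
        dots = np.array([
            float(lat[e.head_id] @ lat[e.tail_id]) for e in edges
        ])
        # latent inner products on edges look like the population: mean ~ 0
        assert abs(dots.mean()) < 3 * dots.std() / np.sqrt(len(dots)) + 0.2


class TestGenerateSequences:
    def test_lengths_within_configured_range(self, default_dataset):
        spec = default_dataset.spec
        for n in default_dataset.graph.nodes_of_type("miRNA"):
            lo, hi = spec.mirna_length
            assert lo <= len(default_dataset.sequences[n.node_id]) <= hi

    def test_zero_signal_kmers_uncorrelated_with_latents(self):
        rng = np.random.default_rng(0)
        ids = [f"n{i}" for i in range(200)]
        lat = {i: rng.standard_normal(8) for i in ids}
        seqs = syn.generate_sequences(ids, lat, signal=0.0, seed=5,
                                      alphabet="rna", length_range=(300, 300))
        V = np.vstack([encode_rna_kmer(seqs[i]) for i in ids])
        U = np.vstack([lat[i] for i in ids])
        # correlate first latent coordinate with every k-mer frequency
        corrs = [
            abs(np.corrcoef(U[:, 0], V[:, j])[0, 1]) for j in range(64)
        ]
        assert np.mean(corrs) < 0.1

    def test_full_signal_links_kmer_similarity_to_latent_similarity(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(8)
        ids = [f"n{i}" for i in range(60)]
        # first 30 share a latent direction, last 30 are its negation
        lat = {ids[i]: (base if i < 30 else -base) + 0.1 * rng.standard_normal(8)
               for i in range(60)}
        seqs = syn.generate_sequences(ids, lat, signal=1.0, seed=6,
                                      alphabet="rna", length_range=(300, 300))
        V = np.vstack([encode_rna_kmer(seqs[i]) for i in ids])
        same = np.corrcoef(V[:30].mean(axis=0), V[1:30].mean(axis=0))[0, 1]
        cross = np.corrcoef(V[:30].mean(axis=0), V[30:].mean(axis=0))[0, 1]
        assert same > cross

    def test_protein_sequences_use_amino_alphabet(self, default_dataset):
        node = default_dataset.graph.nodes_of_type("protein")[0]
        seq = default_dataset.sequences[node.node_id]
        assert set(seq) <= set("ACDEFGHIKLMNPQRSTVWY")


class TestDiseaseForest:
    def test_depth_one_gives_disjoint_dags(self):
        codes = syn.generate_disease_dag_forest(5, depth=1, branching=3, seed=0)
        dags = []
        for i, c in enumerate(codes):
            dag = build_disease_dag(f"d{i}", c)
            contribution_map(dag, 0.5)
            dags.append(dag)
        for a in range(5):
            for b in range(a + 1, 5):
                assert disease_similarity(dags[a], dags[b]) == 0.0

    def test_sibling_similarity_is_one_third(self):
        d1 = build_disease_dag("a", ["C01.001"])
        d2 = build_disease_dag("b", ["C01.002"])
        contribution_map(d1, 0.5)
        contribution_map(d2, 0.5)
        assert disease_similarity(d1, d2) == pytest.approx(1 / 3)

    def test_row_count_and_validity(self):
        codes = syn.generate_disease_dag_forest(40, depth=3, branching=2, seed=1)
        assert len(codes) == 40
        for c in codes:
            dag = build_disease_dag("x", c)  # validates formats
            assert dag.nodes


class TestFingerprints:
    def test_bitstring_length(self, default_dataset):
        for bits in default_dataset.fingerprints.values():
            assert len(bits) == default_dataset.spec.n_bits
            assert set(bits) <= {"0", "1"}

    def test_zero_signal_bits_are_fair_coins(self):
        rng = np.random.default_rng(2)
        ids = [f"d{i}" for i in range(50)]
        lat = {i: rng.standard_normal(8) for i in ids}
        fps = syn.generate_fingerprints(ids, lat, n_bits=512, signal=0.0, seed=3)
        mean_bit = np.mean([[int(b) for b in fps[i]] for i in ids])
        assert abs(mean_bit - 0.5) < 0.02

    def test_strong_signal_bits_track_latent_sign(self):
        rng = np.random.default_rng(4)
        ids = [f"d{i}" for i in range(300)]
        lat = {i: rng.standard_normal(8) for i in ids}
        fps = syn.generate_fingerprints(ids, lat, n_bits=64, signal=5.0, seed=5)
        B = np.array([[int(b) for b in fps[i]] for i in ids])
        U = np.vstack([lat[i] for i in ids])
        W = np.random.default_rng(5 + 13).standard_normal((64, 8))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        proj = U @ W.T  # (drug, bit) projections that drive each bit
        from sklearn.metrics import roc_auc_score

        aucs = [roc_auc_score(B[:, j], proj[:, j]) for j in range(64)
                if 0 < B[:, j].sum() < len(ids)]
        assert np.mean(aucs) > 0.7

    def test_n_bits_below_latent_dim_rejected(self):
        lat = {"a": np.zeros(8)}
        with pytest.raises(ValueError):
            syn.generate_fingerprints(["a"], lat, n_bits=4, signal=1.0, seed=0)


class TestSignalKnob:
    def test_attribute_signal_knob_moves_attribute_auc_only(self, default_dataset,
                                                            default_attrs):
        """Setting s = 0 severs attribute *content* from the link structure:
        attribute-only AUC drops markedly while behavior-only AUC (driven by
        edges alone) stays high.  Attribute-only AUC does not fall all the way
        to chance because fixed per-node attribute vectors still identify
        nodes, and a transductive classifier exploits node identity/degree;
        the shuffled-label null (tested elsewhere) is the true chance floor."""
        from mangf import attr_features as af
        from mangf import evaluation as ev

        ds0 = syn.generate_dataset(syn.SyntheticSpec(attribute_signal=0.0,
                                                     seed=0))
        attrs0 = af.compute_attribute_vectors(
            ds0.graph, ds0.sequences, ds0.disease_descriptors,
            ds0.fingerprints, seed=0,
        )
        _, s_attr0 = ev.cross_validate(
            ds0.graph, attrs0, ev.ExperimentConfig(mode="attribute", seed=0)
        )
        _, s_behav0 = ev.cross_validate(
            ds0.graph, attrs0, ev.ExperimentConfig(mode="behavior", seed=0)
        )
        _, s_attr9 = ev.cross_validate(
            default_dataset.graph, default_attrs,
            ev.ExperimentConfig(mode="attribute", seed=0),
        )
        assert s_attr0["AUC"][0] < s_attr9["AUC"][0] - 0.03
        assert s_behav0["AUC"][0] > 0.8


class TestDatasetBundle:
    def test_payloads_cover_every_node(self, default_dataset):
        ds = default_dataset
        for n in ds.graph.nodes:
            if n.node_type in ("miRNA", "lncRNA", "protein"):
                assert n.node_id in ds.sequences
            elif n.node_type == "disease":
                assert ds.disease_descriptors[n.node_id]
            else:
                assert n.node_id in ds.fingerprints

    def test_write_dataset_round_trips_edges(self, tiny_dataset, tmp_path):
        from mangf.man_graph import load_edge_list

        paths = syn.write_dataset(tiny_dataset, tmp_path / "out")
        g = load_edge_list(paths["edges"], node_meta=paths["nodes"])
        assert g.n_edges == tiny_dataset.graph.n_edges
        assert g.n_nodes == tiny_dataset.graph.n_nodes
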