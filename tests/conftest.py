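"""Shared fixtures: synthetic datasets at the default study conditions plus a
small fast variant for plumbing tests."""

import numpy as np
import pytest

from mangf import attr_features as af
from mangf import synthetic as syn


@pytest.fixture(scope="session")
def default_dataset():
    """The default ~540-node synthetic network with all attribute payloads."""
    return syn.generate_dataset(syn.SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def default_attrs(default_dataset):
    ds = default_dataset
    return af.compute_attribute_vectors(
        ds.graph, ds.sequences, ds.disease_descriptors, ds.fingerprints, seed=0
    )


@pytest.fixture(scope="session")
def strong_dataset():
    """High edge signal and a denser miRNA-disease layer: the strong planted
    signal regime used by the candidate-ranking recovery tests."""
    spec = syn.SyntheticSpec(
        edge_signal=6.0,
        density={"default": 0.05, "miRNA-disease": 0.15},
        seed=0,
    )
    return syn.generate_dataset(spec)


@pytest.fixture(scope="session")
def strong_attrs(strong_dataset):
    ds = strong_dataset
    return af.compute_attribute_vectors(
        ds.graph, ds.sequences, ds.disease_descriptors, ds.fingerprints, seed=0
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    """A ~110-node network for fast plumbing and CLI tests."""
    spec = syn.SyntheticSpec(
        n_mirna=25, n_lncrna=20, n_protein=30, n_drug=15, n_disease=18,
        density=0.08, seed=11,
    )
    return syn.generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_attrs(tiny_dataset):
    ds = tiny_dataset
    return af.compute_attribute_vectors(
        ds.graph, ds.sequences, ds.disease_descriptors, ds.fingerprints, seed=0
    )


def make_toy_graph():
    """Hand-built 6-node graph covering three relation types."""
    from mangf.man_graph import MANGraph

    g = MANGraph()
    g.add_node("m1", "miRNA")
    g.add_node("m2", "miRNA")
    g.add_node("d1", "disease")
    g.add_node("d2", "disease")
    g.add_node("p1", "protein")
    g.add_node("p2", "protein")
    g.add_node("p3", "protein")  # keeps the protein-protein pair space open
    g.add_edge("m1", "d1", "miRNA-disease")
    g.add_edge("m2", "d1", "miRNA-disease")
    g.add_edge("m1", "p1", "miRNA-protein")
    g.add_edge("p1", "p2", "protein-protein")
    g.add_edge("p2", "d2", "protein-disease")
    return g


@pytest.fixture()
def toy_graph():
    return make_toy_graph()
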