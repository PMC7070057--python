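"""Node representations and the edge classifier.

A node is represented by concatenating its 64-dim attribute vector and its
64-dim behavior (graph-factorization) vector into a 128-dim profile; a
candidate edge becomes the 256-dim concatenation of its two endpoint profiles
in canonical (lower global_index first) order.  Ablation modes expose the two
halves separately.  The default classifier is a 100-tree Random Forest, with
Extra Trees, L2 Logistic Regression and Gaussian Naive Bayes as the compared
alternates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .graph_factorization import EmbeddingMatrix
from .man_graph import EdgeRecord, MANGraph, NodeRecord, RELATION_ENDPOINTS

logger = logging.getLogger(__name__)

MODES = ("attribute", "behavior", "both")


@dataclass
class NodeRepresentation:
    node_id: str
    attribute: Optional[np.ndarray] = None
    behavior: Optional[np.ndarray] = None
    mode: str = "both"

    @property
    def combined(self) -> np.ndarray:
        if self.attribute is None or self.behavior is None:
            raise ValueError(f"node '{self.node_id}' lacks a feature half")
        return np.concatenate([self.attribute, self.behavior])

    def vector(self) -> np.ndarray:
        if self.mode == "attribute":
            if self.attribute is None:
                raise ValueError(f"no attribute vector for '{self.node_id}'")
            return self.attribute
        if self.mode == "behavior":
            if self.behavior is None:
                raise ValueError(f"no behavior vector for '{self.node_id}'")
            return self.behavior
        return self.combined


def build_representation(
    node: Union[str, NodeRecord],
    attr_vectors: Optional[Mapping[str, np.ndarray]],
    embedding: Optional[EmbeddingMatrix],
    mode: str = "both",
) -> NodeRepresentation:
    """Assemble one node's representation in the requested mode."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    node_id = node.node_id if isinstance(node, NodeRecord) else node
    node_type = node.node_type if isinstance(node, NodeRecord) else "unknown type"
    attribute = behavior = None
    if mode in ("attribute", "both"):
        if attr_vectors is None or node_id not in attr_vectors:
            raise ValueError(
                f"missing attribute vector for node '{node_id}' ({node_type})"
            )
        attribute = np.asarray(attr_vectors[node_id], dtype=float)
    if mode in ("behavior", "both"):
        if embedding is None:
            raise ValueError(f"missing behavior embedding for node '{node_id}'")
        behavior = np.asarray(embedding.row(node_id), dtype=float)
    return NodeRepresentation(node_id, attribute, behavior, mode)


def build_representations(
    graph: MANGraph,
    attr_vectors: Optional[Mapping[str, np.ndarray]],
    embedding: Optional[EmbeddingMatrix],
    mode: str = "both",
) -> Dict[str, NodeRepresentation]:
    return {
        n.node_id: build_representation(n, attr_vectors, embedding, mode)
        for n in graph.nodes
    }


def pair_features(
    edge: EdgeRecord,
    representations: Mapping[str, NodeRepresentation],
    node_index: Optional[Mapping[str, int]] = None,
) -> np.ndarray:
    """Concatenated endpoint vectors in canonical order.

    If ``node_index`` is given the endpoints are re-canonicalized, so swapping
    head and tail of an undirected pair yields the identical vector.
    """
    head, tail = edge.head_id, edge.tail_id
    if node_index is not None and node_index[tail] < node_index[head]:
        head, tail = tail, head
    rh, rt = representations[head], representations[tail]
    if rh.mode != rt.mode:
        raise ValueError(
            f"representation mode mismatch: {rh.mode} vs {rt.mode}"
        )
    return np.concatenate([rh.vector(), rt.vector()])


@dataclass(frozen=True)
class PairSample:
    edge: EdgeRecord
    features: np.ndarray
    label: int


def make_pair_samples(
    edges: Sequence[EdgeRecord],
    representations: Mapping[str, NodeRepresentation],
    node_index: Optional[Mapping[str, int]] = None,
    labels: Optional[Sequence[int]] = None,
) -> List[PairSample]:
    if labels is None:
        labels = [1 if e.label == "positive" else 0 for e in edges]
    return [
        PairSample(e, pair_features(e, representations, node_index), int(y))
        for e, y in zip(edges, labels)
    ]


def samples_to_xy(samples: Sequence[PairSample]) -> Tuple[np.ndarray, np.ndarray]:
    X = np.vstack([s.features for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    return X, y


@dataclass
class ClassifierSpec:
    kind: str = "RF"  # one of RF, ET, LR, NB
    seed: int = 0
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        self.kind = self.kind.upper()
        if self.kind not in ("RF", "ET", "LR", "NB"):
            raise ValueError("kind must be one of RF, ET, LR, NB")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the classifier family with pinned, explicit defaults."""
    if spec.kind == "RF":
        kw = dict(n_estimators=100, criterion="gini", max_depth=None,
                  random_state=spec.seed)
        kw.update(spec.params)
        return RandomForestClassifier(**kw)
    if spec.kind == "ET":
        kw = dict(n_estimators=100, criterion="gini", max_depth=None,
                  random_state=spec.seed)
        kw.update(spec.params)
        return ExtraTreesClassifier(**kw)
    if spec.kind == "LR":
        # L2 penalty (the library default), unit regularization strength
        kw = dict(C=1.0, max_iter=1000, random_state=spec.seed)
        kw.update(spec.params)
        return LogisticRegression(**kw)
    kw = dict(spec.params)
    return GaussianNB(**kw)


def train_classifier(
    samples: Union[Sequence[PairSample], Tuple[np.ndarray, np.ndarray]],
    spec: ClassifierSpec,
):
    """Fit the edge classifier on labeled pair samples (both classes required)."""
    if isinstance(samples, tuple):
        X, y = samples
    else:
        X, y = samples_to_xy(samples)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = make_classifier(spec)
    clf.fit(X, y)
    return clf


def predict_scores(model, pairs) -> np.ndarray:
    """Probability of the positive class for each candidate pair."""
    if isinstance(pairs, np.ndarray):
        X = np.atleast_2d(pairs)
    else:
        X, _ = samples_to_xy(pairs)
    n_expected = getattr(model, "n_features_in_", None)
    if n_expected is not None and X.shape[1] != n_expected:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model expects {n_expected}"
        )
    proba = model.predict_proba(X)
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    return proba[:, pos_col]


def rank_candidates(
    model,
    anchor: str,
    candidates: Sequence[str],
    representations: Mapping[str, NodeRepresentation],
    node_index: Optional[Mapping[str, int]] = None,
    graph: Optional[MANGraph] = None,
    relation_type: str = "miRNA-disease",
) -> List[Tuple[str, float]]:
    """Score anchor-candidate pairs and sort descending (ties: lexicographic).

    If ``graph`` is given, candidates whose node type cannot legally pair
    with the anchor under any relation type are dropped.
    """
    if graph is not None:
        anchor_type = graph.node(anchor).node_type
        legal = {
            frozenset(p) for p in RELATION_ENDPOINTS.values()
        }
        candidates = [
            c for c in candidates
            if frozenset((anchor_type, graph.node(c).node_type)) in legal
        ]
    if not candidates:
        warnings.warn(f"no legal candidates for anchor '{anchor}'", stacklevel=2)
        return []
    feats = []
    for c in candidates:
        edge = EdgeRecord(anchor, c, relation_type=relation_type)
        feats.append(pair_features(edge, representations, node_index))
    scores = predict_scores(model, np.vstack(feats))
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [(c, float(s)) for c, s in ranked]


def write_predictions(path, rows: Sequence[Tuple[str, str, str, float]]) -> None:
    """Predictions TSV ``head_id  tail_id  relation_type  score``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# head_id\ttail_id\trelation_type\tscore\n")
        for head, tail, rel, score in rows:
            fh.write(f"{head}\t{tail}\t{rel}\t{score:.6f}\n")
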