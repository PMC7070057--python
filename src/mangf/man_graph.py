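"""Data model and I/O for the heterogeneous Molecular Associations Network (MAN).

A MAN joins five kinds of biomedical entities (miRNA, lncRNA, protein, drug,
disease) through nine undirected relation types (miRNA–disease, drug–protein,
protein–protein, ...).  This module owns the typed graph container, edge-list
I/O, adjacency construction, type-stratified negative sampling, k-fold edge
splitting, and edge subsampling for training-proportion experiments.

Edges are undirected and stored canonically with the endpoint of lower
``global_index`` first; self-loops and duplicate (head, tail, relation) rows
are rejected/deduplicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

NODE_TYPES = ("miRNA", "lncRNA", "protein", "drug", "disease")

#: The nine legal relation types and their endpoint node types, in the order
#: ``"<head_type>-<tail_type>"`` as written in edge-list files.
RELATION_ENDPOINTS: Dict[str, Tuple[str, str]] = {
    "miRNA-lncRNA": ("miRNA", "lncRNA"),
    "miRNA-disease": ("miRNA", "disease"),
    "miRNA-protein": ("miRNA", "protein"),
    "lncRNA-disease": ("lncRNA", "disease"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "protein-disease": ("protein", "disease"),
    "drug-protein": ("drug", "protein"),
    "drug-disease": ("drug", "disease"),
    "protein-protein": ("protein", "protein"),
}

RELATION_TYPES = tuple(RELATION_ENDPOINTS)


class EdgeListParseError(ValueError):
    """Raised on malformed edge-list rows; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """Raised when node/edge typing constraints are violated."""


class InsufficientNegativesError(RuntimeError):
    """Raised when a relation type's non-edge space is exhausted."""

    def __init__(self, relation_type: str, requested: int, available: int):
        self.relation_type = relation_type
        super().__init__(
            f"cannot sample {requested} negatives of type '{relation_type}': "
            f"only {available} unlinked pairs available"
        )


@dataclass
class NodeRecord:
    node_id: str
    node_type: str
    global_index: int
    attribute_payload: Optional[object] = None

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise ValidationError(f"unknown node type '{self.node_type}'")


@dataclass(frozen=True)
class EdgeRecord:
    """An undirected typed edge, canonical (head has lower global_index)."""

    head_id: str
    tail_id: str
    relation_type: str
    label: str = "positive"

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.head_id, self.tail_id)


class MANGraph:
    """Typed undirected multigraph of biomolecule relationships.

    Nodes carry a dense 0-based ``global_index`` in insertion order; edges are
    keyed by ``(head_id, tail_id, relation_type)`` after canonicalization.
    The same node pair may appear under two relation types (both are kept as
    typed edges) but contributes a single 1 to the 0/1 adjacency matrix.
    """

    def __init__(self):
        self._nodes: Dict[str, NodeRecord] = {}
        self._edges: Dict[Tuple[str, str, str], EdgeRecord] = {}
        self._pairs: Set[Tuple[int, int]] = set()

    # -- nodes ------------------------------------------------------------
    def add_node(self, node_id: str, node_type: str, payload=None) -> NodeRecord:
        existing = self._nodes.get(node_id)
        if existing is not None:
            if existing.node_type != node_type:
                raise ValidationError(
                    f"node '{node_id}' declared as both "
                    f"'{existing.node_type}' and '{node_type}'"
                )
            if payload is not None:
                existing.attribute_payload = payload
            return existing
        rec = NodeRecord(node_id, node_type, len(self._nodes), payload)
        self._nodes[node_id] = rec
        return rec

    def node(self, node_id: str) -> NodeRecord:
        return self._nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    @property
    def nodes(self) -> List[NodeRecord]:
        return sorted(self._nodes.values(), key=lambda n: n.global_index)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def node_index(self) -> Dict[str, int]:
        return {nid: rec.global_index for nid, rec in self._nodes.items()}

    def nodes_of_type(self, node_type: str) -> List[NodeRecord]:
        return [n for n in self.nodes if n.node_type == node_type]

    # -- edges ------------------------------------------------------------
    def _canonical(self, a: str, b: str) -> Tuple[str, str]:
        ia, ib = self._nodes[a].global_index, self._nodes[b].global_index
        return (a, b) if ia < ib else (b, a)

    def add_edge(self, a: str, b: str, relation_type: str) -> bool:
        """Add a positive edge; returns False if it was a duplicate."""
        if relation_type not in RELATION_ENDPOINTS:
            raise ValidationError(f"unknown relation type '{relation_type}'")
        if a == b:
            raise ValidationError(f"self-loop on '{a}' not allowed")
        for nid in (a, b):
            if nid not in self._nodes:
                raise ValidationError(f"edge references undeclared node '{nid}'")
        ta, tb = self._nodes[a].node_type, self._nodes[b].node_type
        want = set(RELATION_ENDPOINTS[relation_type])
        if {ta, tb} != want:
            raise ValidationError(
                f"edge ({a}:{ta}, {b}:{tb}) illegal for relation "
                f"'{relation_type}' (expects {sorted(want)})"
            )
        head, tail = self._canonical(a, b)
        key = (head, tail, relation_type)
        if key in self._edges:
            return False
        self._edges[key] = EdgeRecord(head, tail, relation_type)
        i, j = self._nodes[head].global_index, self._nodes[tail].global_index
        self._pairs.add((i, j))
        return True

    @property
    def positive_edges(self) -> List[EdgeRecord]:
        return list(self._edges.values())

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def edges_of_type(self, relation_type: str) -> List[EdgeRecord]:
        return [e for e in self._edges.values() if e.relation_type == relation_type]

    def positive_pairs(self) -> Set[Tuple[int, int]]:
        """Index pairs (i<j) linked under *any* relation type."""
        return set(self._pairs)

    def has_pair(self, a: str, b: str) -> bool:
        i, j = self._nodes[a].global_index, self._nodes[b].global_index
        return (min(i, j), max(i, j)) in self._pairs

    def edge_index_arrays(
        self, edges: Optional[Sequence[EdgeRecord]] = None
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Distinct node-index pairs of ``edges`` (default: all positives)."""
        if edges is None:
            edges = self.positive_edges
        idx = self.node_index()
        seen: Set[Tuple[int, int]] = set()
        for e in edges:
            seen.add((idx[e.head_id], idx[e.tail_id]))
        if not seen:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        arr = np.array(sorted(seen), dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def copy_with_edges(self, edges: Iterable[EdgeRecord]) -> "MANGraph":
        """Same node set (and indices), different edge set."""
        g = MANGraph()
        for n in self.nodes:
            g.add_node(n.node_id, n.node_type, n.attribute_payload)
        for e in edges:
            g.add_edge(e.head_id, e.tail_id, e.relation_type)
        return g


def to_adjacency(graph: MANGraph, sparse: bool = False):
    """Symmetric 0/1 adjacency matrix Y with zero diagonal.

    A node pair linked under several relation types contributes a single 1.
    """
    n = graph.n_nodes
    heads, tails = graph.edge_index_arrays()
    data = np.ones(len(heads), dtype=np.int8)
    mat = sp.coo_matrix(
        (np.concatenate([data, data]),
         (np.concatenate([heads, tails]), np.concatenate([tails, heads]))),
        shape=(n, n),
    ).tocsr()
    mat.data = np.minimum(mat.data, 1).astype(np.int8)
    if sparse:
        return mat
    return mat.toarray()


def load_edge_list(path, node_meta=None) -> MANGraph:
    """Read a TSV edge list ``head_id  tail_id  relation_type`` into a MANGraph.

    ``#`` comment lines and blank lines are ignored.  Node types are inferred
    from the relation name (head column = first endpoint type as written);
    an optional node-metadata TSV ``node_id  node_type  payload_ref`` may
    pre-declare nodes.  Duplicate rows are dropped with a logged count.
    """
    graph = MANGraph()
    if node_meta is not None:
        with open(node_meta, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise EdgeListParseError(
                        "node metadata needs >=2 columns", lineno
                    )
                payload = parts[2] if len(parts) > 2 else None
                graph.add_node(parts[0], parts[1], payload)

    dupes = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EdgeListParseError("expected >=3 tab-separated columns", lineno)
            head, tail, rel = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if rel not in RELATION_ENDPOINTS:
                raise EdgeListParseError(f"unknown relation type '{rel}'", lineno)
            t_head, t_tail = RELATION_ENDPOINTS[rel]
            # columns may arrive in either endpoint order; use already-known
            # node types to disambiguate, defaulting to the relation-name order
            if t_head != t_tail:
                th = graph.node(head).node_type if head in graph else None
                tt = graph.node(tail).node_type if tail in graph else None
                straight = th in (None, t_head) and tt in (None, t_tail)
                swapped = th in (None, t_tail) and tt in (None, t_head)
                if swapped and not straight:
                    t_head, t_tail = t_tail, t_head
            try:
                if head not in graph:
                    graph.add_node(head, t_head)
                if tail not in graph:
                    graph.add_node(tail, t_tail)
                if not graph.add_edge(head, tail, rel):
                    dupes += 1
            except ValidationError as exc:
                raise EdgeListParseError(str(exc), lineno) from exc

    n_typed = graph.n_edges
    n_pairs = len(graph.positive_pairs())
    logger.info(
        "loaded %d typed edges over %d nodes (%d duplicate rows dropped; "
        "%d distinct node pairs, %d pairs shared across relation types)",
        n_typed, graph.n_nodes, dupes, n_pairs, n_typed - n_pairs,
    )
    return graph


def write_edge_list(graph: MANGraph, path) -> None:
    """Write the canonical edge multiset as TSV (round-trips with the loader).

    Columns follow the relation name's endpoint order so the file stays
    unambiguous for type inference; the loader re-canonicalizes on read.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# head_id\ttail_id\trelation_type\n")
        for e in graph.positive_edges:
            ta, _ = RELATION_ENDPOINTS[e.relation_type]
            a, b = e.head_id, e.tail_id
            if graph.node(a).node_type != ta:
                a, b = b, a
            fh.write(f"{a}\t{b}\t{e.relation_type}\n")


def _pair_space(graph: MANGraph, relation_type: str) -> int:
    ta, tb = RELATION_ENDPOINTS[relation_type]
    na = len(graph.nodes_of_type(ta))
    nb = len(graph.nodes_of_type(tb))
    if ta == tb:
        return na * (na - 1) // 2
    return na * nb


def sample_negatives(
    graph: MANGraph,
    count: int,
    seed: int,
    relation_types: Optional[Sequence[str]] = None,
    exclude_nodes: Optional[Set[str]] = None,
) -> List[EdgeRecord]:
    """Draw ``count`` unlinked node pairs as negative samples.

    Sampling is stratified by relation type: each type receives negatives in
    proportion to its share of positive edges (largest-remainder rounding), and
    endpoints are drawn uniformly from nodes of the legal types.  A sampled
    pair is rejected if it is linked under *any* relation type, is a self-loop,
    repeats an already-drawn negative, or touches ``exclude_nodes``.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    exclude_nodes = exclude_nodes or set()
    rng = np.random.default_rng(seed)

    positives = graph.positive_edges
    if relation_types is None:
        relation_types = [r for r in RELATION_TYPES
                          if any(e.relation_type == r for e in positives)]
    pos_counts = {r: sum(1 for e in positives if e.relation_type == r)
                  for r in relation_types}
    total_pos = sum(pos_counts.values())
    if total_pos == 0:
        raise ValueError("graph has no positive edges of the requested types")

    # largest-remainder allocation of `count` across relation types
    raw = {r: count * pos_counts[r] / total_pos for r in relation_types}
    quota = {r: int(np.floor(raw[r])) for r in relation_types}
    short = count - sum(quota.values())
    for r in sorted(relation_types, key=lambda r: (raw[r] - quota[r]), reverse=True):
        if short <= 0:
            break
        quota[r] += 1
        short -= 1

    linked = graph.positive_pairs()
    idx = graph.node_index()
    out: List[EdgeRecord] = []
    drawn: Set[Tuple[int, int]] = set()

    for rel in relation_types:
        need = quota[rel]
        if need == 0:
            continue
        ta, tb = RELATION_ENDPOINTS[rel]
        cand_a = [n.node_id for n in graph.nodes_of_type(ta)
                  if n.node_id not in exclude_nodes]
        cand_b = [n.node_id for n in graph.nodes_of_type(tb)
                  if n.node_id not in exclude_nodes]
        # exact availability check against brute-force pair enumeration sizes
        if ta == tb:
            space = len(cand_a) * (len(cand_a) - 1) // 2
        else:
            space = len(cand_a) * len(cand_b)
        linked_in_space = sum(
            1 for (i, j) in linked
            if {graph.nodes[i].node_type, graph.nodes[j].node_type}
            == set(RELATION_ENDPOINTS[rel])
            and graph.nodes[i].node_id not in exclude_nodes
            and graph.nodes[j].node_id not in exclude_nodes
        )
        available = space - linked_in_space
        if need > available:
            raise InsufficientNegativesError(rel, need, available)

        got = 0
        while got < need:
            a = cand_a[rng.integers(len(cand_a))]
            b = cand_b[rng.integers(len(cand_b))]
            if a == b:
                continue
            i, j = idx[a], idx[b]
            key = (min(i, j), max(i, j))
            if key in linked or key in drawn:
                continue
            drawn.add(key)
            head, tail = (a, b) if i < j else (b, a)
            out.append(EdgeRecord(head, tail, rel, label="negative"))
            got += 1

    logger.info("sampled %d negatives across %d relation types (seed=%d)",
                len(out), len([r for r in relation_types if quota[r]]), seed)
    return out


@dataclass
class FoldSplit:
    k: int
    assignments: Dict[EdgeRecord, int]
    seed: int

    def fold_edges(self, fold: int) -> List[EdgeRecord]:
        return [e for e, f in self.assignments.items() if f == fold]

    @property
    def sizes(self) -> List[int]:
        counts = [0] * self.k
        for f in self.assignments.values():
            counts[f] += 1
        return counts


def split_folds(edges: Sequence[EdgeRecord], k: int, seed: int) -> FoldSplit:
    """Partition labeled edges into k near-equal folds, stratified by label.

    Positives and negatives are each shuffled and dealt round-robin with a
    single rolling counter, so per-label and total fold sizes all differ by
    at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(edges) < k:
        raise ValueError(f"cannot split {len(edges)} edges into {k} folds")
    rng = np.random.default_rng(seed)
    pos = [e for e in edges if e.label == "positive"]
    neg = [e for e in edges if e.label != "positive"]
    ordered: List[EdgeRecord] = []
    for group in (pos, neg):
        perm = rng.permutation(len(group))
        ordered.extend(group[i] for i in perm)
    assignments = {e: i % k for i, e in enumerate(ordered)}
    return FoldSplit(k=k, assignments=assignments, seed=seed)


def subsample_edges(
    graph: MANGraph, fraction: float, seed: int
) -> Tuple[MANGraph, List[EdgeRecord]]:
    """Keep ``round(fraction * |E|)`` edges as a training graph.

    The node set is unchanged (nodes may become isolated); the held-out
    complement is returned alongside the training graph.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    edges = graph.positive_edges
    m = len(edges)
    n_train = int(round(fraction * m))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    train = [edges[i] for i in perm[:n_train]]
    held = [edges[i] for i in perm[n_train:]]
    return graph.copy_with_edges(train), held
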