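"""Graph Factorization (GF) behavior embeddings via sequential SGD.

Every node i gets a rank-r factor row Z_i minimizing

    f(Y, Z, lambda) = 1/2 sum_{(i,j) in E} (Y_ij - <Z_i, Z_j>)^2
                      + lambda/2 sum_i ||Z_i||^2

where Y is the 0/1 adjacency of the (training) network and each undirected
edge is counted once.  Training visits edges in a seeded shuffled order with
learning rate eta = 1/sqrt(t) for a global step counter t that is never
reset; both endpoint rows of an edge are updated symmetrically from their
pre-update values.  Training stops when the squared Frobenius change of Z
between epochs drops to ``epsilon`` or after ``max_epochs``.

The regularizer enters the update in the descent direction (-lambda * Z_row),
consistent with the gradient of f.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .man_graph import MANGraph

logger = logging.getLogger(__name__)

try:  # optional JIT of the inner edge loop
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - environment dependent
    _HAVE_NUMBA = False


@dataclass
class GFConfig:
    rank: int = 64
    lam: float = 0.01
    epsilon: float = 1e-4
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class EmbeddingMatrix:
    Z: np.ndarray                       # (n_nodes, rank)
    node_ids: Optional[List[str]]       # row <-> node mapping (None if indexed)
    log: List[Dict[str, float]] = field(default_factory=list)
    converged: bool = False
    epochs_run: int = 0

    def row(self, node_id: str) -> np.ndarray:
        if self.node_ids is None:
            raise ValueError("embedding has no node-id mapping")
        return self.Z[self._index()[node_id]]

    def _index(self) -> Dict[str, int]:
        if not hasattr(self, "_idx_cache"):
            self._idx_cache = {nid: i for i, nid in enumerate(self.node_ids)}
        return self._idx_cache


def gf_loss(
    edges: Iterable[Tuple[int, int, float]], Z: np.ndarray, lam: float
) -> float:
    """Squared reconstruction error plus L2 penalty (each edge counted once)."""
    edges = list(edges)
    total = 0.0
    if edges:
        arr = np.asarray(edges, dtype=float)
        i = arr[:, 0].astype(int)
        j = arr[:, 1].astype(int)
        y = arr[:, 2]
        dots = np.einsum("ij,ij->i", Z[i], Z[j])
        total += 0.5 * float(np.sum((y - dots) ** 2))
    total += 0.5 * lam * float(np.sum(Z ** 2))
    return total


def gf_gradient(
    Z: np.ndarray,
    i: int,
    incident: Sequence[Tuple[int, float]],
    lam: float,
) -> np.ndarray:
    """Gradient of the loss w.r.t. row i: -sum_j (Y_ij - <Z_i,Z_j>) Z_j + lam Z_i."""
    grad = lam * Z[i].copy()
    for j, y in incident:
        grad -= (y - float(Z[i] @ Z[j])) * Z[j]
    return grad


def sgd_step(
    Z: np.ndarray, edge: Tuple[int, int, float], eta: float, lam: float
) -> np.ndarray:
    """One stochastic update for an edge; both endpoint rows move symmetrically.

    Each row steps along the negative partial gradient contributed by this
    edge, using the other row's pre-update value.
    """
    if eta <= 0:
        raise ValueError("eta must be > 0")
    i, j, y = edge
    zi = Z[i].copy()
    zj = Z[j].copy()
    res = y - float(zi @ zj)
    Z[i] = zi + eta * (res * zj - lam * zi)
    Z[j] = zj + eta * (res * zi - lam * zj)
    if not np.all(np.isfinite(Z[i])) or not np.all(np.isfinite(Z[j])):
        raise RuntimeError("non-finite embedding update")
    return Z


def _epoch_update_numpy(Z, heads, tails, ys, t, lam):
    for e in range(heads.shape[0]):
        i = int(heads[e])
        j = int(tails[e])
        eta = 1.0 / math.sqrt(t)
        t += 1
        zi = Z[i].copy()
        zj = Z[j].copy()
        res = ys[e] - float(zi @ zj)
        Z[i] = zi + eta * (res * zj - lam * zi)
        Z[j] = zj + eta * (res * zi - lam * zj)
    return t


if _HAVE_NUMBA:

    @_njit
    def _epoch_update_numba(Z, heads, tails, ys, t, lam):  # pragma: no cover
        r = Z.shape[1]
        for e in range(heads.shape[0]):
            i = heads[e]
            j = tails[e]
            eta = 1.0 / math.sqrt(t)
            t += 1
            dot = 0.0
            for a in range(r):
                dot += Z[i, a] * Z[j, a]
            res = ys[e] - dot
            for a in range(r):
                zi = Z[i, a]
                zj = Z[j, a]
                Z[i, a] = zi + eta * (res * zj - lam * zi)
                Z[j, a] = zj + eta * (res * zi - lam * zj)
        return t

    _epoch_update = _epoch_update_numba
else:
    _epoch_update = _epoch_update_numpy


def factorize_edges(
    n_nodes: int,
    heads: np.ndarray,
    tails: np.ndarray,
    config: GFConfig,
    weights: Optional[np.ndarray] = None,
) -> EmbeddingMatrix:
    """Factorize an edge set given as index arrays (rows have no id mapping)."""
    m = len(heads)
    if m == 0:
        raise ValueError("cannot factorize an empty edge set")
    heads = np.asarray(heads, dtype=np.int64)
    tails = np.asarray(tails, dtype=np.int64)
    ys = (np.ones(m) if weights is None else np.asarray(weights, dtype=float))

    r = config.rank
    rng = np.random.default_rng(config.seed)
    # independent stream for edge ordering so the visit schedule depends only
    # on the edge set, not on how many (possibly isolated) nodes exist
    order_rng = np.random.default_rng([config.seed, 1])
    scale = 0.5 / math.sqrt(r)
    Z = rng.uniform(-scale, scale, size=(n_nodes, r))

    edge_list = list(zip(heads.tolist(), tails.tolist(), ys.tolist()))
    initial = gf_loss(edge_list, Z, config.lam)
    emb = EmbeddingMatrix(Z=Z, node_ids=None)
    emb.log.append({"epoch": 0, "loss": initial, "frob_change": float("nan")})

    t = 1
    for epoch in range(1, config.max_epochs + 1):
        z_prev = Z.copy()
        order = order_rng.permutation(m)
        t = _epoch_update(Z, heads[order], tails[order], ys[order], t, config.lam)
        if not np.all(np.isfinite(Z)):
            raise RuntimeError(f"non-finite embedding at epoch {epoch}")
        loss = gf_loss(edge_list, Z, config.lam)
        frob = float(np.sum((Z - z_prev) ** 2))
        emb.log.append({"epoch": epoch, "loss": loss, "frob_change": frob})
        emb.epochs_run = epoch
        if loss > 10.0 * initial and initial > 0:
            raise RuntimeError(
                f"divergence: loss {loss:.4g} exceeds 10x initial {initial:.4g}"
            )
        if frob <= config.epsilon:
            emb.converged = True
            break
    logger.info(
        "GF: %d nodes, %d edges, rank %d -> %d epochs, converged=%s, loss %.4g",
        n_nodes, m, r, emb.epochs_run, emb.converged, emb.log[-1]["loss"],
    )
    return emb


def factorize(graph: MANGraph, config: GFConfig) -> EmbeddingMatrix:
    """Behavior embedding of a (training) MANGraph.

    The caller must pass the training graph only: edges under evaluation are
    stripped before calling so no label information leaks into the embedding.
    Isolated nodes keep their random initial rows.
    """
    heads, tails = graph.edge_index_arrays()
    emb = factorize_edges(graph.n_nodes, heads, tails, config)
    emb.node_ids = [n.node_id for n in graph.nodes]
    return emb


def write_embedding(emb: EmbeddingMatrix, path) -> None:
    """Persist as TSV ``node_id  v1 ... vr``."""
    ids = emb.node_ids or [str(i) for i in range(emb.Z.shape[0])]
    with open(path, "w", encoding="utf-8") as fh:
        for nid, row in zip(ids, emb.Z):
            fh.write(nid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_training_log(emb: EmbeddingMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("epoch,loss,frob_change\n")
        for rec in emb.log:
            fh.write(f"{rec['epoch']},{rec['loss']},{rec['frob_change']}\n")
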