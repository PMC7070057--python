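"""Seeded synthetic molecular association networks with planted structure.

Every node receives a latent vector u ~ N(0, I_d).  Edges of each of the nine
relation types are Bernoulli draws with probability
``sigma(a * <u_i, u_j> + b_rel)`` where the intercept ``b_rel`` is calibrated
by bisection so the realized pair-space density matches the target.  Matching
attribute payloads are emitted for every node type: sequences whose 3-mer
emission distribution is tilted by a fixed linear map of the latent vector
(signal strength s blends against a uniform background), MeSH-style disease
tree numbers drawn from a random forest of descriptors, and fingerprint bits
whose on-probability follows random projections of the latent vector.

Because the latent dimension (default 8) is far below the embedding rank
(64), the factorization can always represent the planted structure; setting
the attribute signal to 0 disconnects attributes from the link structure
while leaving the behavior signal untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .attr_features import PROTEIN_GROUPS, REDUCED_ALPHABET, RNA_ALPHABET
from .man_graph import MANGraph, RELATION_ENDPOINTS, RELATION_TYPES

_TYPE_PREFIX = {
    "miRNA": "mir", "lncRNA": "lnc", "protein": "pro",
    "drug": "dru", "disease": "dis",
}

_GROUP_MEMBERS: Dict[str, str] = {}
for _res, _grp in PROTEIN_GROUPS.items():
    _GROUP_MEMBERS[_grp] = _GROUP_MEMBERS.get(_grp, "") + _res


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic network (defaults ~540 nodes)."""

    n_mirna: int = 120
    n_lncrna: int = 100
    n_protein: int = 150
    n_drug: int = 80
    n_disease: int = 90
    latent_dim: int = 8
    # scalar or {relation_type: value} with "default" fallback
    density: object = 0.05         # per-relation edge density target
    edge_signal: object = 2.0      # logistic slope a on latent inner products;
                                   # oracle (true-latent) AUC ~0.96, the regime
                                   # curated association networks sit in
    attribute_signal: float = 0.9  # s in [0,1]: 0 = pure noise attributes
    noise_rate: float = 0.0        # mix-in weight of latent-independent edges
    n_bits: int = 1024             # fingerprint length
    mirna_length: Tuple[int, int] = (60, 90)
    lncrna_length: Tuple[int, int] = (200, 400)
    protein_length: Tuple[int, int] = (100, 300)
    dag_depth: int = 4
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self):
        for rel in RELATION_TYPES:
            if not (0.0 < self.density_of(rel) < 1.0):
                raise ValueError("density must lie in (0, 1)")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0.0 <= self.attribute_signal <= 1.0):
            raise ValueError("attribute_signal must lie in [0, 1]")

    def _per_relation(self, value, rel: str) -> float:
        if isinstance(value, Mapping):
            return float(value.get(rel, value.get("default")))
        return float(value)

    def density_of(self, rel: str) -> float:
        return self._per_relation(self.density, rel)

    def edge_signal_of(self, rel: str) -> float:
        return self._per_relation(self.edge_signal, rel)

    @property
    def type_counts(self) -> Dict[str, int]:
        return {
            "miRNA": self.n_mirna, "lncRNA": self.n_lncrna,
            "protein": self.n_protein, "drug": self.n_drug,
            "disease": self.n_disease,
        }


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _calibrate_intercept(logits: np.ndarray, density: float) -> float:
    """Bisect b so that mean(sigmoid(logits + b)) == density."""
    lo, hi = -50.0, 50.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _sigmoid(logits + mid).mean() < density:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_network(spec: SyntheticSpec) -> Tuple[MANGraph, Dict[str, np.ndarray]]:
    """Planted low-rank network plus the ground-truth latent factors."""
    rng = np.random.default_rng(spec.seed)
    graph = MANGraph()
    ids_by_type: Dict[str, List[str]] = {}
    for node_type in _TYPE_PREFIX:
        count = spec.type_counts[node_type]
        ids = [f"{_TYPE_PREFIX[node_type]}{i:04d}" for i in range(count)]
        ids_by_type[node_type] = ids
        for nid in ids:
            graph.add_node(nid, node_type)
    all_ids = [n.node_id for n in graph.nodes]
    U = rng.standard_normal((len(all_ids), spec.latent_dim))
    latents = {nid: U[i] for i, nid in enumerate(all_ids)}
    idx = graph.node_index()

    for rel in RELATION_TYPES:
        ta, tb = RELATION_ENDPOINTS[rel]
        a_ids, b_ids = ids_by_type[ta], ids_by_type[tb]
        Ua = np.vstack([latents[i] for i in a_ids])
        Ub = np.vstack([latents[i] for i in b_ids])
        gram = spec.edge_signal_of(rel) * (Ua @ Ub.T)
        if ta == tb:
            iu, ju = np.triu_indices(len(a_ids), k=1)
            logits = gram[iu, ju]
            pairs = [(a_ids[i], a_ids[j]) for i, j in zip(iu, ju)]
        else:
            logits = gram.ravel()
            pairs = [(ai, bj) for ai in a_ids for bj in b_ids]
        density = spec.density_of(rel)
        b_rel = _calibrate_intercept(logits, density)
        prob = (1.0 - spec.noise_rate) * _sigmoid(logits + b_rel) \
            + spec.noise_rate * density
        draws = rng.random(len(pairs)) < prob
        for (x, y), hit in zip(pairs, draws):
            if hit:
                graph.add_edge(x, y, rel)
    return graph, latents


def _tilted_kmer_distribution(u: np.ndarray, tilt: np.ndarray, s: float) -> np.ndarray:
    logits = tilt @ u
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return (1.0 - s) / len(p) + s * p


def generate_sequences(
    node_ids: Sequence[str],
    latents: Mapping[str, np.ndarray],
    signal: float,
    seed: int,
    alphabet: str = "rna",
    length_range: Tuple[int, int] = (60, 90),
) -> Dict[str, str]:
    """Sequences whose 3-mer bag is tilted by the node's latent vector.

    The tilt map (64 x d) is a fixed seeded Gaussian matrix shared by all
    nodes of the call; at signal 0 the emission distribution is uniform.
    """
    rng = np.random.default_rng(seed)
    d = len(next(iter(latents.values())))
    tilt = np.random.default_rng(seed + 7).standard_normal((64, d))

    if alphabet == "rna":
        import itertools
        kmers = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=3)]
    elif alphabet == "protein":
        import itertools
        kmers = ["".join(p) for p in itertools.product(REDUCED_ALPHABET, repeat=3)]
    else:
        raise ValueError("alphabet must be 'rna' or 'protein'")

    out: Dict[str, str] = {}
    lo, hi = length_range
    for nid in node_ids:
        p = _tilted_kmer_distribution(latents[nid], tilt, signal)
        length = int(rng.integers(lo, hi + 1))
        n_kmers = math.ceil(length / 3)
        chosen = rng.choice(len(kmers), size=n_kmers, p=p)
        seq = "".join(kmers[c] for c in chosen)[:length]
        if alphabet == "protein":
            seq = "".join(
                _GROUP_MEMBERS[g][rng.integers(len(_GROUP_MEMBERS[g]))]
                for g in seq
            )
        out[nid] = seq
    return out


def generate_disease_dag_forest(
    n_diseases: int,
    depth: int = 4,
    branching: int = 3,
    seed: int = 0,
) -> List[List[str]]:
    """MeSH-style tree numbers for ``n_diseases`` diseases.

    A forest of dot-separated codes is grown to ``depth`` levels with
    ``branching`` children per node; diseases are assigned to distinct forest
    nodes so that siblings share ancestors (at depth 1 the forest is all
    roots and distinct diseases share nothing).  Roughly one disease in five
    gets a second descriptor.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)

    pool: List[str] = []
    n_roots = 3
    while True:
        pool = []
        for r in range(n_roots):
            level = [f"C{r + 1:02d}"]
            pool.extend(level)
            for _ in range(depth - 1):
                level = [f"{code}.{i + 1:03d}" for code in level
                         for i in range(branching)]
                pool.extend(level)
        if len(pool) >= n_diseases:
            break
        n_roots += max(1, n_roots)

    picks = rng.choice(len(pool), size=n_diseases, replace=False)
    out: List[List[str]] = []
    for p in picks:
        codes = [pool[p]]
        if depth > 1 and rng.random() < 0.2:
            extra = pool[int(rng.integers(len(pool)))]
            if extra != codes[0]:
                codes.append(extra)
        out.append(codes)
    return out


def generate_fingerprints(
    drug_ids: Sequence[str],
    latents: Mapping[str, np.ndarray],
    n_bits: int,
    signal: float,
    seed: int,
) -> Dict[str, str]:
    """Fingerprint bitstrings: bit b on with probability sigma(s * w_b . u).

    The directions w_b are fixed seeded unit vectors; at signal 0 every bit
    is an independent fair coin.
    """
    d = len(next(iter(latents.values())))
    if n_bits < d:
        raise ValueError("n_bits must be >= latent_dim")
    rng = np.random.default_rng(seed)
    W = np.random.default_rng(seed + 13).standard_normal((n_bits, d))
    W /= np.linalg.norm(W, axis=1, keepdims=True)
    out: Dict[str, str] = {}
    for nid in drug_ids:
        p = _sigmoid(signal * (W @ latents[nid]))
        bits = (rng.random(n_bits) < p).astype(int)
        out[nid] = "".join("1" if b else "0" for b in bits)
    return out


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    graph: MANGraph
    latents: Dict[str, np.ndarray]
    sequences: Dict[str, str]
    disease_descriptors: Dict[str, List[str]]
    fingerprints: Dict[str, str]


def generate_dataset(spec: Optional[SyntheticSpec] = None) -> SyntheticDataset:
    """Full bundle: network, latents and every attribute payload kind."""
    spec = spec or SyntheticSpec()
    graph, latents = generate_network(spec)
    s = spec.attribute_signal
    sequences: Dict[str, str] = {}
    sequences.update(generate_sequences(
        [n.node_id for n in graph.nodes_of_type("miRNA")], latents, s,
        spec.seed + 1, "rna", spec.mirna_length,
    ))
    sequences.update(generate_sequences(
        [n.node_id for n in graph.nodes_of_type("lncRNA")], latents, s,
        spec.seed + 2, "rna", spec.lncrna_length,
    ))
    sequences.update(generate_sequences(
        [n.node_id for n in graph.nodes_of_type("protein")], latents, s,
        spec.seed + 3, "protein", spec.protein_length,
    ))
    disease_ids = [n.node_id for n in graph.nodes_of_type("disease")]
    codes = generate_disease_dag_forest(
        len(disease_ids), spec.dag_depth, spec.dag_branching, spec.seed + 4
    )
    disease_descriptors = dict(zip(disease_ids, codes))
    fingerprints = generate_fingerprints(
        [n.node_id for n in graph.nodes_of_type("drug")], latents,
        spec.n_bits, s, spec.seed + 5,
    )
    return SyntheticDataset(spec, graph, latents, sequences,
                            disease_descriptors, fingerprints)


def write_dataset(dataset: SyntheticDataset, outdir) -> Dict[str, str]:
    """Emit the dataset in the exact formats the loaders consume.

    Returns the written paths: edge TSV, node metadata TSV, FASTA,
    disease-descriptor TSV, fingerprint TSV and ground-truth latents TSV.
    """
    import os

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    from .man_graph import write_edge_list

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "edges": os.path.join(outdir, "edges.tsv"),
        "nodes": os.path.join(outdir, "nodes.tsv"),
        "fasta": os.path.join(outdir, "sequences.fasta"),
        "mesh": os.path.join(outdir, "disease_descriptors.tsv"),
        "fingerprints": os.path.join(outdir, "fingerprints.tsv"),
        "latents": os.path.join(outdir, "latents.tsv"),
    }
    write_edge_list(dataset.graph, paths["edges"])
    with open(paths["nodes"], "w", encoding="utf-8") as fh:
        for n in dataset.graph.nodes:
            fh.write(f"{n.node_id}\t{n.node_type}\n")
    records = [
        SeqRecord(Seq(seq), id=nid, description="")
        for nid, seq in dataset.sequences.items()
    ]
    seqio_write(records, paths["fasta"], "fasta")
    with open(paths["mesh"], "w", encoding="utf-8") as fh:
        for nid, codes in dataset.disease_descriptors.items():
            for code in codes:
                fh.write(f"{nid}\t{code}\n")
    with open(paths["fingerprints"], "w", encoding="utf-8") as fh:
        for nid, bits in dataset.fingerprints.items():
            fh.write(f"{nid}\t{bits}\n")
    with open(paths["latents"], "w", encoding="utf-8") as fh:
        for nid, u in dataset.latents.items():
            fh.write(nid + "\t" + "\t".join(f"{v:.10g}" for v in u) + "\n")
    return paths
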