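"""Node attribute features: k-mer composition, MeSH DAG disease semantics,
and drug fingerprints.

Every node type gets a 64-dimensional attribute vector:

* ncRNA (miRNA/lncRNA): normalized 3-mer frequencies over {A,C,G,U} (4^3 = 64).
* protein: the 20 amino acids are collapsed to 4 side-chain polarity groups,
  then 3-mer frequencies over the reduced alphabet (4^3 = 64).
* disease: a semantic-similarity profile against all diseases, computed from
  MeSH tree-number DAGs with an attenuation factor, then compressed to 64
  dims by a sparse autoencoder.
* drug: a Morgan fingerprint bit vector, compressed to 64 dims by a sparse
  autoencoder.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .man_graph import MANGraph

RNA_ALPHABET = ("A", "C", "G", "U")
REDUCED_ALPHABET = ("A", "B", "C", "D")

#: Side-chain polarity grouping of the 20 standard amino acids.
PROTEIN_GROUPS: Dict[str, str] = {}
for _res in "AVLIMFWP":
    PROTEIN_GROUPS[_res] = "A"
for _res in "GSTCNQY":
    PROTEIN_GROUPS[_res] = "B"
for _res in "RKH":
    PROTEIN_GROUPS[_res] = "C"
for _res in "DE":
    PROTEIN_GROUPS[_res] = "D"


@dataclass(frozen=True)
class KmerSpec:
    """Alphabet + k defining a lexicographic k-mer index space."""

    alphabet: Tuple[str, ...] = RNA_ALPHABET
    k: int = 3

    @property
    def size(self) -> int:
        return len(self.alphabet) ** self.k

    def index_map(self) -> Dict[str, int]:
        return {
            "".join(p): i
            for i, p in enumerate(itertools.product(self.alphabet, repeat=self.k))
        }


def _encode_kmer(symbols: str, spec: KmerSpec) -> np.ndarray:
    """Bag-of-k-mers over valid windows; invalid symbols void their windows."""
    index = spec.index_map()
    vec = np.zeros(spec.size, dtype=float)
    k = spec.k
    valid = 0
    for i in range(len(symbols) - k + 1):
        kmer = symbols[i : i + k]
        pos = index.get(kmer)
        if pos is None:
            continue
        vec[pos] += 1.0
        valid += 1
    if valid == 0:
        warnings.warn(
            "sequence yielded no valid k-mer window; returning zero vector",
            stacklevel=3,
        )
        return vec
    return vec / valid


def encode_rna_kmer(sequence: str, spec: Optional[KmerSpec] = None) -> np.ndarray:
    """Normalized 3-mer composition of an RNA/DNA sequence (T mapped to U)."""
    if not sequence:
        raise ValueError("empty sequence")
    spec = spec or KmerSpec(RNA_ALPHABET, 3)
    seq = sequence.upper().replace("T", "U")
    return _encode_kmer(seq, spec)


def encode_protein_kmer(sequence: str, spec: Optional[KmerSpec] = None) -> np.ndarray:
    """Reduced-alphabet 3-mer composition of an amino-acid sequence.

    Residues outside the 20 standard amino acids (X, U, B, ...) invalidate the
    windows containing them.
    """
    if not sequence:
        raise ValueError("empty sequence")
    spec = spec or KmerSpec(REDUCED_ALPHABET, 3)
    reduced = "".join(PROTEIN_GROUPS.get(c, "?") for c in sequence.upper())
    return _encode_kmer(reduced, spec)


# ---------------------------------------------------------------------------
# Disease semantics over MeSH tree numbers
# ---------------------------------------------------------------------------

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z][0-9]+(\.[0-9]+)*$")


@dataclass
class DiseaseDAG:
    """Ancestor closure of a disease's MeSH descriptors.

    Nodes are tree-number strings; each descriptor contributes itself and all
    its dot-prefix ancestors.  ``contributions`` (the attenuated semantic
    contribution of every node to the disease) and the semantic value
    ``DV1 = sum of contributions`` are filled in by :func:`contribution_map`.
    """

    disease_id: str
    descriptors: Tuple[str, ...]
    nodes: frozenset
    edges: frozenset  # (child, parent) links
    delta: Optional[float] = None
    contributions: Dict[str, float] = field(default_factory=dict)

    @property
    def semantic_value(self) -> float:
        if not self.contributions:
            raise ValueError("call contribution_map first")
        return float(sum(self.contributions.values()))


def _ancestors(code: str) -> List[str]:
    parts = code.split(".")
    return [".".join(parts[: i + 1]) for i in range(len(parts))]


def build_disease_dag(
    disease_id: str,
    tree_numbers: Sequence[str],
    mesh_table: Optional[Mapping[str, str]] = None,
) -> DiseaseDAG:
    """Construct the DAG of a disease from its MeSH tree numbers.

    Ancestors are obtained by truncating tree numbers at '.' separators;
    multiple descriptors yield the union of their ancestor closures.  Cycles
    cannot arise from prefix truncation.  ``mesh_table`` (tree number -> name)
    is accepted for labeling only and does not affect the closure.
    """
    if not tree_numbers:
        raise ValueError(f"disease '{disease_id}' has no tree numbers")
    nodes: Set[str] = set()
    edges: Set[Tuple[str, str]] = set()
    for code in tree_numbers:
        code = code.strip()
        if not _TREE_NUMBER_RE.match(code):
            raise ValueError(f"malformed MeSH tree number '{code}'")
        chain = _ancestors(code)
        nodes.update(chain)
        for child, parent in zip(chain[1:], chain[:-1]):
            edges.add((child, parent))
    return DiseaseDAG(
        disease_id=disease_id,
        descriptors=tuple(dict.fromkeys(t.strip() for t in tree_numbers)),
        nodes=frozenset(nodes),
        edges=frozenset(edges),
    )


def contribution_map(dag: DiseaseDAG, delta: float = 0.5) -> Dict[str, float]:
    """Attenuated semantic contribution of every DAG node to the disease.

    The disease's own descriptors contribute 1; any other node t contributes
    ``max(delta * contribution(t'))`` over its children t' in the DAG, i.e.
    ``delta ** distance`` along the shortest descendant chain to a descriptor.
    Stores the result (and ``delta``) on the DAG and returns the map.
    """
    if not (0.0 < delta < 1.0):
        raise ValueError("attenuation factor must lie in (0, 1)")
    descriptors = set(dag.descriptors)
    children: Dict[str, List[str]] = {}
    for child, parent in dag.edges:
        children.setdefault(parent, []).append(child)

    contrib: Dict[str, float] = {}

    # process deepest nodes first so every child is resolved before its parent
    for node in sorted(dag.nodes, key=lambda c: -c.count(".")):
        if node in descriptors:
            contrib[node] = 1.0
            continue
        kids = [c for c in children.get(node, []) if c in contrib]
        if not kids:
            raise ValueError(f"node '{node}' has no resolved children")
        contrib[node] = max(delta * contrib[c] for c in kids)

    dag.delta = delta
    dag.contributions = contrib
    return contrib


def disease_similarity(i: DiseaseDAG, j: DiseaseDAG) -> float:
    """Shared-ancestor semantic similarity of two diseases, in [0, 1].

    similarity = sum over shared DAG nodes of both contributions, divided by
    the sum of the two semantic values.  Identical closures give 1; disjoint
    closures give 0.
    """
    if not i.contributions or not j.contributions:
        raise ValueError("compute contribution_map on both DAGs first")
    if i.delta != j.delta:
        raise ValueError("DAGs built with different attenuation factors")
    shared = i.nodes & j.nodes
    if not shared:
        return 0.0
    num = sum(i.contributions[t] + j.contributions[t] for t in shared)
    return float(num / (i.semantic_value + j.semantic_value))


def disease_similarity_profile(diseases: Sequence[DiseaseDAG]) -> np.ndarray:
    """Pairwise semantic-similarity matrix (symmetric, unit diagonal)."""
    if not diseases:
        raise ValueError("need at least one disease")
    n = len(diseases)
    mat = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            mat[a, b] = mat[b, a] = disease_similarity(diseases[a], diseases[b])
    return mat


# ---------------------------------------------------------------------------
# Drug fingerprints
# ---------------------------------------------------------------------------


def drug_fingerprint(payload: str, n_bits: int = 1024) -> np.ndarray:
    """Binary structural fingerprint from a bitstring or a SMILES string.

    A payload consisting solely of 0/1 characters is taken as a precomputed
    fingerprint and must have length ``n_bits``.  Otherwise it is parsed as
    SMILES and converted to a Morgan fingerprint (radius 2, ``n_bits`` bits)
    via rdkit; without rdkit installed, precomputed bitstrings must be used.
    """
    payload = payload.strip()
    if not payload:
        raise ValueError("empty fingerprint payload")
    if set(payload) <= {"0", "1"}:
        if len(payload) != n_bits:
            raise ValueError(
                f"bitstring length {len(payload)} != n_bits {n_bits}"
            )
        return np.frombuffer(payload.encode(), dtype=np.uint8) - ord("0")
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "rdkit not available: supply precomputed fingerprint bitstrings"
        ) from exc
    mol = Chem.MolFromSmiles(payload)
    if mol is None:
        raise ValueError(
            f"unparsable SMILES '{payload}': supply a precomputed bitstring"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=np.uint8)


# ---------------------------------------------------------------------------
# Whole-graph attribute assembly
# ---------------------------------------------------------------------------


def read_fasta(path) -> Dict[str, str]:
    """Sequences keyed by record id (record id must equal node_id)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_disease_descriptors(path) -> Dict[str, List[str]]:
    """TSV ``node_id  tree_number`` (one row per tree number)."""
    table: Dict[str, List[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            nid, code = line.split("\t")[:2]
            table.setdefault(nid, []).append(code)
    return table


def read_fingerprints(path) -> Dict[str, str]:
    """TSV ``node_id  bitstring-or-SMILES``."""
    table: Dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            nid, payload = line.split("\t")[:2]
            table[nid] = payload
    return table


def compute_attribute_vectors(
    graph: MANGraph,
    sequences: Optional[Mapping[str, str]] = None,
    disease_descriptors: Optional[Mapping[str, Sequence[str]]] = None,
    fingerprints: Optional[Mapping[str, str]] = None,
    delta: float = 0.5,
    n_bits: int = 1024,
    hidden_dim: int = 64,
    sae_config: Optional[dict] = None,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """64-dim attribute vector for every node of the graph.

    Sequence nodes are encoded directly (their k-mer vectors are already 64
    dimensional); disease similarity profiles and drug fingerprints are
    compressed to ``hidden_dim`` by one sparse autoencoder per node type.
    ``sae_config`` overrides SAEConfig fields (epochs, learning rate, ...).
    """
    from .sparse_autoencoder import SAEConfig, encode, train_sae

    sequences = sequences or {}
    disease_descriptors = disease_descriptors or {}
    fingerprints = fingerprints or {}
    out: Dict[str, np.ndarray] = {}

    for node in graph.nodes:
        if node.node_type in ("miRNA", "lncRNA"):
            if node.node_id not in sequences:
                raise ValueError(
                    f"missing sequence for {node.node_type} '{node.node_id}'"
                )
            out[node.node_id] = encode_rna_kmer(sequences[node.node_id])
        elif node.node_type == "protein":
            if node.node_id not in sequences:
                raise ValueError(f"missing sequence for protein '{node.node_id}'")
            out[node.node_id] = encode_protein_kmer(sequences[node.node_id])

    overrides = dict(sae_config or {})

    diseases = graph.nodes_of_type("disease")
    if diseases:
        dags = []
        for node in diseases:
            codes = disease_descriptors.get(node.node_id)
            if not codes:
                raise ValueError(
                    f"missing MeSH descriptors for disease '{node.node_id}'"
                )
            dag = build_disease_dag(node.node_id, codes)
            contribution_map(dag, delta)
            dags.append(dag)
        profile = disease_similarity_profile(dags)
        kwargs = dict(input_dim=profile.shape[1], hidden_dim=hidden_dim, seed=seed)
        kwargs.update(overrides)
        cfg = SAEConfig(**kwargs)
        model = train_sae(profile, cfg)
        codes64 = encode(model, profile)
        for node, row in zip(diseases, codes64):
            out[node.node_id] = row

    drugs = graph.nodes_of_type("drug")
    if drugs:
        rows = []
        for node in drugs:
            if node.node_id not in fingerprints:
                raise ValueError(f"missing fingerprint for drug '{node.node_id}'")
            rows.append(drug_fingerprint(fingerprints[node.node_id], n_bits=n_bits))
        fp_mat = np.array(rows, dtype=float)
        kwargs = dict(input_dim=fp_mat.shape[1], hidden_dim=hidden_dim, seed=seed + 1)
        kwargs.update(overrides)
        cfg = SAEConfig(**kwargs)
        model = train_sae(fp_mat, cfg)
        codes64 = encode(model, fp_mat)
        for node, row in zip(drugs, codes64):
            out[node.node_id] = row

    return out
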