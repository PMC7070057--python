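"""Metrics and evaluation protocols for heterogeneous link prediction.

Implements balanced k-fold cross-validation with per-fold re-embedding (test
edges are stripped from the graph-factorization input so no label information
leaks), the attribute/behavior/both feature ablation, the training-proportion
sweep, the four-classifier comparison, the local-vs-global contrast for a
single target relation (attribute-only baseline, Gaussian interaction-profile
kernel, relation-local embedding, whole-network embedding), and the
leave-one-disease-out candidate-ranking case study.

Internal scores and rates are fractions in [0, 1]; reporting helpers convert
to the percent scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from . import link_model as lm
from .graph_factorization import EmbeddingMatrix, GFConfig, factorize
from .man_graph import (
    EdgeRecord,
    MANGraph,
    sample_negatives,
    split_folds,
    subsample_edges,
)
from .sparse_autoencoder import SAEConfig, encode, train_sae

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spec: float
    prec: float
    mcc: float
    auc: float
    aupr: float
    fold: Optional[object] = None
    roc_points: Optional[np.ndarray] = None  # (fpr, tpr) columns
    pr_points: Optional[np.ndarray] = None   # (recall, precision) columns

    def as_dict(self) -> Dict[str, float]:
        return {
            "Acc": self.acc, "Sen": self.sen, "Spec": self.spec,
            "Prec": self.prec, "MCC": self.mcc, "AUC": self.auc,
            "AUPR": self.aupr,
        }


def confusion_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Threshold scores at 0.5 and compute confusion-matrix summaries.

    MCC uses the convention 0 when its denominator vanishes; sensitivity,
    specificity and precision are 0 when their denominators vanish.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    pred = (s >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = ((tp * tn - fp * fn) / np.sqrt(denom)) if denom else 0.0
    return MetricsReport(tp, fp, tn, fn, acc, sen, spec, prec, float(mcc),
                         auc=float("nan"), aupr=float("nan"))


def roc_pr_curves(
    labels: Sequence[int], scores: Sequence[float]
) -> Tuple[float, float, np.ndarray, np.ndarray]:
    """ROC-AUC (trapezoidal, tied scores grouped) and average-precision AUPR.

    Returns (auc, aupr, roc_points, pr_points) where the point arrays hold
    (fpr, tpr) and (recall, precision) columns.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, s)
    auc_val = float(_trapezoid_auc(fpr, tpr))
    aupr_val = float(average_precision_score(y, s))
    prec, rec, _ = precision_recall_curve(y, s)
    return auc_val, aupr_val, np.column_stack([fpr, tpr]), np.column_stack([rec, prec])


def evaluate_scores(
    labels: Sequence[int], scores: Sequence[float], fold=None
) -> MetricsReport:
    report = confusion_metrics(labels, scores)
    auc_val, aupr_val, roc_pts, pr_pts = roc_pr_curves(labels, scores)
    report.auc = auc_val
    report.aupr = aupr_val
    report.fold = fold
    report.roc_points = roc_pts
    report.pr_points = pr_pts
    return report


def summarize(reports: Sequence[MetricsReport]) -> Dict[str, Tuple[float, float]]:
    """Mean and standard deviation of each metric across folds."""
    out = {}
    for key in ("Acc", "Sen", "Spec", "Prec", "MCC", "AUC", "AUPR"):
        vals = np.array([r.as_dict()[key] for r in reports])
        out[key] = (float(vals.mean()), float(vals.std()))
    return out


def write_metrics_tsv(path, rows: Mapping[object, Sequence[MetricsReport]]) -> None:
    """Percent-scale metrics table: one row per fold per setting."""
    cols = ("Acc", "Sen", "Spec", "Prec", "MCC", "AUC", "AUPR")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("setting\tfold\t" + "\t".join(f"{c} (%)" for c in cols) + "\n")
        for setting, reports in rows.items():
            for r in reports:
                vals = r.as_dict()
                fh.write(
                    f"{setting}\t{r.fold}\t"
                    + "\t".join(f"{100 * vals[c]:.2f}" for c in cols)
                    + "\n"
                )


def write_curves_csv(path, rows: Mapping[object, Sequence[MetricsReport]]) -> None:
    """ROC and PR curve points per fold per setting."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("setting,fold,curve,x,y\n")
        for setting, reports in rows.items():
            for r in reports:
                for name, pts in (("roc", r.roc_points), ("pr", r.pr_points)):
                    if pts is None:
                        continue
                    for x, y in pts:
                        fh.write(f"{setting},{r.fold},{name},{x:.6f},{y:.6f}\n")


# ---------------------------------------------------------------------------
# Experiment configuration and fold machinery
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    mode: str = "both"
    classifier: lm.ClassifierSpec = field(default_factory=lm.ClassifierSpec)
    k: int = 5
    seed: int = 0
    gf: GFConfig = field(default_factory=GFConfig)
    permute_labels: bool = False


@dataclass
class _FoldData:
    fold: int
    train_edges: List[EdgeRecord]
    test_edges: List[EdgeRecord]
    embedding: Optional[EmbeddingMatrix]


def _derive_seed(seed: int, salt: int) -> int:
    return int((seed * 1_000_003 + salt) % (2 ** 31))


def _assert_no_leakage(test_pos: Sequence[EdgeRecord],
                       gf_edges: Sequence[EdgeRecord]) -> None:
    overlap = set(test_pos) & set(gf_edges)
    if overlap:
        raise AssertionError(
            f"label leakage: {len(overlap)} test edges present in the "
            "embedding input"
        )


def _prepare_folds(
    graph: MANGraph,
    config: ExperimentConfig,
    relation: Optional[str] = None,
    negatives: Optional[List[EdgeRecord]] = None,
    fold_split=None,
    gf_scope: str = "global",
    need_gf: bool = True,
):
    """Build the balanced labeled set, fold assignment and per-fold embeddings.

    ``gf_scope`` is "global" (embedding sees every training positive of the
    whole network) or "target" (only training positives of ``relation``).
    Test positives are always stripped from the embedding input.
    """
    if relation is None:
        positives = graph.positive_edges
    else:
        positives = graph.edges_of_type(relation)
    if not positives:
        raise ValueError("no positive edges for the requested scope")
    if negatives is None:
        negatives = sample_negatives(
            graph, len(positives), _derive_seed(config.seed, 11),
            relation_types=[relation] if relation else None,
        )
    labeled = positives + negatives
    if fold_split is None:
        fold_split = split_folds(labeled, config.k, _derive_seed(config.seed, 23))

    label_map = {e: (1 if e.label == "positive" else 0) for e in labeled}
    if config.permute_labels:
        rng = np.random.default_rng(_derive_seed(config.seed, 31))
        vals = np.array([label_map[e] for e in labeled])
        perm = rng.permutation(len(vals))
        label_map = {e: int(vals[perm[i]]) for i, e in enumerate(labeled)}

    folds: List[_FoldData] = []
    for f in range(config.k):
        test = fold_split.fold_edges(f)
        test_set = set(test)
        train = [e for e in labeled if e not in test_set]
        embedding = None
        if need_gf:
            test_pos = [e for e in test if e.label == "positive"]
            source = graph.positive_edges if gf_scope == "global" else positives
            gf_edges = [e for e in source if e not in test_set]
            _assert_no_leakage(test_pos, gf_edges)
            train_graph = graph.copy_with_edges(gf_edges)
            embedding = factorize(
                train_graph, replace(config.gf, seed=_derive_seed(config.seed, f))
            )
        folds.append(_FoldData(f, train, test, embedding))
    return labeled, label_map, fold_split, folds


def _fold_xy(edges, representations, node_index, label_map):
    X = np.vstack([lm.pair_features(e, representations, node_index) for e in edges])
    y = np.array([label_map[e] for e in edges], dtype=int)
    return X, y


def _run_fold(graph, attr_vectors, fold: _FoldData, mode, label_map, spec,
              representations=None):
    idx = graph.node_index()
    if representations is None:
        representations = lm.build_representations(
            graph, attr_vectors, fold.embedding, mode
        )
    X_train, y_train = _fold_xy(fold.train_edges, representations, idx, label_map)
    X_test, y_test = _fold_xy(fold.test_edges, representations, idx, label_map)
    clf = lm.train_classifier((X_train, y_train), spec)
    scores = lm.predict_scores(clf, X_test)
    return evaluate_scores(y_test, scores, fold=fold.fold)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


def cross_validate(
    graph: MANGraph,
    attr_vectors: Optional[Mapping[str, np.ndarray]],
    config: ExperimentConfig,
    relation: Optional[str] = None,
) -> Tuple[List[MetricsReport], Dict[str, Tuple[float, float]]]:
    """Balanced k-fold cross-validated link prediction.

    Per fold: the embedding is re-fit on training positives only, pair
    features are assembled in ``config.mode``, the classifier is fit on the
    training folds and scored on the held-out fold.
    """
    need_gf = config.mode != "attribute"
    _, label_map, _, folds = _prepare_folds(
        graph, config, relation=relation, need_gf=need_gf
    )
    reports = [
        _run_fold(graph, attr_vectors, fd, config.mode, label_map,
                  replace(config.classifier, seed=_derive_seed(config.seed, fd.fold)))
        for fd in folds
    ]
    return reports, summarize(reports)


def ablation_experiment(
    graph: MANGraph,
    attr_vectors: Mapping[str, np.ndarray],
    config: ExperimentConfig,
) -> Dict[str, Tuple[List[MetricsReport], Dict[str, Tuple[float, float]]]]:
    """Attribute-only vs behavior-only vs combined, on shared folds/negatives."""
    _, label_map, _, folds = _prepare_folds(graph, config, need_gf=True)
    out = {}
    for mode in ("attribute", "behavior", "both"):
        reports = [
            _run_fold(graph, attr_vectors, fd, mode, label_map,
                      replace(config.classifier,
                              seed=_derive_seed(config.seed, fd.fold)))
            for fd in folds
        ]
        out[mode] = (reports, summarize(reports))
    return out


def classifier_comparison(
    graph: MANGraph,
    attr_vectors: Mapping[str, np.ndarray],
    config: ExperimentConfig,
    kinds: Sequence[str] = ("NB", "LR", "ET", "RF"),
) -> Dict[str, Tuple[List[MetricsReport], Dict[str, Tuple[float, float]]]]:
    """Compare classifier families on identical folds and features."""
    _, label_map, _, folds = _prepare_folds(graph, config, need_gf=True)
    idx = graph.node_index()
    fold_xy = []
    for fd in folds:
        reps = lm.build_representations(graph, attr_vectors, fd.embedding,
                                        config.mode)
        fold_xy.append((
            _fold_xy(fd.train_edges, reps, idx, label_map),
            _fold_xy(fd.test_edges, reps, idx, label_map),
        ))
    out = {}
    for kind in kinds:
        reports = []
        for fd, ((Xtr, ytr), (Xte, yte)) in zip(folds, fold_xy):
            spec = lm.ClassifierSpec(kind, seed=_derive_seed(config.seed, fd.fold))
            clf = lm.train_classifier((Xtr, ytr), spec)
            scores = lm.predict_scores(clf, Xte)
            reports.append(evaluate_scores(yte, scores, fold=fd.fold))
        out[kind] = (reports, summarize(reports))
    return out


def proportion_sweep(
    graph: MANGraph,
    config: ExperimentConfig,
    fractions: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    attr_vectors: Optional[Mapping[str, np.ndarray]] = None,
) -> Dict[float, MetricsReport]:
    """Train on a fraction of the edges, test on the complement.

    Behavior-only representations: each node is the embedding of the retained
    network alone.  Negatives are sampled to match the positive counts on
    both sides and never intersect any true edge.
    """
    out = {}
    idx = graph.node_index()
    for pos_i, frac in enumerate(fractions):
        train_graph, held = subsample_edges(
            graph, frac, _derive_seed(config.seed, 41 + pos_i)
        )
        train_pos = train_graph.positive_edges
        _assert_no_leakage(held, train_pos)
        negs = sample_negatives(
            graph, len(train_pos) + len(held),
            _derive_seed(config.seed, 59 + pos_i),
        )
        # negatives come back grouped by relation type; shuffle before the
        # train/test split so both sides share the same type mixture
        rng = np.random.default_rng(_derive_seed(config.seed, 73 + pos_i))
        negs = [negs[i] for i in rng.permutation(len(negs))]
        train_negs = negs[: len(train_pos)]
        test_negs = negs[len(train_pos):]
        emb = factorize(
            train_graph, replace(config.gf, seed=_derive_seed(config.seed, pos_i))
        )
        reps = lm.build_representations(graph, attr_vectors, emb, "behavior")
        label_map = {e: (1 if e.label == "positive" else 0)
                     for e in train_pos + held + negs}
        X_train, y_train = _fold_xy(train_pos + train_negs, reps, idx, label_map)
        X_test, y_test = _fold_xy(held + test_negs, reps, idx, label_map)
        spec = replace(config.classifier, seed=_derive_seed(config.seed, pos_i))
        clf = lm.train_classifier((X_train, y_train), spec)
        scores = lm.predict_scores(clf, X_test)
        out[frac] = evaluate_scores(y_test, scores, fold=frac)
    return out


def gip_kernel_profiles(
    profiles: np.ndarray, gamma_scale: float = 1.0
) -> np.ndarray:
    """Gaussian interaction-profile kernel similarity matrix.

    K(i, j) = exp(-gamma ||y_i - y_j||^2) with the bandwidth gamma =
    gamma_scale / mean(||y_i||^2) over the entities of this side.
    """
    P = np.asarray(profiles, dtype=float)
    sq_norms = np.sum(P ** 2, axis=1)
    mean_norm = sq_norms.mean()
    if mean_norm == 0:
        raise ValueError("all interaction profiles are zero")
    gamma = gamma_scale / mean_norm
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(sq_dist, 0.0, out=sq_dist)
    K = np.exp(-gamma * sq_dist)
    np.fill_diagonal(K, 1.0)
    return K


def local_vs_global(
    graph: MANGraph,
    attr_vectors: Mapping[str, np.ndarray],
    config: ExperimentConfig,
    target_relation: str = "miRNA-disease",
    sae_overrides: Optional[dict] = None,
) -> Dict[str, Tuple[List[MetricsReport], Dict[str, Tuple[float, float]]]]:
    """Four pipelines for one relation, on shared folds.

    (a) ``attribute``: endpoint attribute vectors only;
    (b) ``gip_local``: attribute plus a 64-dim sparse-autoencoder compression
        of the Gaussian interaction-profile similarity rows computed from the
        training edges of the target relation;
    (c) ``gf_local``: attribute plus embedding of the target sub-network only;
    (d) ``gf_global``: attribute plus embedding of the whole network.
    """
    t_head, t_tail = target_relation.split("-")[0], target_relation.split("-")[-1]
    positives = graph.edges_of_type(target_relation)
    negatives = sample_negatives(
        graph, len(positives), _derive_seed(config.seed, 11),
        relation_types=[target_relation],
    )
    labeled = positives + negatives
    fold_split = split_folds(labeled, config.k, _derive_seed(config.seed, 23))

    out = {}
    # (a) attribute-only
    _, label_map, _, folds_a = _prepare_folds(
        graph, config, relation=target_relation, negatives=negatives,
        fold_split=fold_split, need_gf=False,
    )
    out["attribute"] = _collect(graph, attr_vectors, folds_a, "attribute",
                                label_map, config)
    # (c) local GF, (d) global GF
    for name, scope in (("gf_local", "target"), ("gf_global", "global")):
        _, label_map, _, folds = _prepare_folds(
            graph, config, relation=target_relation, negatives=negatives,
            fold_split=fold_split, gf_scope=scope, need_gf=True,
        )
        out[name] = _collect(graph, attr_vectors, folds, "both", label_map, config)

    # (b) GIP kernel similarity compressed to 64, concatenated with attributes
    side_a = [n.node_id for n in graph.nodes_of_type(t_head)]
    side_b = [n.node_id for n in graph.nodes_of_type(t_tail)]
    ia = {nid: i for i, nid in enumerate(side_a)}
    ib = {nid: i for i, nid in enumerate(side_b)}
    idx = graph.node_index()
    reports_b = []
    overrides = dict(sae_overrides or {})
    for fd in folds_a:
        test_set = set(fd.test_edges)
        train_pos = [e for e in positives if e not in test_set]
        _assert_no_leakage([e for e in fd.test_edges if e.label == "positive"],
                           train_pos)
        P = np.zeros((len(side_a), len(side_b)))
        for e in train_pos:
            a, b = e.head_id, e.tail_id
            if a not in ia:
                a, b = b, a
            P[ia[a], ib[b]] = 1.0
        reps = {}
        for ids, profiles, salt in ((side_a, P, 61), (side_b, P.T, 67)):
            K = gip_kernel_profiles(profiles)
            kwargs = dict(input_dim=K.shape[1], hidden_dim=64,
                          seed=_derive_seed(config.seed, salt + fd.fold))
            kwargs.update(overrides)
            model = train_sae(K, SAEConfig(**kwargs))
            codes = encode(model, K)
            for nid, row in zip(ids, codes):
                reps[nid] = lm.NodeRepresentation(
                    nid, attribute=np.asarray(attr_vectors[nid], dtype=float),
                    behavior=row, mode="both",
                )
        X_train, y_train = _fold_xy(fd.train_edges, reps, idx, label_map)
        X_test, y_test = _fold_xy(fd.test_edges, reps, idx, label_map)
        spec = replace(config.classifier, seed=_derive_seed(config.seed, fd.fold))
        clf = lm.train_classifier((X_train, y_train), spec)
        scores = lm.predict_scores(clf, X_test)
        reports_b.append(evaluate_scores(y_test, scores, fold=fd.fold))
    out["gip_local"] = (reports_b, summarize(reports_b))
    return out


def _collect(graph, attr_vectors, folds, mode, label_map, config):
    reports = [
        _run_fold(graph, attr_vectors, fd, mode, label_map,
                  replace(config.classifier, seed=_derive_seed(config.seed, fd.fold)))
        for fd in folds
    ]
    return reports, summarize(reports)


def leave_one_disease_out(
    graph: MANGraph,
    attr_vectors: Mapping[str, np.ndarray],
    disease_id: str,
    top_n: int,
    config: ExperimentConfig,
    target_relation: str = "miRNA-disease",
) -> List[Tuple[str, float]]:
    """Remove a disease's target-relation edges, retrain, rank all candidates.

    All miRNA–disease pairs of ``disease_id`` are withheld; the embedding is
    re-fit on the remaining network (the disease keeps its other relation
    types), the classifier is re-fit on the remaining target-relation pairs,
    and every type-legal candidate is scored against the disease.  Returns
    the ``top_n`` (candidate, score) pairs, ties broken lexicographically.
    """
    if disease_id not in graph:
        raise ValueError(f"unknown disease '{disease_id}'")
    removed = [
        e for e in graph.edges_of_type(target_relation)
        if disease_id in (e.head_id, e.tail_id)
    ]
    if not removed:
        raise ValueError(
            f"disease '{disease_id}' has no '{target_relation}' associations"
        )
    removed_set = set(removed)
    kept = [e for e in graph.positive_edges if e not in removed_set]
    _assert_no_leakage(removed, kept)
    train_graph = graph.copy_with_edges(kept)
    emb = factorize(train_graph,
                    replace(config.gf, seed=_derive_seed(config.seed, 97)))

    train_pos = [e for e in kept if e.relation_type == target_relation]
    negatives = sample_negatives(
        graph, len(train_pos), _derive_seed(config.seed, 101),
        relation_types=[target_relation], exclude_nodes={disease_id},
    )
    reps = lm.build_representations(graph, attr_vectors, emb, config.mode)
    idx = graph.node_index()
    label_map = {e: (1 if e.label == "positive" else 0)
                 for e in train_pos + negatives}
    X_train, y_train = _fold_xy(train_pos + negatives, reps, idx, label_map)
    spec = replace(config.classifier, seed=_derive_seed(config.seed, 103))
    clf = lm.train_classifier((X_train, y_train), spec)

    candidate_type = (
        target_relation.split("-")[0]
        if graph.node(disease_id).node_type != target_relation.split("-")[0]
        else target_relation.split("-")[-1]
    )
    candidates = [n.node_id for n in graph.nodes_of_type(candidate_type)]
    ranking = lm.rank_candidates(
        clf, disease_id, candidates, reps, idx,
        relation_type=target_relation,
    )
    return ranking[:top_n]
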