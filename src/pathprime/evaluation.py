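"""Classification, clustering and retrieval metrics.

Three evaluation views, matching the three ways the trained network is
used: supervised classification scores on predicted labels; the six
clustering agreement scores (homogeneity, completeness, V-measure, ARI,
AMI, Fowlkes-Mallows) between K-Means clusters of an encoding and the true
cell types; and nearest-neighbour retrieval scored by mean average
precision (MAP) over the k = 100 euclidean nearest reference encodings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn import metrics as skm
from sklearn.cluster import KMeans


@dataclass
class SupervisedMetrics:
    accuracy: float
    balanced_accuracy: float
    f1_macro: float
    f1_micro: float
    f1_weighted: float
    precision_macro: float
    precision_micro: float
    precision_weighted: float
    recall_macro: float
    recall_micro: float
    recall_weighted: float
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "accuracy",
                "balanced_accuracy",
                "f1_macro",
                "f1_micro",
                "f1_weighted",
                "precision_macro",
                "precision_micro",
                "precision_weighted",
                "recall_macro",
                "recall_micro",
                "recall_weighted",
            )
        }


@dataclass
class ClusteringMetrics:
    homogeneity: float
    completeness: float
    v_measure: float
    ari: float
    ami: float
    fowlkes_mallows: float

    @property
    def average(self) -> float:
        return float(
            np.mean(
                [
                    self.homogeneity,
                    self.completeness,
                    self.v_measure,
                    self.ari,
                    self.ami,
                    self.fowlkes_mallows,
                ]
            )
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "v_measure": self.v_measure,
            "ari": self.ari,
            "ami": self.ami,
            "fowlkes_mallows": self.fowlkes_mallows,
            "average": self.average,
        }


@dataclass
class RetrievalConfig:
    k: int = 100
    distance: str = "euclidean"
    normalize_by_total_relevant: bool = False
    exclude_self: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.distance != "euclidean":
            raise ValueError("only euclidean distance is supported")


# ---------------------------------------------------------------------------
# supervised
# ---------------------------------------------------------------------------


def supervised_metrics(y_true, y_pred, per_class: bool = False) -> SupervisedMetrics:
    """Accuracy, balanced accuracy and {P, R, F1} × {macro, micro, weighted}.

    Classes predicted for no cell contribute precision 0 (zero-division
    handled silently, as in standard reports on imbalanced data).
    """
    t = np.asarray(getattr(y_true, "labels", y_true), dtype=object)
    p = np.asarray(getattr(y_pred, "labels", y_pred), dtype=object)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred lengths differ")

    with warnings.catch_warnings():
        # classes predicted but never true (or vice versa) score 0 silently
        warnings.simplefilter("ignore", UserWarning)
        balanced = float(skm.balanced_accuracy_score(t, p))
    out = SupervisedMetrics(
        accuracy=float(skm.accuracy_score(t, p)),
        balanced_accuracy=balanced,
        f1_macro=float(skm.f1_score(t, p, average="macro", zero_division=0)),
        f1_micro=float(skm.f1_score(t, p, average="micro", zero_division=0)),
        f1_weighted=float(skm.f1_score(t, p, average="weighted", zero_division=0)),
        precision_macro=float(
            skm.precision_score(t, p, average="macro", zero_division=0)
        ),
        precision_micro=float(
            skm.precision_score(t, p, average="micro", zero_division=0)
        ),
        precision_weighted=float(
            skm.precision_score(t, p, average="weighted", zero_division=0)
        ),
        recall_macro=float(skm.recall_score(t, p, average="macro", zero_division=0)),
        recall_micro=float(skm.recall_score(t, p, average="micro", zero_division=0)),
        recall_weighted=float(
            skm.recall_score(t, p, average="weighted", zero_division=0)
        ),
    )
    if per_class:
        classes = sorted(set(t) | set(p))
        prec, rec, f1, support = skm.precision_recall_fscore_support(
            t, p, labels=classes, zero_division=0
        )
        out.per_class = {
            str(c): {
                "precision": float(prec[i]),
                "recall": float(rec[i]),
                "f1": float(f1[i]),
                "support": int(support[i]),
            }
            for i, c in enumerate(classes)
        }
    return out


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def kmeans_cluster(enc, K: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """K-Means labels for an encoding; best of ``n_init`` seeded restarts."""
    x = np.asarray(getattr(enc, "values", enc), dtype=float)
    if K > x.shape[0]:
        raise ValueError(f"K={K} exceeds the {x.shape[0]} cells")
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed)
    return km.fit_predict(x)


def clustering_metrics(y_true, clusters) -> ClusteringMetrics:
    """The six agreement scores between true labels and cluster assignments.

    Entropy-based scores use natural logarithms; AMI uses arithmetic-mean
    normalisation. All are invariant to cluster relabelling.
    """
    t = np.asarray(getattr(y_true, "labels", y_true), dtype=object)
    c = np.asarray(clusters)
    if t.shape != c.shape:
        raise ValueError("label/cluster lengths differ")
    if t.size < 2:
        raise ValueError("clustering metrics need at least 2 samples")
    return ClusteringMetrics(
        homogeneity=float(skm.homogeneity_score(t, c)),
        completeness=float(skm.completeness_score(t, c)),
        v_measure=float(skm.v_measure_score(t, c)),
        ari=float(skm.adjusted_rand_score(t, c)),
        ami=float(skm.adjusted_mutual_info_score(t, c, average_method="arithmetic")),
        fowlkes_mallows=float(skm.fowlkes_mallows_score(t, c)),
    )


# ---------------------------------------------------------------------------
# retrieval
# ---------------------------------------------------------------------------


def average_precision(
    query_class,
    ranked_neighbor_classes,
    k: int,
    total_relevant: int | None = None,
) -> float:
    """AP of a ranked neighbour list truncated at k.

    AP = (1/R) Σ_{i≤k} precision@i · rel(i), where rel(i) = 1 iff neighbour i
    has the query's class. By default R is the number of relevant neighbours
    *within the top k* (0 relevant → AP 0); passing ``total_relevant``
    normalises by the reference-wide relevant count instead.
    """
    ranked = list(ranked_neighbor_classes)[:k]
    hits = 0
    score = 0.0
    for i, neighbor in enumerate(ranked, start=1):
        if neighbor == query_class:
            hits += 1
            score += hits / i
    denom = total_relevant if total_relevant is not None else hits
    if not denom:
        return 0.0
    return score / denom


def retrieval_map(
    ref_enc,
    ref_labels,
    query_enc,
    query_labels,
    cfg: RetrievalConfig | None = None,
) -> dict:
    """Per-class MAP of nearest-neighbour retrieval plus the unweighted mean.

    Each query cell is matched against its k euclidean nearest reference
    cells (distance ties broken by ascending reference index); the AP of
    same-class matches is averaged within each query class. A query class
    absent from the reference scores 0. ``Mean`` is the plain average over
    query classes, ignoring class sizes.
    """
    cfg = cfg or RetrievalConfig()
    ref = np.asarray(getattr(ref_enc, "values", ref_enc), dtype=float)
    query = np.asarray(getattr(query_enc, "values", query_enc), dtype=float)
    if ref.shape[1] != query.shape[1]:
        raise ValueError("reference and query encodings have different widths")
    rl = np.asarray(getattr(ref_labels, "labels", ref_labels), dtype=object)
    ql = np.asarray(getattr(query_labels, "labels", query_labels), dtype=object)
    if rl.size != ref.shape[0] or ql.size != query.shape[0]:
        raise ValueError("labels not aligned with encodings")

    n_ref = ref.shape[0]
    max_k = n_ref - 1 if (cfg.exclude_self and n_ref > 1) else n_ref
    k = cfg.k
    if k > max_k:
        warnings.warn(f"k={cfg.k} clamped to reference size {max_k}", stacklevel=2)
        k = max_k

    dists = cdist(query, ref, metric="euclidean")
    # stable argsort => equal distances resolved by ascending reference index
    order = np.argsort(dists, axis=1, kind="stable")

    ref_counts = {cls: int((rl == cls).sum()) for cls in set(rl)}
    ap_by_class: dict[str, list[float]] = {}
    for qi in range(query.shape[0]):
        neighbors = order[qi]
        if cfg.exclude_self:
            neighbors = neighbors[neighbors != qi]
        ranked = rl[neighbors[:k]]
        total = None
        if cfg.normalize_by_total_relevant:
            total = ref_counts.get(ql[qi], 0)
        ap = average_precision(ql[qi], ranked, k, total_relevant=total)
        ap_by_class.setdefault(str(ql[qi]), []).append(ap)

    per_class = {cls: float(np.mean(v)) for cls, v in sorted(ap_by_class.items())}
    return {
        "per_class": per_class,
        "mean": float(np.mean(list(per_class.values()))),
        "k": k,
    }
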