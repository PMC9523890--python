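"""Unsupervised subtyping: agglomerative clustering, elbow diagnostics,
cluster-validity metrics, cross-experiment similarity, and a permutation
screen for shared clustering structure across views."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_mutual_info_score

__all__ = [
    "ClusterOutcome",
    "IndependenceTestResult",
    "cluster_agglomerative",
    "elbow_distortion",
    "assign_subtype_labels",
    "ch_score",
    "silhouette_score",
    "ami_score",
    "pairwise_cluster_similarity",
    "confusion_table",
    "independence_permutation_test",
]


@dataclass
class ClusterOutcome:
    labels: np.ndarray  # cluster ids, 0-based
    subtype_map: dict[int, int]  # cluster id -> subtype (1 or 2)
    n_clusters: int
    linkage: str
    feature_set_name: str

    @property
    def subtypes(self) -> np.ndarray:
        return np.array([self.subtype_map[c] for c in self.labels])


@dataclass
class IndependenceTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    view_pair: str = ""


def cluster_agglomerative(
    features: np.ndarray, n_clusters: int, linkage: str = "ward"
) -> np.ndarray:
    """Hierarchical agglomeration (Ward/Euclidean by default) cut at
    ``n_clusters``. Deterministic."""
    features = np.asarray(features, dtype=float)
    if n_clusters > features.shape[0]:
        raise ValueError("n_clusters exceeds the number of samples")
    model = AgglomerativeClustering(n_clusters=n_clusters, linkage=linkage)
    return model.fit_predict(features)


def elbow_distortion(
    features: np.ndarray, k_range, linkage: str = "ward"
) -> dict[int, float]:
    """Mean squared Euclidean distance to the assigned-cluster centroid for
    each candidate k."""
    features = np.asarray(features, dtype=float)
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    out = {}
    for k in ks:
        labels = cluster_agglomerative(features, k, linkage)
        sq = 0.0
        for c in np.unique(labels):
            pts = features[labels == c]
            sq += float(np.sum((pts - pts.mean(axis=0)) ** 2))
        out[k] = sq / features.shape[0]
    return out


def assign_subtype_labels(
    labels: np.ndarray,
    stage_labels: np.ndarray | None,
    early_stage=None,
) -> dict[int, int]:
    """Map the two clusters to subtypes: the cluster with the higher
    early-to-late stage ratio becomes Subtype 1 (milder).

    Ties: a zero late count means an infinite ratio; an exact ratio tie is
    broken by cluster size (larger = Subtype 1), then by cluster index.
    Missing stage labels fall back to cluster-index order with a warning.
    """
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) != 2:
        raise ValueError("subtype assignment expects exactly 2 clusters")
    if stage_labels is None:
        warnings.warn("no stage labels; subtypes follow cluster index", stacklevel=2)
        return {int(c): i + 1 for i, c in enumerate(clusters)}
    stage_labels = np.asarray(stage_labels)
    cats = np.unique(stage_labels)
    if len(cats) > 2:
        raise ValueError("stage labels must be binary")
    early = sorted(cats.tolist())[0] if early_stage is None else early_stage

    def ratio(c):
        in_c = labels == c
        n_early = int(np.sum(stage_labels[in_c] == early))
        n_late = int(np.sum(in_c)) - n_early
        return np.inf if n_late == 0 else n_early / n_late

    # sort: higher ratio first, then larger cluster, then lower index
    keyed = sorted(
        clusters, key=lambda c: (-ratio(c), -int(np.sum(labels == c)), c)
    )
    return {int(keyed[0]): 1, int(keyed[1]): 2}


def ch_score(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [B/(K-1)] / [W/(N-K)].

    Implemented directly (rather than via sklearn) so that a vanishing
    within-cluster dispersion yields the +inf sentinel.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    K, N = len(clusters), features.shape[0]
    if K < 2:
        raise ValueError("CH score needs at least 2 clusters")
    grand = features.mean(axis=0)
    B = W = 0.0
    for c in clusters:
        pts = features[labels == c]
        mu = pts.mean(axis=0)
        B += pts.shape[0] * float(np.sum((mu - grand) ** 2))
        W += float(np.sum((pts - mu) ** 2))
    if W == 0.0:
        return np.inf if B > 0 else 0.0
    return (B / (K - 1)) / (W / (N - K))


def silhouette_score(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a) / max(a, b); singleton clusters and
    zero-distance cases contribute 0."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = cdist(features, features)
    N = features.shape[0]
    sil = np.zeros(N)
    masks = {c: labels == c for c in clusters}
    sizes = {c: int(np.sum(m)) for c, m in masks.items()}
    for i in range(N):
        own = labels[i]
        if sizes[own] == 1:
            continue  # silhouette 0 by convention
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[c]].mean() for c in clusters if c != own)
        denom = max(a, b)
        sil[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(sil.mean())


def ami_score(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted mutual information under the permutation model with the
    arithmetic-mean normalizer; returns 0 when either labeling is constant
    (degenerate denominator convention)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if len(np.unique(labels_a)) < 2 or len(np.unique(labels_b)) < 2:
        return 0.0
    return float(
        adjusted_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
    )


def pairwise_cluster_similarity(outcomes: list[ClusterOutcome]) -> pd.DataFrame:
    """Symmetric AMI matrix between experiments' label vectors; diagonal 1."""
    n = len(outcomes)
    lengths = {len(o.labels) for o in outcomes}
    if len(lengths) > 1:
        raise ValueError("all outcomes must cover the same samples")
    names = [o.feature_set_name for o in outcomes]
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = ami_score(outcomes[i].labels, outcomes[j].labels)
    return pd.DataFrame(M, index=names, columns=names)


def confusion_table(labels: np.ndarray, stage_labels: np.ndarray) -> pd.DataFrame:
    """2x2 stage-by-subtype count table."""
    return pd.crosstab(
        pd.Series(np.asarray(stage_labels), name="stage"),
        pd.Series(np.asarray(labels), name="subtype"),
    )


def independence_permutation_test(
    view_a: np.ndarray,
    view_b: np.ndarray,
    n_clusters: int = 2,
    n_permutations: int = 999,
    seed: int = 0,
    linkage: str = "ward",
    view_pair: str = "",
) -> IndependenceTestResult:
    """Permutation screen for shared clustering across two views.

    The statistic is the AMI between the two views' agglomerative
    clusterings; the null resamples by permuting view B's sample order,
    reclustering, and recomputing the AMI. Small p-values reject
    independence, i.e. support a shared clustering assignment.
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    view_a = np.asarray(view_a, dtype=float)
    view_b = np.asarray(view_b, dtype=float)
    if view_a.shape[0] != view_b.shape[0]:
        raise ValueError("views must share samples")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    labels_a = cluster_agglomerative(view_a, n_clusters, linkage)
    labels_b = cluster_agglomerative(view_b, n_clusters, linkage)
    observed = ami_score(labels_a, labels_b)
    rng = np.random.Generator(np.random.PCG64(seed))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(view_b.shape[0])
        null_labels = cluster_agglomerative(view_b[perm], n_clusters, linkage)
        if ami_score(labels_a, null_labels) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return IndependenceTestResult(
        statistic=float(observed),
        p_value=float(p),
        n_permutations=n_permutations,
        view_pair=view_pair,
    )
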