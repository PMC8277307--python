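"""K-means topic extraction with silhouette-based k selection and filters.

Topics within one stance group are the clusters of a K-means partition of
the count-feature space; the number of clusters is chosen by maximizing
the mean silhouette coefficient over a k range.  Two filters follow:
clusters holding at least a prominence threshold of the group's tweets
are the "prominent" topics, and clusters whose top terms are all
@-mentions ("handle-only" closed-loop conversations) are excluded from
analysis altogether.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import Vocabulary

__all__ = [
    "ClusterAssignment",
    "SilhouetteCurve",
    "ProminentSet",
    "kmeans_fit",
    "mean_silhouette",
    "select_k",
    "prominence_threshold",
    "filter_prominent",
    "top_terms",
    "is_handle_cluster",
]


@dataclass
class ClusterAssignment:
    """A K-means partition: labels, centroids and inertia."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)

    @property
    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass(frozen=True)
class SilhouetteCurve:
    """Mean silhouette coefficient per candidate k."""

    k_values: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not -1.0 - 1e-12 <= s <= 1.0 + 1e-12 for s in self.scores):
            raise ValueError("silhouette coefficients must lie in [-1, 1]")


@dataclass(frozen=True)
class ProminentSet:
    """Partition of clusters into prominent / rest / excluded handle-only."""

    threshold_count: int
    prominent: tuple[int, ...]
    excluded_handle_clusters: tuple[int, ...]
    rest: tuple[int, ...]

    def __post_init__(self) -> None:
        if set(self.prominent) & set(self.excluded_handle_clusters):
            raise ValueError("prominent and excluded cluster sets must be disjoint")


def kmeans_fit(
    features,
    k: int,
    seed: int | None = None,
    n_init: int = 10,
    normalize_rows: bool = False,
) -> ClusterAssignment:
    """Lloyd K-means with ``n_init`` seeded restarts, best inertia kept.

    ``normalize_rows`` L2-normalizes each row first (making clustering
    insensitive to tweet length); off by default — the reference
    procedure clusters raw counts.
    """
    n = features.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n_rows={n}")
    if normalize_rows:
        from sklearn.preprocessing import normalize

        features = normalize(features, norm="l2")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(features)
    return ClusterAssignment(
        k=k,
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def mean_silhouette(features, labels: Sequence[int]) -> float:
    """Mean over points of (b - a) / max(a, b); requires 2 <= k < n."""
    labels = np.asarray(labels)
    ids, counts = np.unique(labels, return_counts=True)
    if len(ids) < 2:
        raise ValueError("silhouette needs at least two clusters")
    if np.any(counts == 0):  # pragma: no cover - unique() never yields zero
        raise ValueError("every cluster must be non-empty")
    return float(silhouette_score(features, labels, metric="euclidean"))


def select_k(
    features,
    k_range: Sequence[int],
    seed: int | None = None,
    n_init: int = 10,
    normalize_rows: bool = False,
) -> tuple[int, SilhouetteCurve]:
    """Pick k maximizing mean silhouette over ``k_range`` (ties: smallest k)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    n = features.shape[0]
    if ks[0] < 2 or ks[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if normalize_rows:
        from sklearn.preprocessing import normalize

        features = normalize(features, norm="l2")
    scores = []
    best_k, best_s = None, -np.inf
    for k in ks:
        assign = kmeans_fit(features, k, seed=seed, n_init=n_init)
        s = mean_silhouette(features, assign.labels)
        scores.append(s)
        if s > best_s:  # strict: ties keep the smallest k
            best_k, best_s = k, s
    return best_k, SilhouetteCurve(tuple(ks), tuple(scores))


def prominence_threshold(total_tweets: int, fraction: float = 0.05) -> int:
    """Minimum cluster size to count as prominent: ceil(fraction * total).

    The base total is the caller's choice (e.g. all stance tweets, or the
    stance tweets net of excluded handle-only clusters).
    """
    if total_tweets < 0:
        raise ValueError("total_tweets must be nonnegative")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    return math.ceil(fraction * total_tweets)


def filter_prominent(
    assignment: ClusterAssignment,
    threshold_count: int,
    excluded: Sequence[int] = (),
) -> ProminentSet:
    """Split clusters into prominent (size >= threshold) and rest.

    Clusters listed in ``excluded`` (handle-only conversations) are left
    out of both sets.  prominent + rest + excluded = all clusters.
    """
    if threshold_count < 0:
        raise ValueError("threshold_count must be nonnegative")
    excluded = tuple(sorted(set(int(c) for c in excluded)))
    sizes = assignment.sizes
    prominent, rest = [], []
    for cid, size in sorted(sizes.items()):
        if cid in excluded:
            continue
        (prominent if size >= threshold_count else rest).append(cid)
    return ProminentSet(
        threshold_count=threshold_count,
        prominent=tuple(prominent),
        excluded_handle_clusters=excluded,
        rest=tuple(rest),
    )


def top_terms(
    features,
    assignment: ClusterAssignment,
    cluster_id: int,
    vocab: Vocabulary,
    n: int = 50,
    kinds: Sequence[str] | None = None,
) -> list[str]:
    """Top-n tokens of a cluster by summed within-cluster frequency.

    Ties are broken lexicographically; zero-frequency tokens never appear.
    ``kinds`` restricts the ranking to the given token kinds (e.g. exclude
    bigrams when ranking "words", as the handle filter does).
    """
    members = assignment.members(cluster_id)
    if members.size == 0:
        raise ValueError(f"unknown or empty cluster id {cluster_id}")
    counts = np.asarray(features[members].sum(axis=0)).ravel()
    tokens = vocab.tokens
    entries = [
        (tokens[j], counts[j])
        for j in np.flatnonzero(counts > 0)
        if kinds is None or vocab.kinds[j] in kinds
    ]
    entries.sort(key=lambda e: (-e[1], e[0]))
    return [tok for tok, _ in entries[:n]]


def is_handle_cluster(top: Sequence[str], vocab: Vocabulary) -> bool:
    """True iff every top term is an @-mention.

    Applied to the top 50 terms (or all available, if fewer): a cluster
    whose vocabulary is exhausted by handles is a closed-loop conversation
    thread, not public discourse.
    """
    if not top:
        raise ValueError("top term list is empty")
    return all(vocab.kind_of(t) == "mention" for t in top)
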