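"""Embedding-based multi-label EC scoring by nearest-cluster label transfer.

A contrastive encoder places proteins in a metric space where functional
similarity is geometric proximity. Function transfer then works per label:
every EC number gamma gets a cluster embedding z_gamma, the mean of all
training proteins annotated with gamma (a promiscuous protein contributes to
every one of its clusters). Query proteins are scored against every cluster
by distance — the smaller the distance, the more likely the query carries
that EC number.

Distances are mapped into [0, 1] scores with a rank-preserving exponential,
``s = exp(-d / tau)`` with tau the median distance of the positive-control
set (all true protein-EC pairs in training), so the conformal threshold grid
on [0, 1] applies directly. Thresholding scores at lam is equivalent to
thresholding distances at ``-tau * ln(lam)``.

Non-conformal cutoff baselines on the same distances:

* top-1: predict only the closest cluster;
* max-separation: sort distances ascending, cut at the largest gap between
  adjacent values, predict everything before the gap;
* sigma-threshold: predict all labels with distance below ``mu + 2*sigma`` of
  the positive-control distance distribution.

Also provides the triplet sampler used for contrastive training: for a
(possibly promiscuous) anchor, one of its EC numbers is chosen uniformly, a
positive is drawn among proteins sharing that EC, and a negative among
proteins sharing none of the anchor's ECs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

from .conformal import ScoreMatrix
from .ontology import AnnotationSet, ECNumber

__all__ = [
    "EmbeddingTable",
    "ClusterTable",
    "NearestClusterScorer",
    "SkipTriplet",
    "cluster_embeddings",
    "query_distances",
    "distances_to_scores",
    "max_separation_set",
    "top1_set",
    "positive_control_stats",
    "sigma_threshold_set",
    "sample_triplet",
]


@dataclass
class EmbeddingTable:
    """Per-protein real vectors of a common dimension."""

    proteins: List[str]
    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("embedding vectors must form a 2-D array")
        if self.vectors.shape[0] != len(self.proteins):
            raise ValueError("one vector per protein required")
        if self.vectors.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding table contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self):
        return len(self.proteins)

    def row(self, pid: str) -> np.ndarray:
        return self.vectors[self.proteins.index(pid)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.vectors,
            index=pd.Index(self.proteins, name="protein_id"),
            columns=[f"v{i + 1}" for i in range(self.dim)],
        )


@dataclass
class ClusterTable:
    """Per-EC cluster centroids with member counts."""

    labels: List[ECNumber]
    centroids: np.ndarray
    member_count: np.ndarray

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.member_count = np.asarray(self.member_count, dtype=int)
        if len(self.labels) != self.centroids.shape[0]:
            raise ValueError("one centroid per label required")
        if (self.member_count < 1).any():
            raise ValueError("clusters must have >= 1 member")

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]


def cluster_embeddings(
    train_emb: EmbeddingTable, train_truth: AnnotationSet
) -> ClusterTable:
    """Mean embedding per EC number over all training proteins carrying it.

    ECs with no embedded member are excluded (they cannot be predicted).
    """
    idx = {p: i for i, p in enumerate(train_emb.proteins)}
    missing = [p for p in train_truth.proteins if p not in idx]
    if missing:
        raise ValueError(
            f"annotated proteins without embeddings: {missing[:5]!r}"
        )
    sums: Dict[ECNumber, np.ndarray] = {}
    counts: Dict[ECNumber, int] = {}
    for pid in train_truth.proteins:
        vec = train_emb.vectors[idx[pid]]
        for ec in train_truth[pid]:
            if ec in sums:
                sums[ec] += vec
                counts[ec] += 1
            else:
                sums[ec] = vec.copy()
                counts[ec] = 1
    labels = sorted(sums)
    centroids = np.stack([sums[ec] / counts[ec] for ec in labels])
    member_count = np.array([counts[ec] for ec in labels])
    return ClusterTable(labels, centroids, member_count)


def query_distances(
    query: np.ndarray, clusters: ClusterTable, metric: str = "euclidean"
) -> np.ndarray:
    """Distance from a query vector to every cluster centroid."""
    query = np.asarray(query, dtype=float)
    if query.shape != (clusters.dim,):
        raise ValueError(
            f"query dimension {query.shape} does not match centroid "
            f"dimension {clusters.dim}"
        )
    return cdist(query[None, :], clusters.centroids, metric=metric).ravel()


def distances_to_scores(dist: np.ndarray, tau: float) -> np.ndarray:
    """Map non-negative distances to (0, 1] scores via ``exp(-d / tau)``.

    Strictly decreasing, so score ranking is the reverse of distance ranking;
    zero distance maps to score 1.
    """
    dist = np.asarray(dist, dtype=float)
    if (dist < 0).any():
        raise ValueError("distances must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")
    return np.exp(-dist / tau)


def _order(dist: np.ndarray) -> np.ndarray:
    # stable sort: label-universe order breaks distance ties
    return np.argsort(dist, kind="stable")


def top1_set(dist: np.ndarray, labels: Sequence[ECNumber]) -> Set[ECNumber]:
    """Singleton set of the closest cluster (ties go to label order)."""
    dist = np.asarray(dist, dtype=float)
    if len(dist) == 0:
        raise ValueError("need at least one label")
    return {labels[int(np.argmin(dist))]}


def max_separation_set(
    dist: np.ndarray, labels: Sequence[ECNumber]
) -> Set[ECNumber]:
    """Everything before the largest gap in the ascending distance list.

    The cut is placed at the first maximal gap between adjacent sorted
    distances; all labels strictly before the gap are predicted. With a
    single label, or when all distances are equal (no informative gap), the
    closest label alone is returned.
    """
    dist = np.asarray(dist, dtype=float)
    if len(dist) < 2:
        return top1_set(dist, labels)
    order = _order(dist)
    gaps = np.diff(dist[order])
    if gaps.max() <= 0:
        return top1_set(dist, labels)
    cut = int(np.argmax(gaps)) + 1  # first maximal gap
    return {labels[i] for i in order[:cut]}


def positive_control_stats(
    train_emb: EmbeddingTable,
    train_truth: AnnotationSet,
    clusters: ClusterTable,
    metric: str = "euclidean",
) -> Tuple[float, float]:
    """Mean and population SD of all true protein-EC cluster distances."""
    d = _positive_control_distances(train_emb, train_truth, clusters, metric)
    if len(d) < 2:
        raise ValueError("need >= 2 true protein-EC pairs to estimate sigma")
    return float(d.mean()), float(d.std())


def _positive_control_distances(
    train_emb: EmbeddingTable,
    train_truth: AnnotationSet,
    clusters: ClusterTable,
    metric: str = "euclidean",
) -> np.ndarray:
    idx = {p: i for i, p in enumerate(train_emb.proteins)}
    col = {ec: j for j, ec in enumerate(clusters.labels)}
    dmat = cdist(train_emb.vectors, clusters.centroids, metric=metric)
    out = []
    for pid in train_truth.proteins:
        i = idx[pid]
        for ec in train_truth[pid]:
            j = col.get(ec)
            if j is not None:
                out.append(dmat[i, j])
    return np.asarray(out, dtype=float)


def sigma_threshold_set(
    dist: np.ndarray, labels: Sequence[ECNumber], mu: float, sigma: float
) -> Set[ECNumber]:
    """Labels with distance strictly below ``mu + 2*sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    dist = np.asarray(dist, dtype=float)
    cutoff = mu + 2.0 * sigma
    return {labels[k] for k in np.flatnonzero(dist < cutoff)}


class SkipTriplet(Exception):
    """No eligible positive or negative exists for this anchor this epoch."""


def sample_triplet(
    anchor_id: str,
    train_truth: AnnotationSet,
    rng: np.random.Generator,
) -> Tuple[str, str, str]:
    """Draw an (anchor, positive, negative) triplet for contrastive training.

    One of the anchor's EC numbers is chosen uniformly at random; the
    positive is drawn uniformly among other proteins sharing that EC; the
    negative uniformly among proteins sharing none of the anchor's ECs.

    Raises
    ------
    SkipTriplet
        When no eligible positive or negative exists.
    """
    anchor_labels = train_truth[anchor_id]
    ecs = sorted(anchor_labels)
    gamma = ecs[int(rng.integers(len(ecs)))]
    positives = [
        p
        for p in train_truth.proteins
        if p != anchor_id and gamma in train_truth[p]
    ]
    negatives = [
        p
        for p in train_truth.proteins
        if p != anchor_id and not (train_truth[p] & anchor_labels)
    ]
    if not positives or not negatives:
        raise SkipTriplet(anchor_id)
    pos = positives[int(rng.integers(len(positives)))]
    neg = negatives[int(rng.integers(len(negatives)))]
    return anchor_id, pos, neg


class NearestClusterScorer(BaseEstimator):
    """Score query proteins against per-EC cluster embeddings.

    ``fit`` builds the cluster table (mean embedding per EC over its training
    members) and the positive-control distance statistics; ``transform``
    turns query embeddings into a [0, 1] score matrix compatible with
    :class:`~conformal_ec.conformal.FDRController`. The non-conformal cutoff
    baselines (top-1, max-separation, sigma-threshold) operate on the raw
    distances from :meth:`distances`.

    Parameters
    ----------
    metric : {"euclidean", "cosine"}, default "euclidean"
        Embedding distance.

    Attributes
    ----------
    clusters_ : ClusterTable
        Per-EC centroids and member counts.
    labels_ : list of ECNumber
        Predictable label universe (ECs with >= 1 embedded training member).
    mu_, sigma_ : float
        Mean and population SD of the positive-control distances (all true
        protein-EC pairs in the training set).
    tau_ : float
        Score scale: the median positive-control distance.
    """

    def __init__(self, metric: str = "euclidean"):
        self.metric = metric

    def fit(self, train_emb: EmbeddingTable, train_truth: AnnotationSet):
        self.clusters_ = cluster_embeddings(train_emb, train_truth)
        self.labels_ = self.clusters_.labels
        pc = _positive_control_distances(
            train_emb, train_truth, self.clusters_, self.metric
        )
        if len(pc) < 2:
            raise ValueError("need >= 2 true protein-EC pairs to calibrate")
        self.mu_ = float(pc.mean())
        self.sigma_ = float(pc.std())
        positive = pc[pc > 0]
        # fall back to the overall mean when the fit is degenerate (all
        # training proteins sit exactly on their centroids)
        self.tau_ = float(np.median(positive)) if len(positive) else max(
            self.mu_, 1e-12
        )
        if self.tau_ <= 0:
            self.tau_ = 1e-12
        return self

    def distances(self, emb: EmbeddingTable) -> np.ndarray:
        """Query-to-cluster distance matrix (rows follow ``emb.proteins``)."""
        self._check_fitted()
        if emb.dim != self.clusters_.dim:
            raise ValueError(
                f"embedding dimension {emb.dim} does not match training "
                f"dimension {self.clusters_.dim}"
            )
        return cdist(emb.vectors, self.clusters_.centroids, metric=self.metric)

    def transform(self, emb: EmbeddingTable) -> ScoreMatrix:
        """Score matrix ``exp(-d / tau_)`` over the predictable universe."""
        d = self.distances(emb)
        scores = np.exp(-d / self.tau_)
        return ScoreMatrix(list(emb.proteins), list(self.labels_), scores)

    def predict_baseline(
        self, emb: EmbeddingTable, strategy: str = "max-separation"
    ) -> List[Set[ECNumber]]:
        """Prediction sets from a non-conformal cutoff strategy.

        ``strategy`` is one of ``"top1"``, ``"max-separation"``,
        ``"sigma-threshold"``.
        """
        d = self.distances(emb)
        if strategy == "top1":
            return [top1_set(row, self.labels_) for row in d]
        if strategy == "max-separation":
            return [max_separation_set(row, self.labels_) for row in d]
        if strategy == "sigma-threshold":
            return [
                sigma_threshold_set(row, self.labels_, self.mu_, self.sigma_)
                for row in d
            ]
        raise ValueError(f"unknown baseline strategy {strategy!r}")

    def _check_fitted(self):
        if not hasattr(self, "clusters_"):
            raise RuntimeError("NearestClusterScorer is not fitted")
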