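"""k-medoids clustering of frame dissimilarities with automatic k selection.

Mesostates are identified by clustering the all-pairs RMSD matrix with a
k-medoids algorithm: the cluster representatives (medoids) are actual
trajectory frames, so every cluster has a concrete structure attached, and
the objective — the summed distance of frames to their medoid — has a clear
geometric meaning.

Two design points make every run exactly reproducible:

* a deterministic ranked initialization: each point j is scored by
  ``v_j = sum_i D(i, j) / sum_l D(i, l)`` and the k lowest-scoring points
  seed the medoids (points central to dense regions score low);
* lowest-index tie-breaking in both the assignment and the medoid-update
  step.

The number of clusters is chosen by an elbow rule on the total cost: k is
increased until the relative cost decrement falls below a threshold (1% by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .geometry import DistanceMatrix

__all__ = [
    "KMedoids",
    "Clustering",
    "ElbowTrace",
    "kmedoids_init",
    "kmedoids_fit",
    "auto_k_cluster",
]

logger = logging.getLogger(__name__)


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, DistanceMatrix):
        return D.values
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("expected a square distance matrix")
    return D


@dataclass
class Clustering:
    """Result of one k-medoids run on a fixed distance matrix."""

    k: int
    labels: np.ndarray
    medoids: np.ndarray
    total_cost: float
    n_iterations: int
    cost_history: list[float] = field(default_factory=list)


@dataclass
class ElbowTrace:
    """Cost-vs-k trace and the elbow decision derived from it."""

    costs: list[float]  # costs[i] is the total cost at k = i + 1
    chosen_k: int
    relative_decrements: list[float]  # entry i compares k = i + 1 with k = i + 2


def kmedoids_init(D, k: int) -> np.ndarray:
    """Deterministic ranked seeding: the k points with smallest v_j.

    ``v_j = sum_i D(i, j) / sum_l D(i, l)`` weights each distance to j by
    how isolated the opposite point i is; points at the heart of dense
    regions get small scores. Ties break toward the lowest index.
    """
    D = _as_matrix(D)
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    row_sums = D.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(row_sums[:, None] > 0, D / row_sums[:, None], 0.0)
    v = normalized.sum(axis=0)
    order = np.lexsort((np.arange(n), v))  # stable: lowest index on ties
    return np.sort(order[:k])


def _assign(D: np.ndarray, medoids: np.ndarray) -> np.ndarray:
    # argmin over medoid columns; ties resolve to the first (lowest) medoid
    # index because medoids are kept sorted
    return np.argmin(D[:, medoids], axis=1)


def _cost(D: np.ndarray, medoids: np.ndarray, labels: np.ndarray) -> float:
    return float(D[np.arange(D.shape[0]), medoids[labels]].sum())


class KMedoids(ClusterMixin, BaseEstimator):
    """k-medoids on a precomputed distance matrix (Voronoi-style updates).

    The algorithm alternates (a) assigning every point to its nearest
    medoid and (b) replacing each cluster's medoid by the in-cluster point
    minimizing the summed distance to its members, until the medoid set is
    stable. The total cost never increases, so termination is guaranteed.

    The ranked seeding concentrates on globally central points and can
    place several seeds inside one large basin; the Voronoi alternation
    alone cannot always escape such a start. A deterministic greedy swap
    refinement (best single medoid/non-medoid exchange, repeated until no
    exchange lowers the cost; ties to the lowest indices) therefore runs
    after the alternation converges. It preserves determinism and the
    non-increasing cost trace while reliably reaching the enumeration
    optimum on well-separated data.

    Parameters
    ----------
    n_clusters : number of clusters k.
    init : "ranked" for the deterministic seeding, or an explicit array of
        k medoid indices.
    max_iter : safety cap on alternation sweeps.
    swap_refine : run the greedy swap refinement after convergence
        (default True).

    Attributes
    ----------
    labels_ : (n,) cluster index per point.
    medoid_indices_ : (k,) sorted point indices acting as medoids.
    inertia_ : total cost (sum of distances to the assigned medoid).
    n_iter_ : sweeps executed.
    cost_history_ : cost after each sweep (non-increasing).
    """

    def __init__(
        self, n_clusters: int = 2, init="ranked", max_iter: int = 300, swap_refine: bool = True
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.max_iter = max_iter
        self.swap_refine = swap_refine

    def fit(self, X, y=None):
        D = _as_matrix(X)
        n = D.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} outside [1, {n}]")
        if isinstance(self.init, str):
            if self.init != "ranked":
                raise ValueError(f"unknown init {self.init!r}")
            medoids = kmedoids_init(D, k)
        else:
            medoids = np.sort(np.asarray(self.init, dtype=int))
            if medoids.size != k or np.unique(medoids).size != k:
                raise ValueError("init must give k distinct medoid indices")
            if medoids.min() < 0 or medoids.max() >= n:
                raise ValueError("init medoid index out of range")

        labels = _assign(D, medoids)
        medoids, labels = self._fix_empty(D, medoids, labels)
        history = [_cost(D, medoids, labels)]
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            new_medoids = medoids.copy()
            for c in range(k):
                members = np.flatnonzero(labels == c)
                # in-cluster cost minimizer; lowest index wins ties via argmin
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[c] = members[int(np.argmin(within))]
            new_medoids = np.sort(new_medoids)
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
            labels = _assign(D, medoids)
            medoids, labels = self._fix_empty(D, medoids, labels)
            history.append(_cost(D, medoids, labels))

        if self.swap_refine:
            medoids, labels, history = self._swap_refine(D, medoids, history)

        self.labels_ = labels
        self.medoid_indices_ = medoids
        self.inertia_ = history[-1]
        self.n_iter_ = n_iter
        self.cost_history_ = history
        return self

    @staticmethod
    def _swap_refine(
        D: np.ndarray, medoids: np.ndarray, history: list[float]
    ) -> tuple[np.ndarray, np.ndarray, list[float]]:
        """Greedy best-improvement medoid/non-medoid exchange to convergence."""
        n = D.shape[0]
        k = medoids.size
        current = history[-1]
        while True:
            best = (current, None, None)
            non_medoids = np.setdiff1d(np.arange(n), medoids)
            if non_medoids.size == 0:
                break
            for pos in range(k):
                others = np.delete(medoids, pos)
                # nearest distance to the retained medoids, per point
                cache = D[:, others].min(axis=1) if others.size else np.full(n, np.inf)
                costs = np.minimum(cache[:, None], D[:, non_medoids]).sum(axis=0)
                j = int(np.argmin(costs))  # lowest candidate index wins ties
                if costs[j] < best[0] - 1e-12:
                    best = (float(costs[j]), pos, non_medoids[j])
            if best[1] is None:
                break
            current, pos, h = best
            medoids = np.sort(np.concatenate([np.delete(medoids, pos), [h]]))
            history.append(current)
        labels = _assign(D, medoids)
        return medoids, labels, history

    @staticmethod
    def _fix_empty(
        D: np.ndarray, medoids: np.ndarray, labels: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Re-seed clusters emptied by the assignment step.

        An empty cluster (possible with duplicated points) is re-seeded
        with the non-medoid point farthest from all current medoids; the
        event is logged, never silently dropped.
        """
        while True:
            empty = [c for c in range(medoids.size) if not np.any(labels == c)]
            if not empty:
                return medoids, labels
            c = empty[0]
            candidates = np.setdiff1d(np.arange(D.shape[0]), medoids)
            far = candidates[int(np.argmax(D[np.ix_(candidates, medoids)].min(axis=1)))]
            logger.warning("re-seeding empty cluster %d with point %d", c, far)
            medoids = np.sort(np.concatenate([np.delete(medoids, c), [far]]))
            labels = _assign(D, medoids)


def kmedoids_fit(D, k: int, init=None) -> Clustering:
    """Functional wrapper around :class:`KMedoids` returning a :class:`Clustering`."""
    est = KMedoids(n_clusters=k, init="ranked" if init is None else init).fit(D)
    return Clustering(
        k=k,
        labels=est.labels_,
        medoids=est.medoid_indices_,
        total_cost=est.inertia_,
        n_iterations=est.n_iter_,
        cost_history=est.cost_history_,
    )


def auto_k_cluster(
    D,
    threshold: float = 0.01,
    k_max: int | None = None,
    keep_at_elbow: str = "previous",
) -> tuple[Clustering, ElbowTrace]:
    """Elbow-rule clustering: grow k until the cost stops improving.

    k runs 1, 2, ... and stops at the first k >= 2 whose relative cost
    decrement ``(cost(k-1) - cost(k)) / cost(k-1)`` drops below
    ``threshold`` (or when the cost reaches zero, or at ``k_max``).
    A sub-threshold decrement means the step to k bought essentially
    nothing, so by default the clustering *before* it is kept
    (``keep_at_elbow="previous"``); ``"current"`` keeps the clustering at
    the stopping k itself.
    """
    Dm = _as_matrix(D)
    n = Dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if k_max is None:
        k_max = n
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if keep_at_elbow not in ("current", "previous"):
        raise ValueError("keep_at_elbow must be 'current' or 'previous'")

    costs: list[float] = []
    decrements: list[float] = []
    previous: Clustering | None = None
    clustering = kmedoids_fit(Dm, 1)
    costs.append(clustering.total_cost)
    k = 1
    while clustering.total_cost > 0 and k < k_max:
        k += 1
        previous = clustering
        clustering = kmedoids_fit(Dm, k)
        costs.append(clustering.total_cost)
        dec = (costs[-2] - costs[-1]) / costs[-2]
        decrements.append(dec)
        if dec < threshold:
            if keep_at_elbow == "previous" and previous is not None:
                clustering = previous
            break
    return clustering, ElbowTrace(
        costs=costs, chosen_k=clustering.k, relative_decrements=decrements
    )
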