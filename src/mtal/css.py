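"""Clustered Stratified Sampling (CSS).

Greedy uncertainty sampling tends to pile queries onto whichever classes the
current model confuses, biasing the labeled pool. CSS counters this by
partitioning the unlabeled pool into k feature-space clusters (k-means) and
filling the query batch with an **equal quota of the most informative samples
from each cluster**. The cluster count follows the task structure:

* one-sided / alternating selection: k = number of classes of the (current)
  reference task;
* rank combination (no reference task): k = C_max, the maximum class count
  over all tasks.

Quota rules for batch size b and k clusters: every cluster owes floor(b/k);
the b mod k remainder goes one-by-one to clusters in decreasing order of their
single best candidate's informativeness (ties -> lowest cluster id). A cluster
smaller than its quota contributes everything it has and the deficit is
redistributed by the same order rule. With k = 1, CSS reduces exactly to plain
top-b selection under the same measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .datasets import PoolState, TaskSpec
from .exceptions import EmptyPoolError
from .strategies import QueryBatch

__all__ = ["ClusterAssignment", "choose_cluster_count", "cluster_pool", "stratified_select"]


@dataclass
class ClusterAssignment:
    """Cluster id per unlabeled-pool position, with centers and the seed used."""

    cluster_ids: np.ndarray
    k: int
    centers: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=np.int64)
        if self.cluster_ids.min(initial=0) < 0 or self.cluster_ids.max(initial=0) >= self.k:
            raise ValueError("cluster ids must lie in [0, k)")


def choose_cluster_count(
    tasks: list[TaskSpec],
    strategy: str,
    reference: int | None = None,
) -> int:
    """Cluster count rule: reference task's class count, or C_max when no reference."""
    if strategy in ("one_sided", "alternating"):
        if reference is None:
            raise ValueError(f"strategy {strategy!r} needs a reference task for the cluster count")
        return tasks[reference].n_classes
    return max(t.n_classes for t in tasks)


def cluster_pool(
    features: np.ndarray,
    k: int,
    seed: int,
    restarts: int = 10,
) -> ClusterAssignment:
    """Partition the unlabeled pool's features into k clusters with k-means.

    Runs ``restarts`` seeded initialisations and keeps the best inertia, so the
    assignment is deterministic under ``seed``. If the pool holds fewer than k
    samples, k is reduced to the pool size with a warning.
    """
    X = np.asarray(features, dtype=float)
    m = X.shape[0]
    if m == 0:
        raise EmptyPoolError("cannot cluster an empty pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    if m < k:
        warnings.warn(f"pool size {m} < k={k}; reducing k to {m}", stacklevel=2)
        k = m
    km = KMeans(n_clusters=k, n_init=restarts, random_state=int(seed) % (2**31))
    ids = km.fit_predict(X)
    return ClusterAssignment(cluster_ids=ids, k=k, centers=km.cluster_centers_, seed=seed)


def stratified_select(
    assignment: ClusterAssignment,
    scores: np.ndarray,
    pool: PoolState,
    b: int,
    strategy: str = "css",
) -> QueryBatch:
    """Fill the batch with equal per-cluster quotas of the most informative samples.

    ``scores`` is a 1-D informativeness vector aligned with ``pool.unlabeled``
    (higher = more informative; for rank-combination mode pass negated rank
    sums). Selects ``min(b, |U_m|)`` indices in total.
    """
    scores = np.asarray(scores, dtype=float)
    if pool.n_unlabeled == 0:
        raise EmptyPoolError("unlabeled pool is empty")
    if scores.shape != (pool.n_unlabeled,) or assignment.cluster_ids.shape != scores.shape:
        raise ValueError("scores and cluster ids must align with the unlabeled pool")
    if b < 1:
        raise ValueError("batch size must be >= 1")
    total = min(b, pool.n_unlabeled)
    if total < b:
        warnings.warn(f"batch size {b} exceeds pool size {pool.n_unlabeled}; truncating", stacklevel=2)

    k = assignment.k
    members = [np.flatnonzero(assignment.cluster_ids == c) for c in range(k)]
    sizes = np.array([len(mem) for mem in members])

    # remainder/deficit order: decreasing best-candidate score, ties -> lowest id
    best = np.array([scores[mem].max() if len(mem) else -np.inf for mem in members])
    order = np.lexsort((np.arange(k), -best))

    quota = np.minimum(total // k, sizes)
    left = total - int(quota.sum())
    while left > 0:
        progressed = False
        for c in order:
            if left == 0:
                break
            if quota[c] < sizes[c]:
                quota[c] += 1
                left -= 1
                progressed = True
        if not progressed:  # no spare capacity anywhere
            break

    positions: list[int] = []
    for c in range(k):
        if quota[c] == 0:
            continue
        mem = members[c]
        # most informative members first, ties -> lowest unlabeled index
        inner = np.lexsort((pool.unlabeled[mem], -scores[mem]))
        positions.extend(mem[inner[: quota[c]]].tolist())

    pos = np.asarray(positions, dtype=np.int64)
    return QueryBatch(
        indices=pool.unlabeled[pos],
        strategy=strategy,
        provenance=[
            {"cluster_id": int(assignment.cluster_ids[p]), "score": float(scores[p])}
            for p in pos
        ],
    )
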