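"""Query strategies over an uncertainty matrix and a pool state.

Three uncertainty-driven strategies plus a random control:

* **one-sided** — rank the unlabeled pool by informativeness on a single
  reference task; by default the task with maximum *combined correlation*,
  i.e. the largest sum of absolute pairwise label correlations with the other
  tasks.
* **alternating** — one-sided with the reference task rotating round-robin
  over iterations.
* **rank combination (RC)** — per task, rank samples by entropy (rank 1 =
  highest entropy); sum the T ranks per sample and query the smallest sums.
* **random** — uniform without replacement, the control baseline.

Tie conventions (the batch must be reproducible): within-task rank ties get
average (fractional) ranks; ties in a final score or rank sum are broken by
lowest sample index; ties in combined correlation by lowest task index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from scipy.stats.contingency import association, crosstab

from .datasets import PoolState
from .uncertainty import UncertaintyMatrix

__all__ = [
    "QueryBatch",
    "pairwise_association",
    "combined_correlation",
    "reference_task",
    "select_one_sided",
    "select_alternating",
    "rank_sums",
    "select_rank_combination",
    "select_random",
]


@dataclass
class QueryBatch:
    """The indices chosen in one query iteration, with per-index provenance."""

    indices: np.ndarray
    strategy: str
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("query batch contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


# --- Reference-task selection ---------------------------------------------------


def pairwise_association(labels: np.ndarray, method: str = "pearson") -> np.ndarray:
    """T x T matrix of absolute pairwise associations between label columns.

    ``method='pearson'`` uses |Pearson r| of the integer-coded columns (codes
    follow the dataset's declared class order); ``method='cramers_v'`` uses
    Cramér's V from the contingency table. A constant column associates 0 with
    everything (with a warning), never raising.
    """
    labels = np.asarray(labels)
    T = labels.shape[1]
    out = np.zeros((T, T))
    constant = [i for i in range(T) if np.unique(labels[:, i]).size < 2]
    if constant:
        warnings.warn(
            f"label column(s) {constant} are constant; they contribute 0 association",
            stacklevel=2,
        )
    for i in range(T):
        for j in range(i + 1, T):
            if i in constant or j in constant:
                val = 0.0
            elif method == "pearson":
                val = abs(float(np.corrcoef(labels[:, i].astype(float), labels[:, j].astype(float))[0, 1]))
            elif method == "cramers_v":
                table = crosstab(labels[:, i], labels[:, j]).count
                val = float(association(table, method="cramer"))
            else:
                raise ValueError(f"unknown association method {method!r}")
            out[i, j] = out[j, i] = val
    return out


def combined_correlation(
    labels: np.ndarray | None = None,
    *,
    matrix: np.ndarray | None = None,
    method: str = "pearson",
) -> np.ndarray:
    """Combined correlation per task: sum of its pairwise associations with all others.

    Either pass the (n, T) label matrix, or ``matrix=`` a precomputed T x T
    pairwise association matrix (its diagonal is ignored).
    """
    if (labels is None) == (matrix is None):
        raise ValueError("pass exactly one of labels or matrix")
    if matrix is None:
        matrix = pairwise_association(labels, method=method)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("association matrix must be square")
    off = matrix - np.diag(np.diag(matrix))
    return off.sum(axis=1)


def reference_task(
    labels: np.ndarray | None = None,
    *,
    matrix: np.ndarray | None = None,
    method: str = "pearson",
) -> int:
    """Index of the task with maximum combined correlation (ties -> lowest index)."""
    combined = combined_correlation(labels, matrix=matrix, method=method)
    return int(np.argmax(combined))  # argmax already takes the first maximum


# --- Selectors ------------------------------------------------------------------


def _effective_batch(pool: PoolState, b: int) -> int:
    if b < 1:
        raise ValueError("batch size must be >= 1")
    if pool.n_unlabeled == 0:
        raise ValueError("unlabeled pool is empty")
    if b > pool.n_unlabeled:
        warnings.warn(
            f"batch size {b} exceeds unlabeled pool size {pool.n_unlabeled}; truncating",
            stacklevel=3,
        )
        return pool.n_unlabeled
    return b


def _top_b(scores: np.ndarray, pool: PoolState, b: int) -> np.ndarray:
    """Positions (into pool.unlabeled) of the b best scores, ties -> lowest index."""
    order = np.lexsort((pool.unlabeled, -scores))
    return order[:b]


def select_one_sided(
    uncertainty: UncertaintyMatrix,
    reference: int,
    pool: PoolState,
    b: int,
) -> QueryBatch:
    """Query the b unlabeled samples most informative for the reference task."""
    if not 0 <= reference < uncertainty.n_tasks:
        raise ValueError(f"reference task {reference} out of range [0, {uncertainty.n_tasks})")
    if uncertainty.scores.shape[0] != pool.n_unlabeled:
        raise ValueError("uncertainty rows must align with the unlabeled pool")
    b = _effective_batch(pool, b)
    col = uncertainty.scores[:, reference]
    pos = _top_b(col, pool, b)
    return QueryBatch(
        indices=pool.unlabeled[pos],
        strategy="one_sided",
        provenance=[
            {"reference_task": reference, "score": float(col[p])} for p in pos
        ],
    )


def select_alternating(
    uncertainty: UncertaintyMatrix,
    iteration: int,
    pool: PoolState,
    b: int,
) -> QueryBatch:
    """One-sided selection with the reference task rotating as ``iteration % T``."""
    ref = int(iteration) % uncertainty.n_tasks
    batch = select_one_sided(uncertainty, ref, pool, b)
    batch.strategy = "alternating"
    return batch


def rank_sums(scores: np.ndarray) -> np.ndarray:
    """Combined rank R per sample: per task, rank 1 = most informative; sum over tasks.

    Ties within a task receive average (fractional) ranks, making the sums
    stable under permutation of tied samples.
    """
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(-scores, axis=0, method="average")
    return ranks.sum(axis=1)


def select_rank_combination(
    uncertainty: UncertaintyMatrix,
    pool: PoolState,
    b: int,
) -> QueryBatch:
    """Query the b samples with the smallest combined rank across tasks."""
    if uncertainty.scores.shape[0] != pool.n_unlabeled:
        raise ValueError("uncertainty rows must align with the unlabeled pool")
    b = _effective_batch(pool, b)
    sums = rank_sums(uncertainty.scores)
    pos = _top_b(-sums, pool, b)  # smallest rank sum = best
    return QueryBatch(
        indices=pool.unlabeled[pos],
        strategy="rank_combination",
        provenance=[{"rank_sum": float(sums[p])} for p in pos],
    )


def select_random(pool: PoolState, b: int, seed: int) -> QueryBatch:
    """Uniform sample without replacement from the unlabeled pool."""
    b = _effective_batch(pool, b)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool.unlabeled, size=b, replace=False)
    return QueryBatch(
        indices=chosen,
        strategy="random",
        provenance=[{"seed": int(seed)} for _ in range(b)],
    )
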