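"""The iterative multitask active-learning driver.

Each iteration trains the multitask model on the labeled pool L_n, scores the
unlabeled pool U_m, selects a mini-batch of b samples (optionally through
clustered stratified sampling), asks the simulated oracle for their labels,
and moves them into L_n — so after q iterations |L_n| = n_seed + q*b. The loop
stops when the query budget B is exhausted (or the pool empties), then trains
a final model on everything labeled.

Budget guard: the classic loop condition ``while k*b < B`` overshoots B when b
does not divide it. The default ``budget_mode='capped'`` clamps the final batch
so total queries equal B exactly (the budget is a hard cap); ``'literal'``
keeps the classic guard and may overshoot by up to b-1 queries.

The non-iterative control trains once on the seed, selects all B samples in a
single batch with that seed model's scores, labels them, and retrains once —
one oracle interaction regardless of budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .css import choose_cluster_count, cluster_pool, stratified_select
from .datasets import MultitaskDataset, PoolState
from .exceptions import InvalidQueryError
from .model import ModelConfig, evaluate_accuracy, fit, predict_proba
from .strategies import (
    QueryBatch,
    rank_sums,
    reference_task,
    select_alternating,
    select_one_sided,
    select_random,
    select_rank_combination,
)
from .uncertainty import score_pool

__all__ = [
    "CSSConfig",
    "RunConfig",
    "IterationRecord",
    "RunResult",
    "oracle_label",
    "run_iterative",
    "run_non_iterative",
    "run_experiment",
]

STRATEGIES = ("one_sided", "alternating", "rank_combination", "random")

#: informativeness measure each strategy uses unless overridden
DEFAULT_MEASURES = {
    "one_sided": "least_confidence",
    "alternating": "least_confidence",
    "rank_combination": "entropy",
}


@dataclass(frozen=True)
class CSSConfig:
    """Clustered-stratified-sampling settings for a run.

    ``k='auto'`` applies the cluster-count rule (reference task's class count,
    or C_max for rank combination). For alternating selection the reference
    task rotates; ``rotate_k=True`` lets the cluster count rotate with it,
    ``False`` pins it at C_max.
    """

    enabled: bool = False
    k: int | str = "auto"
    restarts: int = 10
    rotate_k: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Everything one active-learning run needs besides the dataset."""

    strategy: str = "rank_combination"
    measure: str | None = None
    css: CSSConfig = CSSConfig()
    budget: int = 100
    batch_size: int = 20
    n_seed: int = 3
    reference: int | str = "auto"
    iterative: bool = True
    budget_mode: str = "capped"
    max_queries: int | None = None
    model: ModelConfig = ModelConfig()
    data_seed: int = 0
    strategy_seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; choose from {STRATEGIES}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.iterative and self.budget < self.batch_size:
            raise ValueError("iterative mode needs budget >= batch_size")
        if self.budget_mode not in ("capped", "literal"):
            raise ValueError("budget_mode must be 'capped' or 'literal'")
        if self.measure is not None and self.strategy == "rank_combination" and self.measure != "entropy":
            # permitted, but the classic formulation ranks entropies
            pass

    @property
    def effective_measure(self) -> str | None:
        if self.measure is not None:
            return self.measure
        return DEFAULT_MEASURES.get(self.strategy)

    @property
    def query_cap(self) -> int:
        return self.budget if self.max_queries is None else self.max_queries


@dataclass
class IterationRecord:
    iteration: int
    queries_spent: int
    n_labeled: int
    n_unlabeled: int
    task_accuracy: list[float]
    average_accuracy: float


@dataclass
class RunResult:
    """Per-iteration trace of one run plus the final labeled pool."""

    records: list[IterationRecord]
    config: dict
    final_fingerprint: str
    labeled_indices: np.ndarray
    reference: int | None = None

    @property
    def total_queries(self) -> int:
        return self.records[-1].queries_spent if self.records else 0

    @property
    def final_average_accuracy(self) -> float:
        return self.records[-1].average_accuracy

    def to_frame(self) -> pd.DataFrame:
        rows = [asdict(r) for r in self.records]
        frame = pd.DataFrame(rows)
        accs = pd.DataFrame(
            frame.pop("task_accuracy").tolist(),
            columns=[f"task{i}_accuracy" for i in range(len(self.records[0].task_accuracy))],
        )
        return pd.concat([frame, accs], axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "records": [asdict(r) for r in self.records],
            "config": self.config,
            "final_fingerprint": self.final_fingerprint,
            "labeled_indices": self.labeled_indices.tolist(),
            "reference": self.reference,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunResult":
        payload = json.loads(Path(path).read_text())
        records = [IterationRecord(**r) for r in payload["records"]]
        return cls(
            records=records,
            config=payload["config"],
            final_fingerprint=payload["final_fingerprint"],
            labeled_indices=np.asarray(payload["labeled_indices"], dtype=np.int64),
            reference=payload.get("reference"),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def oracle_label(dataset: MultitaskDataset, pool: PoolState, indices: np.ndarray) -> np.ndarray:
    """Simulated annotator: ground-truth labels (all T tasks) for queried indices.

    Only indices currently in the unlabeled pool may be queried.
    """
    indices = np.asarray(indices, dtype=np.int64)
    outside = indices[~np.isin(indices, pool.unlabeled)]
    if outside.size:
        raise InvalidQueryError(f"indices not in the unlabeled pool: {outside.tolist()}")
    return dataset.labels[indices]


def _resolve_reference(dataset: MultitaskDataset, config: RunConfig) -> int | None:
    """Reference task for one-sided selection (max combined correlation).

    Computed once per run from the training-split labels, mirroring the
    dataset-level correlation analysis that motivates the rule. Alternating
    selection rotates its own reference and rank combination needs none.
    """
    if config.reference != "auto":
        return int(config.reference)
    if config.strategy == "one_sided":
        return reference_task(dataset.labels[dataset.train_indices])
    return None


def _iteration_seed(base: int, iteration: int, salt: int) -> int:
    ss = np.random.SeedSequence([int(base) % (2**31), iteration, salt])
    return int(ss.generate_state(1)[0] % (2**31))


def _select_batch(
    dataset: MultitaskDataset,
    pool: PoolState,
    config: RunConfig,
    model,
    iteration: int,
    reference: int | None,
) -> QueryBatch:
    b = min(config.batch_size, pool.n_unlabeled)
    if config.strategy == "random" and not config.css.enabled:
        return select_random(pool, b, seed=_iteration_seed(config.strategy_seed, iteration, 2))

    X_um = dataset.features[pool.unlabeled]
    probs = predict_proba(model, X_um)
    measure = config.effective_measure or "least_confidence"
    U = score_pool(probs, measure)

    ref = reference
    if config.strategy == "alternating":
        ref = iteration % dataset.n_tasks

    if config.css.enabled and config.strategy != "random":
        if config.css.k == "auto":
            if config.strategy == "alternating" and not config.css.rotate_k:
                k = max(t.n_classes for t in dataset.tasks)
            else:
                k = choose_cluster_count(dataset.tasks, config.strategy, ref)
        else:
            k = int(config.css.k)
        assignment = cluster_pool(
            X_um, k,
            seed=_iteration_seed(config.strategy_seed, iteration, 3),
            restarts=config.css.restarts,
        )
        if config.strategy == "rank_combination":
            scores = -rank_sums(U.scores)  # smaller rank sum = more informative
        else:
            scores = U.scores[:, ref]
        batch = stratified_select(assignment, scores, pool, b, strategy=f"css_{config.strategy}")
        return batch

    if config.strategy == "one_sided":
        return select_one_sided(U, ref, pool, b)
    if config.strategy == "alternating":
        return select_alternating(U, iteration, pool, b)
    if config.strategy == "rank_combination":
        return select_rank_combination(U, pool, b)
    # random + css is not meaningful: fall back to plain random
    return select_random(pool, b, seed=_iteration_seed(config.strategy_seed, iteration, 2))


def _fit_on_pool(dataset: MultitaskDataset, pool: PoolState, config: RunConfig, iteration: int):
    X = dataset.features[pool.labeled]
    Y = dataset.labels[pool.labeled]
    model_cfg = config.model.with_seed(_iteration_seed(config.model.seed, iteration, 1))
    return fit(model_cfg, X, Y, dataset.tasks)


def run_iterative(dataset: MultitaskDataset, pool: PoolState, config: RunConfig) -> RunResult:
    """Run the mini-batch active-learning loop until the budget is spent.

    The supplied pool is not mutated; the returned result carries the final
    labeled index set. Fully deterministic under the config's seeds.
    """
    pool = pool.copy()
    reference = _resolve_reference(dataset, config)
    n_train = pool.n_train
    model = _fit_on_pool(dataset, pool, config, iteration=0)

    records: list[IterationRecord] = []
    queries = 0
    k = 0
    while pool.n_unlabeled > 0:
        if config.budget_mode == "capped":
            remaining = config.query_cap - queries
            if remaining <= 0:
                break
            b_iter = min(config.batch_size, remaining)
        else:
            if k * config.batch_size >= config.budget:
                break
            b_iter = config.batch_size
        cfg_iter = config if b_iter == config.batch_size else _with_batch(config, b_iter)
        batch = _select_batch(dataset, pool, cfg_iter, model, k, reference)
        oracle_label(dataset, pool, batch.indices)  # validates and "labels"
        pool.move_to_labeled(batch.indices)
        queries += len(batch)
        k += 1
        model = _fit_on_pool(dataset, pool, config, iteration=k)
        per_task, avg = evaluate_accuracy(model, dataset, "test")
        assert pool.n_train == n_train  # pool conservation
        records.append(
            IterationRecord(
                iteration=k,
                queries_spent=queries,
                n_labeled=pool.n_labeled,
                n_unlabeled=pool.n_unlabeled,
                task_accuracy=per_task.tolist(),
                average_accuracy=avg,
            )
        )

    return RunResult(
        records=records,
        config=_config_dict(config),
        final_fingerprint=model.fingerprint,
        labeled_indices=pool.labeled.copy(),
        reference=reference,
    )


def run_non_iterative(dataset: MultitaskDataset, pool: PoolState, config: RunConfig) -> RunResult:
    """Single-interaction control: seed model picks all B samples at once."""
    pool = pool.copy()
    reference = _resolve_reference(dataset, config)
    model = _fit_on_pool(dataset, pool, config, iteration=0)
    B = min(config.query_cap, pool.n_unlabeled)
    cfg = _with_batch(config, B)
    batch = _select_batch(dataset, pool, cfg, model, 0, reference)
    oracle_label(dataset, pool, batch.indices)
    pool.move_to_labeled(batch.indices)
    model = _fit_on_pool(dataset, pool, config, iteration=1)
    per_task, avg = evaluate_accuracy(model, dataset, "test")
    record = IterationRecord(
        iteration=1,
        queries_spent=len(batch),
        n_labeled=pool.n_labeled,
        n_unlabeled=pool.n_unlabeled,
        task_accuracy=per_task.tolist(),
        average_accuracy=avg,
    )
    return RunResult(
        records=[record],
        config=_config_dict(config),
        final_fingerprint=model.fingerprint,
        labeled_indices=pool.labeled.copy(),
        reference=reference,
    )


def run_experiment(dataset: MultitaskDataset, config: RunConfig) -> RunResult:
    """Convenience wrapper: draw the seed pool, then run per ``config.iterative``."""
    from .datasets import split_seed

    pool = split_seed(dataset, config.n_seed, seed=config.data_seed)
    runner = run_iterative if config.iterative else run_non_iterative
    return runner(dataset, pool, config)


def _with_batch(config: RunConfig, b: int) -> RunConfig:
    from dataclasses import replace

    return replace(config, batch_size=b, budget=max(config.budget, b))


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = asdict(config)
    d["model"]["shared_layer_widths"] = list(d["model"]["shared_layer_widths"])
    return d
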