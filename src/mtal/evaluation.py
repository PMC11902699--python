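"""Strategy-comparison harness and reporting.

Runs a grid of (strategy x CSS flag) cells on a shared synthetic benchmark,
reads average test accuracy at the requested budget checkpoints, and
aggregates mean +/- sd over repeats into a comparison table. Reporting is
pure: regenerating a table from stored run results is byte-identical.

Seed isolation: every cell derives its seeds from (master seed, strategy name,
css flag, repeat index), so adding a strategy or budget to the grid never
perturbs the numbers of existing cells.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import MultitaskDataset
from .loop import CSSConfig, RunConfig, RunResult, run_experiment

__all__ = ["learning_curve", "ComparisonCell", "ComparisonTable", "compare_strategies", "format_table", "plot_learning_curves"]


def learning_curve(results: Sequence[RunResult]) -> pd.DataFrame:
    """Aggregate repeated runs into a budget -> accuracy table.

    Rows are the distinct ``queries_spent`` checkpoints (ascending); columns
    give per-task and average accuracy as mean and sd over the runs that
    reached each checkpoint.
    """
    if not results:
        raise ValueError("need at least one run result")
    n_tasks = {len(r.records[0].task_accuracy) for r in results}
    if len(n_tasks) != 1:
        raise ValueError("runs mix different task counts")
    T = n_tasks.pop()
    rows = []
    for r in results:
        for rec in r.records:
            rows.append(
                {"queries": rec.queries_spent, "average": rec.average_accuracy,
                 **{f"task{i}": rec.task_accuracy[i] for i in range(T)}}
            )
    long = pd.DataFrame(rows)
    agg = long.groupby("queries").agg(["mean", "std", "count"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    agg = agg.rename(columns={c: c.replace("_count", "_n") for c in agg.columns})
    return agg.sort_index().reset_index()


@dataclass
class ComparisonCell:
    strategy: str
    css: bool
    budget: int
    mean: float | None
    sd: float | None
    n_repeats: int
    error: str | None = None


@dataclass
class ComparisonTable:
    """Mean +/- sd average accuracy per (strategy, css, budget) cell."""

    cells: list[ComparisonCell]
    master_seed: int
    results: dict = field(default_factory=dict)  # (strategy, css) -> list[RunResult]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [
                {
                    "strategy": c.strategy,
                    "css": c.css,
                    "budget": c.budget,
                    "mean_accuracy": c.mean,
                    "sd": c.sd,
                    "n_repeats": c.n_repeats,
                    "error": c.error,
                }
                for c in self.cells
            ]
        )
        return frame.sort_values(["strategy", "css", "budget"], kind="stable").reset_index(drop=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _cell_seed(master_seed: int, strategy: str, css: bool, repeat: int, salt: int) -> int:
    key = [int(master_seed) % (2**31), zlib.crc32(strategy.encode()) % (2**31), int(css), repeat, salt]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def compare_strategies(
    dataset: MultitaskDataset,
    strategies: Sequence[str],
    budgets: Sequence[int],
    repeats: int = 5,
    master_seed: int = 0,
    css_flags: Sequence[bool] = (False, True),
    base_config: RunConfig | None = None,
) -> ComparisonTable:
    """Run the full (strategy x css x repeat) grid and tabulate budget checkpoints.

    Each (strategy, css, repeat) run is executed once at the largest budget and
    read at every requested checkpoint — the checkpoints of a single run are
    exactly the per-iteration budget levels. A failed run marks its cells with
    the error instead of aborting the grid.
    """
    if not strategies or not budgets:
        raise ValueError("need at least one strategy and one budget")
    budgets = sorted(int(b) for b in budgets)
    base = base_config or RunConfig()
    cells: list[ComparisonCell] = []
    all_results: dict = {}

    for strategy in strategies:
        for css_on in css_flags:
            runs: list[RunResult] = []
            error: str | None = None
            for rep in range(repeats):
                cfg = replace(
                    base,
                    strategy=strategy,
                    css=CSSConfig(
                        enabled=bool(css_on),
                        k=base.css.k,
                        restarts=base.css.restarts,
                        rotate_k=base.css.rotate_k,
                    ),
                    budget=budgets[-1],
                    data_seed=_cell_seed(master_seed, strategy, css_on, rep, 0),
                    strategy_seed=_cell_seed(master_seed, strategy, css_on, rep, 1),
                    model=base.model.with_seed(_cell_seed(master_seed, strategy, css_on, rep, 2)),
                )
                try:
                    runs.append(run_experiment(dataset, cfg))
                except Exception as exc:  # record, do not abort the grid
                    error = f"{type(exc).__name__}: {exc}"
                    break
            all_results[(strategy, bool(css_on))] = runs
            for budget in budgets:
                if error is not None:
                    cells.append(ComparisonCell(strategy, bool(css_on), budget, None, None, len(runs), error))
                    continue
                vals = [_accuracy_at(r, budget) for r in runs]
                vals = [v for v in vals if v is not None]
                mean = float(np.mean(vals)) if vals else None
                sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0 if vals else None
                cells.append(ComparisonCell(strategy, bool(css_on), budget, mean, sd, len(vals)))

    return ComparisonTable(cells=cells, master_seed=master_seed, results=all_results)


def _accuracy_at(result: RunResult, budget: int) -> float | None:
    """Average accuracy at the last checkpoint with queries_spent <= budget."""
    best = None
    for rec in result.records:
        if rec.queries_spent <= budget:
            best = rec.average_accuracy
        else:
            break
    return best


def format_table(table: ComparisonTable) -> str:
    """Human-readable table, accuracies as percentages at two decimals."""
    frame = table.to_frame()
    lines = [f"{'strategy':<18} {'css':<5} {'budget':>7} {'accuracy %':>12} {'sd':>7} {'n':>3}"]
    for _, row in frame.iterrows():
        if row["error"]:
            lines.append(f"{row.strategy:<18} {str(bool(row.css)):<5} {row.budget:>7} ERROR: {row.error}")
            continue
        lines.append(
            f"{row.strategy:<18} {str(bool(row.css)):<5} {row.budget:>7} "
            f"{100 * row.mean_accuracy:>12.2f} {100 * (row.sd or 0):>7.2f} {int(row.n_repeats):>3}"
        )
    return "\n".join(lines)


def plot_learning_curves(
    curves: dict[str, pd.DataFrame],
    path: str | Path,
    title: str = "Active-learning learning curves",
) -> None:
    """Plot average-accuracy learning curves (one line per labelled curve)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, frame in curves.items():
        ax.errorbar(
            frame["queries"], 100 * frame["average_mean"],
            yerr=100 * frame["average_std"].fillna(0.0),
            marker="o", capsize=3, label=label,
        )
    ax.set_xlabel("queries spent")
    ax.set_ylabel("average accuracy (%)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
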