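"""Multitask dataset model and synthetic data generation.

The data model mirrors pool-based multitask active learning: one shared feature
matrix ``x`` (n samples x D features, e.g. windowed sensor descriptors), ``T``
aligned integer label columns (one per classification task), and a train/test
split from which a tiny labeled seed pool and a large unlabeled pool are drawn.

Synthetic datasets emulate the structure of windowed wearable-sensor data: each
sample belongs to one of ``n_fine`` fine-grained latent classes (think 18
distinct activities), realised as isotropic Gaussian blobs in feature space, and
every task label is a many-to-one coarse-graining of the fine class (activity
type, intensity band, stress category, ...). Congruent coarse-grainings yield
highly correlated tasks; disjoint ones yield nearly independent tasks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyPoolError, MissingMappingError

__all__ = [
    "TaskSpec",
    "MultitaskDataset",
    "PoolState",
    "generate_fine_grained",
    "coarse_grain_tasks",
    "assemble_dataset",
    "split_seed",
    "ku_like_config",
    "deap_like_config",
    "ku_like",
    "deap_like",
    "save_dataset",
    "load_dataset",
    "KU_ACTIVITIES",
    "KU_TASK_MAPS",
    "KU_TASK_CLASS_NAMES",
]


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: a name, a class count ``C_i`` and a loss weight."""

    name: str
    n_classes: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError(f"task {self.name!r}: n_classes must be >= 2, got {self.n_classes}")
        if self.weight < 0:
            raise ValueError(f"task {self.name!r}: weight must be non-negative, got {self.weight}")


@dataclass
class MultitaskDataset:
    """Shared features plus T aligned integer label columns and a fixed split.

    Attributes
    ----------
    features : (n, D) float array
    labels : (n, T) int array; column i takes values in ``[0, tasks[i].n_classes)``
    tasks : list of TaskSpec, one per label column
    train_indices, test_indices : disjoint, exhaustive row index sets
    fine_labels : optional (n,) int array with the latent generator class
    provenance : generator configuration / source-file record
    """

    features: np.ndarray
    labels: np.ndarray
    tasks: list[TaskSpec]
    train_indices: np.ndarray
    test_indices: np.ndarray
    fine_labels: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.train_indices = np.asarray(self.train_indices, dtype=np.int64)
        self.test_indices = np.asarray(self.test_indices, dtype=np.int64)
        if self.fine_labels is not None:
            self.fine_labels = np.asarray(self.fine_labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        n = self.features.shape[0]
        if self.labels.ndim != 2 or self.labels.shape[0] != n:
            raise ValueError("labels must be an (n, T) matrix aligned with features")
        if self.labels.shape[1] != len(self.tasks):
            raise ValueError("one TaskSpec required per label column")
        for i, task in enumerate(self.tasks):
            col = self.labels[:, i]
            if col.min(initial=0) < 0 or col.max(initial=0) >= task.n_classes:
                raise ValueError(
                    f"label column {i} ({task.name!r}) has values outside [0, {task.n_classes})"
                )
        both = np.intersect1d(self.train_indices, self.test_indices)
        if both.size:
            raise ValueError("train and test indices overlap")
        union = np.union1d(self.train_indices, self.test_indices)
        if union.size != n or (np.sort(union) != np.arange(n)).any():
            raise ValueError("train and test indices must cover all rows exactly once")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_tasks(self) -> int:
        return len(self.tasks)

    def split(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (features, labels) for ``which`` in {'train', 'test'}."""
        idx = {"train": self.train_indices, "test": self.test_indices}[which]
        return self.features[idx], self.labels[idx]


@dataclass
class PoolState:
    """Disjoint labeled/unlabeled index sets over the training split.

    ``labeled`` starts as the seed pool L_n; every query moves indices from
    ``unlabeled`` (U_m) into ``labeled``, keeping the union constant.
    """

    labeled: np.ndarray
    unlabeled: np.ndarray
    n_seed: int

    def __post_init__(self) -> None:
        self.labeled = np.asarray(self.labeled, dtype=np.int64)
        self.unlabeled = np.asarray(self.unlabeled, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if np.intersect1d(self.labeled, self.unlabeled).size:
            raise ValueError("labeled and unlabeled pools overlap")
        if len(np.unique(self.labeled)) != len(self.labeled):
            raise ValueError("duplicate indices in labeled pool")
        if len(np.unique(self.unlabeled)) != len(self.unlabeled):
            raise ValueError("duplicate indices in unlabeled pool")

    @property
    def n_labeled(self) -> int:
        return len(self.labeled)

    @property
    def n_unlabeled(self) -> int:
        return len(self.unlabeled)

    @property
    def n_train(self) -> int:
        return len(self.labeled) + len(self.unlabeled)

    def copy(self) -> "PoolState":
        return PoolState(self.labeled.copy(), self.unlabeled.copy(), self.n_seed)

    def move_to_labeled(self, indices: np.ndarray) -> None:
        """Move ``indices`` from the unlabeled to the labeled pool (in place)."""
        indices = np.asarray(indices, dtype=np.int64)
        if not np.isin(indices, self.unlabeled).all():
            missing = indices[~np.isin(indices, self.unlabeled)]
            raise ValueError(f"indices not in unlabeled pool: {missing.tolist()}")
        self.labeled = np.concatenate([self.labeled, indices])
        self.unlabeled = self.unlabeled[~np.isin(self.unlabeled, indices)]


def generate_fine_grained(
    n: int,
    n_features: int,
    n_fine: int,
    separation: float,
    proportions: Sequence[float] | str = "uniform",
    seed: int = 0,
    groups: Sequence[int] | None = None,
    within_separation: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample isotropic Gaussian blobs, one per fine-grained latent class.

    Class centers are drawn from an isotropic Gaussian and rescaled so that the
    **closest** pair of centers lies exactly ``separation`` apart (in units of
    the unit within-class standard deviation); ``separation=0`` collapses all
    centers onto the origin. With ``groups`` given (a fine-class -> group map),
    centers are placed hierarchically: group centers with minimum pairwise
    distance ``separation`` and fine centers offset from their group center
    with minimum within-group offset distance ``within_separation`` —
    emulating, e.g., activities of the same intensity producing similar sensor
    windows.

    Returns ``(features, fine_labels)`` with per-class counts following
    ``proportions`` (largest-remainder rounding so counts sum to ``n``).
    """
    if n <= 0 or n_features <= 0:
        raise ValueError("n and n_features must be positive")
    if n_fine < 2:
        raise ValueError("n_fine must be >= 2")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if isinstance(proportions, str):
        if proportions != "uniform":
            raise ValueError(f"unknown proportions keyword {proportions!r}")
        props = np.full(n_fine, 1.0 / n_fine)
    else:
        props = np.asarray(proportions, dtype=float)
        if props.shape != (n_fine,):
            raise ValueError("proportions must have one entry per fine class")
        if (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    if groups is None:
        centers = _scale_min_gap(rng.standard_normal((n_fine, n_features)), separation)
    else:
        groups = np.asarray(groups, dtype=np.int64)
        if groups.shape != (n_fine,):
            raise ValueError("groups must map every fine class to a group id")
        if within_separation is None:
            within_separation = separation / 2.0
        n_groups = int(groups.max()) + 1
        group_centers = _scale_min_gap(rng.standard_normal((n_groups, n_features)), separation)
        offsets = rng.standard_normal((n_fine, n_features))
        gaps = [
            np.linalg.norm(offsets[i] - offsets[j])
            for i in range(n_fine)
            for j in range(i + 1, n_fine)
            if groups[i] == groups[j]
        ]
        if gaps:
            offsets = offsets * (within_separation / max(min(gaps), 1e-12))
        centers = group_centers[groups] + offsets

    # largest-remainder apportionment of n samples over classes
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    if remainder:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:remainder]] += 1

    fine = np.repeat(np.arange(n_fine), counts)
    features = centers[fine] + rng.standard_normal((n, n_features))
    perm = rng.permutation(n)
    return features[perm], fine[perm]


def _scale_min_gap(centers: np.ndarray, separation: float) -> np.ndarray:
    """Rescale centers so the closest pair lies exactly ``separation`` apart."""
    from scipy.spatial.distance import pdist

    d_min = float(pdist(centers).min())
    return centers * (separation / max(d_min, 1e-12))


def coarse_grain_tasks(
    fine_labels: np.ndarray,
    task_maps: Sequence[Mapping[int, int] | Sequence[int]],
) -> np.ndarray:
    """Derive T coarse task label columns from fine classes via many-to-one maps.

    ``task_maps[i]`` maps each fine class to a task class in ``0..C_i-1``
    (a dict or a dense sequence indexed by fine class). Deterministic.
    """
    fine_labels = np.asarray(fine_labels, dtype=np.int64)
    present = np.unique(fine_labels)
    columns = []
    for i, task_map in enumerate(task_maps):
        if isinstance(task_map, Mapping):
            lut_keys = set(task_map)
            missing = [int(c) for c in present if int(c) not in lut_keys]
            if missing:
                raise MissingMappingError(
                    f"task map {i} has no entry for fine class(es) {missing}"
                )
            size = max(max(lut_keys), int(present.max())) + 1
            lut = np.zeros(size, dtype=np.int64)
            for k, v in task_map.items():
                lut[k] = v
        else:
            lut = np.asarray(task_map, dtype=np.int64)
            if present.max() >= len(lut):
                missing = [int(c) for c in present if c >= len(lut)]
                raise MissingMappingError(
                    f"task map {i} has no entry for fine class(es) {missing}"
                )
        domain = (
            np.asarray(sorted(task_map), dtype=np.int64)
            if isinstance(task_map, Mapping)
            else np.arange(len(lut))
        )
        image = np.unique(lut[domain])
        if image[0] != 0 or (np.diff(image) != 1).any():
            raise ValueError(f"task map {i}: class image must be contiguous 0..C-1")
        columns.append(lut[fine_labels])
    return np.stack(columns, axis=1)


def assemble_dataset(config: Mapping) -> MultitaskDataset:
    """Build a MultitaskDataset from a generator configuration dict.

    Recognised keys: ``n``, ``n_features``, ``n_fine``, ``separation``,
    ``proportions``, ``task_maps``, ``task_names``, ``task_weights``,
    ``groups``, ``within_separation``, ``test_fraction`` (default 0.2),
    ``seed``.
    """
    config = dict(config)
    seed = int(config.get("seed", 0))
    test_fraction = float(config.get("test_fraction", 0.2))
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    task_maps = config["task_maps"]
    features, fine = generate_fine_grained(
        n=int(config["n"]),
        n_features=int(config["n_features"]),
        n_fine=int(config["n_fine"]),
        separation=float(config["separation"]),
        proportions=config.get("proportions", "uniform"),
        seed=seed,
        groups=config.get("groups"),
        within_separation=config.get("within_separation"),
    )
    labels = coarse_grain_tasks(fine, task_maps)
    T = labels.shape[1]
    names = config.get("task_names", [f"task{i}" for i in range(T)])
    weights = config.get("task_weights", [1.0] * T)
    tasks = [
        TaskSpec(name=str(names[i]), n_classes=int(labels[:, i].max()) + 1, weight=float(weights[i]))
        for i in range(T)
    ]
    # declared class counts may exceed observed ones
    for i, c in enumerate(config.get("n_classes_per_task", [])):
        tasks[i] = TaskSpec(tasks[i].name, int(c), tasks[i].weight)

    rng = np.random.default_rng(seed + 1)
    n = features.shape[0]
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    provenance = {"generator": {k: _jsonable(v) for k, v in config.items()}, "seed": seed}
    return MultitaskDataset(
        features=features,
        labels=labels,
        tasks=tasks,
        train_indices=train_idx,
        test_indices=test_idx,
        fine_labels=fine,
        provenance=provenance,
    )


def split_seed(dataset: MultitaskDataset, n_seed: int, seed: int = 0) -> PoolState:
    """Draw the seed labeled pool L_n uniformly from the training split.

    No class-coverage guarantee is applied: a tiny seed (the default protocol
    uses 3 samples) routinely misses one or more classes, which the multitask
    model must tolerate.
    """
    train = dataset.train_indices
    if n_seed < 1 or n_seed >= len(train):
        raise ValueError(f"n_seed must be in [1, {len(train)}), got {n_seed}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(train, size=n_seed, replace=False)
    labeled = np.sort(chosen)
    unlabeled = np.setdiff1d(train, labeled)
    return PoolState(labeled=labeled, unlabeled=unlabeled, n_seed=n_seed)


# --- Benchmark configurations -------------------------------------------------

#: 18 fine-grained activities (smartphone accelerometer/gyroscope windows).
KU_ACTIVITIES = [
    "stand", "sit", "talk-sit", "talk-stand", "stand-sit", "lay", "lay-stand",
    "pick", "jump", "push-up", "sit-up", "walk", "walk-backward", "walk-circle",
    "run", "stair-up", "stair-down", "table-tennis",
]

KU_TASK_CLASS_NAMES = {
    "activity_type": ["stationary", "adl", "exercise"],
    "met_level": ["light", "moderate", "vigorous"],
    "stress": ["inducing", "relieving", "highly-relieving"],
}

#: Three coarse-grainings of the 18 activities: by activity type, by metabolic
#: intensity (MET band) and by stress effect. Highly congruent by construction.
KU_TASK_MAPS = {
    "activity_type": {
        "stand": 0, "sit": 0, "talk-sit": 0, "talk-stand": 0, "lay": 0,
        "stand-sit": 1, "lay-stand": 1, "stair-up": 1, "stair-down": 1,
        "pick": 2, "jump": 2, "push-up": 2, "sit-up": 2, "walk": 2,
        "walk-backward": 2, "walk-circle": 2, "run": 2, "table-tennis": 2,
    },
    "met_level": {
        "stand": 0, "sit": 0, "talk-sit": 0, "talk-stand": 0, "lay": 0,
        "stand-sit": 1, "lay-stand": 1, "walk": 1, "walk-backward": 1,
        "walk-circle": 1, "table-tennis": 1,
        "pick": 2, "jump": 2, "push-up": 2, "sit-up": 2, "run": 2,
        "stair-up": 2, "stair-down": 2,
    },
    "stress": {
        "stand": 0, "sit": 0, "talk-sit": 0, "talk-stand": 0,
        "stand-sit": 1, "lay": 1, "lay-stand": 1, "walk": 1,
        "walk-backward": 1, "walk-circle": 1,
        "pick": 2, "jump": 2, "push-up": 2, "sit-up": 2, "run": 2,
        "stair-up": 2, "stair-down": 2, "table-tennis": 2,
    },
}


def _ku_maps_as_int() -> list[list[int]]:
    index = {a: i for i, a in enumerate(KU_ACTIVITIES)}
    maps = []
    for task in ("activity_type", "met_level", "stress"):
        lut = [0] * len(KU_ACTIVITIES)
        for act, cls in KU_TASK_MAPS[task].items():
            lut[index[act]] = cls
        maps.append(lut)
    return maps


def ku_like_config(n: int = 3000, seed: int = 0) -> dict:
    """High-task-congruence benchmark: 18 fine activity blobs, 3 tasks x 3 classes.

    Feature geometry is hierarchical — fine-class centers are grouped by the
    intensity (MET) coarse-graining, so feature-space clusters align with the
    coarse classes, the regime in which clustered stratified sampling is
    designed to help.
    """
    maps = _ku_maps_as_int()
    return {
        "name": "ku_like",
        "n": n,
        "n_features": 16,
        "n_fine": 18,
        "separation": 6.0,
        "within_separation": 3.0,
        "groups": maps[1],  # intensity band drives feature similarity
        "task_maps": maps,
        "task_names": ["activity_type", "met_level", "stress"],
        "seed": seed,
    }


def deap_like_config(n: int = 2000, seed: int = 0) -> dict:
    """Low-task-congruence benchmark: 3 binary tasks from 8 weakly linked fine classes.

    Fine classes are the 8 corners of a 3-bit code; task i reads bit i, so the
    binary labelings are only weakly associated (mild correlation induced by
    over-weighting the all-agree corners). Features are higher-dimensional and
    less separated, emulating noisy spectral descriptors.
    """
    task_maps = [[(f >> i) & 1 for f in range(8)] for i in range(3)]
    props = np.array([2.0, 1, 1, 1, 1, 1, 1, 2.0])
    return {
        "name": "deap_like",
        "n": n,
        "n_features": 70,
        "n_fine": 8,
        "separation": 3.0,
        "proportions": (props / props.sum()).tolist(),
        "task_maps": task_maps,
        "task_names": ["valence", "arousal", "dominance"],
        "seed": seed,
    }


def ku_like(n: int = 3000, seed: int = 0) -> MultitaskDataset:
    return assemble_dataset(ku_like_config(n=n, seed=seed))


def deap_like(n: int = 2000, seed: int = 0) -> MultitaskDataset:
    return assemble_dataset(deap_like_config(n=n, seed=seed))


# --- Disk format ----------------------------------------------------------------


def save_dataset(dataset: MultitaskDataset, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (features + labels) and ``<prefix>.json`` (metadata).

    CSV columns are ``f0..f{D-1}, task0..task{T-1}[, fine]`` with a header row;
    the JSON sidecar holds TaskSpec metadata, provenance and the train/test split.
    """
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    cols = {f"f{j}": dataset.features[:, j] for j in range(dataset.n_features)}
    for i in range(dataset.n_tasks):
        cols[f"task{i}"] = dataset.labels[:, i]
    if dataset.fine_labels is not None:
        cols["fine"] = dataset.fine_labels
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "tasks": [
            {"name": t.name, "n_classes": t.n_classes, "weight": t.weight}
            for t in dataset.tasks
        ],
        "seed": dataset.provenance.get("seed"),
        "generator": dataset.provenance.get("generator"),
        "split": {
            "train": dataset.train_indices.tolist(),
            "test": dataset.test_indices.tolist(),
        },
    }
    json_path.write_text(json.dumps(meta))
    return csv_path, json_path


def load_dataset(prefix: str | Path) -> MultitaskDataset:
    """Load a dataset written by :func:`save_dataset`."""
    prefix = Path(prefix)
    frame = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    tasks = [TaskSpec(t["name"], int(t["n_classes"]), float(t.get("weight", 1.0))) for t in meta["tasks"]]
    feat_cols = [c for c in frame.columns if c.startswith("f") and c != "fine"]
    task_cols = [f"task{i}" for i in range(len(tasks))]
    fine = frame["fine"].to_numpy() if "fine" in frame.columns else None
    return MultitaskDataset(
        features=frame[feat_cols].to_numpy(dtype=float),
        labels=frame[task_cols].to_numpy(dtype=np.int64),
        tasks=tasks,
        train_indices=np.asarray(meta["split"]["train"], dtype=np.int64),
        test_indices=np.asarray(meta["split"]["test"], dtype=np.int64),
        fine_labels=fine,
        provenance={"seed": meta.get("seed"), "generator": meta.get("generator"), "path": str(prefix)},
    )


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    return value
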