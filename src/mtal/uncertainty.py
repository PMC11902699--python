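"""Per-sample informativeness measures over predicted class probabilities.

All three classic uncertainty measures are returned under a single sign
convention — **higher score = more informative** — so downstream selectors are
measure-agnostic:

* ``least_confidence``: 1 - max_c p(c); in [0, 1 - 1/C].
* ``margin``: -(p(1st) - p(2nd)), the negated top-two gap; in [-1, 0].
* ``entropy``: -sum_c p(c) ln p(c) (natural log); in [0, ln C].

The argmin formulations of least-confidence and margin sampling are recovered
exactly by taking argmax of the converted scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["UncertaintyMatrix", "least_confidence", "margin", "entropy", "score_pool", "MEASURES"]

_EPS = 1e-12


def _check_rows(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probability input must be a 2-D (samples x classes) matrix")
    if (probs < -_EPS).any():
        raise ValueError("probabilities must be non-negative")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (tolerance 1e-6)")
    return probs


def least_confidence(probs: np.ndarray) -> np.ndarray:
    """Score = 1 - top-class probability."""
    probs = _check_rows(probs)
    return 1.0 - probs.max(axis=1)


def margin(probs: np.ndarray) -> np.ndarray:
    """Score = -(p(1st) - p(2nd)); a top-two tie gives the maximal score 0."""
    probs = _check_rows(probs)
    if probs.shape[1] < 2:
        raise ValueError("margin requires at least two classes")
    part = np.partition(probs, probs.shape[1] - 2, axis=1)
    return -(part[:, -1] - part[:, -2])


def entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy in nats; 0*log(0) is treated as 0."""
    probs = _check_rows(probs)
    return -(probs * np.log(np.clip(probs, _EPS, None))).sum(axis=1)


MEASURES = {
    "least_confidence": least_confidence,
    "margin": margin,
    "entropy": entropy,
}


@dataclass
class UncertaintyMatrix:
    """(m, T) informativeness scores for the unlabeled pool under one measure.

    Row r corresponds to the r-th entry of the pool's unlabeled index list;
    column i to task i. Convention: higher = more informative.
    """

    scores: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be an (m, T) matrix")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def n_tasks(self) -> int:
        return self.scores.shape[1]


def score_pool(probabilities: list[np.ndarray], measure: str) -> UncertaintyMatrix:
    """Apply one measure to each task's probability matrix, column-stacked."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {sorted(MEASURES)}")
    fn = MEASURES[measure]
    cols = [fn(p) for p in probabilities]
    return UncertaintyMatrix(scores=np.stack(cols, axis=1), measure=measure)
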