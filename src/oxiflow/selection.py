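"""Wrapper feature-subset selection: best-first forward search.

The search starts from the empty subset and grows it one feature at a time,
scoring every candidate subset by the cross-validated accuracy of the
wrapped node classifier itself.  An open list keeps all evaluated but
unexpanded subsets ranked by score, so the search can backtrack to an
earlier, more promising subset when forward expansions stop helping.  It
terminates after a fixed number (default 5) of consecutive expansions that
fail to improve on the incumbent.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from oxiflow.classifiers import predict_node, train_node

__all__ = ["FeatureSubset", "SearchTrace", "wrapper_select"]


@dataclass
class FeatureSubset:
    """An ordered set of catalog feature indices with its CV accuracy."""

    indices: np.ndarray
    score: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("indices must be unique")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class SearchTrace:
    """Every evaluated (subset, score) pair plus the stall-counter maximum."""

    evaluated_nodes: list = field(default_factory=list)
    termination_counter_max: int = 0


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (fold id per instance)."""
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    k: int,
    algorithm: str,
    sample_weight: Optional[np.ndarray],
) -> float:
    """Pooled k-fold accuracy of the wrapped classifier on these columns."""
    correct = 0
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        train = ~test
        ytr = y[train]
        if len(np.unique(ytr)) < 2:
            pred = np.full(test.sum(), int(np.round(ytr.mean())) if ytr.size else 0)
        else:
            w = None if sample_weight is None else sample_weight[train]
            model = train_node(X[train], ytr, w=w, algorithm=algorithm)
            pred, _ = predict_node(model, X[test])
            pred = np.atleast_1d(pred)
        correct += int((pred == y[test]).sum())
    return correct / y.size


def wrapper_select(
    X: np.ndarray,
    y: np.ndarray,
    node_algorithm: str = "lda",
    cv_folds: int = 5,
    seed: int = 0,
    termination: int = 5,
    improvement_tol: float = 1e-5,
    sample_weight: Optional[np.ndarray] = None,
    max_subset_size: Optional[int] = None,
):
    """Best-first forward search over feature subsets.

    Parameters
    ----------
    X, y : feature matrix (m features) and binary 0/1 labels.
    node_algorithm : wrapped classifier ("tree", "lda" or "logistic").
    cv_folds, seed : stratified CV folds used to score every subset;
        the fold assignment is fixed once so the search is deterministic.
    termination : number of consecutive non-improving expansions allowed
        before the search stops (default 5).
    sample_weight : optional instance weights applied when training the
        wrapped classifier inside each fold (accuracy stays unweighted).
    max_subset_size : optional cap on the size of subsets expanded.

    Returns
    -------
    (FeatureSubset, SearchTrace)
        The incumbent (best-scoring) subset -- ties broken toward smaller
        subsets, then lexicographic indices -- and the full search trace.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y shapes disagree")
    if not np.array_equal(np.unique(y), [0, 1]):
        raise ValueError("y must be binary with both classes present (0/1)")
    if termination < 1:
        raise ValueError("termination must be >= 1")
    m = X.shape[1]
    folds = _stratified_folds(y, cv_folds, seed)

    trace = SearchTrace()
    evaluated: dict[frozenset, float] = {}

    def evaluate(subset: tuple) -> float:
        key = frozenset(subset)
        if key in evaluated:
            return evaluated[key]
        if subset:
            score = _cv_accuracy(
                X[:, list(subset)], y, folds, cv_folds, node_algorithm, sample_weight
            )
        else:
            # empty subset: no information, majority-class rate
            score = max(np.bincount(y)) / y.size
        evaluated[key] = score
        trace.evaluated_nodes.append((subset, score))
        return score

    root: tuple = ()
    inc_subset, inc_score = root, evaluate(root)

    def tie_key(subset: tuple) -> tuple:
        return (len(subset), subset)

    # open list: max-score first, then smaller subset, then lexicographic
    heap: list = []
    heapq.heappush(heap, (-inc_score, tie_key(root), root))

    stall = 0
    while heap and stall < termination:
        if inc_score >= 1.0:
            break  # nothing can improve on perfect CV accuracy
        _, _, subset = heapq.heappop(heap)
        if max_subset_size is not None and len(subset) >= max_subset_size:
            continue
        improved = False
        for f in range(m):
            if f in subset:
                continue
            child = tuple(sorted(subset + (f,)))
            if frozenset(child) in evaluated:
                continue
            score = evaluate(child)
            heapq.heappush(heap, (-score, tie_key(child), child))
            if score > inc_score + improvement_tol:
                inc_subset, inc_score = child, score
                improved = True
            elif abs(score - inc_score) <= improvement_tol and tie_key(child) < tie_key(
                inc_subset
            ):
                inc_subset = child
                inc_score = max(inc_score, score)
        if improved:
            stall = 0
        else:
            stall += 1
            trace.termination_counter_max = max(trace.termination_counter_max, stall)

    return FeatureSubset(indices=np.array(inc_subset, dtype=int), score=inc_score), trace
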