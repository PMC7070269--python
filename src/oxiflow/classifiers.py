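"""Node classifiers and the two-level binary hierarchical classifier (BHC).

The BHC is a binary tree with three leaves, one per intensity class: an
upper node (phi1) separates sedentary from active windows, and a lower node
(phi2), consulted only for active windows, separates light from moderate
intensity.  Each node carries its own feature subset (psi1, psi2) found by
wrapper selection.

Node algorithms are implemented here rather than delegated because the
contracts require instance-weighted fits and C4.5-style behaviour:

* ``lda`` -- weighted class means, pooled weighted covariance and weighted
  priors; emits the positive-class posterior.
* ``tree`` -- univariate threshold tree with gain-ratio splitting, a
  minimum leaf weight of 2 and pessimistic-error pruning; emits a
  Laplace-smoothed leaf frequency.
* ``logistic`` -- weighted maximum likelihood (IRLS) with an L2 stabiliser
  of 1e-6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from oxiflow.synthetic_data import Intensity

logger = logging.getLogger(__name__)

__all__ = [
    "balance_weights",
    "NodeModel",
    "train_node",
    "predict_node",
    "BhcSpec",
    "TrainedBHC",
    "train_bhc",
    "predict_bhc",
    "node_to_dict",
    "node_from_dict",
]


def balance_weights(y: np.ndarray) -> np.ndarray:
    """Instance weights that equalise the total weight of every class.

    ``w_i = N / (K * n_class(i))`` with N instances and K classes, so the
    per-class weight sums are all N/K and the mean weight is 1.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("y is empty")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("balance_weights needs at least two classes")
    n, k = y.size, len(classes)
    per_class = {c: n / (k * cnt) for c, cnt in zip(classes, counts)}
    return np.array([per_class[c] for c in y], dtype=float)


# ---------------------------------------------------------------------------
# LDA


@dataclass
class _LdaParams:
    means: np.ndarray      # (2, d)
    cov_inv: np.ndarray    # (d, d)
    log_priors: np.ndarray  # (2,)


def _fit_lda(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> _LdaParams:
    d = X.shape[1]
    means = np.zeros((2, d))
    cov = np.zeros((d, d))
    wsum = np.zeros(2)
    for c in (0, 1):
        m = y == c
        wc = w[m]
        wsum[c] = wc.sum()
        means[c] = np.average(X[m], axis=0, weights=wc)
        dx = X[m] - means[c]
        cov += (dx * wc[:, None]).T @ dx
    cov /= w.sum()
    # guard against degenerate (rank-deficient) pooled covariance
    ridge = 1e-6 * np.trace(cov) / d if np.trace(cov) > 0 else 1e-6
    try:
        cov_inv = np.linalg.inv(cov)
        if not np.all(np.isfinite(cov_inv)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        logger.info("LDA covariance degenerate; adding ridge %.3g", ridge)
        cov_inv = np.linalg.inv(cov + ridge * np.eye(d))
    log_priors = np.log(wsum / wsum.sum())
    return _LdaParams(means=means, cov_inv=cov_inv, log_priors=log_priors)


def _lda_score(p: _LdaParams, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class."""
    delta = np.empty((X.shape[0], 2))
    for c in (0, 1):
        mu = p.means[c]
        delta[:, c] = X @ p.cov_inv @ mu - 0.5 * mu @ p.cov_inv @ mu + p.log_priors[c]
    z = delta[:, 1] - delta[:, 0]
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ---------------------------------------------------------------------------
# Gain-ratio threshold tree with pessimistic pruning

_MIN_LEAF_WEIGHT = 2.0
_PRUNE_Z = float(norm.ppf(0.75))  # confidence factor 0.25


def _entropy(counts: np.ndarray) -> float:
    tot = counts.sum()
    if tot <= 0:
        return 0.0
    p = counts[counts > 0] / tot
    return float(-(p * np.log2(p)).sum())


def _best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Best (feature, threshold) by gain ratio among splits with at least
    average information gain and >= 2 weight on each side."""
    n, d = X.shape
    tot1 = w[y == 1].sum()
    tot0 = w.sum() - tot1
    parent_h = _entropy(np.array([tot0, tot1]))
    candidates = []
    for j in range(d):
        order = np.argsort(X[:, j], kind="mergesort")
        xs = X[order, j]
        ws = w[order]
        w1 = np.where(y[order] == 1, ws, 0.0)
        cw = np.cumsum(ws)
        cw1 = np.cumsum(w1)
        # split between distinct adjacent values only
        change = np.nonzero(np.diff(xs) > 0)[0]
        if change.size == 0:
            continue
        lw, lw1 = cw[change], cw1[change]
        rw, rw1 = cw[-1] - lw, cw1[-1] - lw1
        ok = (lw >= _MIN_LEAF_WEIGHT) & (rw >= _MIN_LEAF_WEIGHT)
        if not ok.any():
            continue
        lw, lw1, rw, rw1 = lw[ok], lw1[ok], rw[ok], rw1[ok]
        idx = change[ok]

        def h2(a, b):
            tot = a + b
            out = np.zeros_like(tot)
            for part in (a, b):
                p = np.divide(part, tot, out=np.zeros_like(tot), where=tot > 0)
                nz = p > 0
                out[nz] -= p[nz] * np.log2(p[nz])
            return out

        child_h = (lw * h2(lw - lw1, lw1) + rw * h2(rw - rw1, rw1)) / cw[-1]
        gain = parent_h - child_h
        split_h = h2(lw, rw)  # split info over the two branch weights
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(split_h > 1e-12, gain / np.maximum(split_h, 1e-12), 0.0)
        for k in range(len(idx)):
            if gain[k] > 1e-12:
                thr = 0.5 * (xs[idx[k]] + xs[idx[k] + 1])
                candidates.append((gain[k], ratio[k], j, thr))
    if not candidates:
        return None
    gains = np.array([c[0] for c in candidates])
    mean_gain = gains.mean()
    eligible = [c for c in candidates if c[0] >= mean_gain - 1e-12]
    # maximise gain ratio among splits with at least average gain
    best = max(eligible, key=lambda c: (c[1], c[0], -c[2]))
    return best[2], best[3]


def _leaf(counts: np.ndarray) -> dict:
    return {"leaf": True, "counts": [float(counts[0]), float(counts[1])]}


def _grow_tree(X, y, w, depth, max_depth) -> dict:
    counts = np.array([w[y == 0].sum(), w[y == 1].sum()])
    if (
        counts.min() == 0.0
        or counts.sum() < 2 * _MIN_LEAF_WEIGHT
        or depth >= max_depth
    ):
        return _leaf(counts)
    split = _best_split(X, y, w)
    if split is None:
        return _leaf(counts)
    j, thr = split
    mask = X[:, j] <= thr
    left = _grow_tree(X[mask], y[mask], w[mask], depth + 1, max_depth)
    right = _grow_tree(X[~mask], y[~mask], w[~mask], depth + 1, max_depth)
    return {"leaf": False, "feature": int(j), "threshold": float(thr),
            "counts": [float(counts[0]), float(counts[1])],
            "left": left, "right": right}


def _pessimistic_errors(node: dict) -> float:
    """Upper confidence bound on the subtree's absolute error count."""
    if node["leaf"]:
        return _leaf_ucb(node["counts"])
    return _pessimistic_errors(node["left"]) + _pessimistic_errors(node["right"])


def _leaf_ucb(counts) -> float:
    n = counts[0] + counts[1]
    if n <= 0:
        return 0.0
    e = min(counts)  # misclassified weight under majority vote
    f = e / n
    z = _PRUNE_Z
    ucb = (f + z * z / (2 * n) + z * np.sqrt(f * (1 - f) / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return float(ucb * n)


def _prune(node: dict) -> dict:
    if node["leaf"]:
        return node
    node["left"] = _prune(node["left"])
    node["right"] = _prune(node["right"])
    subtree_err = _pessimistic_errors(node)
    leaf_err = _leaf_ucb(node["counts"])
    if leaf_err <= subtree_err + 1e-12:
        return _leaf(np.array(node["counts"]))
    return node


def _tree_score(node: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(node, np.arange(X.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if idx.size == 0:
            continue
        if nd["leaf"]:
            c0, c1 = nd["counts"]
            out[idx] = (c1 + 1.0) / (c0 + c1 + 2.0)  # Laplace smoothing
        else:
            mask = X[idx, nd["feature"]] <= nd["threshold"]
            stack.append((nd["left"], idx[mask]))
            stack.append((nd["right"], idx[~mask]))
    return out


# ---------------------------------------------------------------------------
# Weighted logistic regression (IRLS)


def _fit_logistic(X, y, w, l2=1e-6, max_iter=100, tol=1e-10) -> np.ndarray:
    n, d = X.shape
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(d + 1)
    for _ in range(max_iter):
        z = np.clip(A @ beta, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        r = w * p * (1 - p) + 1e-12
        grad = A.T @ (w * (y - p)) - l2 * beta
        H = (A * r[:, None]).T @ A + l2 * np.eye(d + 1)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _logistic_score(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    z = np.clip(beta[0] + X @ beta[1:], -500, 500)
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Node API

_ALGORITHMS = ("tree", "lda", "logistic")


@dataclass
class NodeModel:
    """A trained binary node: algorithm, learned state and feature subset.

    ``feature_subset`` holds catalog column indices; prediction selects those
    columns from the full feature vector.  ``classes`` names the two
    meta-classes the node separates (negative first).
    """

    algorithm: str
    params: object
    feature_subset: Optional[np.ndarray] = None
    classes: tuple = (0, 1)
    n_features_in: int = 0

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite input")
        if X.shape[1] != self.n_features_in:
            raise ValueError(
                f"expected {self.n_features_in} input features, got {X.shape[1]}"
            )
        if self.feature_subset is not None:
            X = X[:, self.feature_subset]
        if self.algorithm == "lda":
            return _lda_score(self.params, X)
        if self.algorithm == "tree":
            return _tree_score(self.params, X)
        if self.algorithm == "logistic":
            return _logistic_score(self.params, X)
        raise ValueError(f"unknown algorithm {self.algorithm!r}")


def train_node(
    X: np.ndarray,
    y: np.ndarray,
    w: Optional[np.ndarray] = None,
    algorithm: str = "lda",
    feature_subset=None,
    max_depth: int = 25,
) -> NodeModel:
    """Train one binary node on (optionally instance-weighted) data.

    ``y`` must contain exactly two classes, encoded as 0/1.  When
    ``feature_subset`` is given the model trains and predicts on those
    catalog columns of ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X and y shapes disagree")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    uniq = np.unique(y)
    if not np.array_equal(uniq, [0, 1]):
        raise ValueError("y must be binary with both classes present (0/1)")
    if algorithm not in _ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {_ALGORITHMS}")
    if w is None:
        w = np.ones(y.size)
    w = np.asarray(w, dtype=float)
    if w.size != y.size:
        raise ValueError("weight vector length mismatch")

    n_in = X.shape[1]
    subset = None
    if feature_subset is not None:
        subset = np.asarray(list(feature_subset), dtype=int)
        Xs = X[:, subset]
    else:
        Xs = X

    if algorithm == "lda":
        params = _fit_lda(Xs, y, w)
    elif algorithm == "tree":
        params = _prune(_grow_tree(Xs, y, w, 0, max_depth))
    else:
        params = _fit_logistic(Xs, y, w)
    return NodeModel(
        algorithm=algorithm,
        params=params,
        feature_subset=subset,
        n_features_in=n_in,
    )


def predict_node(model: NodeModel, x: np.ndarray):
    """Predict (label, score) for one feature vector or a batch.

    The label is ``score >= 0.5``; the score is the positive meta-class
    probability, monotone in the node's discriminant.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    s = model.scores(x)
    labels = (s >= 0.5).astype(int)
    if single:
        return int(labels[0]), float(s[0])
    return labels, s


# ---------------------------------------------------------------------------
# Binary hierarchical classifier


@dataclass
class BhcSpec:
    """Configuration of the two internal nodes and the wrapper selection.

    ``selection`` is a dict of keyword arguments passed to
    :func:`oxiflow.selection.wrapper_select` (e.g. cv_folds, seed,
    termination); ``None`` disables selection and uses all features.
    """

    phi1_algorithm: str = "tree"
    phi2_algorithm: str = "lda"
    selection: Optional[dict] = field(default_factory=dict)


@dataclass
class TrainedBHC:
    """phi1 (sedentary vs active) and phi2 (light vs moderate) with their
    feature subsets psi1, psi2."""

    phi1: NodeModel
    phi2: NodeModel

    @property
    def psi1(self):
        return self.phi1.feature_subset

    @property
    def psi2(self):
        return self.phi2.feature_subset


def train_bhc(X: np.ndarray, y: np.ndarray, spec: Optional[BhcSpec] = None) -> TrainedBHC:
    """Train the full hierarchy on a 3-class labelled feature matrix.

    phi1 learns sedentary (0) vs active (1, 2); phi2 learns light (1) vs
    moderate (2) on active instances only, with instance weights balancing
    the two classes.  Feature subsets come from wrapper selection unless
    ``spec.selection`` is ``None``.
    """
    from oxiflow.selection import wrapper_select  # deferred: circular import

    if spec is None:
        spec = BhcSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    present = np.unique(y)
    if not np.array_equal(present, [0, 1, 2]):
        raise ValueError("training data must contain all three intensity classes")

    y1 = (y > 0).astype(int)
    active = y > 0
    X2, y2 = X[active], (y[active] == 2).astype(int)
    w2 = balance_weights(y2)

    psi1 = psi2 = None
    if spec.selection is not None:
        sub1, _ = wrapper_select(X, y1, node_algorithm=spec.phi1_algorithm,
                                 **spec.selection)
        psi1 = sub1.indices
        sub2, _ = wrapper_select(X2, y2, node_algorithm=spec.phi2_algorithm,
                                 sample_weight=w2, **spec.selection)
        psi2 = sub2.indices

    phi1 = train_node(X, y1, algorithm=spec.phi1_algorithm, feature_subset=psi1)
    phi2 = train_node(X2, y2, w=w2, algorithm=spec.phi2_algorithm, feature_subset=psi2)
    return TrainedBHC(phi1=phi1, phi2=phi2)


def predict_bhc(model: TrainedBHC, x: np.ndarray):
    """Predict the intensity class for one feature vector.

    phi1 is consulted first; phi2 is evaluated only when phi1 predicts
    "active".  Returns (IntensityClass, {"phi1": score, "phi2": score|None}).
    """
    lab1, s1 = predict_node(model.phi1, np.asarray(x, dtype=float))
    if lab1 == 0:
        return Intensity.SEDENTARY, {"phi1": s1, "phi2": None}
    lab2, s2 = predict_node(model.phi2, np.asarray(x, dtype=float))
    cls = Intensity.MODERATE if lab2 == 1 else Intensity.LIGHT
    return cls, {"phi1": s1, "phi2": s2}


def predict_bhc_batch(model: TrainedBHC, X: np.ndarray) -> np.ndarray:
    """Vectorised hierarchy prediction for a feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    lab1, _ = predict_node(model.phi1, X)
    out = np.zeros(X.shape[0], dtype=int)
    active = lab1 == 1
    if active.any():
        lab2, _ = predict_node(model.phi2, X[active])
        out[active] = np.where(lab2 == 1, 2, 1)
    return out


# ---------------------------------------------------------------------------
# Serialization


def node_to_dict(model: NodeModel) -> dict:
    d = {
        "algorithm": model.algorithm,
        "feature_subset": None
        if model.feature_subset is None
        else model.feature_subset.tolist(),
        "n_features_in": model.n_features_in,
    }
    if model.algorithm == "lda":
        p = model.params
        d["params"] = {
            "means": p.means.tolist(),
            "cov_inv": p.cov_inv.tolist(),
            "log_priors": p.log_priors.tolist(),
        }
    elif model.algorithm == "tree":
        d["params"] = model.params
    else:
        d["params"] = {"beta": model.params.tolist()}
    return d


def node_from_dict(d: dict) -> NodeModel:
    alg = d["algorithm"]
    if alg == "lda":
        params = _LdaParams(
            means=np.array(d["params"]["means"]),
            cov_inv=np.array(d["params"]["cov_inv"]),
            log_priors=np.array(d["params"]["log_priors"]),
        )
    elif alg == "tree":
        params = d["params"]
    else:
        params = np.array(d["params"]["beta"])
    subset = d["feature_subset"]
    return NodeModel(
        algorithm=alg,
        params=params,
        feature_subset=None if subset is None else np.array(subset, dtype=int),
        n_features_in=d["n_features_in"],
    )
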