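"""Random forest classifier, implemented from first principles.

Each tree is grown on a bootstrap sample (|S| = |T|, with replacement).  At
every node a fixed number of candidate decisions (feature index phi, drawn
uniformly; threshold tau, drawn uniformly between the node's min and max of
that feature) is sampled and the candidate maximizing the information gain

    I(S, theta) = H(S) - sum_{i in {L,R}} |S_i|/|S| * H(S_i)

is taken, where H is the Shannon entropy in bits and the left child holds
samples with ``v[phi] < tau``.  A node becomes a leaf when its labels are
homogeneous, the maximum depth is reached, or no candidate split keeps both
children at least ``min_node_fraction`` of the full training-set size.  Leaf
posteriors are empirical label frequencies, and the forest posterior is the
plain average of per-tree leaf posteriors.

Binary classes only: label 1 = microcalcification, 0 = background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

_FORMAT_VERSION = 1


class TrainingError(ValueError):
    """Invalid training data (e.g. a single class)."""


def entropy(labels: np.ndarray | Sequence[int]) -> float:
    """Shannon entropy in bits of a binary label multiset."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("entropy of an empty set is undefined")
    p = float(np.mean(y == 1))
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * np.log2(q)
    return h


def information_gain(
    X: np.ndarray, y: np.ndarray, phi: int, tau: float
) -> float:
    """Information gain of splitting (X, y) at feature ``phi`` with
    threshold ``tau`` (left: ``X[:, phi] < tau``).  A split leaving either
    side empty has gain 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    left = X[:, phi] < tau
    n_l = int(left.sum())
    n = len(y)
    if n_l == 0 or n_l == n:
        return 0.0
    h = entropy(y)
    h_l = entropy(y[left])
    h_r = entropy(y[~left])
    return h - (n_l / n) * h_l - ((n - n_l) / n) * h_r


@dataclass
class DecisionTree:
    """Flat array representation; node 0 is the root.  Internal nodes carry
    (feature, threshold, left, right); leaves carry the class-1 posterior
    and the training-sample count that reached them."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    is_leaf: np.ndarray
    posterior: np.ndarray  # P(class 1) at leaves, NaN at internal nodes
    count: np.ndarray

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        node = np.zeros(len(X), dtype=np.int32)
        while True:
            active = ~self.is_leaf[node]
            if not active.any():
                break
            idx = np.flatnonzero(active)
            n = node[idx]
            go_left = X[idx, self.feature[n]] < self.threshold[n]
            node[idx] = np.where(go_left, self.left[n], self.right[n])
        return self.posterior[node]

    def max_depth_reached(self) -> int:
        depth = np.zeros(len(self.feature), dtype=int)
        for i in range(len(self.feature)):
            if not self.is_leaf[i]:
                depth[self.left[i]] = depth[i] + 1
                depth[self.right[i]] = depth[i] + 1
        return int(depth.max()) if len(depth) else 0


class _TreeBuilder:
    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.is_leaf: list[bool] = []
        self.posterior: list[float] = []
        self.count: list[int] = []

    def add(self) -> int:
        for lst, val in (
            (self.feature, -1), (self.threshold, np.nan), (self.left, -1),
            (self.right, -1), (self.is_leaf, True), (self.posterior, np.nan),
            (self.count, 0),
        ):
            lst.append(val)
        return len(self.feature) - 1

    def finalize(self) -> DecisionTree:
        return DecisionTree(
            feature=np.asarray(self.feature, dtype=np.int32),
            threshold=np.asarray(self.threshold, dtype=np.float64),
            left=np.asarray(self.left, dtype=np.int32),
            right=np.asarray(self.right, dtype=np.int32),
            is_leaf=np.asarray(self.is_leaf, dtype=bool),
            posterior=np.asarray(self.posterior, dtype=np.float64),
            count=np.asarray(self.count, dtype=np.int64),
        )


def _draw_candidates(
    X: np.ndarray,
    idx: np.ndarray,
    n_candidates: int | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (phi, tau) candidates for a node, or enumerate them all
    exhaustively (phi x midpoints of consecutive sorted unique values) when
    ``n_candidates`` is None."""
    n_dims = X.shape[1]
    if n_candidates is None:
        phis, taus = [], []
        for phi in range(n_dims):
            vals = np.unique(X[idx, phi])
            mids = 0.5 * (vals[:-1] + vals[1:])
            phis.extend([phi] * len(mids))
            taus.extend(mids.tolist())
        return np.asarray(phis, dtype=int), np.asarray(taus, dtype=float)
    phis = rng.integers(0, n_dims, size=n_candidates)
    lo = X[idx][:, phis].min(axis=0)
    hi = X[idx][:, phis].max(axis=0)
    taus = rng.uniform(lo, hi)
    return phis, taus


def _node_entropy(y: np.ndarray) -> float:
    return entropy(y)


def train_tree(
    X: np.ndarray,
    y: np.ndarray,
    max_depth: int = 30,
    min_node_count: float = 1.0,
    n_candidate_splits: int | None = 50,
    rng: np.random.Generator | None = None,
) -> DecisionTree:
    """Grow one tree on (X, y).

    ``min_node_count`` is the minimum admissible child size (normally
    ``min_node_fraction`` times the *full* training-set size); candidates
    producing a smaller child are invalid, and a node with no valid
    candidate becomes a leaf.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int8)
    if len(X) == 0:
        raise TrainingError("empty training data")
    rng = rng if rng is not None else np.random.default_rng()
    builder = _TreeBuilder()

    def grow(idx: np.ndarray, depth: int) -> int:
        node = builder.add()
        yy = y[idx]
        builder.count[node] = len(idx)
        p1 = float(np.mean(yy == 1))
        homogeneous = p1 in (0.0, 1.0)
        if homogeneous or depth >= max_depth:
            builder.posterior[node] = p1
            return node
        phis, taus = _draw_candidates(X, idx, n_candidate_splits, rng)
        best_gain, best = -1.0, None
        if len(phis):
            vals = X[idx][:, phis]  # (n, n_cand)
            less = vals < taus
            n_left = less.sum(axis=0)
            n = len(idx)
            valid = (n_left >= min_node_count) & ((n - n_left) >= min_node_count)
            if valid.any():
                h = _node_entropy(yy)
                pos = (yy == 1)
                n_pos_left = less[pos].sum(axis=0)
                n_pos = int(pos.sum())
                gains = np.full(len(phis), -np.inf)
                for j in np.flatnonzero(valid):
                    nl = int(n_left[j])
                    nr = n - nl
                    pl = n_pos_left[j] / nl
                    pr = (n_pos - n_pos_left[j]) / nr
                    gains[j] = h - (nl / n) * _binary_entropy(pl) - (nr / n) * _binary_entropy(pr)
                j_star = int(np.argmax(gains))  # first-drawn wins ties
                best_gain = gains[j_star]
                best = (int(phis[j_star]), float(taus[j_star]))
        if best is None:
            builder.posterior[node] = p1
            return node
        phi, tau = best
        go_left = X[idx, phi] < tau
        builder.is_leaf[node] = False
        builder.posterior[node] = np.nan
        builder.feature[node] = phi
        builder.threshold[node] = tau
        builder.left[node] = grow(idx[go_left], depth + 1)
        builder.right[node] = grow(idx[~go_left], depth + 1)
        return node

    grow(np.arange(len(X)), 0)
    return builder.finalize()


def _binary_entropy(p: float) -> float:
    h = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            h -= q * np.log2(q)
    return h


@dataclass
class DecisionForest:
    """Ensemble of decision trees with averaged leaf posteriors."""

    trees: list[DecisionTree]
    feature_length: int
    n_trees: int = 100
    max_depth: int = 30
    min_node_fraction: float = 0.01
    n_candidate_splits: int = 50
    seed: int = 0

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        """Averaged per-tree posteriors, one P(microcalcification) per row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_length:
            raise ValueError(
                f"feature length {X.shape[1]} != expected {self.feature_length}"
            )
        acc = np.zeros(len(X))
        for tree in self.trees:
            acc += tree.predict_posterior(X)
        return acc / len(self.trees)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format_version": _FORMAT_VERSION,
            "feature_length": self.feature_length,
            "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "min_node_fraction": self.min_node_fraction,
            "n_candidate_splits": self.n_candidate_splits,
            "seed": self.seed,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "is_leaf": t.is_leaf.tolist(),
                    "posterior": t.posterior.tolist(),
                    "count": t.count.tolist(),
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionForest":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != _FORMAT_VERSION:
            raise ValueError("unsupported forest file version")
        trees = [
            DecisionTree(
                feature=np.asarray(t["feature"], dtype=np.int32),
                threshold=np.asarray(t["threshold"], dtype=np.float64),
                left=np.asarray(t["left"], dtype=np.int32),
                right=np.asarray(t["right"], dtype=np.int32),
                is_leaf=np.asarray(t["is_leaf"], dtype=bool),
                posterior=np.asarray(t["posterior"], dtype=np.float64),
                count=np.asarray(t["count"], dtype=np.int64),
            )
            for t in payload["trees"]
        ]
        return cls(
            trees=trees,
            feature_length=payload["feature_length"],
            n_trees=payload["n_trees"],
            max_depth=payload["max_depth"],
            min_node_fraction=payload["min_node_fraction"],
            n_candidate_splits=payload["n_candidate_splits"],
            seed=payload["seed"],
        )


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    max_depth: int = 30,
    min_node_fraction: float = 0.01,
    n_candidate_splits: int = 50,
    seed: int = 0,
) -> DecisionForest:
    """Train the forest: each tree sees an independent bootstrap sample of
    size |T| and an independent random substream derived from ``seed``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=np.int8)
    if len(np.unique(y)) < 2:
        raise TrainingError("training data must contain both classes")
    n = len(X)
    min_node_count = min_node_fraction * n
    root_rng = np.random.default_rng(seed)
    streams = root_rng.spawn(n_trees)
    trees = []
    for rng in streams:
        boot = rng.integers(0, n, size=n)
        trees.append(
            train_tree(
                X[boot], y[boot],
                max_depth=max_depth,
                min_node_count=min_node_count,
                n_candidate_splits=n_candidate_splits,
                rng=rng,
            )
        )
    return DecisionForest(
        trees=trees,
        feature_length=X.shape[1],
        n_trees=n_trees,
        max_depth=max_depth,
        min_node_fraction=min_node_fraction,
        n_candidate_splits=n_candidate_splits,
        seed=seed,
    )


def predict_posterior(forest: DecisionForest, v: np.ndarray) -> np.ndarray | float:
    """Forest posterior P(microcalcification | v); scalar for a single
    vector, array for a matrix."""
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    out = forest.predict_posterior(np.atleast_2d(v))
    return float(out[0]) if single else out


def classify_candidates(
    forest: DecisionForest,
    coords: np.ndarray,
    X: np.ndarray,
    shape: tuple[int, int],
    theta_rf: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold the posterior map: pixel flagged iff posterior >= theta_rf.

    Returns ``(flag_map, prob_map)`` as full-image grids (probability 0
    outside the supplied coordinates).
    """
    if not 0.0 <= theta_rf <= 1.0:
        raise ValueError("theta_rf must be in [0, 1]")
    probs = forest.predict_posterior(X)
    prob_map = np.zeros(shape, dtype=np.float64)
    prob_map[coords[:, 0], coords[:, 1]] = probs
    flag_map = np.zeros(shape, dtype=bool)
    flag_map[coords[:, 0], coords[:, 1]] = probs >= theta_rf
    return flag_map, prob_map
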