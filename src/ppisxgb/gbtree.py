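"""Second-order gradient-boosted decision trees, written from scratch.

The learner is the classic additive tree ensemble: at round *t* the margin
is updated by a new regression tree,

    margin_t(x) = margin_{t-1}(x) + eta * f_t(x),

where f_t is grown greedily to minimise the second-order Taylor expansion
of the regularised objective

    obj = sum_i [ g_i f(x_i) + 1/2 h_i f(x_i)^2 ] + gamma * T + 1/2 lambda * sum_j w_j^2,

with g_i, h_i the first and second derivatives of the loss at the current
margin, T the number of leaves and w_j the leaf weights.  For a fixed tree
structure the optimal leaf weight has the closed form

    w_j* = - G_j / (H_j + lambda),        G_j = sum_{i in leaf j} g_i,

and the objective of the tree is  -1/2 sum_j G_j^2/(H_j + lambda) + gamma*T.
A split of a node with statistics (G, H) into (G_L, H_L) and (G_R, H_R)
improves the objective by

    gain = 1/2 [ G_L^2/(H_L+lambda) + G_R^2/(H_R+lambda) - G^2/(H+lambda) ] - gamma.

Split finding is *exact greedy*: every midpoint between consecutive
distinct sorted feature values is scored; no quantile sketch, sparsity
handling or subsampling — the learner is fully deterministic given its
inputs.  Ties are broken toward the lowest feature index, then the lowest
threshold.  Samples route left iff ``x[feature] < threshold``.

Two losses are provided: squared error (the regression default,
g = -2(y - margin), h = 2) and logistic deviance for binary labels with an
optional positive-class weight.  Shrinkage ``eta`` scales each tree's
contribution; ``eta = 1`` recovers the plain additive update.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "BoostParams",
    "TreeNode",
    "BoostedTreeModel",
    "GradHess",
    "grad_hess",
    "leaf_weight",
    "split_gain",
    "find_best_split",
    "build_tree",
    "fit",
    "predict_margin",
    "predict_proba",
]

LOSSES = ("logistic", "squared")


@dataclass
class BoostParams:
    """Hyperparameters of the boosted ensemble.

    lambda_ is the L2 penalty on leaf weights, gamma the per-leaf cost
    subtracted from every split gain, eta the shrinkage applied to each
    tree, min_child_weight the minimum sum of Hessians allowed in a child.
    """

    n_rounds: int = 200
    eta: float = 0.1
    lambda_: float = 1.0
    gamma: float = 0.0
    max_depth: int = 6
    min_child_weight: float = 1.0
    loss: str = "logistic"
    base_margin: float = 0.0
    pos_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must be in [0, 1]")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_child_weight < 0:
            raise ValueError("min_child_weight must be >= 0")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.pos_weight < 0:
            raise ValueError("pos_weight must be >= 0")


@dataclass
class TreeNode:
    """Either an internal split (feature, threshold, children) or a leaf (weight)."""

    weight: float | None = None
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.weight is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Route every row of X to its leaf and return the leaf weights."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        self._predict_into(X, np.arange(X.shape[0]), out)
        return out

    def _predict_into(self, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
        if self.is_leaf:
            out[idx] = self.weight
            return
        go_left = X[idx, self.feature] < self.threshold
        self.left._predict_into(X, idx[go_left], out)
        self.right._predict_into(X, idx[~go_left], out)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"weight": self.weight}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "weight" in d:
            return cls(weight=d["weight"])
        return cls(
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class GradHess:
    """Per-sample first- and second-order gradients of the loss."""

    g: np.ndarray
    h: np.ndarray


def grad_hess(loss: str, y: np.ndarray, margin: np.ndarray, pos_weight: float = 1.0) -> GradHess:
    """Gradients of the loss at the current margins.

    squared:   l = (y - margin)^2        -> g = -2(y - margin), h = 2
    logistic:  l = -w[y log p + (1-y) log(1-p)], p = sigmoid(margin)
               -> g = w (p - y), h = w p (1-p), w = pos_weight if y == 1 else 1
    """
    y = np.asarray(y, dtype=float)
    margin = np.asarray(margin, dtype=float)
    if not np.all(np.isfinite(margin)):
        raise ValueError("non-finite margin")
    if loss == "squared":
        g = -2.0 * (y - margin)
        h = np.full_like(g, 2.0)
    elif loss == "logistic":
        if not np.all((y == 0) | (y == 1)):
            raise ValueError("logistic loss requires labels in {0, 1}")
        p = _sigmoid(margin)
        w = np.where(y == 1, pos_weight, 1.0)
        g = w * (p - y)
        h = w * p * (1.0 - p)
    else:
        raise ValueError(f"loss must be one of {LOSSES}")
    return GradHess(g=g, h=h)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def leaf_weight(G: float, H: float, lambda_: float) -> float:
    """Closed-form optimal leaf weight  -G / (H + lambda).

    This is the minimiser of the per-leaf quadratic  G*w + 1/2 (H+lambda) w^2.
    """
    denom = H + lambda_
    if denom <= 0:
        raise ValueError(f"H + lambda must be > 0, got {denom}")
    return -G / denom


def split_gain(
    GL: float, HL: float, GR: float, HR: float, lambda_: float, gamma: float
) -> float:
    """Objective improvement of splitting (GL+GR, HL+HR) into left/right, minus gamma."""
    if HL + lambda_ <= 0 or HR + lambda_ <= 0:
        raise ValueError("child Hessian sums plus lambda must be > 0")
    G, H = GL + GR, HL + HR
    return 0.5 * (GL**2 / (HL + lambda_) + GR**2 / (HR + lambda_) - G**2 / (H + lambda_)) - gamma


@dataclass
class Split:
    feature: int
    threshold: float
    gain: float


def find_best_split(
    X: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    idx: np.ndarray,
    params: BoostParams,
) -> Split | None:
    """Exact greedy split search over every (feature, midpoint) candidate.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature within the node; both children must satisfy
    sum(h) >= min_child_weight.  Returns None when no candidate has
    strictly positive gain.  Ties break to the lowest feature index, then
    the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if X.shape[0] != g.shape[0] or g.shape[0] != h.shape[0]:
        raise ValueError("feature rows and gradient lengths disagree")
    idx = np.asarray(idx)
    if idx.size == 0:
        raise ValueError("empty sample index set")
    if idx.size < 2:
        return None

    Xs = X[idx]
    gs = g[idx]
    hs = h[idx]
    n = idx.size
    order = np.argsort(Xs, axis=0, kind="stable")
    Xsort = np.take_along_axis(Xs, order, axis=0)
    GL = np.cumsum(gs[order], axis=0)[:-1]
    HL = np.cumsum(hs[order], axis=0)[:-1]
    Gtot, Htot = gs.sum(), hs.sum()
    GR, HR = Gtot - GL, Htot - HL

    lam, gam, mcw = params.lambda_, params.gamma, params.min_child_weight
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - Gtot**2 / (Htot + lam)) - gam
    valid = (Xsort[1:] > Xsort[:-1]) & (HL >= mcw) & (HR >= mcw) & (HL + lam > 0) & (HR + lam > 0)
    gain = np.where(valid, gain, -np.inf)

    best = gain.max()
    if not best > 0 or not np.isfinite(best):
        return None
    # the cumsum scan can perturb the last bits of tied candidates, so
    # near-ties are re-scored with direct partition sums before the
    # deterministic tie-break (lowest feature index, then lowest threshold)
    tol = 1e-10 * max(1.0, abs(best))
    ks, js = np.nonzero(gain >= best - tol)
    chosen: Split | None = None
    for j in np.unique(js):
        for k in ks[js == j]:
            thr = float(0.5 * (Xsort[k, j] + Xsort[k + 1, j]))
            left = Xs[:, j] < thr
            exact = split_gain(
                gs[left].sum(), hs[left].sum(), gs[~left].sum(), hs[~left].sum(), lam, gam
            )
            if chosen is None or exact > chosen.gain + 1e-12:
                chosen = Split(feature=int(j), threshold=thr, gain=float(exact))
            # within tolerance: keep the earlier (lower feature, lower threshold)
    if chosen is None or not chosen.gain > 0:
        return None
    return chosen


def build_tree(X: np.ndarray, g: np.ndarray, h: np.ndarray, params: BoostParams) -> TreeNode:
    """Grow one regression tree by recursive exact-greedy splitting.

    Splitting stops at ``max_depth`` or when no candidate improves the
    regularised objective; every leaf carries its closed-form weight.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if X.shape[0] < 1:
        raise ValueError("need at least one sample")
    return _grow(X, g, h, np.arange(X.shape[0]), params, depth=0)


def _grow(X, g, h, idx, params: BoostParams, depth: int) -> TreeNode:
    if depth + 1 < params.max_depth and idx.size >= 2:
        split = find_best_split(X, g, h, idx, params)
    else:
        split = None
    if split is None:
        return TreeNode(weight=leaf_weight(g[idx].sum(), h[idx].sum(), params.lambda_))
    go_left = X[idx, split.feature] < split.threshold
    return TreeNode(
        feature=split.feature,
        threshold=split.threshold,
        left=_grow(X, g, h, idx[go_left], params, depth + 1),
        right=_grow(X, g, h, idx[~go_left], params, depth + 1),
    )


def tree_objective(root: TreeNode, X: np.ndarray, g: np.ndarray, h: np.ndarray, params: BoostParams) -> float:
    """Regularised objective  -1/2 sum_j G_j^2/(H_j+lambda) + gamma*T  of a tree on (g, h)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    leaves: dict[int, list[int]] = {}
    _assign_leaves(root, X, np.arange(X.shape[0]), leaves)
    obj = params.gamma * len(leaves)
    for members in leaves.values():
        G = g[members].sum()
        H = h[members].sum()
        obj -= 0.5 * G**2 / (H + params.lambda_)
    return obj


def _assign_leaves(node: TreeNode, X, idx, leaves: dict) -> None:
    if node.is_leaf:
        leaves[id(node)] = idx
        return
    go_left = X[idx, node.feature] < node.threshold
    _assign_leaves(node.left, X, idx[go_left], leaves)
    _assign_leaves(node.right, X, idx[~go_left], leaves)


@dataclass
class BoostedTreeModel:
    """An ordered ensemble of regression trees plus its hyperparameters.

    margin(x) = base_margin + eta * sum_t tree_t(x).
    """

    trees: list[TreeNode]
    params: BoostParams
    feature_count: int
    train_loss: list[float] = field(default_factory=list)

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_count:
            raise ValueError(f"expected {self.feature_count} feature columns, got {X.shape[1]}")
        margin = np.full(X.shape[0], self.params.base_margin, dtype=float)
        for tree in self.trees:
            margin += self.params.eta * tree.predict(X)
        return margin

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probabilities under the logistic loss; raw margins under squared loss."""
        margin = self.predict_margin(X)
        if self.params.loss == "logistic":
            return _sigmoid(margin)
        return margin

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": asdict(self.params),
                "feature_count": self.feature_count,
                "train_loss": self.train_loss,
                "trees": [t.to_dict() for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostedTreeModel":
        d = json.loads(text)
        return cls(
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            params=BoostParams(**d["params"]),
            feature_count=d["feature_count"],
            train_loss=list(d.get("train_loss", [])),
        )


def _mean_loss(loss: str, y: np.ndarray, margin: np.ndarray, pos_weight: float) -> float:
    if loss == "squared":
        return float(np.mean((y - margin) ** 2))
    p = np.clip(_sigmoid(margin), 1e-15, 1 - 1e-15)
    w = np.where(y == 1, pos_weight, 1.0)
    return float(np.mean(-w * (y * np.log(p) + (1 - y) * np.log(1 - p))))


def fit(X: np.ndarray, y: np.ndarray, params: BoostParams | None = None) -> BoostedTreeModel:
    """Train the boosted ensemble for ``params.n_rounds`` rounds.

    Each round computes (g, h) at the current margins, grows one tree and
    advances the margins by ``eta`` times its predictions.  The mean
    training loss after each round is recorded on the model.
    """
    params = params or BoostParams()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y lengths disagree")

    margin = np.full(X.shape[0], params.base_margin, dtype=float)
    trees: list[TreeNode] = []
    losses: list[float] = []
    for _ in range(params.n_rounds):
        gh = grad_hess(params.loss, y, margin, params.pos_weight)
        tree = build_tree(X, gh.g, gh.h, params)
        trees.append(tree)
        margin = margin + params.eta * tree.predict(X)
        loss = _mean_loss(params.loss, y, margin, params.pos_weight)
        if not math.isfinite(loss):
            raise FloatingPointError(f"training loss became non-finite at round {len(trees)}")
        losses.append(loss)
    return BoostedTreeModel(trees=trees, params=params, feature_count=X.shape[1], train_loss=losses)


def predict_margin(model: BoostedTreeModel, X: np.ndarray) -> np.ndarray:
    return model.predict_margin(X)


def predict_proba(model: BoostedTreeModel, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)
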