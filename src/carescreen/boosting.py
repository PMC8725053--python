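"""Stochastic gradient-boosted regression trees with logistic loss.

A from-scratch boosting machine for the binary careless/regular outcome:

* logistic loss L = y ln(1+e^-F) + (1-y) ln(1+e^F) on the margin F,
* negative gradient (pseudo-residual) g = y - p with p = sigmoid(F),
* greedy least-squares CART trees on the pseudo-residuals, depth- and
  leaf-size-limited so each tree stays a weak learner,
* terminal-node values by a single Newton step gamma = sum g / sum p(1-p),
* shrinkage lambda on every tree's contribution, and
* stochastic subsampling: each tree is grown on a without-replacement
  random subsample of the training rows (default fraction .5).

The module follows the statsmodels convention: :class:`GradientBoostedTrees`
is the model (data + hyperparameters), ``fit()`` returns a
:class:`BoostingResults` carrying the ensemble, the training-loss trace and
prediction methods. :func:`grid_search_cv` tunes hyperparameters by
stratified k-fold cross-validation with up-sampling applied inside each
training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ValidationError

__all__ = [
    "GradientBoostedTrees",
    "BoostingResults",
    "TreeModel",
    "TuningGrid",
    "logistic_loss",
    "loss_gradient",
    "fit_tree",
    "gbm_fit",
    "gbm_predict",
    "upsample",
    "stratified_folds",
    "grid_search_cv",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    """log(1 + e^z), overflow-safe."""
    return np.logaddexp(0.0, z)


def logistic_loss(y: np.ndarray, margin: np.ndarray) -> np.ndarray:
    """Per-observation logistic loss at margin (log-odds) predictions."""
    y = np.asarray(y, dtype=float)
    margin = np.asarray(margin, dtype=float)
    return y * _softplus(-margin) + (1.0 - y) * _softplus(margin)


def loss_gradient(y: np.ndarray, margin: np.ndarray) -> np.ndarray:
    """Negative gradient of the logistic loss: g = y - sigmoid(margin)."""
    return np.asarray(y, dtype=float) - _sigmoid(np.asarray(margin, dtype=float))


@dataclass
class TreeModel:
    """Flat-array binary regression tree.

    ``feature[i] == -1`` marks a leaf with score ``value[i]``; internal
    nodes route rows with x[feature] <= threshold to ``left``, else
    ``right``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_node: np.ndarray

    @property
    def n_leaves(self) -> int:
        return int((self.feature == -1).sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        node = np.zeros(X.shape[0], dtype=np.int32)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                break
            rows = np.flatnonzero(active)
            f = feat[rows]
            go_left = X[rows, f] <= self.threshold[node[rows]]
            node[rows] = np.where(go_left, self.left[node[rows]],
                                  self.right[node[rows]])
        return self.value[node]

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist()
                for k in ("feature", "threshold", "left", "right", "value", "n_node")}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int32),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            value=np.asarray(d["value"], dtype=float),
            n_node=np.asarray(d["n_node"], dtype=np.int64),
        )


class _SplitContext:
    """Pre-binned feature codes shared by all trees of one ensemble fit.

    Every feature's observed unique values become one code segment of a
    global bin axis; a single pair of bincounts per node then yields the
    exhaustive least-squares split scan over all features at once, visiting
    candidates in (feature index, threshold) order so that ``argmax`` ties
    resolve toward the lowest feature, then the lowest threshold.
    """

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        self.X = X
        self.n, self.p = n, p
        uniqs = [np.unique(X[:, j]) for j in range(p)]
        sizes = np.array([len(u) for u in uniqs])
        starts = np.r_[0, np.cumsum(sizes)[:-1]]
        self.n_bins = int(sizes.sum())
        self.bin_values = np.concatenate(uniqs)
        self.seg_start = starts
        self.seg_end = starts + sizes
        codes = np.empty((n, p), dtype=np.int64)
        for j in range(p):
            codes[:, j] = starts[j] + np.searchsorted(uniqs[j], X[:, j])
        self.codes = codes
        # candidate boundaries: every bin except each segment's last
        mask = np.ones(self.n_bins, dtype=bool)
        mask[self.seg_end - 1] = False
        self.boundary = np.flatnonzero(mask)
        seg_of_bin = np.repeat(np.arange(p), sizes)
        self.boundary_seg = seg_of_bin[self.boundary]

    def best_split(self, idx: np.ndarray, g: np.ndarray, min_leaf: int):
        """Best (gain, feature, threshold) over all features for node rows
        ``idx`` with pseudo-residuals ``g`` (aligned with idx), or None."""
        n_node = len(idx)
        flat = self.codes[idx].ravel()
        w = np.repeat(g, self.p)
        cnt = np.bincount(flat, minlength=self.n_bins)
        gs = np.bincount(flat, weights=w, minlength=self.n_bins)
        ccnt = np.cumsum(cnt)
        cgs = np.cumsum(gs)
        total = g.sum()
        b = self.boundary
        seg = self.boundary_seg
        base_cnt = np.where(self.seg_start[seg] > 0,
                            ccnt[self.seg_start[seg] - 1], 0)
        base_g = np.where(self.seg_start[seg] > 0,
                          cgs[self.seg_start[seg] - 1], 0.0)
        nl = ccnt[b] - base_cnt
        gl = cgs[b] - base_g
        nr = n_node - nl
        valid = (cnt[b] > 0) & (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            return None
        with np.errstate(invalid="ignore", divide="ignore"):
            gain = gl**2 / nl + (total - gl) ** 2 / nr - total**2 / n_node
        gain[~valid] = -np.inf
        k = int(np.argmax(gain))
        if not np.isfinite(gain[k]) or gain[k] <= 1e-12:
            return None
        bin_k = b[k]
        j = int(seg[k])
        # midpoint to the next bin occupied in this node
        hi = self.seg_end[j]
        nxt = bin_k + 1 + int(np.argmax(cnt[bin_k + 1: hi] > 0))
        thr = (self.bin_values[bin_k] + self.bin_values[nxt]) / 2.0
        return float(gain[k]), j, float(thr)


def _grow_tree(ctx: _SplitContext, idx: np.ndarray, targets: np.ndarray,
               weights: np.ndarray, depth: int, min_leaf: int) -> TreeModel:
    """Grow one greedy least-squares tree on the rows ``idx``."""
    feature, threshold, left, right, value, n_node = [], [], [], [], [], []

    def leaf_value(rows):
        denom = weights[rows].sum()
        return float(targets[rows].sum() / max(denom, 1e-12))

    def build(rows: np.ndarray, d: int) -> int:
        node_id = len(feature)
        feature.append(-1)
        threshold.append(np.nan)
        left.append(-1)
        right.append(-1)
        value.append(leaf_value(rows))
        n_node.append(len(rows))
        if d >= depth or len(rows) < 2 * min_leaf:
            return node_id
        best = ctx.best_split(rows, targets[rows], min_leaf)
        if best is None:
            return node_id
        _, j, thr = best
        go_left = ctx.X[rows, j] <= thr
        feature[node_id] = j
        threshold[node_id] = thr
        left_id = build(rows[go_left], d + 1)
        right_id = build(rows[~go_left], d + 1)
        left[node_id] = left_id
        right[node_id] = right_id
        return node_id

    build(idx, 0)
    return TreeModel(
        feature=np.asarray(feature, dtype=np.int32),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        value=np.asarray(value, dtype=float),
        n_node=np.asarray(n_node, dtype=np.int64),
    )


def fit_tree(
    X: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    depth: int = 2,
    min_leaf: int = 5,
) -> TreeModel:
    """Greedy least-squares regression tree on pseudo-residuals.

    Splits minimize the residual sum of squares of ``targets``; candidate
    thresholds are the midpoints of sorted unique feature values present at
    the node; ties are broken toward the lowest feature index, then the
    lowest threshold. Leaf scores are the one-step Newton update
    sum(targets) / sum(weights). Constant targets yield a single leaf.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ctx = _SplitContext(X)
    return _grow_tree(ctx, np.arange(X.shape[0]), targets, weights,
                      depth, min_leaf)


@dataclass
class BoostingResults:
    """Fitted boosted ensemble: F0 plus M shrunken trees."""

    f0: float
    trees: list
    shrinkage: float
    subsample: float
    loss_trace: np.ndarray
    n_features: int
    val_loss: dict = field(default_factory=dict)   # checkpoint M -> mean val loss
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def decision_margin(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValidationError(
                f"feature count mismatch: got {X.shape[1] if X.ndim == 2 else X.ndim}"
                f", expected {self.n_features}"
            )
        m = np.full(X.shape[0], self.f0)
        use = self.trees if n_trees is None else self.trees[:n_trees]
        for tree in use:
            m += self.shrinkage * tree.predict(X)
        return m

    def predict_proba(self, X: np.ndarray, n_trees: int | None = None) -> np.ndarray:
        return _sigmoid(self.decision_margin(X, n_trees))

    def predict(self, X: np.ndarray, p_cut: float = 0.5,
                n_trees: int | None = None) -> np.ndarray:
        return (self.predict_proba(X, n_trees) >= p_cut).astype(int)

    def summary(self) -> str:
        hp = ", ".join(f"{k}={v}" for k, v in sorted(self.hyperparams.items()))
        return (
            "Stochastic Gradient Boosted Trees (logistic loss)\n"
            f"trees: {self.n_trees}  shrinkage: {self.shrinkage}  "
            f"subsample: {self.subsample}\n"
            f"F0 (prior log-odds): {self.f0:.4f}\n"
            f"hyperparameters: {hp or '(defaults)'}\n"
            f"final training loss: {self.loss_trace[-1]:.5f}"
        )

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "shrinkage": self.shrinkage,
            "subsample": self.subsample,
            "n_features": self.n_features,
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BoostingResults":
        return cls(
            f0=float(d["f0"]),
            trees=[TreeModel.from_dict(t) for t in d["trees"]],
            shrinkage=float(d["shrinkage"]),
            subsample=float(d["subsample"]),
            loss_trace=np.array([np.nan]),
            n_features=int(d["n_features"]),
        )


class GradientBoostedTrees:
    """Boosted-tree model for a binary outcome (1 = careless).

    Parameters
    ----------
    X : ndarray (n, p)
        Feature table (raw item responses and/or response-time parcels).
    y : ndarray (n,)
        Binary labels; both classes must be present.
    n_trees, depth, min_leaf, shrinkage, subsample
        The usual boosting hyperparameters; subsampling is without
        replacement per iteration.
    """

    def __init__(self, X, y, n_trees: int = 250, depth: int = 2,
                 min_leaf: int = 5, shrinkage: float = 0.01,
                 subsample: float = 0.5):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValidationError("X must be (n, p) with matching y")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValidationError("y must contain both classes 0 and 1")
        if not 0 < subsample <= 1:
            raise ValidationError("subsample fraction outside (0, 1]")
        self.X, self.y = X, y
        self.n_trees, self.depth, self.min_leaf = n_trees, depth, min_leaf
        self.shrinkage, self.subsample = shrinkage, subsample

    def fit(self, seed=0, X_val=None, y_val=None,
            checkpoints: tuple = ()) -> BoostingResults:
        """Boost ``n_trees`` rounds; optionally track validation loss.

        ``checkpoints`` are tree counts at which the mean validation loss is
        recorded (used by the grid search to evaluate nested tree counts
        from a single fit).
        """
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        X, y = self.X, self.y
        n = len(y)
        pbar = y.mean()
        f0 = float(np.log(pbar / (1 - pbar)))
        margin = np.full(n, f0)
        val_margin = None
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=float)
            val_margin = np.full(X_val.shape[0], f0)
        n_sub = max(2 * self.min_leaf, int(round(self.subsample * n)))
        n_sub = min(n_sub, n)
        ctx = _SplitContext(X)
        trees = []
        loss_trace = np.empty(self.n_trees + 1)
        loss_trace[0] = logistic_loss(y, margin).mean()
        val_loss = {}
        for m in range(1, self.n_trees + 1):
            p = _sigmoid(margin)
            g = y - p
            h = p * (1 - p)
            idx = rng.choice(n, size=n_sub, replace=False) if n_sub < n else np.arange(n)
            tree = _grow_tree(ctx, idx, g, h, self.depth, self.min_leaf)
            trees.append(tree)
            margin += self.shrinkage * tree.predict(X)
            loss_trace[m] = logistic_loss(y, margin).mean()
            if val_margin is not None:
                val_margin += self.shrinkage * tree.predict(X_val)
                if m in checkpoints:
                    val_loss[m] = float(logistic_loss(y_val, val_margin).mean())
        return BoostingResults(
            f0=f0, trees=trees, shrinkage=self.shrinkage,
            subsample=self.subsample, loss_trace=loss_trace,
            n_features=X.shape[1], val_loss=val_loss,
            hyperparams={"n_trees": self.n_trees, "depth": self.depth,
                         "min_leaf": self.min_leaf,
                         "shrinkage": self.shrinkage},
        )


def gbm_fit(X, y, n_trees=250, depth=2, min_leaf=5, shrinkage=0.01,
            subsample=0.5, seed=0) -> BoostingResults:
    """Functional wrapper around :class:`GradientBoostedTrees`."""
    return GradientBoostedTrees(
        X, y, n_trees=n_trees, depth=depth, min_leaf=min_leaf,
        shrinkage=shrinkage, subsample=subsample,
    ).fit(seed=seed)


def gbm_predict(results: BoostingResults, X) -> tuple[np.ndarray, np.ndarray]:
    """(margins, probabilities) for a fitted ensemble."""
    m = results.decision_margin(X)
    return m, _sigmoid(m)


def upsample(X, y, seed=0, return_indices: bool = False):
    """Replicate minority-class rows (with replacement) to the majority count.

    Majority rows are untouched; balanced input is returned unchanged.
    With ``return_indices`` the source row index of every output row is
    returned, so callers can assert that no replicate leaks into a
    validation fold.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y), np.bincount(y)
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    minority = int(np.argmin(counts[:2]))
    n_extra = int(counts[1 - minority] - counts[minority])
    idx_all = np.arange(len(y))
    if n_extra == 0:
        return (X, y, idx_all) if return_indices else (X, y)
    pool = np.flatnonzero(y == minority)
    extra = rng.choice(pool, size=n_extra, replace=True)
    idx = np.r_[idx_all, extra]
    if return_indices:
        return X[idx], y[idx], idx
    return X[idx], y[idx]


def stratified_folds(y: np.ndarray, k: int, seed=0) -> list:
    """Class-stratified k-fold partition; returns a list of validation
    index arrays that partition all rows exactly once."""
    y = np.asarray(y, dtype=int)
    if len(y) < k:
        raise ValidationError("fewer rows than folds")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for i, ix in enumerate(idx):
            folds[i % k].append(ix)
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


@dataclass(frozen=True)
class TuningGrid:
    """Hyperparameter grid for the cross-validated search."""

    depth: tuple = (2, 3)
    min_leaf: tuple = (5, 10)
    shrinkage: tuple = (0.005, 0.015, 0.03)
    n_trees: tuple = (250, 500)

    @classmethod
    def reduced(cls) -> "TuningGrid":
        """Desk-scale default grid."""
        return cls()

    @classmethod
    def full(cls) -> "TuningGrid":
        """The complete benchmark grid: depth 2-4, leaf 4-10, shrinkage
        .001-.03 in steps of .002, trees 250-800 in steps of 50."""
        return cls(
            depth=(2, 3, 4),
            min_leaf=tuple(range(4, 11)),
            shrinkage=tuple(np.round(np.arange(0.001, 0.0301, 0.002), 3)),
            n_trees=tuple(range(250, 801, 50)),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "TuningGrid":
        kw = {k: tuple(v) for k, v in d.items()}
        return cls(**kw)

    def cells(self):
        for d in self.depth:
            for leaf in self.min_leaf:
                for lam in self.shrinkage:
                    yield d, leaf, lam

    def __len__(self):
        return len(self.depth) * len(self.min_leaf) * len(self.shrinkage) * len(self.n_trees)


def grid_search_cv(X, y, grid: TuningGrid | None = None, k: int = 10,
                   seed=0, subsample: float = 0.5):
    """Stratified k-fold grid search minimizing mean validation logistic loss.

    Up-sampling is applied inside each training fold only. All tree counts
    in the grid are evaluated from a single fit per (depth, leaf,
    shrinkage) cell using staged validation losses. Ties are broken toward
    fewer trees, then shallower depth, then larger leaves.

    Returns (best_params dict, cv_table DataFrame).
    """
    grid = TuningGrid.reduced() if grid is None else grid
    if len(grid) == 0:
        raise ValidationError("empty tuning grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = stratified_folds(y, k, rng)
    m_max = max(grid.n_trees)
    checkpoints = tuple(sorted(grid.n_trees))
    records = {}
    for fold_ix, val_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        Xt, yt = upsample(X[train_mask], y[train_mask], seed=rng)
        for d, leaf, lam in grid.cells():
            model = GradientBoostedTrees(
                Xt, yt, n_trees=m_max, depth=d, min_leaf=leaf,
                shrinkage=lam, subsample=subsample,
            )
            res = model.fit(seed=rng, X_val=X[val_idx], y_val=y[val_idx],
                            checkpoints=checkpoints)
            for M, loss in res.val_loss.items():
                records.setdefault((d, leaf, lam, M), []).append(loss)
    rows = []
    for (d, leaf, lam, M), losses in records.items():
        rows.append({"depth": d, "min_leaf": leaf, "shrinkage": lam,
                     "n_trees": M, "mean_val_loss": float(np.mean(losses))})
    table = pd.DataFrame(rows)
    # tie-breaks: fewer trees, then shallower, then larger leaves
    table = table.sort_values(
        ["mean_val_loss", "n_trees", "depth", "min_leaf"],
        ascending=[True, True, True, False],
    ).reset_index(drop=True)
    best = table.iloc[0]
    best_params = {
        "depth": int(best["depth"]),
        "min_leaf": int(best["min_leaf"]),
        "shrinkage": float(best["shrinkage"]),
        "n_trees": int(best["n_trees"]),
    }
    return best_params, table
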