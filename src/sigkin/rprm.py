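"""Recursively partitioned regression models (ANOVA CART).

A binary regression tree grown by exhaustively evaluating every candidate
threshold of every predictor at each node and taking the split that
maximizes the between-child sum of squares, with three stopping rules:
a node below ``minsplit`` rows is not split, a split leaving a child below
``minbucket`` rows is not allowed, and a split whose improvement is less
than ``cp`` times the root sum of squares is rejected (the rpart
cost-complexity convention).  Over-fitting is then removed by k-fold
cross-validation over the tree's cost-complexity sequence: for each fold a
tree is regrown on the remaining data, every complexity level is scored on
the held-out fold by predictive R-squared, and the full-data tree is pruned
at the complexity level with the best mean held-out score.

Conventions: thresholds sit at midpoints between consecutive distinct
values; rows with value equal to the threshold go left; ties in improvement
break toward the earlier column and then the smaller threshold; a missing
value at prediction time follows the majority direction recorded at
training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class TreeNode:
    n: int
    mean: float
    dev: float                      # within-node sum of squared deviations
    var: Optional[str] = None       # split variable (None for a leaf)
    threshold: float = math.nan
    improve: float = 0.0            # between-child SS gained by the split
    majority: str = "L"             # direction for missing values
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        return [self] + self.left.internal_nodes() + self.right.internal_nodes()

    def n_nodes(self) -> int:
        return 1 if self.is_leaf else 1 + self.left.n_nodes() + self.right.n_nodes()

    def copy(self) -> "TreeNode":
        node = TreeNode(self.n, self.mean, self.dev, self.var, self.threshold,
                        self.improve, self.majority)
        if not self.is_leaf:
            node.left = self.left.copy()
            node.right = self.right.copy()
        return node


@dataclass
class RegressionTree:
    """A fitted tree plus the metadata needed to predict and prune it."""

    root: TreeNode
    columns: list[str]
    minsplit: int = 15
    minbucket: int = 15
    cp: float = 0.01
    cv_record: Optional[pd.DataFrame] = None   # complexity level x fold scores

    def predict(self, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
        return predict(self, rows)

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def render(self) -> str:
        out: list[str] = []

        def walk(node: TreeNode, indent: str, tag: str) -> None:
            if node.is_leaf:
                out.append(f"{indent}{tag}leaf n={node.n} mean={node.mean:.4g}")
            else:
                out.append(f"{indent}{tag}{node.var} <= {node.threshold:.4g} "
                           f"n={node.n} mean={node.mean:.4g}")
                walk(node.left, indent + "  ", "L: ")
                walk(node.right, indent + "  ", "R: ")

        walk(self.root, "", "")
        return "\n".join(out)

    def to_json_obj(self) -> dict:
        def walk(node: TreeNode) -> dict:
            obj = {"n": node.n, "mean": node.mean, "dev": node.dev}
            if not node.is_leaf:
                obj.update(var=node.var, threshold=node.threshold,
                           improve=node.improve, majority=node.majority,
                           left=walk(node.left), right=walk(node.right))
            return obj
        return {"columns": self.columns, "minsplit": self.minsplit,
                "minbucket": self.minbucket, "cp": self.cp,
                "tree": walk(self.root)}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_obj(), fh, indent=1)

    @classmethod
    def from_json_obj(cls, obj: dict) -> "RegressionTree":
        def walk(d: dict) -> TreeNode:
            node = TreeNode(d["n"], d["mean"], d["dev"])
            if "var" in d:
                node.var = d["var"]
                node.threshold = d["threshold"]
                node.improve = d.get("improve", 0.0)
                node.majority = d.get("majority", "L")
                node.left = walk(d["left"])
                node.right = walk(d["right"])
            return node
        return cls(root=walk(obj["tree"]), columns=list(obj["columns"]),
                   minsplit=obj["minsplit"], minbucket=obj["minbucket"],
                   cp=obj["cp"])


def _as_matrix(rows: pd.DataFrame | np.ndarray,
               columns: Sequence[str]) -> np.ndarray:
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in columns if c not in rows.columns]
        if missing:
            raise KeyError(f"rows lack split variables {missing}")
        return rows[list(columns)].to_numpy(dtype=float)
    return np.asarray(rows, dtype=float)


def best_split(X: np.ndarray, y: np.ndarray, columns: Sequence[str],
               minbucket: int = 1) -> Optional[tuple[str, float, float]]:
    """Exhaustive maximizer of the between-child sum of squares.

    Returns ``(variable, threshold, between_SS)`` or None when no split
    satisfies ``minbucket`` or the outcome has zero variance.  Thresholds are
    midpoints of consecutive distinct values; ties break toward the earlier
    column and then the smaller threshold.
    """
    n = len(y)
    if n < 2:
        return None
    total = y.sum()
    mean = total / n
    if np.allclose(y, mean):
        return None
    best: Optional[tuple[str, float, float]] = None
    for j, name in enumerate(columns):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        csum = np.cumsum(ys)[:-1]          # left sums for split after row i
        nl = np.arange(1, n)
        valid = (xs[1:] != xs[:-1]) & (nl >= minbucket) & (n - nl >= minbucket)
        if not valid.any():
            continue
        between = (csum ** 2 / nl + (total - csum) ** 2 / (n - nl)
                   - total ** 2 / n)
        between = np.where(valid, between, -np.inf)
        i = int(np.argmax(between))
        if between[i] > (best[2] if best else 0.0) + 1e-12:
            thr = (xs[i] + xs[i + 1]) / 2.0
            best = (name, float(thr), float(between[i]))
    return best


def grow_tree(design: pd.DataFrame, outcome: str = "y",
              variables: Optional[list[str]] = None,
              minsplit: int = 15, minbucket: int = 15,
              cp: float = 0.01) -> RegressionTree:
    """Grow the over-fitted tree under the three stopping rules."""
    if len(design) == 0:
        raise ValueError("empty design matrix")
    if variables is None:
        variables = [c for c in design.columns
                     if c not in (outcome, "focal", "month")]
    X = _as_matrix(design, variables)
    y = design[outcome].to_numpy(dtype=float)
    root_dev = float(((y - y.mean()) ** 2).sum())

    def build(idx: np.ndarray) -> TreeNode:
        yy = y[idx]
        node = TreeNode(n=len(idx), mean=float(yy.mean()),
                        dev=float(((yy - yy.mean()) ** 2).sum()))
        if node.n < minsplit or node.dev <= 0.0:
            return node
        found = best_split(X[idx], yy, variables, minbucket)
        if found is None:
            return node
        var, thr, between = found
        if root_dev > 0 and between < cp * root_dev:
            return node
        j = variables.index(var)
        go_left = X[idx, j] <= thr
        node.var, node.threshold, node.improve = var, thr, between
        node.majority = "L" if go_left.sum() >= (~go_left).sum() else "R"
        node.left = build(idx[go_left])
        node.right = build(idx[~go_left])
        return node

    root = build(np.arange(len(y)))
    return RegressionTree(root=root, columns=variables, minsplit=minsplit,
                          minbucket=minbucket, cp=cp)


def predict(tree: RegressionTree, rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Route rows to leaves; prediction is the leaf mean."""
    X = _as_matrix(rows, tree.columns)
    col = {c: j for j, c in enumerate(tree.columns)}
    out = np.empty(len(X))

    def walk(node: TreeNode, idx: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = node.mean
            return
        v = X[idx, col[node.var]]
        left = v <= node.threshold
        nan = np.isnan(v)
        left[nan] = node.majority == "L"
        walk(node.left, idx[left])
        walk(node.right, idx[~left])

    walk(tree.root, np.arange(len(X)))
    return out


# -- cost-complexity machinery -----------------------------------------------

def _weakest_g(node: TreeNode) -> float:
    """Cost-complexity value of collapsing this internal node's subtree."""
    leaves = node.leaves()
    return (node.dev - sum(l.dev for l in leaves)) / (len(leaves) - 1)


def alpha_sequence(root: TreeNode) -> list[float]:
    """Increasing alphas at which weakest-link pruning collapses a node."""
    work = root.copy()
    alphas = []
    while not work.is_leaf:
        g = min(_weakest_g(n) for n in work.internal_nodes())
        alphas.append(g)
        for n in work.internal_nodes():
            if _weakest_g(n) <= g + 1e-12:
                n.var, n.left, n.right = None, None, None
    return sorted(set(alphas))


def prune(tree_or_root: RegressionTree | TreeNode,
          alpha: float) -> RegressionTree | TreeNode:
    """Weakest-link prune: collapse while the minimal g is <= alpha."""
    is_tree = isinstance(tree_or_root, RegressionTree)
    root = (tree_or_root.root if is_tree else tree_or_root).copy()
    while not root.is_leaf:
        internals = root.internal_nodes()
        g = min(_weakest_g(n) for n in internals)
        if g > alpha + 1e-12:
            break
        for n in internals:
            if _weakest_g(n) <= g + 1e-12:
                n.var, n.left, n.right = None, None, None
    if is_tree:
        return RegressionTree(root=root, columns=tree_or_root.columns,
                              minsplit=tree_or_root.minsplit,
                              minbucket=tree_or_root.minbucket,
                              cp=tree_or_root.cp)
    return root


def make_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint covering folds with sizes differing by at most one."""
    if k > n:
        raise ValueError(f"k={k} exceeds row count {n}")
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, k)]


def predictive_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Signed 1 - SSE/SST; zero for the mean predictor, negative when worse."""
    sst = float(((observed - observed.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("zero variance in observed outcome")
    sse = float(((observed - predicted) ** 2).sum())
    return 1.0 - sse / sst


def cv_prune(design: pd.DataFrame, tree: RegressionTree, k: int = 10,
             rng_seed: int = 0, outcome: str = "y",
             rule: str = "1se") -> RegressionTree:
    """Prune by k-fold cross-validation over the cost-complexity sequence.

    For each fold the tree is regrown on the remaining rows and every
    complexity level (geometric means of consecutive alphas of the full-data
    tree, plus the unpruned and root-only extremes) predicts the held-out
    fold; after testing across all k folds each level's accuracy is the
    predictive R-squared of the pooled out-of-fold predictions.  Under
    ``rule="best"`` the full-data tree is pruned at the level with the
    highest accuracy (ties resolve toward the simpler tree); the default
    ``rule="1se"`` is the standard one-standard-error rule — the simplest
    level whose accuracy is within one standard error of the best — which
    reliably collapses spurious structure fitted to noise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(design)
    if n < k:
        raise ValueError(f"k={k} exceeds row count {n}")
    alphas = alpha_sequence(tree.root)
    if not alphas:
        return RegressionTree(root=tree.root.copy(), columns=tree.columns,
                              minsplit=tree.minsplit, minbucket=tree.minbucket,
                              cp=tree.cp)
    grid = [0.0]
    for a, b in zip(alphas, alphas[1:]):
        grid.append(math.sqrt(a * b))
    grid.append(math.inf)   # the root-leaf (mean predictor) complexity level
    rng = np.random.default_rng(rng_seed)
    folds = make_folds(n, k, rng)
    y = design[outcome].to_numpy(dtype=float)
    oof = np.zeros((len(grid), n))           # out-of-fold predictions
    fold_sse = np.zeros((len(grid), k))
    for fi, hold in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[hold] = False
        sub = design.iloc[train_mask.nonzero()[0]]
        fold_tree = grow_tree(sub, outcome=outcome, variables=tree.columns,
                              minsplit=tree.minsplit, minbucket=tree.minbucket,
                              cp=tree.cp)
        held = design.iloc[hold]
        for gi, alpha in enumerate(grid):
            pred = predict(prune(fold_tree, alpha), held)
            oof[gi, hold] = pred
            fold_sse[gi, fi] = float(((y[hold] - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        scores = np.zeros(len(grid))
        se = np.zeros(len(grid))
    else:
        scores = 1.0 - fold_sse.sum(axis=1) / sst
        se = np.sqrt(k * fold_sse.var(axis=1, ddof=1)) / sst
    best = max(range(len(grid)),
               key=lambda i: (round(scores[i], 12), grid[i]))
    pick = best
    if rule == "1se":
        floor = scores[best] - se[best]
        pick = max(i for i in range(len(grid)) if scores[i] >= floor - 1e-12)
    elif rule != "best":
        raise ValueError(f"unknown selection rule {rule!r}")
    pruned = prune(tree, grid[pick])
    pruned.cv_record = pd.DataFrame(
        {"alpha": grid, "cv_r2": scores, "cv_se": se})
    return pruned


def external_validation(tree: RegressionTree, holdout: pd.DataFrame,
                        outcome: str = "y") -> dict[str, float]:
    """Accuracy on an independent population built with the same model spec.

    Returns the signed predictive R-squared (primary) and the squared Pearson
    correlation between predicted and observed outcomes.
    """
    obs = holdout[outcome].to_numpy(dtype=float)
    if float(((obs - obs.mean()) ** 2).sum()) == 0.0:
        raise ValueError("zero variance in holdout outcome; accuracy undefined")
    pred = predict(tree, holdout)
    r2 = predictive_r2(obs, pred)
    if np.std(pred) == 0.0:
        pearson = 0.0
    else:
        pearson = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return {"predictive_r2": r2, "pearson_r2": pearson}
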