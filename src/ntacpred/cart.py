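"""From-scratch CART binary decision tree over one-hot sequence features.

Greedy recursive binary partitioning with the Gini impurity criterion on
(position, residue) indicator features.  Training is fully deterministic:
ties between equal-gain features are broken toward the lowest feature index
(position-major, alphabet-rank-minor), and leaf label ties predict
"unacetylated" — the conservative call for a modification.  The maximum tree
depth is the single tuned hyperparameter, selected by stratified 5-fold
cross-validated grid search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .encoding import (ALPHABET, N_RESIDUES, WindowSpec, encode_dataset,
                       extract_window, feature_name)
from .seqdata import DataError, NEGATIVE, POSITIVE, SequenceDataset, STANDARD_RESIDUES


def gini_impurity(n_pos: int, n_neg: int) -> float:
    """Gini impurity 1 - p+^2 - p-^2 of a binary node; in [0, 0.5]."""
    n = n_pos + n_neg
    if n < 1:
        raise ValueError("empty node has no impurity")
    p = n_pos / n
    q = n_neg / n
    return 1.0 - p * p - q * q


@dataclass
class TreeNode:
    """Internal split node (feature set) or leaf (feature None).

    `n_pos`/`n_neg` are training-case counts reaching the node, so child
    counts always sum to the parent's — the arrow-number semantics of the
    predictor flowchart.
    """

    n_pos: int
    n_neg: int
    feature: Optional[int] = None
    yes: Optional["TreeNode"] = None
    no: Optional["TreeNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def predicted_label(self) -> str:
        # tie -> negative: conservative for calling a modification
        return POSITIVE if self.n_pos > self.n_neg else NEGATIVE

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.yes.depth(), self.no.depth())

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.yes.leaves() + self.no.leaves()


def _split_scores(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature child counts and the score whose maximum minimizes the
    size-weighted child Gini impurity.

    For a yes/no partition the weighted impurity equals
    ``1 - T/n`` with ``T = (pos_y^2 + neg_y^2)/n_y + (pos_n^2 + neg_n^2)/n_n``,
    so maximizing T maximizes the impurity decrease.
    """
    n = y.size
    n_pos = int(y.sum())
    n_yes = X.sum(axis=0, dtype=np.int64)
    pos_yes = X[y == 1].sum(axis=0, dtype=np.int64) if n_pos else np.zeros_like(n_yes)
    n_no = n - n_yes
    pos_no = n_pos - pos_yes
    neg_yes = n_yes - pos_yes
    neg_no = n_no - pos_no
    valid = (n_yes > 0) & (n_no > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = ((pos_yes.astype(float) ** 2 + neg_yes.astype(float) ** 2) / n_yes
             + (pos_no.astype(float) ** 2 + neg_no.astype(float) ** 2) / n_no)
    T[~valid] = -np.inf
    return T, n_yes, pos_yes


def find_best_split(X: np.ndarray, y: np.ndarray) -> Optional[tuple[int, float]]:
    """Best (feature, impurity decrease) over all indicators, or None.

    Returns None when no split gives a strictly positive Gini decrease or
    every candidate leaves a child empty.  Equal-gain ties go to the lowest
    feature index; positivity of the winning gain is confirmed in exact
    integer arithmetic so float rounding can never manufacture a split.
    """
    n = y.size
    if n == 0:
        raise ValueError("empty case set")
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    T, n_yes, pos_yes = _split_scores(X, y)
    fmax = float(np.max(T))
    if not np.isfinite(fmax):
        return None
    # resolve near-ties exactly: compare S_f / (n_y * n_n) as integer
    # cross-products so float rounding never decides between equal gains
    candidates = np.flatnonzero(T >= fmax - 1e-9 * max(1.0, abs(fmax)))

    def exact_num_den(f: int) -> tuple[int, int]:
        ny, py = int(n_yes[f]), int(pos_yes[f])
        nn, pn = n - ny, n_pos - py
        S = (py * py + (ny - py) ** 2) * nn + (pn * pn + (nn - pn) ** 2) * ny
        return S, ny * nn

    f = int(candidates[0])
    best_num, best_den = exact_num_den(f)
    for g in candidates[1:]:
        num, den = exact_num_den(int(g))
        if num * best_den > best_num * den:  # strictly better only
            f, best_num, best_den = int(g), num, den
    ny, py = int(n_yes[f]), int(pos_yes[f])
    nn, pn = n - ny, n_pos - py
    # exact positivity: T_f > (n_pos^2 + n_neg^2)/n  <=>  S*n > parent*ny*nn
    S = (py * py + (ny - py) ** 2) * nn + (pn * pn + (nn - pn) ** 2) * ny
    if S * n <= (n_pos * n_pos + n_neg * n_neg) * ny * nn:
        return None
    parent = gini_impurity(n_pos, n_neg)
    weighted = (ny * gini_impurity(py, ny - py) + nn * gini_impurity(pn, nn - pn)) / n
    return f, parent - weighted


def grow_tree_root(X: np.ndarray, y: np.ndarray, max_depth: int,
                   min_split: int = 2, min_leaf: int = 1) -> TreeNode:
    """Recursive greedy growth; returns the root TreeNode."""
    if y.size == 0:
        raise ValueError("cannot grow a tree on an empty case set")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")

    def build(idx: np.ndarray, depth_left: int) -> TreeNode:
        yy = y[idx]
        node = TreeNode(n_pos=int(yy.sum()), n_neg=int(yy.size - yy.sum()))
        if depth_left == 0 or yy.size < min_split or node.n_pos == 0 or node.n_neg == 0:
            return node
        best = find_best_split(X[idx], yy)
        if best is None:
            return node
        f, _ = best
        mask = X[idx, f] == 1
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return node
        node.feature = f
        node.yes = build(idx[mask], depth_left - 1)
        node.no = build(idx[~mask], depth_left - 1)
        return node

    return build(np.arange(y.size), max_depth)


@dataclass
class DecisionTree:
    """A trained CART predictor over a fixed sequence window."""

    root: TreeNode
    max_depth: int
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    alphabet: str = ALPHABET

    def depth(self) -> int:
        return self.root.depth()

    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def predict_one(self, seq: str) -> str:
        """Deterministic root-to-leaf traversal on one sequence."""
        bad = set(seq) - STANDARD_RESIDUES - {"X", "-"}
        if bad:
            raise DataError(f"illegal residue(s) {sorted(bad)} in {seq!r}")
        window = extract_window(seq, self.window_spec)
        node = self.root
        while not node.is_leaf:
            pos, rank = divmod(node.feature, N_RESIDUES)
            node = node.yes if window[pos] == self.alphabet[rank] else node.no
        return node.predicted_label

    def predict(self, seqs: Iterable[str]) -> list[str]:
        return [self.predict_one(s) for s in seqs]

    # -- portable text serialization ------------------------------------
    def to_dict(self) -> dict:
        def node_dict(nd: TreeNode) -> dict:
            d = {"n_pos": nd.n_pos, "n_neg": nd.n_neg}
            if nd.is_leaf:
                d["leaf"] = True
                d["label"] = nd.predicted_label
            else:
                d["feature"] = feature_name(nd.feature)
                d["yes"] = node_dict(nd.yes)
                d["no"] = node_dict(nd.no)
            return d

        return {
            "format": "ntacpred-tree",
            "version": 1,
            "window": {"k": self.window_spec.k, "start": self.window_spec.start},
            "max_depth": self.max_depth,
            "alphabet": self.alphabet,
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        if d.get("format") != "ntacpred-tree":
            raise DataError("not an ntacpred tree file")
        alphabet = d.get("alphabet", ALPHABET)

        def parse(nd: dict) -> TreeNode:
            node = TreeNode(n_pos=int(nd["n_pos"]), n_neg=int(nd["n_neg"]))
            if not nd.get("leaf"):
                pos_s, _, res = nd["feature"].partition(":")
                node.feature = (int(pos_s) - 1) * N_RESIDUES + alphabet.index(res)
                node.yes = parse(nd["yes"])
                node.no = parse(nd["no"])
            return node

        return cls(root=parse(d["root"]), max_depth=int(d["max_depth"]),
                   window_spec=WindowSpec(k=int(d["window"]["k"]), start=int(d["window"]["start"])),
                   alphabet=alphabet)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTree":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameter-search configuration for fitting a predictor."""

    depth_grid: tuple[int, ...] = tuple(range(2, 11))
    n_folds: int = 5
    selection_metric: str = "MCC"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.depth_grid or any(d < 1 for d in self.depth_grid):
            raise ValueError("depth_grid must be nonempty with all depths >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.selection_metric.upper() not in ("MCC", "ACC", "F1"):
            raise ValueError(f"unsupported selection metric {self.selection_metric!r}")


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per case: per-class seeded shuffle dealt round-robin."""
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def _metric_value(tp: int, tn: int, fp: int, fn: int, metric: str) -> float:
    from .evalstats import ConfusionCounts, compute_metrics

    v = getattr(compute_metrics(ConfusionCounts(tp, tn, fp, fn)), metric.lower())
    return np.nan if v is None else v


def cross_validate_depth(train: SequenceDataset, cfg: TrainConfig,
                         spec: WindowSpec) -> tuple[int, pd.DataFrame]:
    """Stratified seeded k-fold CV over the depth grid.

    Returns ``(best_depth, table)`` where the table has one row per depth
    with per-fold and mean values of the selection metric.  The best depth is
    the argmax of the mean; ties go to the smallest depth.
    """
    X, y = encode_dataset(train, spec)
    if y.size == 0 or y.sum() in (0, y.size):
        raise ValueError("cross-validation needs cases of both classes")
    folds = _stratified_folds(y, cfg.n_folds, cfg.seed)
    rows = []
    for depth in cfg.depth_grid:
        vals = []
        for k in range(cfg.n_folds):
            tr, te = folds != k, folds == k
            if y[tr].sum() in (0, y[tr].size) or te.sum() == 0:
                vals.append(np.nan)
                continue
            root = grow_tree_root(X[tr], y[tr], depth)
            pred = _predict_encoded(root, X[te])
            tp = int(((pred == 1) & (y[te] == 1)).sum())
            tn = int(((pred == 0) & (y[te] == 0)).sum())
            fp = int(((pred == 1) & (y[te] == 0)).sum())
            fn = int(((pred == 0) & (y[te] == 1)).sum())
            vals.append(_metric_value(tp, tn, fp, fn, cfg.selection_metric))
        rows.append([depth] + vals + [np.nanmean(vals)])
    cols = ["depth"] + [f"fold_{k}" for k in range(cfg.n_folds)] + ["mean"]
    table = pd.DataFrame(rows, columns=cols).set_index("depth")
    means = table["mean"].to_numpy()
    best_depth = int(table.index[int(np.argmax(means))])  # first max -> smallest depth
    return best_depth, table


def _predict_encoded(root: TreeNode, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0], dtype=np.int8)
    for i in range(X.shape[0]):
        node = root
        while not node.is_leaf:
            node = node.yes if X[i, node.feature] == 1 else node.no
        out[i] = 1 if node.predicted_label == POSITIVE else 0
    return out


def grow_tree(train: SequenceDataset, max_depth: int,
              spec: WindowSpec | None = None) -> DecisionTree:
    """Grow a tree of bounded depth on the full dataset (no CV)."""
    spec = spec or WindowSpec(k=train.window_length)
    X, y = encode_dataset(train, spec)
    root = grow_tree_root(X, y, max_depth)
    return DecisionTree(root=root, max_depth=max_depth, window_spec=spec)


def fit_predictor(train: SequenceDataset, cfg: TrainConfig | None = None,
                  spec: WindowSpec | None = None) -> DecisionTree:
    """CV-select the maximum depth, then grow the final tree on all cases."""
    cfg = cfg or TrainConfig()
    spec = spec or WindowSpec(k=train.window_length)
    best_depth, _ = cross_validate_depth(train, cfg, spec)
    return grow_tree(train, best_depth, spec)
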