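"""Interpretable gain-ratio decision trees (C4.5 lineage) for LVH calls.

Top-down induction on continuous features with binary threshold splits
(candidate thresholds are midpoints between consecutive distinct sorted
values), split selection by information gain ratio, error-based pessimistic
pruning at confidence factor 0.25, and optional winnowing (dropping features
whose univariate gain ratio is zero before induction).

Asymmetric misclassification costs enter as instance weights: each non-LVH
instance carries weight ``cost_fp`` (the cost of a false positive) in the
split statistics, the pruning error estimates and the Laplace-smoothed leaf
probabilities.  The decision threshold itself stays fixed at probability
0.5, so raising ``cost_fp`` shifts leaf probabilities down and trades
sensitivity for specificity without moving the threshold.

Thresholds are stored in original feature units: when a model is trained on
standardized data, the scaling parameters invert each split threshold at
build time (midpoints map exactly under affine transforms, so the tree is
identical either way).  Prediction therefore consumes original-unit rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import beta

CONFIDENCE_FACTOR = 0.25
_EPS = 1e-12


@dataclass
class TrainConfig:
    """Induction hyperparameters; the 0.5 probability threshold is fixed."""

    min_cases: int = 2
    winnow: bool = False
    cost_fp: float = 1.0
    threshold: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be a positive integer")
        if self.cost_fp < 1.0:
            raise ValueError("cost_fp must be >= 1")
        if self.threshold != 0.5:
            raise ValueError("the decision threshold is fixed at 0.5")


@dataclass
class Node:
    """A split node (feature, threshold, children) or a leaf (counts)."""

    feature: str | None = None
    threshold: float | None = None          # original units; left: value <= t
    left: "Node | None" = None
    right: "Node | None" = None
    n0: float = 0.0                          # unweighted class counts
    n1: float = 0.0
    w0: float = 0.0                          # cost-weighted counts
    w1: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def probability(self) -> float:
        """Laplace-smoothed LVH probability from the weighted counts."""
        return (self.w1 + 1.0) / (self.w0 + self.w1 + 2.0)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": True, "n0": self.n0, "n1": self.n1,
                    "w0": self.w0, "w1": self.w1,
                    "probability": self.probability}
        return {"leaf": False, "feature": self.feature,
                "threshold": self.threshold,
                "n0": self.n0, "n1": self.n1, "w0": self.w0, "w1": self.w1,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "Node":
        node = cls(n0=d["n0"], n1=d["n1"], w0=d["w0"], w1=d["w1"])
        if not d["leaf"]:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass
class TreeModel:
    """An induced tree plus its training metadata."""

    root: Node
    whitelist: tuple[str, ...]
    config: TrainConfig
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    training_confusion: dict[str, int] = field(default_factory=dict)

    # -- prediction --------------------------------------------------------
    def predict_proba(self, row: Mapping[str, float]) -> float:
        node = self.root
        while not node.is_leaf:
            v = row.get(node.feature, np.nan) if hasattr(row, "get") \
                else row[node.feature]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                # missing value: follow the majority (heavier) branch
                lw = node.left.w0 + node.left.w1
                rw = node.right.w0 + node.right.w1
                node = node.left if lw >= rw else node.right
            else:
                node = node.left if v <= node.threshold else node.right
        return node.probability

    def predict(self, row: Mapping[str, float]) -> tuple[float, int]:
        p = self.predict_proba(row)
        return p, int(p >= self.config.threshold)

    def predict_frame(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        cols = {f: df[f].to_numpy(dtype=float) if f in df.columns
                else np.full(len(df), np.nan) for f in self.whitelist}
        probs = np.empty(len(df))

        def route(node: Node, idx: np.ndarray) -> None:
            if idx.size == 0:
                return
            if node.is_leaf:
                probs[idx] = node.probability
                return
            v = cols.get(node.feature)
            if v is None:
                v = np.full(len(df), np.nan)
            vals = v[idx]
            nan = np.isnan(vals)
            lw = node.left.w0 + node.left.w1
            rw = node.right.w0 + node.right.w1
            go_left = np.where(nan, lw >= rw, vals <= node.threshold)
            route(node.left, idx[go_left])
            route(node.right, idx[~go_left])

        route(self.root, np.arange(len(df)))
        return probs, (probs >= self.config.threshold).astype(int)

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "whitelist": list(self.whitelist),
            "config": {"min_cases": self.config.min_cases,
                       "winnow": self.config.winnow,
                       "cost_fp": self.config.cost_fp,
                       "threshold": self.config.threshold,
                       "seed": self.config.seed},
            "scaling": {k: list(v) for k, v in self.scaling.items()},
            "training_confusion": self.training_confusion,
            "root": self.root.to_dict(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        return cls(root=Node.from_dict(d["root"]),
                   whitelist=tuple(d["whitelist"]),
                   config=TrainConfig(**d["config"]),
                   scaling={k: tuple(v) for k, v in d["scaling"].items()},
                   training_confusion=d["training_confusion"])


# ---------------------------------------------------------------------------
# Induction
# ---------------------------------------------------------------------------

def _entropy(w0: float, w1: float) -> float:
    n = w0 + w1
    if n <= 0 or w0 <= 0 or w1 <= 0:
        return 0.0
    p0, p1 = w0 / n, w1 / n
    return -(p0 * np.log2(p0) + p1 * np.log2(p1))


def _entropy_vec(w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
    n = w0 + w1
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(n > 0, w0 / np.where(n > 0, n, 1.0), 0.0)
        p1 = np.where(n > 0, w1 / np.where(n > 0, n, 1.0), 0.0)
        h = -(np.where(p0 > 0, p0 * np.log2(np.where(p0 > 0, p0, 1.0)), 0.0)
              + np.where(p1 > 0, p1 * np.log2(np.where(p1 > 0, p1, 1.0)), 0.0))
    return h


def _best_split(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                min_cases: int) -> tuple[float, float, float] | None:
    """Best threshold for one feature: (gain_ratio, gain, threshold).

    Scans midpoints between consecutive distinct sorted values; both sides
    must keep at least ``min_cases`` instances (unweighted).
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys, ws = x[order], y[order], w[order]
    n = xs.size
    w1_cum = np.cumsum(ws * ys)
    w_cum = np.cumsum(ws)
    w_tot, w1_tot = w_cum[-1], w1_cum[-1]
    base = _entropy(w_tot - w1_tot, w1_tot)

    # split after position i (left = [0..i]); candidates where value changes
    cut = np.nonzero(np.diff(xs) > 0)[0]
    cut = cut[(cut + 1 >= min_cases) & (n - cut - 1 >= min_cases)]
    if cut.size == 0:
        return None
    wl, wl1 = w_cum[cut], w1_cum[cut]
    wr, wr1 = w_tot - wl, w1_tot - wl1
    gain = base - (wl / w_tot) * _entropy_vec(wl - wl1, wl1) \
                - (wr / w_tot) * _entropy_vec(wr - wr1, wr1)
    split_info = _entropy_vec(wl, wr)
    ok = (gain > _EPS) & (split_info > _EPS)
    if not np.any(ok):
        return None
    ratio = np.where(ok, gain / np.where(split_info > 0, split_info, 1.0),
                     -np.inf)
    i_best = int(np.argmax(ratio))  # first max wins: deterministic tie-break
    i = cut[i_best]
    return (float(ratio[i_best]), float(gain[i_best]),
            float((xs[i] + xs[i + 1]) / 2.0))


def _grow(X: np.ndarray, y: np.ndarray, w: np.ndarray,
          features: list[str], cfg: TrainConfig) -> Node:
    """Recursive induction; ``X`` is an (n, F) array aligned with ``features``."""
    node = Node(n0=float(np.sum(y == 0)), n1=float(np.sum(y == 1)),
                w0=float(w[y == 0].sum()), w1=float(w[y == 1].sum()))
    if node.n0 == 0 or node.n1 == 0 or len(y) < 2 * cfg.min_cases:
        return node

    best = None
    for j, f in enumerate(features):  # tie-break: first feature in order wins
        res = _best_split(X[:, j], y, w, cfg.min_cases)
        if res is not None and (best is None or res[0] > best[1][0] + _EPS):
            best = (j, res)
    if best is None:
        return node

    j, (_, _, thr) = best
    mask = X[:, j] <= thr
    node.feature = features[j]
    node.threshold = float(thr)
    node.left = _grow(X[mask], y[mask], w[mask], features, cfg)
    node.right = _grow(X[~mask], y[~mask], w[~mask], features, cfg)
    return node


def _ucf_errors(e: float, n: float, cf: float = CONFIDENCE_FACTOR) -> float:
    """Pessimistic error count: n times the upper confidence limit of the
    binomial error rate (Clopper-Pearson upper bound at 1 - cf)."""
    if n <= 0:
        return 0.0
    if e >= n:
        return float(n)
    return float(n * beta.ppf(1.0 - cf, e + 1.0, n - e))


def _leaf_errors(node: Node) -> float:
    """Weighted training errors if this node were a leaf (majority by weight,
    ties resolved toward non-LVH, the action cost weighting favours)."""
    return min(node.w0, node.w1)


def _prune(node: Node) -> float:
    """Bottom-up error-based pruning; returns the pessimistic error estimate
    of the (possibly collapsed) subtree."""
    n = node.w0 + node.w1
    leaf_est = _ucf_errors(_leaf_errors(node), n)
    if node.is_leaf:
        return leaf_est
    subtree_est = _prune(node.left) + _prune(node.right)
    if leaf_est <= subtree_est + _EPS:
        node.feature = None
        node.threshold = None
        node.left = node.right = None
        return leaf_est
    return subtree_est


def _univariate_gain_ratio(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                           min_cases: int) -> float:
    res = _best_split(x, y, w, min_cases)
    return 0.0 if res is None else res[0]


def train_tree(X: pd.DataFrame, y, whitelist, cfg: TrainConfig | None = None,
               scaling: Mapping[str, tuple[float, float]] | None = None,
               prune: bool = True) -> TreeModel:
    """Induce a gain-ratio tree on the whitelisted columns of ``X``.

    ``scaling`` maps feature -> (mean, sd) of the standardization applied to
    ``X``; stored split thresholds are inverted back to original units, and
    prediction then expects original-unit rows.
    """
    cfg = cfg or TrainConfig()
    whitelist = [f for f in whitelist if f in X.columns]
    if not whitelist:
        raise ValueError("empty predictor whitelist")
    X = X[whitelist]
    if scaling:
        scaling = {f: scaling[f] for f in whitelist if f in scaling}
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    w = np.where(y == 0, cfg.cost_fp, 1.0)

    features = list(whitelist)
    if cfg.winnow:
        kept = [f for f in features
                if _univariate_gain_ratio(X[f].to_numpy(dtype=float), y, w,
                                          cfg.min_cases) > 0.0]
        if kept:
            features = kept

    root = _grow(X[features].to_numpy(dtype=float), y, w, features, cfg)
    if prune:
        _prune(root)

    if scaling:
        _rescale_thresholds(root, scaling)

    model = TreeModel(root=root, whitelist=tuple(whitelist), config=cfg,
                      scaling=dict(scaling or {}))

    # training confusion stored in metadata; prediction must be done in
    # original units if scaling was supplied
    X_orig = X.copy()
    if scaling:
        for f, (mu, sd) in scaling.items():
            if f in X_orig.columns:
                X_orig[f] = X_orig[f] * sd + mu
    probs, calls = model.predict_frame(X_orig)
    model.training_confusion = {
        "TP": int(np.sum((calls == 1) & (y == 1))),
        "FP": int(np.sum((calls == 1) & (y == 0))),
        "FN": int(np.sum((calls == 0) & (y == 1))),
        "TN": int(np.sum((calls == 0) & (y == 0))),
    }
    return model


def _rescale_thresholds(node: Node,
                        scaling: Mapping[str, tuple[float, float]]) -> None:
    if node.is_leaf:
        return
    if node.feature in scaling:
        mu, sd = scaling[node.feature]
        node.threshold = node.threshold * sd + mu
    _rescale_thresholds(node.left, scaling)
    _rescale_thresholds(node.right, scaling)


def render_rules(model: TreeModel, decimals: int = 3) -> str:
    """Human-readable rule rendering of a tree, thresholds in original units."""
    lines: list[str] = []

    def walk(node: Node, indent: int) -> None:
        pad = "  " * indent
        if node.is_leaf:
            lines.append(f"{pad}-> LVH p={node.probability:.3f} "
                         f"[{int(node.n1)} LVH / {int(node.n0)} non-LVH]")
            return
        lines.append(f"{pad}{node.feature} <= {node.threshold:.{decimals}f}:")
        walk(node.left, indent + 1)
        lines.append(f"{pad}{node.feature} >  {node.threshold:.{decimals}f}:")
        walk(node.right, indent + 1)

    walk(model.root, 0)
    return "\n".join(lines)
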