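"""Preprocessing, Lasso feature pruning and construction of the three
interpretable tree criteria (VCG-only, VCG+ECG, and a specificity-tuned
VCG+ECG variant).

The feature table is a pandas DataFrame with one row per patient, a binary
``lvh`` label column, an optional ``split`` column ({train, test}), and
column group tags ({VCG, ECG}) carried in ``df.attrs['groups']`` (persisted
as a ``# group:`` header line in CSV form).

Pipeline: 70/30 random split; per-column imputation (mean when |skewness| <=
1, median otherwise) and z-scoring fitted on the training rows; L1-penalized
logistic regression per signal family with the penalty chosen by 5-fold
cross-validated AUC; gain-ratio tree induction with hyperparameters (minCases,
winnowing, and for the specificity variant the false-positive cost) chosen by
grid search on training-set cross-validation.  Tree split thresholds are
reported in original units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import skew
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import PINNED_VCG, PINNED_VCG_ECG
from .trees import TrainConfig, TreeModel, train_tree

LABEL = "lvh"
SPLIT = "split"

#: hyperparameter grid (the knobs are named by the method; the ranges are
#: this package's choices)
MIN_CASES_GRID = (2, 5, 10, 20)
WINNOW_GRID = (False, True)
COST_FP_GRID = (1.5, 2.0, 3.0)

#: minimum cross-validated sensitivity the specificity-tuned variant must keep
SP_VARIANT_MIN_SENSITIVITY = 0.55

SKEWNESS_CUT = 1.0


@dataclass
class ScalingParams:
    """Imputation values and z-scoring parameters fitted on training rows."""

    fill: dict[str, float]
    mean: dict[str, float]
    sd: dict[str, float]
    dropped: tuple[str, ...] = ()

    def pairs(self) -> dict[str, tuple[float, float]]:
        return {f: (self.mean[f], self.sd[f]) for f in self.mean}

    def impute(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c, v in self.fill.items():
            if c in out.columns:
                out[c] = out[c].fillna(v)
        return out


# ---------------------------------------------------------------------------
# Feature-table plumbing
# ---------------------------------------------------------------------------

def feature_columns(df: pd.DataFrame, group: str | None = None) -> list[str]:
    groups = df.attrs.get("groups", {})
    cols = [c for c in df.columns if c not in (LABEL, SPLIT)]
    if group is None:
        return cols
    return [c for c in cols if groups.get(c) == group]


def validate_table(df: pd.DataFrame) -> None:
    if LABEL not in df.columns:
        raise ValueError("feature table must carry an 'lvh' label column")
    if df[LABEL].isna().any():
        raise ValueError("labels must be present for all rows")
    if not set(df[LABEL].unique()) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")


def assign_split(df: pd.DataFrame, train_frac: float = 0.7,
                 seed: int | None = None) -> pd.DataFrame:
    """Randomly allocate rows to train/test (unstratified, as the study did)."""
    rng = np.random.default_rng(seed)
    n = len(df)
    n_train = int(round(train_frac * n))
    idx = rng.permutation(n)
    split = np.array(["test"] * n, dtype=object)
    split[idx[:n_train]] = "train"
    out = df.copy()
    out.attrs = dict(df.attrs)
    out[SPLIT] = split
    return out


def write_feature_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with a leading ``# group:`` header line preserving the group tags."""
    groups = df.attrs.get("groups", {})
    buf = io.StringIO()
    tags = ",".join(groups.get(c, "") for c in df.columns)
    buf.write(f"# group: {tags}\n")
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_feature_csv(path: str | Path,
                     column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a feature CSV; ``column_map`` renames external column headers
    (e.g. a generically labelled export) onto this package's names."""
    text = Path(path).read_text().splitlines()
    group_line = None
    start = 0
    while start < len(text) and text[start].startswith("#"):
        if text[start].startswith("# group:"):
            group_line = text[start][len("# group:"):].strip()
        start += 1
    df = pd.read_csv(io.StringIO("\n".join(text[start:])))
    if column_map:
        df = df.rename(columns=column_map)
    if group_line is not None:
        tags = group_line.split(",")
        df.attrs["groups"] = {c: t for c, t in zip(df.columns, tags) if t}
    else:
        from .features import feature_groups
        df.attrs["groups"] = feature_groups(
            c for c in df.columns if c not in (LABEL, SPLIT))
    validate_table(df)
    return df


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(df: pd.DataFrame,
               train_mask: np.ndarray | None = None
               ) -> tuple[pd.DataFrame, ScalingParams]:
    """Impute and z-score all feature columns; fit on the training rows.

    Imputation is the training mean for roughly symmetric columns
    (|skewness| <= 1) and the training median otherwise.  Columns with zero
    training variance are dropped with a warning.  Returns the transformed
    table and the parameters needed to invert thresholds to original units.
    """
    import warnings

    validate_table(df)
    if train_mask is None:
        train_mask = (df[SPLIT] == "train").to_numpy() if SPLIT in df.columns \
            else np.ones(len(df), dtype=bool)
    out = df.copy()
    out.attrs = dict(df.attrs)
    fill: dict[str, float] = {}
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    dropped: list[str] = []
    for c in feature_columns(df):
        col = df[c].astype(float)
        train_vals = col[train_mask].dropna()
        if len(train_vals) < 2:
            raise ValueError(f"column {c}: fewer than 2 non-missing "
                             f"training values")
        if float(train_vals.std(ddof=0)) == 0.0 and not col.isna().any():
            warnings.warn(f"column {c} has zero training variance; excluded")
            dropped.append(c)
            out = out.drop(columns=c)
            continue
        sk = skew(train_vals) if len(train_vals) > 2 else 0.0
        fill[c] = float(train_vals.mean() if abs(sk) <= SKEWNESS_CUT
                        else train_vals.median())
        filled = col.fillna(fill[c])
        mu = float(filled[train_mask].mean())
        sigma = float(filled[train_mask].std(ddof=0))
        if sigma == 0.0:
            warnings.warn(f"column {c} has zero training variance; excluded")
            dropped.append(c)
            out = out.drop(columns=c)
            del fill[c]
            continue
        mean[c], sd[c] = mu, sigma
        out[c] = (filled - mu) / sigma
    out.attrs["groups"] = {c: g for c, g in
                           df.attrs.get("groups", {}).items()
                           if c not in dropped}
    return out, ScalingParams(fill=fill, mean=mean, sd=sd,
                              dropped=tuple(dropped))


# ---------------------------------------------------------------------------
# Lasso pruning
# ---------------------------------------------------------------------------

def lasso_select(df: pd.DataFrame, group: str, seed: int | None = None,
                 k: int = 5,
                 c_grid: tuple[float, ...] = (0.003, 0.01, 0.03, 0.1, 0.3,
                                              1.0, 3.0)) -> list[str]:
    """L1-logistic feature pruning for one signal family (VCG or ECG).

    The inverse penalty C is chosen by k-fold cross-validated AUC on the
    training rows of the standardized table; features with nonzero
    coefficients at the refit optimum are returned.  Deterministic given the
    seed (it fixes the fold assignment).
    """
    cols = feature_columns(df, group)
    if not cols:
        raise ValueError(f"no columns tagged {group!r}")
    mask = (df[SPLIT] == "train").to_numpy() if SPLIT in df.columns \
        else np.ones(len(df), dtype=bool)
    X = df.loc[mask, cols].to_numpy(dtype=float)
    y = df.loc[mask, LABEL].to_numpy(dtype=int)
    if len(y) < 20:
        raise ValueError("need at least 20 training rows")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class")

    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(cv.split(X, y))
    best_c, best_auc = None, -np.inf
    for c in c_grid:
        aucs = []
        for tr, te in folds:
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c,
                                     max_iter=2000, random_state=0)
            clf.fit(X[tr], y[tr])
            scores = clf.decision_function(X[te])
            aucs.append(roc_auc_score(y[te], scores))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc + 1e-12:
            best_c, best_auc = c, mean_auc
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=best_c,
                             max_iter=2000, random_state=0)
    clf.fit(X, y)
    coef = clf.coef_.ravel()
    return [c for c, b in zip(cols, coef) if b != 0.0]


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def _cv_metrics(Xs: pd.DataFrame, y: np.ndarray, whitelist, cfg: TrainConfig,
                scaling: ScalingParams, k: int = 5,
                seed: int | None = None) -> dict[str, float]:
    """k-fold CV of a tree config on the (standardized) training table;
    returns pooled AUC, sensitivity and specificity."""
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    probs = np.empty(len(y))
    Xs = Xs[[f for f in whitelist if f in Xs.columns]]
    pairs = {f: p for f, p in scaling.pairs().items() if f in Xs.columns}
    X_orig = Xs.copy()
    for f, (mu, sd) in pairs.items():
        if f in X_orig.columns:
            X_orig[f] = X_orig[f] * sd + mu
    for tr, te in cv.split(Xs, y):
        model = train_tree(Xs.iloc[tr], y[tr], whitelist, cfg,
                           scaling=pairs)
        p, _ = model.predict_frame(X_orig.iloc[te])
        probs[te] = p
    calls = (probs >= 0.5).astype(int)
    tp = np.sum((calls == 1) & (y == 1))
    tn = np.sum((calls == 0) & (y == 0))
    return {
        "auc": float(roc_auc_score(y, probs)),
        "sensitivity": float(tp / max(1, np.sum(y == 1))),
        "specificity": float(tn / max(1, np.sum(y == 0))),
    }


def build_models(df: pd.DataFrame, seed: int | None = None,
                 pinned: bool = False,
                 grid_search: bool = True) -> dict[str, TreeModel]:
    """Train the three tree criteria on a split feature table.

    * ``vcg`` — Lasso-selected VCG features only;
    * ``vcg_ecg`` — union of the VCG and ECG Lasso selections;
    * ``vcg_ecg_sp`` — same predictors, false-positive cost chosen by grid
      search to maximize cross-validated specificity subject to sensitivity
      >= 0.55.

    ``pinned=True`` restricts the whitelists to the established 5/6/6
    predictor sets instead of running the Lasso (the table must contain
    those columns).  Deterministic given ``seed``.
    """
    validate_table(df)
    if SPLIT not in df.columns:
        df = assign_split(df, seed=seed)
    scaled, params = preprocess(df)
    train_mask = (scaled[SPLIT] == "train").to_numpy()
    Xs = scaled.loc[train_mask, feature_columns(scaled)]
    y = scaled.loc[train_mask, LABEL].to_numpy(dtype=int)

    if pinned:
        wl_vcg = [c for c in PINNED_VCG if c in Xs.columns]
        wl_comb = [c for c in PINNED_VCG_ECG if c in Xs.columns]
        if len(wl_vcg) < len(PINNED_VCG) or len(wl_comb) < len(PINNED_VCG_ECG):
            raise ValueError("pinned mode requires the established predictor "
                             "columns to be present")
    else:
        wl_vcg = lasso_select(scaled, "VCG", seed=seed)
        wl_ecg = lasso_select(scaled, "ECG", seed=seed)
        if not wl_vcg:
            raise ValueError("Lasso selected no VCG features")
        wl_comb = wl_vcg + [c for c in wl_ecg if c not in wl_vcg]

    def search(whitelist, cost_fp_grid=(1.0,), constraint=None):
        best = None
        grid_mc = MIN_CASES_GRID if grid_search else (MIN_CASES_GRID[0],)
        grid_wn = WINNOW_GRID if grid_search else (False,)
        for cost_fp in cost_fp_grid:
            for mc in grid_mc:
                for wn in grid_wn:
                    cfg = TrainConfig(min_cases=mc, winnow=wn,
                                      cost_fp=cost_fp, seed=seed)
                    m = _cv_metrics(Xs, y, whitelist, cfg, params, seed=seed)
                    if constraint is not None:
                        key = (m["sensitivity"] >= constraint,
                               m["specificity"], m["sensitivity"])
                    else:
                        key = (m["auc"],)
                    if best is None or key > best[0]:
                        best = (key, cfg)
        return best[1]

    cfg_vcg = search(wl_vcg)
    cfg_comb = search(wl_comb)
    cfg_sp = search(wl_comb, cost_fp_grid=COST_FP_GRID,
                    constraint=SP_VARIANT_MIN_SENSITIVITY)

    pairs = params.pairs()
    return {
        "vcg": train_tree(Xs, y, wl_vcg, cfg_vcg, scaling=pairs),
        "vcg_ecg": train_tree(Xs, y, wl_comb, cfg_comb, scaling=pairs),
        "vcg_ecg_sp": train_tree(Xs, y, wl_comb, cfg_sp, scaling=pairs),
    }


def predict_table(model: TreeModel, df: pd.DataFrame,
                  params: ScalingParams | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Predict every row of an original-unit feature table.

    Missing values are imputed with the stored training fills when ``params``
    is given; otherwise they route down majority branches.
    """
    X = df[[c for c in df.columns if c not in (LABEL, SPLIT)]]
    if params is not None:
        X = params.impute(X)
    return model.predict_frame(X)
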