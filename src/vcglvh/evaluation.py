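"""Performance statistics: confusion metrics with exact CIs, DeLong AUC
comparisons, McNemar tests with Bonferroni correction, k-fold cross
validation, per-stratum correct-classification rates, and the two-proportion
(arcsine) power computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import asin, ceil, sqrt

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_calls(cls, calls, truth) -> "ConfusionCounts":
        calls = np.asarray(calls, dtype=int)
        truth = np.asarray(truth, dtype=int)
        if calls.shape != truth.shape:
            raise ValueError("calls and truth must be paired")
        return cls(TP=int(np.sum((calls == 1) & (truth == 1))),
                   FP=int(np.sum((calls == 1) & (truth == 0))),
                   FN=int(np.sum((calls == 0) & (truth == 1))),
                   TN=int(np.sum((calls == 0) & (truth == 0))))


def counts_from_rates(sensitivity_pct: float, specificity_pct: float,
                      n_pos: int, n_neg: int) -> ConfusionCounts:
    """Invert printed sensitivity/specificity and class sizes to the integer
    confusion counts (nearest-integer reconstruction)."""
    tp = int(round(sensitivity_pct / 100.0 * n_pos))
    tn = int(round(specificity_pct / 100.0 * n_neg))
    return ConfusionCounts(TP=tp, FP=n_neg - tn, FN=n_pos - tp, TN=tn)


@dataclass
class EvalReport:
    """Confusion-derived metrics; proportions in [0, 1], NaN when undefined."""

    counts: ConfusionCounts
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    auc: float | None = None
    extras: dict = field(default_factory=dict)

    def as_percent_row(self) -> dict[str, float]:
        """Display-rounded row matching the reporting convention: percentages
        to one decimal (half away from zero), F1 to three decimals."""
        def pct(x: float) -> float:
            return float(np.floor(x * 1000 + 0.5) / 10) if np.isfinite(x) \
                else float("nan")
        return {
            "accuracy_pct": pct(self.accuracy),
            "accuracy_ci_low_pct": pct(self.accuracy_ci[0]),
            "accuracy_ci_high_pct": pct(self.accuracy_ci[1]),
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "f1": float(np.floor(self.f1 * 1000 + 0.5) / 1000)
            if np.isfinite(self.f1) else float("nan"),
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def confusion_metrics(c: ConfusionCounts,
                      ci_method: str = "clopper-pearson",
                      alpha: float = 0.05) -> EvalReport:
    """Standard confusion-matrix metrics with an exact (Clopper-Pearson)
    binomial CI on accuracy (Wilson available via ``ci_method``)."""
    correct = c.TP + c.TN
    n = c.total
    accuracy = correct / n
    if ci_method == "clopper-pearson":
        lo = stats.beta.ppf(alpha / 2, correct, n - correct + 1) \
            if correct > 0 else 0.0
        hi = stats.beta.ppf(1 - alpha / 2, correct + 1, n - correct) \
            if correct < n else 1.0
    elif ci_method == "wilson":
        from statsmodels.stats.proportion import proportion_confint
        lo, hi = proportion_confint(correct, n, alpha=alpha, method="wilson")
    else:
        raise ValueError(f"unknown CI method {ci_method!r}")
    return EvalReport(
        counts=c,
        accuracy=accuracy,
        accuracy_ci=(float(lo), float(hi)),
        sensitivity=_safe_div(c.TP, c.TP + c.FN),
        specificity=_safe_div(c.TN, c.TN + c.FP),
        ppv=_safe_div(c.TP, c.TP + c.FP),
        npv=_safe_div(c.TN, c.TN + c.FN),
        f1=_safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN),
    )


# ---------------------------------------------------------------------------
# DeLong correlated-ROC comparison
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _auc_and_placements(scores: np.ndarray, labels: np.ndarray
                        ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (Mann-Whitney, half credit for ties) and the per-case placement
    values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    ranks_all = _midrank(np.concatenate([pos, neg]))
    ranks_pos = _midrank(pos)
    ranks_neg = _midrank(neg)
    auc_val = (ranks_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (ranks_all[:m] - ranks_pos) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_neg) / m
    return float(auc_val), v10, v01


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided DeLong test comparing two correlated AUCs on paired scores."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores and labels must be paired")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    auc_a, v10_a, v01_a = _auc_and_placements(scores_a, labels)
    auc_b, v10_b, v01_b = _auc_and_placements(scores_b, labels)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    s = s10 / m + s01 / n
    var = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b,
                        var_a=float(s[0, 0]), var_b=float(s[1, 1]),
                        cov_ab=float(s[0, 1]), z=float(z), p=p)


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with half tie credit."""
    val, _, _ = _auc_and_placements(np.asarray(scores, float),
                                    np.asarray(labels, int))
    return val


# ---------------------------------------------------------------------------
# McNemar with Bonferroni
# ---------------------------------------------------------------------------

EXACT_DISCORDANT_CUT = 25


def mcnemar_bonferroni(calls_a, calls_b, truth, m_comparisons: int = 1
                       ) -> float:
    """Bonferroni-adjusted McNemar p comparing two paired classifiers.

    Discordance is about correctness: b counts cases only classifier A gets
    right, c cases only B gets right.  Exact binomial below 25 discordant
    pairs, continuity-corrected chi-square otherwise.  The adjusted p is
    truncated at 1.0 and zero discordance yields p = 1.0, not an error.
    """
    calls_a = np.asarray(calls_a, dtype=int)
    calls_b = np.asarray(calls_b, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if not (calls_a.shape == calls_b.shape == truth.shape):
        raise ValueError("call vectors must be paired")
    ok_a = calls_a == truth
    ok_b = calls_b == truth
    b = int(np.sum(ok_a & ~ok_b))
    c = int(np.sum(~ok_a & ok_b))
    if b + c == 0:
        return 1.0
    table = [[int(np.sum(ok_a & ok_b)), b], [c, int(np.sum(~ok_a & ~ok_b))]]
    exact = (b + c) < EXACT_DISCORDANT_CUT
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return min(1.0, float(res.pvalue) * m_comparisons)


# ---------------------------------------------------------------------------
# Cross validation
# ---------------------------------------------------------------------------

def crossvalidate(df: pd.DataFrame, builder, k: int = 10,
                  seed: int | None = None) -> dict:
    """Seeded k-fold CV on a feature table.

    ``builder(train_df, seed)`` returns an object exposing
    ``predict_frame(test_df) -> (probs, calls)`` (a tree model fits).
    Returns the pooled confusion report (with AUC over the pooled
    out-of-fold probabilities), per-fold metrics, and a mean/min/max summary
    per metric — both pooled and fold-level views.
    """
    from sklearn.model_selection import StratifiedKFold

    from .modeling import LABEL, SPLIT

    if k < 2:
        raise ValueError("k must be >= 2")
    y = df[LABEL].to_numpy(dtype=int)
    if k > min(np.sum(y == 0), np.sum(y == 1)):
        raise ValueError("k exceeds the minority class count")
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    feats = [c for c in df.columns if c not in (LABEL, SPLIT)]
    probs = np.empty(len(y))
    calls = np.empty(len(y), dtype=int)
    fold_rows = []
    for fold, (tr, te) in enumerate(cv.split(df[feats], y)):
        model = builder(df.iloc[tr], seed)
        p, cl = model.predict_frame(df.iloc[te][feats])
        probs[te], calls[te] = p, cl
        rep = confusion_metrics(ConfusionCounts.from_calls(cl, y[te]))
        fold_rows.append({"fold": fold, "n": len(te),
                          "accuracy": rep.accuracy,
                          "sensitivity": rep.sensitivity,
                          "specificity": rep.specificity})
    pooled = confusion_metrics(ConfusionCounts.from_calls(calls, y))
    pooled.auc = auc(probs, y)
    per_fold = pd.DataFrame(fold_rows)
    summary = {
        metric: {"mean": float(per_fold[metric].mean()),
                 "min": float(per_fold[metric].min()),
                 "max": float(per_fold[metric].max())}
        for metric in ("accuracy", "sensitivity", "specificity")
    }
    return {"pooled": pooled, "per_fold": per_fold, "summary": summary}


# ---------------------------------------------------------------------------
# Subgroup CCR and power
# ---------------------------------------------------------------------------

def ccr_table(calls, truth, strata) -> pd.DataFrame:
    """Correct-classification rate per stratum.

    In all-negative strata the CCR equals the in-stratum specificity; in
    all-positive strata, the in-stratum sensitivity.  Empty strata are
    omitted with a warning.
    """
    import warnings

    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth, dtype=int)
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        mask = strata == s
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"stratum {s!r} is empty; omitted")
            continue
        correct = int(np.sum(calls[mask] == truth[mask]))
        rows.append({"stratum": s, "n": n, "correct": correct,
                     "ccr_pct": 100.0 * correct / n})
    return pd.DataFrame(rows)


def power_two_proportions(p1: float, p2: float, alpha: float = 0.05,
                          power: float = 0.80) -> int:
    """Per-group n to detect p1 -> p2 via Cohen's arcsine effect size h:
    n = ceil((z_{1-alpha/2} + z_power)^2 / h^2)."""
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie in (0, 1)")
    if p1 == p2:
        raise ValueError("equal proportions need an infinite sample")
    h = 2 * asin(sqrt(p2)) - 2 * asin(sqrt(p1))
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return int(ceil((z_a + z_b) ** 2 / h ** 2))
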