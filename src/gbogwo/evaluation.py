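"""Confusion-matrix evaluation, filter-method baselines, and run comparison.

Confusion matrices here follow the rows-predicted / columns-true orientation
used in the activity-recognition reporting convention this package mirrors.
Under that orientation the convention's "precision" of a class is
diagonal / column-sum and its "sensitivity" is diagonal / row-sum — the
transpose of the usual textbook naming, so both namings are exposed side by
side and the caller picks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .selection import FeatureMask, repair_mask, split_feature_table

__all__ = [
    "ConfusionMatrix",
    "ClassRates",
    "build_confusion",
    "class_rates",
    "macro_summary",
    "ttest_filter",
    "relieff_filter",
    "wilcoxon_compare",
]


@dataclass
class ConfusionMatrix:
    """K x K counts with rows = predicted class, columns = true class."""

    counts: np.ndarray
    labels: list[str]
    orientation: str = "rows_predicted_cols_true"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.labels) != self.counts.shape[0]:
            raise ValueError("labels must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class ClassRates:
    """Per-class rates (percent) under both naming conventions.

    ``per_class`` columns: precision_paper (diag/column-sum),
    sensitivity_paper (diag/row-sum), specificity, precision_std
    (diag/row-sum, standard naming given rows = predicted),
    recall_std (diag/column-sum).  Undefined rates (zero denominator) are
    NaN, never 0.
    """

    per_class: pd.DataFrame
    accuracy: float
    macro_pr: float
    macro_sensitivity: float


def build_confusion(y_true, y_pred, labels: list[str]) -> ConfusionMatrix:
    """Count predictions into a rows-predicted / columns-true matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape[0] != y_pred.shape[0]:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.shape[0] == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    known = set(labels)
    unknown = (set(np.unique(y_true)) | set(np.unique(y_pred))) - known
    if unknown:
        raise ValueError(f"unknown labels {sorted(map(str, unknown))}")
    # sklearn counts rows=true/cols=predicted; transpose to this convention
    counts = _sk_confusion(y_true, y_pred, labels=labels).T
    return ConfusionMatrix(counts, list(labels))


def class_rates(cm: ConfusionMatrix) -> ClassRates:
    """Derive per-class and overall rates (in percent) from the counts."""
    c = cm.counts.astype(float)
    total = c.sum()
    diag = np.diag(c)
    row = c.sum(axis=1)   # predicted-class totals
    col = c.sum(axis=0)   # true-class totals
    fp = col - diag       # column off-diagonal
    tn = total - row - col + diag

    def _rate(num, den):
        out = np.full_like(num, np.nan, dtype=float)
        ok = den > 0
        out[ok] = 100.0 * num[ok] / den[ok]
        return out

    per_class = pd.DataFrame(
        {
            "precision_paper": _rate(diag, col),
            "sensitivity_paper": _rate(diag, row),
            "specificity": _rate(tn, fp + tn),
            "precision_std": _rate(diag, row),
            "recall_std": _rate(diag, col),
        },
        index=cm.labels,
    )
    acc = 100.0 * diag.sum() / total if total > 0 else np.nan
    pr = per_class["precision_paper"]
    sens = per_class["sensitivity_paper"]
    if pr.isna().any() or sens.isna().any():
        warnings.warn("undefined per-class rates excluded from macro averages")
    return ClassRates(per_class, float(acc), float(pr.mean(skipna=True)),
                      float(sens.mean(skipna=True)))


def macro_summary(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy %, macro precision %, macro sensitivity %)."""
    r = class_rates(cm)
    return r.accuracy, r.macro_pr, r.macro_sensitivity


# ---------------------------------------------------------------------------
# filter baselines
# ---------------------------------------------------------------------------


def ttest_filter(feature_table: pd.DataFrame, alpha_level: float = 0.05,
                 label_col: str | None = None
                 ) -> tuple[FeatureMask, pd.DataFrame]:
    """Per-feature one-vs-rest Welch t screening.

    Each feature is scored by the largest absolute one-vs-rest t statistic
    over the classes; the mask keeps features whose best p-value is below
    ``alpha_level``.  The ranking (score-descending) is returned alongside.
    """
    X, y = split_feature_table(feature_table, label_col)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("t-test filter needs at least 2 classes")
    Xv = X.to_numpy(dtype=float)
    scores = np.zeros(Xv.shape[1])
    pvals = np.ones(Xv.shape[1])
    for c in classes:
        in_c = (y == c).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(Xv[in_c], Xv[~in_c], equal_var=False)
        t = np.nan_to_num(np.abs(t), nan=0.0)  # zero-variance features score 0
        p = np.nan_to_num(p, nan=1.0)
        better = t > scores
        scores[better] = t[better]
        pvals[better] = p[better]
    ranking = pd.DataFrame({"feature": X.columns, "score": scores,
                            "p_value": pvals})
    ranking = ranking.sort_values("score", ascending=False,
                                  kind="stable").reset_index(drop=True)
    mask = FeatureMask((pvals < alpha_level).astype(np.int8))
    return mask, ranking


def relieff_filter(feature_table: pd.DataFrame, k_neighbors: int = 10,
                   weight_threshold: float = 0.0,
                   label_col: str | None = None
                   ) -> tuple[FeatureMask, np.ndarray]:
    """Multi-class ReliefF weights with a non-negativity selection rule.

    Features are min-max normalized; every instance is sampled once; for each
    instance the k nearest same-class hits and, per other class, the k
    nearest misses (Manhattan distance) adjust the weights — penalizing
    features that differ among hits and rewarding features that differ from
    misses, the miss terms weighted by class priors.  Ties in neighbor
    distance break deterministically by instance order.
    """
    X, y = split_feature_table(feature_table, label_col)
    yv = y.to_numpy()
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2:
        raise ValueError("ReliefF needs at least 2 classes")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if k_neighbors >= counts.min():
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the smallest "
            f"class size ({counts.min()})"
        )
    Xv = X.to_numpy(dtype=float)
    n, d = Xv.shape
    span = Xv.max(axis=0) - Xv.min(axis=0)
    span[span == 0] = 1.0  # constant features contribute zero diff anyway
    Xn = (Xv - Xv.min(axis=0)) / span
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    by_class = {c: np.flatnonzero(yv == c) for c in classes}

    weights = np.zeros(d)
    for i in range(n):
        diffs = np.abs(Xn - Xn[i])          # (n, d)
        dist = diffs.sum(axis=1)            # Manhattan
        ci = yv[i]
        hits = by_class[ci][by_class[ci] != i]
        hit_order = hits[np.argsort(dist[hits], kind="stable")][:k_neighbors]
        weights -= diffs[hit_order].sum(axis=0) / (n * k_neighbors)
        for c in classes:
            if c == ci:
                continue
            miss = by_class[c]
            miss_order = miss[np.argsort(dist[miss], kind="stable")][:k_neighbors]
            w_c = priors[c] / (1.0 - priors[ci])
            weights += w_c * diffs[miss_order].sum(axis=0) / (n * k_neighbors)
    mask = FeatureMask((weights >= weight_threshold).astype(np.int8))
    return mask, weights


def wilcoxon_compare(runs_a, runs_b, alpha_level: float = 0.05
                     ) -> tuple[int, float]:
    """Rank-sum comparison of two sets of per-run scores.

    Returns (H, p): H = 1 iff the two-sided rank-sum p-value (normal
    approximation) falls below ``alpha_level``.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("wilcoxon_compare needs at least 3 runs per side")
    if np.unique(np.concatenate([a, b])).size == 1:
        return 0, 1.0  # all values tied across both samples
    stat, p = stats.ranksums(a, b)
    return int(p < alpha_level), float(p)
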