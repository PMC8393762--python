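"""Wrapper feature selection: binarization, classifier-in-the-loop fitness,
and the selection loop driving a continuous optimizer.

A continuous position vector is cut at a threshold into a binary feature
mask; the mask's fitness is

    Fit = lambda * (1 - PR) + (1 - lambda) * |mask| / Dim

where PR is the macro-averaged precision of a classifier trained on the
masked feature table (internal stratified evaluation).  Lower is better:
the first term rewards precision, the second rewards sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import precision_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .optimizers import (
    SearchSettings,
    SearchResult,
    run_gbo,
    run_gbogwo,
    run_gwo,
)

__all__ = [
    "FeatureMask",
    "FitnessSpec",
    "SelectionResult",
    "FitnessEvaluator",
    "binarize",
    "repair_mask",
    "fitness",
    "select_features",
    "reduction_ratio",
    "split_feature_table",
]

_OPTIMIZERS = {"gbo": run_gbo, "gwo": run_gwo, "gbogwo": run_gbogwo}


@dataclass
class FeatureMask:
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    @property
    def dim(self) -> int:
        return int(self.bits.shape[0])


@dataclass
class FitnessSpec:
    """How a candidate mask is scored.

    The internal precision is estimated by stratified k-fold cross-validation
    on the supplied table by default; ``holdout`` keeps a stratified fraction
    aside, ``fixed_test`` scores on a user-provided test split.
    """

    lambda_: float = 0.99
    classifier: Literal["svm_multiclass", "random_forest"] = "svm_multiclass"
    eval_protocol: Literal["holdout", "kfold", "fixed_test"] = "kfold"
    k: int = 3
    holdout_fraction: float = 0.3
    rf_trees: int = 50

    def validate(self) -> None:
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda_ must lie in [0, 1], got {self.lambda_}")
        if self.rf_trees < 1:
            raise ValueError(f"rf_trees must be >= 1, got {self.rf_trees}")
        if self.classifier not in ("svm_multiclass", "random_forest"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.eval_protocol not in ("holdout", "kfold", "fixed_test"):
            raise ValueError(f"unknown eval protocol {self.eval_protocol!r}")


@dataclass
class SelectionResult:
    mask: FeatureMask
    selected_names: list[str]
    fitness: float
    precision_internal: float
    reduction_pct: float
    trace: list[float]
    seed: int
    optimizer: str
    n_evaluations: int = 0
    n_classifier_fits: int = 0

    def to_dict(self) -> dict:
        return {
            "optimizer": self.optimizer,
            "mask": [int(b) for b in self.mask.bits],
            "selected_names": list(self.selected_names),
            "n_selected": self.mask.n_selected,
            "fitness": float(self.fitness),
            "precision_internal": float(self.precision_internal),
            "reduction_pct": float(self.reduction_pct),
            "trace": [float(v) for v in self.trace],
            "seed": int(self.seed),
            "n_evaluations": int(self.n_evaluations),
            "n_classifier_fits": int(self.n_classifier_fits),
        }


def binarize(position: np.ndarray, thr: float) -> FeatureMask:
    """Bit j is 1 iff position_j is strictly above the threshold."""
    return FeatureMask((np.asarray(position) > thr).astype(np.int8))


def repair_mask(mask: FeatureMask, rng: np.random.Generator) -> FeatureMask:
    """Guarantee at least one selected feature.

    An all-zero mask leaves the classifier with no inputs, so one uniformly
    chosen bit is switched on; any non-empty mask passes through unchanged.
    """
    if mask.n_selected > 0:
        return mask
    bits = mask.bits.copy()
    bits[int(rng.integers(0, bits.shape[0]))] = 1
    return FeatureMask(bits)


def split_feature_table(table: pd.DataFrame, label_col: str | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into (X, y); the label is the last column by
    default."""
    if label_col is None:
        label_col = table.columns[-1]
    return table.drop(columns=[label_col]), table[label_col]


def _make_classifier(spec: FitnessSpec, seed: int):
    if spec.classifier == "random_forest":
        return RandomForestClassifier(n_estimators=spec.rf_trees,
                                      random_state=seed)
    return SVC(random_state=seed)


class FitnessEvaluator:
    """Memoized Eq-style fitness over one feature table.

    Each distinct mask triggers exactly one round of classifier fits; repeat
    evaluations are served from a cache keyed by the mask bit-string.
    """

    def __init__(self, table: pd.DataFrame, spec: FitnessSpec,
                 seed: int = 0, label_col: str | None = None,
                 test_table: pd.DataFrame | None = None):
        spec.validate()
        X, y = split_feature_table(table, label_col)
        if X.shape[1] == 0 or X.shape[0] == 0:
            raise ValueError("empty feature table")
        if y.nunique() < 2:
            raise ValueError("feature table must contain at least 2 classes")
        self.X = X.to_numpy(dtype=float)
        self.y = y.to_numpy()
        self.feature_names = list(X.columns)
        self.dim = X.shape[1]
        self.spec = spec
        self.seed = int(seed)
        self._cache: dict[bytes, tuple[float, float]] = {}
        self.n_classifier_fits = 0
        if spec.eval_protocol == "fixed_test":
            if test_table is None:
                raise ValueError("fixed_test protocol requires a test table")
            Xt, yt = split_feature_table(test_table, label_col)
            self.X_test = Xt.to_numpy(dtype=float)
            self.y_test = yt.to_numpy()
        counts = pd.Series(self.y).value_counts()
        if spec.eval_protocol == "kfold" and counts.min() < spec.k:
            raise ValueError(
                f"stratification error: smallest class has {counts.min()} "
                f"instances, fewer than k={spec.k} folds"
            )

    def _precision(self, cols: np.ndarray) -> float:
        spec = self.spec
        Xm = self.X[:, cols]
        if spec.eval_protocol == "kfold":
            skf = StratifiedKFold(n_splits=spec.k, shuffle=True,
                                  random_state=self.seed)
            preds = np.empty_like(self.y)
            for tr, te in skf.split(Xm, self.y):
                clf = _make_classifier(spec, self.seed)
                clf.fit(Xm[tr], self.y[tr])
                self.n_classifier_fits += 1
                preds[te] = clf.predict(Xm[te])
            return float(precision_score(self.y, preds, average="macro",
                                         zero_division=0))
        if spec.eval_protocol == "holdout":
            try:
                Xtr, Xte, ytr, yte = train_test_split(
                    Xm, self.y, test_size=spec.holdout_fraction,
                    random_state=self.seed, stratify=self.y)
            except ValueError as exc:
                raise ValueError(f"stratification error: {exc}") from exc
            clf = _make_classifier(spec, self.seed)
            clf.fit(Xtr, ytr)
            self.n_classifier_fits += 1
            return float(precision_score(yte, clf.predict(Xte),
                                         average="macro", zero_division=0))
        # fixed_test
        clf = _make_classifier(spec, self.seed)
        clf.fit(Xm, self.y)
        self.n_classifier_fits += 1
        preds = clf.predict(self.X_test[:, cols])
        return float(precision_score(self.y_test, preds, average="macro",
                                     zero_division=0))

    def __call__(self, mask: FeatureMask) -> tuple[float, float]:
        """Return (Fit, PR) for a repaired mask."""
        key = mask.bits.tobytes()
        if key not in self._cache:
            cols = np.flatnonzero(mask.bits)
            if cols.size == 0:
                raise ValueError("fitness requires a repaired (non-empty) mask")
            pr = self._precision(cols)
            lam = self.spec.lambda_
            fit = lam * (1.0 - pr) + (1.0 - lam) * (cols.size / self.dim)
            self._cache[key] = (fit, pr)
        return self._cache[key]


def fitness(mask: FeatureMask, feature_table: pd.DataFrame, spec: FitnessSpec,
            rng: np.random.Generator | int = 0,
            test_table: pd.DataFrame | None = None) -> tuple[float, float]:
    """One-shot (Fit, PR) for a mask; see :class:`FitnessEvaluator`."""
    seed = (int(rng.integers(0, 2 ** 31)) if isinstance(rng, np.random.Generator)
            else int(rng))
    return FitnessEvaluator(feature_table, spec, seed,
                            test_table=test_table)(mask)


def reduction_ratio(n_selected: float, dim: int) -> float:
    """Percentage of features removed, reported to one decimal.

    Fractional selected counts (means over runs) are accepted.
    """
    if dim <= 0:
        raise ValueError(f"dim must be positive, got {dim}")
    if not 0 <= n_selected <= dim:
        raise ValueError(f"n_selected={n_selected} outside [0, {dim}]")
    return round(100.0 * (dim - n_selected) / dim, 1)


def select_features(feature_table: pd.DataFrame, optimizer_name: str,
                    settings: SearchSettings, spec: FitnessSpec,
                    label_col: str | None = None,
                    test_table: pd.DataFrame | None = None
                    ) -> SelectionResult:
    """Run a continuous optimizer over mask space and report the best subset.

    The optimizer objective is fitness o repair o binarize over the table's
    feature columns; repairs and classifier fits draw from streams seeded
    from ``settings.seed`` so identical calls give identical results.
    """
    if optimizer_name not in _OPTIMIZERS:
        raise ValueError(
            f"unknown optimizer {optimizer_name!r}; expected one of "
            f"{sorted(_OPTIMIZERS)}"
        )
    evaluator = FitnessEvaluator(feature_table, spec, seed=settings.seed,
                                 label_col=label_col, test_table=test_table)
    repair_rng = np.random.default_rng((settings.seed, 1))

    def objective(position: np.ndarray) -> float:
        mask = repair_mask(binarize(position, settings.thr), repair_rng)
        fit, _ = evaluator(mask)
        return fit

    result: SearchResult = _OPTIMIZERS[optimizer_name](
        objective, evaluator.dim, settings)
    best_mask = repair_mask(binarize(result.best_position, settings.thr),
                            np.random.default_rng((settings.seed, 2)))
    fit, pr = evaluator(best_mask)
    names = [n for n, b in zip(evaluator.feature_names, best_mask.bits) if b]
    return SelectionResult(
        mask=best_mask,
        selected_names=names,
        fitness=fit,
        precision_internal=pr,
        reduction_pct=reduction_ratio(best_mask.n_selected, evaluator.dim),
        trace=result.fitness_trace,
        seed=settings.seed,
        optimizer=optimizer_name,
        n_evaluations=result.evaluation_count,
        n_classifier_fits=evaluator.n_classifier_fits,
    )
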