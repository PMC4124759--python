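"""The 12-cell method grid: three learners x {original, feature-selected}
x {binary, weighted}, evaluated per GO term by stratified 10-fold CV.

Learners: AdaBoost over depth-1 decision stumps (50 rounds), a soft-margin
RBF-kernel SVM, and a linear-kernel SVM solved by sequential minimal
optimization — the classical trio for binary profiles, all with C = 1 by
default and overridable through ``learner_params``.

Feature selection and the weighted transform are fitted inside each
training fold only: selected columns come from the training portion's
co-occurrence counts and correlations are estimated from training rows,
then applied unchanged to the held-out fold.  A deliberate
``leakage="full"`` mode fits both on the complete balanced set instead,
for sensitivity analysis of how much that contaminates the error estimate.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .annotation_io import AnnotationMatrix
from .balance import (
    BalancedDataset,
    InsufficientNegativesError,
    NoPositivesError,
    undersample,
)
from .feature_select import select_features
from .weighted_ipr import phi_correlation_matrix, weighted_transform

__all__ = [
    "MethodConfig",
    "CrossvalRow",
    "MethodGridReport",
    "FoldInfeasibleError",
    "full_grid",
    "crossval_error",
    "run_grid",
    "LEARNERS",
]

LEARNERS = ("adaboost", "svm", "smo")


class FoldInfeasibleError(ValueError):
    """Too few proteins per class to populate every CV fold."""


@dataclass(frozen=True)
class MethodConfig:
    """One cell of the method grid."""

    learner: str
    use_feature_selection: bool = False
    use_weighted: bool = False
    learner_params: tuple[tuple[str, object], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}, got {self.learner!r}")

    @property
    def label(self) -> str:
        fs = "W" if self.use_feature_selection else "W/O"
        data = "weighted" if self.use_weighted else "original"
        return f"{self.learner} | {fs} feature selection | {data} IPR"


def full_grid(seed: int = 0) -> list[MethodConfig]:
    """The 12 distinct grid cells (3 learners x 2 x 2), sharing one seed."""
    return [
        MethodConfig(learner=lr, use_feature_selection=fs, use_weighted=w, seed=seed)
        for lr in LEARNERS
        for w in (False, True)
        for fs in (False, True)
    ]


def _make_learner(config: MethodConfig):
    params = dict(config.learner_params)
    if config.learner == "adaboost":
        defaults = dict(n_estimators=50)
        defaults.update(params)
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            random_state=config.seed,
            **defaults,
        )
    if config.learner == "svm":
        defaults = dict(kernel="rbf", C=1.0)
    else:  # smo: libsvm's solver is sequential minimal optimization
        defaults = dict(kernel="linear", C=1.0)
    defaults.update(params)
    return SVC(random_state=config.seed, **defaults)


@dataclass
class CrossvalRow:
    """One (GO term, method) evaluation: mean CV error and per-fold detail."""

    go_term: str
    config: MethodConfig
    error_rate: float
    fold_errors: list[float]
    n_train: int
    n_features_used: int
    seed: int


def _fold_features(X_tr, y_tr, X_te, config, min_cooccur, X_all=None, y_all=None):
    """Resolve the feature pipeline for one fold; returns (train, test) arrays."""
    leak = X_all is not None
    if config.use_feature_selection:
        sel = select_features(X_all if leak else X_tr, y_all if leak else y_tr, min_cooccur)
        if sel.empty:
            # fall back to all non-zero columns, else keep everything
            base = X_all if leak else X_tr
            cols = np.flatnonzero(base.sum(axis=0) >= 1)
            if len(cols) == 0:
                cols = np.arange(X_tr.shape[1])
        else:
            cols = sel.indices
        X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        if leak:
            X_all = X_all[:, cols]
    if config.use_weighted:
        C = phi_correlation_matrix(X_all if leak else X_tr)
        X_tr = weighted_transform(X_tr, C).values
        X_te = weighted_transform(X_te, C).values
    return np.asarray(X_tr, dtype=float), np.asarray(X_te, dtype=float)


def crossval_error(
    dataset: BalancedDataset,
    config: MethodConfig,
    n_splits: int = 10,
    min_cooccur: int = 1,
    pooled: bool = False,
    leakage: str = "none",
) -> CrossvalRow:
    """Stratified k-fold CV misclassification rate for one grid cell.

    Parameters
    ----------
    pooled
        If True, the reported error is the pooled misclassification count
        over all held-out folds divided by n; default is the mean of the
        per-fold error rates.
    leakage
        ``"none"`` (default) fits feature selection and correlations on
        the training portion of each fold only; ``"full"`` fits them on
        the complete dataset, an intentionally contaminated estimate for
        sensitivity analysis.

    Raises
    ------
    FoldInfeasibleError
        If either class has fewer than ``n_splits`` members (some fold
        would lack that class); use fewer splits.
    """
    if leakage not in ("none", "full"):
        raise ValueError("leakage must be 'none' or 'full'")
    X, y = dataset.X, dataset.y
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if min(n_pos, n_neg) < n_splits:
        raise FoldInfeasibleError(
            f"{n_pos} positives / {n_neg} negatives cannot fill {n_splits} "
            f"stratified folds; reduce n_splits"
        )
    leak_args = (X, y) if leakage == "full" else (None, None)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
    fold_errors: list[float] = []
    n_wrong = 0
    n_features = []
    for train_idx, test_idx in skf.split(X, y):
        X_tr, X_te = _fold_features(
            X[train_idx], y[train_idx], X[test_idx], config, min_cooccur, *leak_args
        )
        learner = _make_learner(config)
        learner.fit(X_tr, y[train_idx])
        pred = learner.predict(X_te)
        wrong = int((pred != y[test_idx]).sum())
        n_wrong += wrong
        fold_errors.append(wrong / len(test_idx))
        n_features.append(X_tr.shape[1])
    error = n_wrong / len(y) if pooled else float(np.mean(fold_errors))
    return CrossvalRow(
        go_term=dataset.go_term,
        config=config,
        error_rate=error,
        fold_errors=fold_errors,
        n_train=len(y),
        n_features_used=int(round(float(np.mean(n_features)))),
        seed=config.seed,
    )


_REPORT_COLUMNS = [
    "go_term",
    "learner",
    "feature_selection",
    "weighted",
    "error_rate",
    "error_sd",
    "fold_errors",
    "n_train",
    "n_features",
    "n_resamples",
    "seed",
    "status",
]


@dataclass
class MethodGridReport:
    """Per-(GO term, method) error rates, one row per grid cell."""

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_REPORT_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def __len__(self) -> int:
        return len(self.frame)


def _term_seed(seed: int, go_term: str) -> int:
    # stable per-term sub-seed, independent of the term list ordering
    return (zlib.crc32(go_term.encode()) ^ (seed * 0x9E3779B1)) & 0x7FFFFFFF


def run_grid(
    ipr_matrix: AnnotationMatrix,
    go_matrix: AnnotationMatrix,
    go_terms: list[str],
    grid: list[MethodConfig] | None = None,
    seed: int = 0,
    n_splits: int = 10,
    min_cooccur: int = 1,
    n_resamples: int = 1,
    pooled: bool = False,
    leakage: str = "none",
) -> MethodGridReport:
    """Evaluate every (GO term, method) pair of the grid.

    Each term's balanced dataset is drawn with a stable sub-seed of
    ``seed``; with ``n_resamples > 1`` the undersample-and-evaluate step
    is repeated and the mean and sd across resamples reported.  Per-term
    failures (no positives, too few negatives, infeasible folds) become
    skipped rows carrying the reason; the grid never aborts.
    """
    if grid is None:
        grid = full_grid(seed)
    rows = []
    for term in go_terms:
        labels = go_matrix.column(term)
        base_seed = _term_seed(seed, term)
        for config in grid:
            config = replace(config, seed=base_seed)
            try:
                errors, first = [], None
                for r in range(n_resamples):
                    ds = undersample(ipr_matrix, labels, seed=base_seed + r, go_term=term)
                    row = crossval_error(
                        ds, config, n_splits=n_splits, min_cooccur=min_cooccur,
                        pooled=pooled, leakage=leakage,
                    )
                    errors.append(row.error_rate)
                    first = first or row
                rows.append({
                    "go_term": term,
                    "learner": config.learner,
                    "feature_selection": config.use_feature_selection,
                    "weighted": config.use_weighted,
                    "error_rate": float(np.mean(errors)),
                    "error_sd": float(np.std(errors, ddof=1)) if n_resamples > 1 else np.nan,
                    "fold_errors": ";".join(f"{e:.6f}" for e in first.fold_errors),
                    "n_train": first.n_train,
                    "n_features": first.n_features_used,
                    "n_resamples": n_resamples,
                    "seed": base_seed,
                    "status": "ok",
                })
            except (NoPositivesError, InsufficientNegativesError, FoldInfeasibleError) as exc:
                rows.append({
                    "go_term": term,
                    "learner": config.learner,
                    "feature_selection": config.use_feature_selection,
                    "weighted": config.use_weighted,
                    "error_rate": np.nan,
                    "error_sd": np.nan,
                    "fold_errors": "",
                    "n_train": 0,
                    "n_features": 0,
                    "n_resamples": n_resamples,
                    "seed": base_seed,
                    "status": f"skipped: {exc}",
                })
    return MethodGridReport(frame=pd.DataFrame(rows, columns=_REPORT_COLUMNS))
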