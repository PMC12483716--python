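"""Random-forest classifier contract used throughout the package.

Bagged Gini-split trees with per-split feature subsampling, grown to purity
(minimum node size 1 by default), with out-of-bag class-probability
predictions, impurity-based feature importances, and repeated stratified
k-fold tuning of (mtry, n_trees).  The ensemble itself is scikit-learn's
``RandomForestClassifier``; nominal features are integer-coded, with splits on
the ordered codes (equivalent in expectation to category-subset splits for
binary outcomes with the <=3-category predictors used here).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import ParameterError, UndefinedResultError


@dataclass(frozen=True)
class ForestParams:
    mtry: int = 2
    n_trees: int = 1000
    min_node_size: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.mtry < 1 or self.n_trees < 1 or self.min_node_size < 1:
            raise ParameterError("mtry, n_trees and min_node_size must be >= 1")


# the tuning grid used by the reference analyses
DEFAULT_MTRY_GRID = (2, 3, 4, 5)
DEFAULT_NTREE_GRID = (1000, 1500, 2000, 2500, 3000)


@dataclass
class ForestFit:
    params: ForestParams
    feature_names: list
    model: object = None
    inbag_prob: np.ndarray = None
    oob_prob: np.ndarray = None
    oob_valid: np.ndarray = None
    oob_error: float = float("nan")
    gini_importance: np.ndarray = None
    degenerate_class: int | None = None
    labels: np.ndarray = None

    def predict_prob(self, X) -> np.ndarray:
        """Probability of class 1 for new rows (DataFrame columns are matched
        to the training feature names when present)."""
        if isinstance(X, pd.DataFrame) and set(self.feature_names) <= set(X.columns):
            X = X[self.feature_names]
        X = np.asarray(X, dtype=float)
        if self.degenerate_class is not None:
            return np.full(len(X), float(self.degenerate_class))
        proba = self.model.predict_proba(X)
        return proba[:, list(self.model.classes_).index(1)]

    def train_prob(self, prefer_oob: bool = True) -> np.ndarray:
        """Training-row probabilities: OOB where defined, in-bag otherwise."""
        if self.degenerate_class is not None:
            return np.full(len(self.inbag_prob), float(self.degenerate_class))
        if not prefer_oob:
            return self.inbag_prob
        return np.where(self.oob_valid, self.oob_prob, self.inbag_prob)


def fit_forest(X, y, params: ForestParams, allow_degenerate: bool = False,
               feature_names=None) -> ForestFit:
    """Fit a seeded random forest and compute OOB probabilities.

    With ``allow_degenerate`` a single-class label vector yields a constant
    predictor (probability equal to the class) instead of an error; this arises
    when the hybrid algorithm's pseudo-response collapses to one class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, k = X.shape
    if n < 2:
        raise ParameterError("need at least 2 rows")
    if params.mtry > k:
        raise ParameterError(f"mtry={params.mtry} exceeds {k} features")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(k)]

    classes = np.unique(y)
    if len(classes) == 1:
        if not allow_degenerate:
            raise ParameterError("labels are single-class; pass allow_degenerate")
        c = int(classes[0])
        const = np.full(n, float(c))
        return ForestFit(
            params=params, feature_names=names, inbag_prob=const,
            oob_prob=const, oob_valid=np.ones(n, bool), oob_error=0.0,
            gini_importance=np.zeros(k), degenerate_class=c, labels=y,
        )

    import warnings

    model = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.mtry,
        min_samples_leaf=params.min_node_size,
        criterion="gini",
        bootstrap=True,
        oob_score=True,
        random_state=params.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # rows in-bag in every tree are reported as missing OOB values below
        warnings.filterwarnings("ignore", message=".*out-of-bag.*")
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        model.fit(X, y)
    col1 = list(model.classes_).index(1)
    inbag = model.predict_proba(X)[:, col1]

    # average of per-tree class-1 proportions over each row's OOB trees;
    # rows in-bag in every tree have an all-zero decision row
    decision = model.oob_decision_function_
    valid = decision.sum(axis=1) > 0.5
    oob = np.where(valid, decision[:, col1], np.nan)

    fit = ForestFit(
        params=params,
        feature_names=names,
        model=model,
        inbag_prob=inbag,
        oob_prob=oob,
        oob_valid=valid,
        gini_importance=model.feature_importances_.copy(),
        labels=y,
    )
    fit.oob_error = oob_brier(fit, y)
    return fit


def oob_brier(fit: ForestFit, labels) -> float:
    """Mean squared error of the OOB probabilities against ``labels``."""
    labels = np.asarray(labels, dtype=float)
    if fit.oob_prob is None or not np.any(fit.oob_valid):
        raise UndefinedResultError("no rows have out-of-bag predictions")
    m = fit.oob_valid
    return float(np.mean((labels[m] - fit.oob_prob[m]) ** 2))


def tune_forest(
    X,
    y,
    mtry_grid=DEFAULT_MTRY_GRID,
    ntree_grid=DEFAULT_NTREE_GRID,
    k: int = 10,
    repeats: int = 5,
    seed: int = 0,
    min_node_size: int = 1,
):
    """Grid search over (mtry, n_trees) by repeated stratified k-fold CV.

    The resampling metric is classification accuracy at the 0.5 probability
    threshold, averaged over the k * repeats folds; ties are broken toward the
    smaller mtry, then the smaller number of trees.  Returns the winning
    :class:`ForestParams` and the per-fold resample table.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not len(mtry_grid) or not len(ntree_grid):
        raise ParameterError("tuning grid is empty")
    if k > len(y):
        raise ParameterError("k exceeds the number of rows")
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X, y))
    records = []
    means = {}
    for mtry, nt in product(sorted(mtry_grid), sorted(ntree_grid)):
        if mtry > X.shape[1]:
            raise ParameterError(f"mtry={mtry} exceeds {X.shape[1]} features")
        accs = []
        for fold_id, (tr, te) in enumerate(splits):
            model = RandomForestClassifier(
                n_estimators=nt, max_features=mtry,
                min_samples_leaf=min_node_size, criterion="gini",
                random_state=seed + fold_id, n_jobs=1,
            )
            model.fit(X[tr], y[tr])
            col1 = list(model.classes_).index(1)
            prob = model.predict_proba(X[te])[:, col1]
            acc = float(np.mean((prob > 0.5).astype(int) == y[te]))
            accs.append(acc)
            records.append({"mtry": mtry, "n_trees": nt, "resample": fold_id,
                            "accuracy": acc})
        means[(mtry, nt)] = float(np.mean(accs))
    best = max(means, key=lambda cell: (means[cell], -cell[0], -cell[1]))
    table = pd.DataFrame.from_records(records)
    return ForestParams(mtry=best[0], n_trees=best[1],
                        min_node_size=min_node_size, seed=seed), table
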