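"""Correlative suitability modelling with a random forest.

Presence vs pseudo-absence classification on bioclim features, with the
hybrid evaluation protocol used for the pest: k-fold cross-validation where,
inside each fold, only a random 70% of the non-held-out data trains the
model. Variable importance is permutation importance on AUC, normalised to
percentage contributions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array

from .bioclim import BIOCLIM_NAMES, BioclimStack
from .grid import Raster
from .metrics import EvaluationReport, auc, evaluate_at_max_tss


class RandomForestSuitability(BaseEstimator, ClassifierMixin):
    """Probability-emitting random-forest presence/absence classifier.

    A thin scikit-learn estimator around :class:`RandomForestClassifier`
    (500 trees by default, probability = fraction of votes), with the
    single-class guard and deterministic seeding the pipeline relies on.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: str | int | float = "sqrt",
        min_samples_leaf: int = 1,
        random_state: int | None = 0,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        self.classes_ = classes
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _check_fitted_X(self, X):
        if not hasattr(self, "forest_"):
            raise ValueError("model is not fitted")
        if isinstance(X, pd.DataFrame) and hasattr(self, "feature_names_in_"):
            if list(X.columns) != list(self.feature_names_in_):
                raise ValueError("feature names do not match the fitted model")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count does not match the fitted model")
        return X

    def predict_proba(self, X):
        return self.forest_.predict_proba(self._check_fitted_X(X))

    def predict_suitability(self, X) -> np.ndarray:
        """Probability of the positive (presence) class."""
        return self.predict_proba(X)[:, -1]

    def predict(self, X):
        return self.forest_.predict(self._check_fitted_X(X))


def fit_suitability_model(
    features: pd.DataFrame, labels, seed: int = 0, **forest_kwargs
) -> RandomForestSuitability:
    """Fit the default forest on a feature table; thin wrapper."""
    model = RandomForestSuitability(random_state=seed, **forest_kwargs)
    return model.fit(features, np.asarray(labels))


def cross_validate(
    features: pd.DataFrame,
    labels,
    model: RandomForestSuitability | None = None,
    k: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> EvaluationReport:
    """K-fold evaluation with a 70% training subsample inside each fold.

    Each fold is held out in turn; of the remaining data a stratified random
    ``train_fraction`` trains a fresh model, which is scored on the held-out
    fold. Metrics are reported per fold and pooled over all held-out
    predictions. Folds whose test part ends up single-class are flagged and
    excluded from pooling.
    """
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    y = np.asarray(labels).astype(int)
    if model is None:
        model = RandomForestSuitability(random_state=seed)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)

    rows = []
    excluded = []
    pooled_scores = np.full(y.size, np.nan)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(X, y)):
        y_test = y[test_idx]
        if np.unique(y_test).size < 2:
            warnings.warn(f"fold {fold} has a single class in its test part; excluded")
            excluded.append(fold)
            continue
        # the hybrid protocol: subsample the training portion
        n_sub = max(2, int(round(train_fraction * train_idx.size)))
        sub = rng.choice(train_idx, size=n_sub, replace=False)
        if np.unique(y[sub]).size < 2:  # re-draw once keeping both classes
            pos = train_idx[y[train_idx] == 1]
            neg = train_idx[y[train_idx] == 0]
            sub = np.concatenate([sub, pos[:1], neg[:1]])
        fold_model = clone(model)
        fold_model.random_state = seed + fold
        fold_model.fit(X[sub], y[sub])
        scores = fold_model.predict_suitability(X[test_idx])
        pooled_scores[test_idx] = scores
        m = evaluate_at_max_tss(scores, y_test)
        rows.append(
            {"fold": fold, "n_test": test_idx.size, "auc": m["auc"],
             "kappa": m["kappa"], "tss": m["tss"], "threshold": m["threshold"]}
        )
    if not rows:
        raise ValueError("no usable folds: every fold was single-class")
    ok = ~np.isnan(pooled_scores)
    pooled = evaluate_at_max_tss(pooled_scores[ok], y[ok])
    pooled.pop("confusion")
    return EvaluationReport(
        fold_metrics=pd.DataFrame(rows), pooled=pooled, excluded_folds=excluded
    )


def variable_importance(
    model: RandomForestSuitability,
    features: pd.DataFrame,
    labels,
    n_permutations: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance as percentage contributions (sums to 100).

    Importance of a feature is the mean drop in AUC when that feature's
    column is shuffled; negative drops are floored at zero before
    normalising. If no feature matters, uniform shares are returned with a
    warning.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels).astype(int)
    base = auc(model.predict_suitability(X), y)
    rng = np.random.default_rng(seed)
    drops = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops[j] += base - auc(model.predict_suitability(Xp), y)
    drops = np.maximum(drops / n_permutations, 0.0)
    total = drops.sum()
    if total <= 0:
        warnings.warn("no feature shows positive importance; returning uniform shares")
        shares = np.full(X.shape[1], 100.0 / X.shape[1])
    else:
        shares = 100.0 * drops / total
    return pd.Series(shares, index=list(features.columns), name="contribution_pct")


def predict_suitability_raster(
    model: RandomForestSuitability, stack: BioclimStack, chunk_cells: int = 500_000
) -> Raster:
    """Per-cell presence probability over a bioclim stack; geometry preserved."""
    if hasattr(model, "feature_names_in_") and list(model.feature_names_in_) != list(BIOCLIM_NAMES):
        raise ValueError("model was not fitted on the bioclim feature set")
    g = stack.geometry
    flat = stack.values.reshape(len(BIOCLIM_NAMES), g.n_cells).T
    out = np.empty(g.n_cells)
    for start in range(0, g.n_cells, chunk_cells):
        sl = slice(start, min(start + chunk_cells, g.n_cells))
        out[sl] = model.predict_suitability(flat[sl])
    return Raster(
        out.reshape(g.shape), g,
        meta={"layer": "suitability", "scenario": stack.meta.get("scenario", "unknown")},
    )
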