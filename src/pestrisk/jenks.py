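"""Exact Fisher-Jenks natural-breaks classification.

Finds the partition of sorted 1-D values into k contiguous classes that
minimises the total within-class sum of squared deviations, by dynamic
programming (exact, O(k n^2)). Exposed both as functions and as a
scikit-learn style discretiser.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

SUITABILITY_LABELS = ("unsuitable", "very_low", "low", "medium", "high")


def _class_sse_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) SSE of any contiguous slice of sorted x."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    return s1, s2


def _sse(s1: np.ndarray, s2: np.ndarray, i: np.ndarray, j: int) -> np.ndarray:
    """SSE of x[i..j] inclusive (vectorised over i)."""
    n = j - i + 1
    tot = s1[j + 1] - s1[i]
    return (s2[j + 1] - s2[i]) - tot * tot / n


def jenks_breaks(values, n_classes: int = 5) -> np.ndarray:
    """Optimal class bounds for 1-D values.

    Returns ``n_classes + 1`` ascending bounds: the minimum, the k-1 interior
    breaks (each the *upper* value of its class), and the maximum. Requires at
    least ``n_classes`` distinct finite values. Ties in the dynamic program
    resolve to the smallest left index, which makes the partition of sorted
    values deterministic and scale-equivariant.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if np.unique(x).size < n_classes:
        raise ValueError(
            f"need at least {n_classes} distinct finite values, got {np.unique(x).size}"
        )
    x = np.sort(x)
    n = x.size
    s1, s2 = _class_sse_matrix(x)
    idx = np.arange(n)

    # cost[j] = minimal SSE of x[0..j] split into m classes
    cost = np.array([_sse(s1, s2, np.array([0]), j)[0] for j in range(n)])
    # backptr[m-1][j]: start index of the last class in the optimal m-split of x[0..j]
    backptr = np.zeros((n_classes, n), dtype=int)
    for m in range(1, n_classes):
        new_cost = np.full(n, np.inf)
        for j in range(m, n):
            starts = idx[m : j + 1]  # last class = x[start..j]
            cand = cost[starts - 1] + _sse(s1, s2, starts, j)
            best = int(np.argmin(cand))  # first minimum -> smallest start
            new_cost[j] = cand[best]
            backptr[m, j] = starts[best]
        cost = new_cost

    bounds = np.empty(n_classes + 1)
    bounds[0] = x[0]
    bounds[-1] = x[-1]
    j = n - 1
    for m in range(n_classes - 1, 0, -1):
        start = backptr[m, j]
        bounds[m] = x[start - 1]  # upper value of the previous class
        j = start - 1
    return bounds


def total_within_class_sse(values, bounds: np.ndarray) -> float:
    """Within-class SSE of values under given class bounds."""
    x = np.asarray(values, dtype=float).ravel()
    x = np.sort(x[np.isfinite(x)])
    classes = assign_classes(x, bounds)
    return float(
        sum(np.sum((x[classes == c] - x[classes == c].mean()) ** 2) for c in np.unique(classes))
    )


def assign_classes(values, bounds: np.ndarray) -> np.ndarray:
    """Class indices 0..k-1; a value equal to a break goes to the lower class."""
    x = np.asarray(values, dtype=float)
    interior = np.asarray(bounds, dtype=float)[1:-1]
    out = np.searchsorted(interior, x, side="left")
    return np.where(np.isnan(x), -1, out)


class JenksBreaks(BaseEstimator, TransformerMixin):
    """Natural-breaks discretiser with a scikit-learn interface.

    ``fit`` computes ``breaks_`` (k+1 bounds) from the finite values of X; for
    arrays larger than ``max_fit_values`` a deterministic quantile subsample
    is used (the exact program is quadratic in n). ``transform`` assigns class
    indices 0..k-1 in ascending value order; NaN maps to -1.
    """

    def __init__(self, n_classes: int = 5, max_fit_values: int = 2000):
        self.n_classes = n_classes
        self.max_fit_values = max_fit_values

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size > self.max_fit_values:
            q = np.linspace(0.0, 1.0, self.max_fit_values)
            x = np.quantile(x, q)
        self.breaks_ = jenks_breaks(x, self.n_classes)
        return self

    def transform(self, X):
        if not hasattr(self, "breaks_"):
            raise ValueError("JenksBreaks instance is not fitted yet")
        return assign_classes(np.asarray(X, dtype=float), self.breaks_)

    def class_labels(self) -> tuple:
        if self.n_classes == len(SUITABILITY_LABELS):
            return SUITABILITY_LABELS
        return tuple(f"class_{i}" for i in range(self.n_classes))


def jenks_classify(values, n_classes: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Breaks plus class assignment for an array (NaN-aware); thin wrapper."""
    model = JenksBreaks(n_classes=n_classes).fit(values)
    return model.breaks_, model.transform(values)
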