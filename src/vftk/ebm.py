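"""Explainable additive boosting classifier.

A generalized additive model for binary classification,

    logit(P[y = 1]) = beta_0 + sum_i f_i(x_i),

where each shape function ``f_i`` is learned by cyclic gradient
boosting: every pass visits the features round-robin and fits one
shallow single-feature regression tree (at most ``max_leaves`` leaves,
Newton leaf values) to the current logistic gradient, scaled by the
learning rate and accumulated into that feature's shape.  Features are
pre-binned on training quantiles, so a fitted shape function is a
piecewise-constant curve over bin edges with open-ended extreme bins.
No interaction terms are used, keeping every prediction an exact sum of
per-feature contributions.

Shapes are centered after training (their training-set mean is folded
into the intercept), so contributions are deviations from the average
subject.  Global importance of a feature is the mean absolute
contribution across samples; local explanations are the signed
per-feature contributions whose sum with the intercept reproduces the
prediction logit exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["ShapeFunction", "AdditiveBoostingClassifier",
           "global_importance", "local_explanation"]

_LOGIT_CLIP = 30.0
_PREVALENCE_EPS = 1e-6


@dataclass(frozen=True)
class ShapeFunction:
    """Piecewise-constant additive contribution curve of one feature."""

    feature: str
    bin_edges: np.ndarray  # interior cut points, strictly increasing
    values: np.ndarray  # one contribution per bin; len(edges) + 1 bins

    def __post_init__(self) -> None:
        if len(self.values) != len(self.bin_edges) + 1:
            raise ValueError("need exactly len(bin_edges) + 1 bin values")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges, np.asarray(x, dtype=float), side="right")
        return self.values[idx]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_LOGIT_CLIP, _LOGIT_CLIP)))


def _boost_python(bins, y, f0, n_passes, lr, n_bins, max_leaves):
    """Cyclic boosting over pre-binned features (reference implementation)."""
    n, p = bins.shape
    contrib = np.zeros((p, int(n_bins.max())))
    F = np.full(n, f0)
    lam = 1e-3
    for _ in range(n_passes):
        for j in range(p):
            B = n_bins[j]
            prob = _sigmoid(F)
            g = np.bincount(bins[:, j], weights=y - prob, minlength=B)
            h = np.bincount(bins[:, j], weights=prob * (1 - prob), minlength=B)
            update = _tree_update(g, h, B, max_leaves, lam) * lr
            contrib[j, :B] += update
            F = F + update[bins[:, j]]
    return contrib, F


def _tree_update(g, h, B, max_leaves, lam):
    """Best single-feature tree (<= max_leaves leaves) as per-bin values."""
    gc = np.concatenate(([0.0], np.cumsum(g)))
    hc = np.concatenate(([0.0], np.cumsum(h)))

    def best_split(lo, hi):
        # returns (gain, split) for region [lo, hi)
        G, H = gc[hi] - gc[lo], hc[hi] - hc[lo]
        base = G * G / (H + lam)
        best = (0.0, -1)
        for s in range(lo + 1, hi):
            GL, HL = gc[s] - gc[lo], hc[s] - hc[lo]
            GR, HR = G - GL, H - HL
            gain = GL * GL / (HL + lam) + GR * GR / (HR + lam) - base
            if gain > best[0]:
                best = (gain, s)
        return best

    regions = [(0, B)]
    while len(regions) < max_leaves:
        gains = [best_split(lo, hi) for lo, hi in regions]
        k = int(np.argmax([gn for gn, _ in gains]))
        gain, s = gains[k]
        if s < 0 or gain <= 1e-12:
            break
        lo, hi = regions.pop(k)
        regions[k:k] = [(lo, s), (s, hi)]
    update = np.zeros(B)
    for lo, hi in regions:
        G, H = gc[hi] - gc[lo], hc[hi] - hc[lo]
        update[lo:hi] = np.clip(G / (H + lam), -4.0, 4.0)
    return update


try:  # optional JIT of the inner loop; semantics identical to the python path
    from numba import njit

    @njit(cache=False)
    def _boost_numba(bins, y, f0, n_passes, lr, n_bins, max_leaves):  # pragma: no cover
        n, p = bins.shape
        Bmax = int(n_bins.max())
        contrib = np.zeros((p, Bmax))
        F = np.full(n, f0)
        lam = 1e-3
        g = np.zeros(Bmax)
        h = np.zeros(Bmax)
        for _ in range(n_passes):
            for j in range(p):
                B = n_bins[j]
                for b in range(B):
                    g[b] = 0.0
                    h[b] = 0.0
                for i in range(n):
                    z = F[i]
                    if z > _LOGIT_CLIP:
                        z = _LOGIT_CLIP
                    elif z < -_LOGIT_CLIP:
                        z = -_LOGIT_CLIP
                    pr = 1.0 / (1.0 + np.exp(-z))
                    b = bins[i, j]
                    g[b] += y[i] - pr
                    h[b] += pr * (1.0 - pr)
                gc = np.zeros(B + 1)
                hc = np.zeros(B + 1)
                for b in range(B):
                    gc[b + 1] = gc[b] + g[b]
                    hc[b + 1] = hc[b] + h[b]
                # grow up to max_leaves regions greedily
                lo_arr = np.empty(max_leaves, dtype=np.int64)
                hi_arr = np.empty(max_leaves, dtype=np.int64)
                lo_arr[0] = 0
                hi_arr[0] = B
                n_regions = 1
                while n_regions < max_leaves:
                    best_gain = 1e-12
                    best_region = -1
                    best_s = -1
                    for r in range(n_regions):
                        lo, hi = lo_arr[r], hi_arr[r]
                        G = gc[hi] - gc[lo]
                        H = hc[hi] - hc[lo]
                        base = G * G / (H + lam)
                        for s in range(lo + 1, hi):
                            GL = gc[s] - gc[lo]
                            HL = hc[s] - hc[lo]
                            GR = G - GL
                            HR = H - HL
                            gain = (GL * GL / (HL + lam)
                                    + GR * GR / (HR + lam) - base)
                            if gain > best_gain:
                                best_gain = gain
                                best_region = r
                                best_s = s
                    if best_region < 0:
                        break
                    hi = hi_arr[best_region]
                    hi_arr[best_region] = best_s
                    lo_arr[n_regions] = best_s
                    hi_arr[n_regions] = hi
                    n_regions += 1
                update = np.zeros(B)
                for r in range(n_regions):
                    lo, hi = lo_arr[r], hi_arr[r]
                    G = gc[hi] - gc[lo]
                    H = hc[hi] - hc[lo]
                    val = G / (H + lam)
                    if val > 4.0:
                        val = 4.0
                    elif val < -4.0:
                        val = -4.0
                    val *= lr
                    for b in range(lo, hi):
                        update[b] = val
                        contrib[j, b] += val
                for i in range(n):
                    F[i] += update[bins[i, j]]
        return contrib, F

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


class AdditiveBoostingClassifier(ClassifierMixin, BaseEstimator):
    """Boosted generalized additive classifier with exact explanations.

    Parameters
    ----------
    learning_rate : shrinkage applied to every tree's Newton leaf values.
    n_passes : number of cyclic passes over the features; each pass fits
        one shallow tree per feature.
    max_leaves : maximum leaves per single-feature tree.
    n_bins : maximum quantile bins per feature (fewer if the training
        column has few distinct values).

    Attributes
    ----------
    classes_ : class labels; the second one is modeled as y = 1.
    intercept_ : fitted intercept beta_0 (shape-centering folded in).
    shapes_ : list of :class:`ShapeFunction`, one per feature.
    feature_names_ : column names seen during fit.
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        n_passes: int = 300,
        max_leaves: int = 3,
        n_bins: int = 32,
    ):
        self.learning_rate = learning_rate
        self.n_passes = n_passes
        self.max_leaves = max_leaves
        self.n_bins = n_bins

    def fit(self, X, y):
        feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        n, p = X.shape
        self.feature_names_ = feature_names or [f"x{j}" for j in range(p)]
        self.n_features_in_ = p
        if len(self.classes_) > 2:
            raise ValueError("binary classification only")
        if len(self.classes_) == 1:
            # degenerate: all labels identical -> clipped-prevalence model
            self.intercept_ = -_LOGIT_CLIP  # lone class is coded as y = 0
            self.shapes_ = [
                ShapeFunction(name, np.array([0.0]), np.zeros(2))
                for name in self.feature_names_
            ]
            return self

        prevalence = float(np.clip(y01.mean(), _PREVALENCE_EPS, 1 - _PREVALENCE_EPS))
        beta0 = float(np.log(prevalence / (1 - prevalence)))

        edges_list, bins = [], np.empty((n, p), dtype=np.int64)
        for j in range(p):
            col = X[:, j]
            qs = np.quantile(col, np.linspace(0, 1, self.n_bins + 1)[1:-1])
            edges = np.unique(qs)
            edges_list.append(edges)
            bins[:, j] = np.searchsorted(edges, col, side="right")
        n_bins = np.array([len(e) + 1 for e in edges_list], dtype=np.int64)

        boost = _boost_numba if _HAVE_NUMBA else _boost_python
        contrib, F = boost(
            bins, y01.astype(float), float(beta0), int(self.n_passes),
            float(self.learning_rate), n_bins, int(self.max_leaves),
        )

        # center shapes on the training set; fold means into the intercept
        shapes = []
        for j in range(p):
            vals = contrib[j, : n_bins[j]].copy()
            mean_contrib = vals[bins[:, j]].mean()
            vals -= mean_contrib
            beta0 += mean_contrib
            edges = edges_list[j]
            if edges.size == 0:  # constant training column: single bin
                edges, vals = np.array([0.0]), np.array([vals[0], vals[0]])
            shapes.append(ShapeFunction(self.feature_names_[j], edges, vals))
        self.intercept_ = beta0
        self.shapes_ = shapes
        return self

    # ------------------------------------------------------------------

    def _validate_for_predict(self, X) -> np.ndarray:
        check_is_fitted(self, "shapes_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with {self.n_features_in_}"
            )
        return X

    def contributions(self, X) -> np.ndarray:
        """Per-sample signed contributions f_i(x_i), shape (n, p)."""
        X = self._validate_for_predict(X)
        return np.column_stack([s(X[:, j]) for j, s in enumerate(self.shapes_)])

    def decision_function(self, X) -> np.ndarray:
        return self.intercept_ + self.contributions(X).sum(axis=1)

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate_for_predict(X)
        if len(self.classes_) == 1:
            return np.ones((X.shape[0], 1))
        p1 = _sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X) -> np.ndarray:
        if len(self.classes_) == 1:
            X = self._validate_for_predict(X)
            return np.full(X.shape[0], self.classes_[0])
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]


def global_importance(model: AdditiveBoostingClassifier, X) -> pd.DataFrame:
    """Mean absolute contribution per feature, sorted descending.

    Importance_i = (1/n) sum_k |f_i(x_{k,i})|; ties broken by feature
    name for a stable ordering.
    """
    contrib = model.contributions(X)
    if contrib.shape[0] == 0:
        raise ValueError("X must be non-empty")
    table = pd.DataFrame(
        {
            "feature": model.feature_names_,
            "importance": np.abs(contrib).mean(axis=0),
        }
    )
    return table.sort_values(
        ["importance", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def local_explanation(
    model: AdditiveBoostingClassifier, x, top_k: int | None = 10
) -> dict:
    """Signed per-feature contributions for one subject.

    The full contribution list plus intercept reconstructs the
    prediction logit exactly; ``top_k`` limits the ranked list reported
    for plotting (dominant features first by absolute contribution).
    """
    x = np.asarray(x, dtype=float).reshape(1, -1)
    contrib = model.contributions(x)[0]
    logit = float(model.intercept_ + contrib.sum())
    order = np.argsort(-np.abs(contrib), kind="stable")
    ranked = [
        (model.feature_names_[j], float(contrib[j]))
        for j in order
        if contrib[j] != 0.0
    ]
    return {
        "intercept": float(model.intercept_),
        "contributions": dict(zip(model.feature_names_, contrib)),
        "ranked": ranked[: top_k if top_k is not None else len(ranked)],
        "logit": logit,
        "probability": float(_sigmoid(np.array([logit]))[0]),
    }
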