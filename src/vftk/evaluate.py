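"""Z-scoring, leave-one-out evaluation, and baseline learner adapters.

Evaluation follows the clinical protocol: features are Z-score
normalized with parameters fit on the training rows only, models are
assessed by leave-one-out cross-validation (each subject held out once,
normalization re-fit on the remaining n-1), and pooled held-out
probabilities are scored at a fixed 0.5 decision threshold with
classification accuracy, sensitivity, specificity, positive predictive
value, F1, and tie-aware AUC.  The schizophrenia group (SH) is the
positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .ebm import AdditiveBoostingClassifier

__all__ = [
    "ZScoreParams",
    "zscore_fit",
    "zscore_apply",
    "auc",
    "EvalReport",
    "loocv_evaluate",
    "get_baseline",
    "BASELINE_REGISTRY",
]

POSITIVE_LABEL = "SH"


@dataclass(frozen=True)
class ZScoreParams:
    means: np.ndarray
    sds: np.ndarray  # sample SD (ddof=1); zero-SD columns replaced by 1


def zscore_fit(train: np.ndarray) -> ZScoreParams:
    """Column means and sample SDs from training rows only."""
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.ones(train.shape[1])
    constant = sds == 0.0
    if constant.any():
        import warnings

        warnings.warn(f"{int(constant.sum())} constant column(s); using sd = 1")
        sds = np.where(constant, 1.0, sds)
    return ZScoreParams(means=means, sds=sds)


def zscore_apply(params: ZScoreParams, matrix: np.ndarray) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - params.means) / params.sds


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware (midrank Mann-Whitney) area under the ROC curve."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    y = labels == POSITIVE_LABEL if labels.dtype.kind in "OU" else labels.astype(bool)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, scores))


@dataclass
class EvalReport:
    """LOOCV metric suite plus per-subject held-out probabilities."""

    CA: float
    SEN: float
    SPE: float
    PPV: float
    F1: float
    AUC: float
    probabilities: pd.Series  # held-out P(SH) per subject
    confusion: dict[str, int]  # TP, FN, FP, TN at threshold 0.5

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("CA", "SEN", "SPE", "PPV", "F1", "AUC")}


def metrics_from_scores(
    probs: np.ndarray, y_true: np.ndarray, threshold: float = 0.5
) -> tuple[dict[str, float], dict[str, int]]:
    """Threshold metrics + AUC from positive-class probabilities."""
    y_true = np.asarray(y_true, dtype=bool)
    pred = np.asarray(probs) >= threshold
    tp = int(np.sum(pred & y_true))
    fn = int(np.sum(~pred & y_true))
    fp = int(np.sum(pred & ~y_true))
    tn = int(np.sum(~pred & ~y_true))
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * ppv * sen / (ppv + sen) if ppv + sen else 0.0
    vals = {
        "CA": (tp + tn) / len(y_true),
        "SEN": sen,
        "SPE": spe,
        "PPV": ppv,
        "F1": f1,
        "AUC": auc(probs, y_true),
    }
    return vals, {"TP": tp, "FN": fn, "FP": fp, "TN": tn}


def loocv_evaluate(
    features: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    trainer=None,
    threshold: float = 0.5,
    fold_local_zscore: bool = True,
) -> EvalReport:
    """Leave-one-out evaluation of any conforming probabilistic learner.

    Per fold: Z-score parameters are fit on the n-1 training rows (never
    the held-out row), the trainer is cloned and fit, and the held-out
    subject's P(SH) is recorded.  ``fold_local_zscore=False`` switches
    to a single global normalization for sensitivity analysis.
    """
    trainer = trainer if trainer is not None else AdditiveBoostingClassifier()
    X = features.to_numpy(dtype=float)
    labels = np.asarray(labels)
    y = labels == POSITIVE_LABEL
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    if fold_local_zscore:
        global_params = None
    else:
        global_params = zscore_fit(X)
    probs = np.empty(n)
    cols = list(features.columns)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        params = global_params or zscore_fit(X[mask])
        Xtr = pd.DataFrame(zscore_apply(params, X[mask]), columns=cols)
        Xte = pd.DataFrame(zscore_apply(params, X[[i]]), columns=cols)
        model = clone(trainer)
        try:
            model.fit(Xtr, y[mask].astype(int))
            proba = model.predict_proba(Xte)
        except Exception as exc:  # noqa: BLE001 - re-raise with fold context
            raise RuntimeError(f"trainer failed on fold {i} "
                               f"(subject index {i})") from exc
        classes = list(getattr(model, "classes_", [0, 1]))
        probs[i] = proba[0][classes.index(1)] if 1 in classes else 0.0
    vals, confusion = metrics_from_scores(probs, y, threshold)
    index = (
        features.index if features.index.is_unique else pd.RangeIndex(n)
    )
    return EvalReport(
        **vals,
        probabilities=pd.Series(probs, index=index, name="p_sh"),
        confusion=confusion,
    )


def _make_xgb():
    from xgboost import XGBClassifier

    return XGBClassifier(
        n_estimators=100, eval_metric="logloss", random_state=0, verbosity=0
    )


BASELINE_REGISTRY: dict[str, object] = {}


def _register_defaults() -> None:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    BASELINE_REGISTRY.update(
        {
            "ebm": lambda: AdditiveBoostingClassifier(),
            "gnb": lambda: GaussianNB(),
            "lasso": lambda: LogisticRegression(
                penalty="l1", solver="liblinear", random_state=0
            ),
            "ridge": lambda: LogisticRegression(penalty="l2", random_state=0),
            "rf": lambda: RandomForestClassifier(random_state=0),
            "svc": lambda: SVC(probability=True, random_state=0),
            "xgb": _make_xgb,
        }
    )


_register_defaults()


def get_baseline(name: str):
    """A fresh conforming learner by registry name (default settings)."""
    try:
        factory = BASELINE_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; registered: {sorted(BASELINE_REGISTRY)}")
    return factory()
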