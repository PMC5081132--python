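"""Cross-validated estimation of classification error, sensitivity and
specificity.

Leave-one-out cross-validation (LOOCV) is the primary estimator: each subject
is held out once, the classifier is trained on the remaining n-1 and the
held-out label predicted.  Sensitivity is the true-positive rate on group G2
(the effect-injected "case" group), specificity the true-negative rate on G1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .learners import DegenerateModelError, TunedParams, fit_predict

__all__ = ["PerformanceEstimate", "confusion_summary", "loocv", "kfold_cv"]

POSITIVE = "G2"
NEGATIVE = "G1"


@dataclass
class PerformanceEstimate:
    method: str
    error: float | None
    sensitivity: float | None
    specificity: float | None
    per_sample_predictions: np.ndarray | None = None
    n_eval: int = 0
    missing: bool = False

    def to_record(self) -> dict:
        return {
            "method": self.method,
            "error": self.error,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n": self.n_eval,
            "missing": self.missing,
        }


def confusion_summary(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[float, float | None, float | None]:
    """(error, sensitivity, specificity) with G2 as the positive class.

    A class absent from ``truth`` yields ``None`` for the corresponding rate.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    n = len(truth)
    error = float(np.mean(predicted != truth))
    pos = truth == POSITIVE
    neg = truth == NEGATIVE
    sens = float(np.mean(predicted[pos] == POSITIVE)) if pos.any() else None
    spec = float(np.mean(predicted[neg] == NEGATIVE)) if neg.any() else None
    return error, sens, spec


def _estimate_from_predictions(
    method: str, pred: np.ndarray, truth: np.ndarray
) -> PerformanceEstimate:
    error, sens, spec = confusion_summary(pred, truth)
    return PerformanceEstimate(
        method, error, sens, spec, per_sample_predictions=pred, n_eval=len(truth)
    )


def loocv(
    method: str,
    params: TunedParams,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
) -> PerformanceEstimate:
    """Leave-one-out estimate of error/sensitivity/specificity.

    A degenerate fit (LDA with p >= n-1, or a training fold losing a class)
    is recorded as a missing estimate, never raised to the caller.
    """
    n = len(y)
    if n < 2:
        raise ValueError("LOOCV requires n >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    fit_seeds = rng.integers(0, 2**31 - 1, size=n)
    pred = np.empty(n, dtype=y.dtype)
    mask = np.ones(n, dtype=bool)
    try:
        for i in range(n):
            mask[i] = False
            pred[i] = fit_predict(
                method, params, X[mask], y[mask], X[i : i + 1], seed=int(fit_seeds[i])
            )[0]
            mask[i] = True
    except DegenerateModelError:
        return PerformanceEstimate(method, None, None, None, missing=True)
    return _estimate_from_predictions(method, pred, y)


def kfold_cv(
    method: str,
    params: TunedParams,
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    seed: int | None = None,
) -> PerformanceEstimate:
    """Stratified k-fold estimate; ``folds == n`` reproduces LOOCV exactly."""
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds n={n}")
    if folds == n:
        return loocv(method, params, X, y, seed=seed)
    from .learners import _make_folds

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    fit_seeds = rng.integers(0, 2**31 - 1, size=folds)
    pred = np.empty(n, dtype=y.dtype)
    try:
        for fi, (tr, te) in enumerate(_make_folds(y, folds, fold_seed)):
            pred[te] = fit_predict(
                method, params, X[tr], y[tr], X[te], seed=int(fit_seeds[fi])
            )
    except DegenerateModelError:
        return PerformanceEstimate(method, None, None, None, missing=True)
    return _estimate_from_predictions(method, pred, y)
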