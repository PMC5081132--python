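"""Uniform train/predict contract over RF, RBF-SVM, LDA and kNN with
per-dataset hyperparameter grid search under 10-fold cross-validation.

Grids always contain the software default values, so the CV error at the
selected parameters can never exceed the CV error at the defaults on the same
folds.  Ties are broken toward the smallest parameter values in each method's
key order (simpler models win).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "METHODS",
    "PARAM_ORDER",
    "TuningGrid",
    "TunedParams",
    "DegenerateModelError",
    "build_rf_grid",
    "build_svm_grid",
    "build_knn_grid",
    "build_grid",
    "tune",
    "fit_predict",
]

METHODS = ("rf", "svm_rbf", "lda", "knn")

# tie-break key order per method: smallest values win in this order
PARAM_ORDER = {
    "rf": ("mtry", "nodesize", "ntree"),
    "svm_rbf": ("cost", "gamma"),
    "knn": ("k",),
    "lda": (),
}


class DegenerateModelError(ValueError):
    """Raised when a method cannot be fitted (e.g. LDA with p >= n_train)."""


def default_params(method: str, p: int) -> dict:
    """Software default tuning-parameter values; every grid contains them."""
    if method == "rf":
        return {"mtry": max(1, int(np.sqrt(p))), "nodesize": 1, "ntree": 500}
    if method == "svm_rbf":
        return {"cost": 1.0, "gamma": 1.0 / p}
    if method == "knn":
        return {"k": 1}
    return {}


@dataclass
class TuningGrid:
    method: str
    candidates: list[dict]
    folds: int = 10

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "lda" and not self.candidates:
            raise ValueError("candidate list must be non-empty")


@dataclass
class TunedParams:
    method: str
    params: dict = field(default_factory=dict)
    cv_error_at_optimum: float | None = None


def build_rf_grid(p: int, rng: np.random.Generator) -> TuningGrid:
    """Random-forest grid: mtry = default plus 4 distinct draws from
    {1..floor(p/2)} (the whole sequence if it has < 5 elements), nodesize
    {1..5}, ntree {50, 100, 500, 1000}.

    The classification default mtry = floor(sqrt(p)) is always included.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    default = max(1, int(np.sqrt(p)))
    seq = np.arange(1, max(p // 2, 1) + 1)
    if len(seq) < 5:
        mtry = sorted(set(seq.tolist()) | {default} if default <= seq[-1] else set(seq.tolist()))
    else:
        pool = seq[seq != default]
        draws = rng.choice(pool, size=4, replace=False)
        mtry = sorted({default, *draws.tolist()})
    candidates = [
        {"mtry": int(m), "nodesize": ns, "ntree": nt}
        for m, ns, nt in itertools.product(mtry, range(1, 6), (50, 100, 500, 1000))
    ]
    return TuningGrid("rf", candidates)


def build_svm_grid(p: int, rng: np.random.Generator | None = None) -> TuningGrid:
    """RBF-SVM grid: uniform samples of size 5 (inclusive of the defaults) from
    the ranges (1/10, 10) for cost and (1/(10p), 10/p) for gamma — i.e. the
    default plus 4 random uniform draws per parameter, 25 candidate pairs.

    With ``rng=None`` a deterministic variant is used instead: 5 geometrically
    spaced values d * 10^{-1,-1/2,0,1/2,1} around each default d.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if rng is None:
        steps = 10.0 ** np.array([-1.0, -0.5, 0.0, 0.5, 1.0])
        costs = 1.0 * steps
        gammas = (1.0 / p) * steps
    else:
        costs = np.concatenate([[1.0], rng.uniform(0.1, 10.0, size=4)])
        gammas = np.concatenate([[1.0 / p], rng.uniform(1 / (10 * p), 10 / p, size=4)])
    candidates = [
        {"cost": float(c), "gamma": float(g)}
        for c, g in itertools.product(costs, gammas)
    ]
    return TuningGrid("svm_rbf", candidates)


def build_knn_grid(n_train: int, folds: int = 10) -> TuningGrid:
    """kNN grid: k from 1 up to the size of the smallest CV training fold."""
    if n_train < 2:
        raise ValueError("n_train must be >= 2")
    k_max = max(1, n_train - int(np.ceil(n_train / folds)))
    return TuningGrid("knn", [{"k": k} for k in range(1, k_max + 1)], folds)


def build_grid(
    method: str,
    p: int,
    n_train: int,
    rng: np.random.Generator,
    overrides: dict | None = None,
) -> TuningGrid:
    """Build the default grid for a method, with optional per-parameter
    overrides (lists of candidate values) for scaled-down runs."""
    if method == "lda":
        return TuningGrid("lda", [])
    if method == "rf":
        grid = build_rf_grid(p, rng)
    elif method == "svm_rbf":
        grid = build_svm_grid(p, rng)
    elif method == "knn":
        grid = build_knn_grid(n_train)
    else:
        raise ValueError(f"unknown method {method!r}")
    if overrides:
        keys = PARAM_ORDER[method]
        pools = []
        for key in keys:
            if key in overrides:
                pools.append(list(overrides[key]))
            else:
                pools.append(sorted({c[key] for c in grid.candidates}))
        grid = TuningGrid(
            method,
            [dict(zip(keys, combo)) for combo in itertools.product(*pools)],
            grid.folds,
        )
    return grid


def _labels_to_binary(y: np.ndarray) -> np.ndarray:
    """G2 (the case group) maps to 1, G1 to 0; other binary labels by sort order."""
    classes = np.unique(y)
    if len(classes) > 2:
        raise ValueError("only binary classification is supported")
    return (y == classes[-1]).astype(int)


def _knn_predict_multi_k(
    X_train: np.ndarray, yb_train: np.ndarray, X_test: np.ndarray, ks: list[int]
) -> np.ndarray:
    """Vectorized kNN votes for several k at once (binary labels 0/1).

    Euclidean distance on raw values; distance ties resolved by training row
    order (stable argsort); even-k vote ties resolved by the nearer neighbour
    subset's majority (k-1, k-2, ...) and finally by label order (G1 first).
    Returns array of shape (len(ks), n_test) of binary labels.
    """
    d2 = (
        np.sum(X_test**2, axis=1)[:, None]
        - 2 * X_test @ X_train.T
        + np.sum(X_train**2, axis=1)[None, :]
    )
    order = np.argsort(d2, axis=1, kind="stable")
    sorted_labels = yb_train[order]  # n_test x n_train
    cum = np.cumsum(sorted_labels, axis=1)
    out = np.empty((len(ks), X_test.shape[0]), dtype=int)
    for ki, k in enumerate(ks):
        votes_g2 = cum[:, k - 1]
        pred = np.where(2 * votes_g2 > k, 1, 0)
        tied = 2 * votes_g2 == k
        if np.any(tied):
            for t in np.flatnonzero(tied):
                lab = 0  # label-order fallback: G1
                for kk in range(k - 1, 0, -1):
                    v = cum[t, kk - 1]
                    if 2 * v != kk:
                        lab = int(2 * v > kk)
                        break
                pred[t] = lab
        out[ki] = pred
    return out


def _make_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified CV folds; plain shuffled folds when a class has fewer
    members than folds (e.g. 10-fold tuning at n=10)."""
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= folds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def tune(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    grid: TuningGrid,
    rng: np.random.Generator,
) -> TunedParams:
    """Select the grid candidate minimising stratified k-fold CV error.

    Ties at the minimum CV error are broken in favour of the software default
    setting when it is among the tied candidates (the defaults are the
    protocol's anchor), otherwise toward the smallest parameter values in the
    method's key order.  Preferring the default matters under LOOCV: on
    strongly separable data many settings tie at CV error 0, and the most
    extreme of them (e.g. a heavily regularized SVM) can degenerate to a
    majority-vote rule whose leave-one-out error is catastrophic.
    """
    if method == "lda":
        return TunedParams("lda", {}, None)
    if len(grid.candidates) == 1:
        return TunedParams(method, grid.candidates[0], None)
    n = len(y)
    if n < grid.folds:
        raise ValueError(f"n={n} smaller than number of folds {grid.folds}")
    fold_seed = int(rng.integers(0, 2**31 - 1))
    folds = _make_folds(y, grid.folds, fold_seed)
    keys = PARAM_ORDER[method]
    candidates = sorted(grid.candidates, key=lambda c: tuple(c[k] for k in keys))
    yb = _labels_to_binary(y)
    if method == "knn":
        ks = [c["k"] for c in candidates]
        errors = np.zeros(len(ks))
        for tr, te in folds:
            usable = [min(k, len(tr)) for k in ks]
            preds = _knn_predict_multi_k(X[tr], yb[tr], X[te], usable)
            errors += np.sum(preds != yb[te][None, :], axis=1)
        errors /= n
        best = int(np.argmin(errors))  # argmin returns first minimum: smallest k
        return TunedParams("knn", candidates[best], float(errors[best]))
    fit_seeds = rng.integers(0, 2**31 - 1, size=(len(candidates), len(folds)))
    errors = np.empty(len(candidates))
    for ci, cand in enumerate(candidates):
        miss = 0
        for fi, (tr, te) in enumerate(folds):
            try:
                pred = fit_predict(
                    method, TunedParams(method, cand), X[tr], y[tr], X[te],
                    seed=int(fit_seeds[ci, fi]),
                )
                miss += int(np.sum(pred != y[te]))
            except DegenerateModelError:
                # a fold that cannot be fitted counts as fully misclassified
                miss += len(te)
        errors[ci] = miss / n
    best_err = errors.min()
    tied = [c for c, e in zip(candidates, errors) if e == best_err]
    default = default_params(method, X.shape[1])
    best_params = next(
        (c for c in tied if all(np.isclose(c[k], default[k]) for k in keys)), tied[0]
    )
    return TunedParams(method, best_params, float(best_err))


def fit_predict(
    method: str,
    params: TunedParams,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    seed: int | None = None,
) -> np.ndarray:
    """Fit one classifier and predict labels for ``X_test``.

    Deterministic given ``seed`` (random forest) or exactly (LDA, SVM, kNN).
    LDA raises :class:`DegenerateModelError` when p >= n_train or the pooled
    within-class covariance is singular; callers record a missing estimate.
    """
    X_test = np.atleast_2d(X_test)
    classes = np.unique(y_train)
    if len(classes) < 2:
        raise DegenerateModelError("training data contain a single class")
    p = X_train.shape[1]
    n_train = X_train.shape[0]
    cfg = params.params
    if method == "rf":
        clf = RandomForestClassifier(
            n_estimators=cfg.get("ntree", 500),
            max_features=min(cfg.get("mtry", max(1, int(np.sqrt(p)))), p),
            min_samples_leaf=cfg.get("nodesize", 1),
            random_state=seed,
            n_jobs=1,
        )
        # trees are grown on float32 internally; converting once avoids a copy
        clf.fit(X_train.astype(np.float32), y_train)
        return clf.predict(X_test.astype(np.float32))
    if method == "svm_rbf":
        # standardize by training-set mean/SD, as the reference SVM
        # implementations do by default; gamma = 1/p is calibrated to
        # unit-variance features
        m = X_train.mean(axis=0)
        s = X_train.std(axis=0)
        s[s == 0] = 1.0
        clf = SVC(
            C=cfg.get("cost", 1.0), gamma=cfg.get("gamma", 1.0 / p), kernel="rbf"
        )
        clf.fit((X_train - m) / s, y_train)
        return clf.predict((X_test - m) / s)
    if method == "lda":
        if p >= n_train:
            raise DegenerateModelError(
                f"LDA degenerate: p={p} >= n_train={n_train}"
            )
        # classical LDA needs an invertible pooled within-class covariance
        resid = np.vstack(
            [X_train[y_train == c] - X_train[y_train == c].mean(axis=0) for c in classes]
        )
        sv = np.linalg.svd(resid, compute_uv=False)
        if sv[-1] < 1e-9 * max(sv[0], 1.0):
            raise DegenerateModelError("LDA degenerate: singular pooled covariance")
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X_train, y_train)
        return clf.predict(X_test)
    if method == "knn":
        k = min(cfg.get("k", 1), n_train)
        yb = _labels_to_binary(y_train)
        pred_bin = _knn_predict_multi_k(X_train, yb, X_test, [k])[0]
        return classes[pred_bin]
    raise ValueError(f"unknown method {method!r}")
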