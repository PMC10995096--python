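"""Model evaluation: error metrics, the 70/15/15 split, and leave-one-out
cross-validation.

The LOOCV score follows ``CV(n) = (1/n) * sum_i MSE_i`` where fold *i*
trains on all samples but the *i*-th (with a fresh seeded initialization
and fold-local normalization — the estimators fit their min-max scalers
inside ``fit``, so no statistic leaks from the held-out year) and ``MSE_i``
is the squared error of the single held-out prediction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone

__all__ = [
    "MetricsReport",
    "CVResult",
    "compute_metrics",
    "split_70_15_15",
    "loocv",
]


@dataclass(frozen=True)
class MetricsReport:
    """Standard regression error metrics on the original target scale."""

    mse: float
    rmse: float
    mae: float
    mape_percent: float     # NaN when any y_true == 0 (undefined)
    r: float                # Pearson correlation

    def as_dict(self) -> dict[str, float]:
        return {"mse": self.mse, "rmse": self.rmse, "mae": self.mae,
                "mape_percent": self.mape_percent, "r": self.r}


def compute_metrics(y_true, y_pred) -> MetricsReport:
    """MSE, RMSE, MAE, MAPE (percent) and Pearson r.

    MAPE is flagged undefined (NaN, with a warning) when any true value is
    zero.  Requires at least two samples so the correlation is defined.
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length vectors")
    if yt.size < 2:
        raise ValueError("need at least 2 samples")
    resid = yt - yp
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))
    if np.any(yt == 0):
        warnings.warn("MAPE undefined: a true value is zero", RuntimeWarning)
        mape = math.nan
    else:
        mape = 100.0 * float(np.mean(np.abs(resid) / np.abs(yt)))
    if np.std(yt) == 0 or np.std(yp) == 0:
        r = math.nan
    else:
        r = float(stats.pearsonr(yt, yp).statistic)
    return MetricsReport(mse=mse, rmse=math.sqrt(mse), mae=mae,
                         mape_percent=mape, r=r)


def split_70_15_15(n_samples: int, seed: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 70/15/15 index partition (train, validation, test).

    Sizes are the floors of the nominal fractions with every remainder
    sample assigned to the training set first; the three parts are disjoint
    and exhaustive.  Eight samples split (6, 1, 1).
    """
    if n_samples < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    n_val = int(0.15 * n_samples)
    n_test = int(0.15 * n_samples)
    n_train = n_samples - n_val - n_test
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_val]),
            np.sort(perm[n_train + n_val:]))


@dataclass
class CVResult:
    """Leave-one-out result: per-fold squared errors and their mean."""

    per_fold_mse: list[float]
    cv_score: float
    n_folds: int
    failed_folds: list[int] = field(default_factory=list)
    predictions: list[float] = field(default_factory=list)


def loocv(X, y, model_factory, master_seed: int | None = None) -> CVResult:
    """Leave-one-out cross-validation of an estimator factory.

    ``model_factory`` is either a fitted/unfitted sklearn-style estimator
    (cloned per fold) or a zero-argument callable returning a fresh one.
    Each fold's estimator gets ``random_state = master_seed * 1000 + fold``
    when it exposes that parameter, trains on the n-1 remaining samples and
    predicts the held-out one; ``cv_score`` is the mean of the per-fold
    squared errors.  A fold whose training raises is flagged and excluded
    (with a warning) rather than aborting the whole validation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for leave-one-out")
    per_fold, failed, preds = [], [], []
    for i in range(n):
        mask = np.arange(n) != i
        model = model_factory() if callable(model_factory) and not hasattr(
            model_factory, "get_params") else clone(model_factory)
        if master_seed is not None and "random_state" in model.get_params():
            model.set_params(random_state=master_seed * 1000 + i)
        try:
            model.fit(X[mask], y[mask])
            pred = float(np.asarray(model.predict(X[i:i + 1]))[0])
        except Exception as exc:  # noqa: BLE001 - fold isolation by design
            warnings.warn(f"LOOCV fold {i} failed: {exc}", RuntimeWarning)
            failed.append(i)
            continue
        preds.append(pred)
        per_fold.append((y[i] - pred) ** 2)
    if not per_fold:
        raise RuntimeError("every LOOCV fold failed")
    return CVResult(per_fold_mse=[float(e) for e in per_fold],
                    cv_score=float(np.mean(per_fold)),
                    n_folds=n, failed_folds=failed, predictions=preds)
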