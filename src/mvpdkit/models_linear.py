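"""Linear region-to-region dependence models.

The mapping ``Y_train = B X_train + E_train`` is fitted jointly for all
target voxels (they share one design matrix), which is mathematically
identical to independent per-voxel solves. An intercept is always fitted and
never penalized.

Penalty conventions (documented so strengths can be mapped from other
software):

* ridge: ``||Y - BX||_F^2 + strength * ||B||_F^2`` — no ``1/T`` factor.
* lasso: ``1/(2T) * ||Y - BX||_F^2 + strength * ||B||_1`` (the
  scikit-learn coordinate-descent objective, per target voxel).

Nested cross-validated ridge selects the strength by an inner
leave-one-run-out loop over the TRAINING runs only, scoring candidates by
mean inner-fold prediction MSE (ties broken toward the smallest strength),
then refits on all training runs. Held-out test data never enters the
selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from mvpdkit.dimreduce import Reducer

__all__ = [
    "LinearMapping",
    "fit_ridge",
    "fit_lasso",
    "fit_ridge_nested_cv",
    "predict",
    "DEFAULT_REG_STRENGTH",
    "DEFAULT_STRENGTH_LIST",
]

DEFAULT_REG_STRENGTH = 0.001
DEFAULT_STRENGTH_LIST = (0.001, 0.01, 0.1)

_LASSO_MAX_ITER = 10000


@dataclass
class LinearMapping:
    """A fitted linear map from predictor features to target voxels.

    ``coefficients`` is ``n_Y x p`` where ``p`` is the number of predictor
    features after any reduction; ``intercept`` is length ``n_Y``. If
    ``reducer`` is set, :func:`predict` expects raw voxel-space predictor
    data and transforms it first; if ``target_reducer`` is set, the targets
    were fitted in component space and predictions are back-projected to
    voxel space.
    """

    coefficients: np.ndarray
    intercept: np.ndarray
    reg_type: str = "none"
    reg_strength: float = 0.0
    reducer: Reducer | None = None
    target_reducer: Reducer | None = None
    inner_cv_mse: dict | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        self.intercept = np.asarray(self.intercept, dtype=float).ravel()
        if self.coefficients.shape[0] != self.intercept.shape[0]:
            raise ValueError("coefficient rows must match intercept length")
        if self.reg_strength < 0:
            raise ValueError("regularization strength must be nonnegative")

    @property
    def n_targets(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[1]


def _check_xy(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"X and Y must share timepoints (columns): {X.shape[1]} vs {Y.shape[1]}"
        )
    return X, Y


def fit_ridge(
    X: np.ndarray,
    Y: np.ndarray,
    strength: float = DEFAULT_REG_STRENGTH,
    reducer: Reducer | None = None,
    target_reducer: Reducer | None = None,
) -> LinearMapping:
    """Ridge (L2) regression of target rows on predictor rows.

    ``strength=0`` falls back to ordinary least squares solved by a
    numerically safe least-squares routine (minimum-norm solution on
    rank-deficient designs).
    """
    X, Y = _check_xy(X, Y)
    if strength < 0:
        raise ValueError(f"strength must be >= 0, got {strength}")
    if strength == 0:
        est = LinearRegression(fit_intercept=True)
        reg_type = "none"
    else:
        est = Ridge(alpha=strength, fit_intercept=True, solver="cholesky")
        reg_type = "ridge"
    est.fit(X.T, Y.T)
    return LinearMapping(
        coefficients=est.coef_,
        intercept=est.intercept_,
        reg_type=reg_type,
        reg_strength=float(strength),
        reducer=reducer,
        target_reducer=target_reducer,
    )


def fit_lasso(
    X: np.ndarray,
    Y: np.ndarray,
    strength: float,
    reducer: Reducer | None = None,
    target_reducer: Reducer | None = None,
) -> LinearMapping:
    """Lasso (L1) regression, coordinate descent per target voxel."""
    X, Y = _check_xy(X, Y)
    if strength <= 0:
        raise ValueError(f"lasso strength must be > 0, got {strength}")
    est = Lasso(alpha=strength, fit_intercept=True, max_iter=_LASSO_MAX_ITER)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            est.fit(X.T, Y.T)
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"lasso did not converge within {_LASSO_MAX_ITER} iterations"
            ) from exc
    return LinearMapping(
        coefficients=est.coef_,
        intercept=est.intercept_,
        reg_type="lasso",
        reg_strength=float(strength),
        reducer=reducer,
        target_reducer=target_reducer,
    )


def fit_ridge_nested_cv(
    train_runs: Sequence[tuple[np.ndarray, np.ndarray]],
    strength_list: Sequence[float] = DEFAULT_STRENGTH_LIST,
    reducer: Reducer | None = None,
    target_reducer: Reducer | None = None,
) -> LinearMapping:
    """Ridge with the strength chosen by inner leave-one-run-out CV.

    Parameters
    ----------
    train_runs : sequence of (X_i, Y_i)
        Per-run training matrices (voxels x T_i). At least two runs are
        required so the inner loop has held-out data.
    strength_list : sequence of float
        Candidate strengths; the one minimizing mean inner-fold prediction
        MSE wins, with ties going to the smallest strength.

    The returned mapping is refitted on all training runs at the chosen
    strength; ``inner_cv_mse`` records the candidate scores.
    """
    runs = [(np.atleast_2d(np.asarray(X, float)), np.atleast_2d(np.asarray(Y, float)))
            for X, Y in train_runs]
    if len(runs) < 2:
        raise ValueError(
            "nested-CV ridge needs at least 2 training runs for the inner "
            "loop; with a single run use fit_ridge with a fixed strength"
        )
    strengths = [float(s) for s in strength_list]
    if not strengths:
        raise ValueError("strength_list must be nonempty")
    if any(s < 0 for s in strengths):
        raise ValueError("strengths must be nonnegative")

    mean_mse: dict[float, float] = {}
    for s in strengths:
        if s in mean_mse:  # duplicated candidate: same score by definition
            continue
        fold_mse = []
        for i in range(len(runs)):
            X_tr = np.hstack([X for j, (X, _) in enumerate(runs) if j != i])
            Y_tr = np.hstack([Y for j, (_, Y) in enumerate(runs) if j != i])
            X_te, Y_te = runs[i]
            mapping = fit_ridge(X_tr, Y_tr, strength=s)
            Yhat = predict(mapping, X_te)
            fold_mse.append(float(np.mean((Y_te - Yhat) ** 2)))
        mean_mse[s] = float(np.mean(fold_mse))

    # minimal MSE; exact ties resolved toward the smallest strength
    best = min(mean_mse, key=lambda s: (mean_mse[s], s))
    X_all = np.hstack([X for X, _ in runs])
    Y_all = np.hstack([Y for _, Y in runs])
    final = fit_ridge(X_all, Y_all, strength=best,
                      reducer=reducer, target_reducer=target_reducer)
    final.reg_type = "ridge_cv"
    final.inner_cv_mse = dict(mean_mse)
    return final


def predict(mapping: LinearMapping, X_test: np.ndarray) -> np.ndarray:
    """Apply a fitted mapping to held-out predictor data.

    If the mapping carries a predictor reducer, ``X_test`` must be raw
    voxel-space data and is transformed with the frozen training basis; if
    it carries a target reducer, component-space predictions are
    back-projected so the result is always in target voxel space.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    feats = mapping.reducer.transform(X_test) if mapping.reducer is not None else X_test
    if feats.shape[0] != mapping.n_features:
        raise ValueError(
            f"predictor has {feats.shape[0]} features, mapping expects {mapping.n_features}"
        )
    Yhat = mapping.coefficients @ feats + mapping.intercept[:, None]
    if mapping.target_reducer is not None:
        Yhat = mapping.target_reducer.inverse_transform(Yhat)
    return Yhat
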