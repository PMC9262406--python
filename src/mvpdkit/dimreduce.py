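"""Dimensionality reduction of region timecourses (PCA / ICA).

Reducers are fitted on training-fold data only and then applied, with the
frozen training mean and basis, to both training and held-out data. The API
makes test-set leakage structurally impossible: :func:`fit_reducer` is the
only fitting entry point and :meth:`Reducer.transform` never re-fits.

Layout convention: matrices are voxels x timepoints (as everywhere in this
package), so timepoints are the samples and voxels the variables; internally
data is transposed for scikit-learn.

The number of components is user-chosen (default 3). Automatic selection
(e.g. Minka's MLE, nested CV over dimensions) can be plugged in by passing a
custom fitted reducer to the workflow, but is not built in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = ["Reducer", "fit_reducer", "DEFAULT_N_COMPONENTS"]

DEFAULT_N_COMPONENTS = 3

_ICA_MAX_ITER = 1000
_ICA_TOL = 1e-4


@dataclass
class Reducer:
    """A fitted linear reducer (PCA or ICA) between voxel and component space.

    Attributes
    ----------
    method : {"pca", "ica"}
    n_components : int
    center : ndarray, shape (n_voxels,)
        Per-voxel mean of the training data; subtracted before projection
        and added back after back-projection.
    explained_variance_ratio : ndarray or None
        PCA only: fraction of training variance per component, decreasing.
    fit_seed : int or None
        ICA only: the seed used for the FastICA initialization.
    """

    method: str
    n_components: int
    _estimator: object
    fit_seed: int | None = None

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self._estimator.mean_)

    @property
    def n_voxels(self) -> int:
        return self.center.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray | None:
        return getattr(self._estimator, "explained_variance_ratio_", None)

    def transform(self, data: np.ndarray) -> np.ndarray:
        """Project voxels x T data onto component space -> n_components x T.

        Centering uses the TRAINING mean; held-out data is never re-fitted.
        """
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} rows (voxels), got shape {data.shape}"
            )
        return self._estimator.transform(data.T).T

    def inverse_transform(self, comps: np.ndarray) -> np.ndarray:
        """Back-project n_components x T component scores to voxel space."""
        comps = np.asarray(comps, dtype=float)
        if comps.ndim != 2 or comps.shape[0] != self.n_components:
            raise ValueError(
                f"expected {self.n_components} component rows, got shape {comps.shape}"
            )
        return self._estimator.inverse_transform(comps.T).T


def fit_reducer(
    train: np.ndarray,
    method: str = "pca",
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
) -> Reducer:
    """Fit a PCA or ICA reducer on a training voxels x T matrix.

    ``n_components`` must lie in [1, min(n_voxels, T)]. ICA uses FastICA
    with a fixed iteration cap (1000) and tolerance (1e-4); non-convergence
    is an error rather than a warning so results are never silently
    unstable.
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2:
        raise ValueError("training data must be 2D (voxels x time)")
    n, T = train.shape
    bound = min(n, T)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} out of bounds [1, {bound}] "
            f"for {n} voxels and {T} training timepoints"
        )
    method = method.lower()
    if method == "pca":
        est = PCA(n_components=n_components)
        est.fit(train.T)
        return Reducer(method="pca", n_components=n_components, _estimator=est)
    if method == "ica":
        est = FastICA(
            n_components=n_components,
            max_iter=_ICA_MAX_ITER,
            tol=_ICA_TOL,
            random_state=seed,
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            try:
                est.fit(train.T)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"ICA did not converge within {_ICA_MAX_ITER} iterations "
                    f"(tol={_ICA_TOL}): {exc}"
                ) from exc
        return Reducer(method="ica", n_components=n_components, _estimator=est, fit_seed=seed)
    raise ValueError(f"unknown reduction method {method!r}; use 'pca' or 'ica'")
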