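"""Voxelwise variance explained, thresholding, aggregation, model comparison.

The accuracy of a dependence model is the voxelwise proportion of variance
explained on held-out data:

    varExpl(j) = 1 - mean[(Y_test(j) - Yhat(j))^2] / var[Y_test(j)]

with the population (divide-by-T) variance in the denominator. The numerator
is, by default, the UNCENTERED mean squared residual: a prediction that
matches the target's pattern but misses its mean is penalized, so after
thresholding its varExpl is 0 even though its Pearson correlation with the
target is 1 — variance explained is deliberately more stringent than
correlation. A centered variant (residual variance in the numerator, under
which a pure mean offset is forgiven) is available via
``convention="centered"``.

Unthresholded values range over (-inf, 1]; :func:`threshold_nonnegative`
clips negatives to zero, reading a failed prediction as zero explained
variance. Target voxels with zero variance have an undefined ratio; they are
flagged and excluded from every average rather than silently zeroed.

Model comparisons follow the paired-subject logic: per-subject scalar
summaries are differenced and tested with a one-sample one-tailed t-test,
Bonferroni-corrected for the number of comparisons. Per-subject difference
maps can be exported as NIfTI volumes for external group-level
nonparametric software; that inference step is not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from mvpdkit.io_volumes import RoiMask, write_voxel_map

__all__ = [
    "VarExplMap",
    "ModelComparison",
    "variance_explained",
    "threshold_nonnegative",
    "aggregate_varexpl",
    "compare_models",
    "best_model_map",
    "export_subject_difference_maps",
]


@dataclass
class VarExplMap:
    """Per-voxel variance-explained values for one fold (or a fold mean)."""

    values: np.ndarray
    thresholded: bool = False
    fold_id: int | str = 0
    undefined_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.undefined_mask is None:
            self.undefined_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.undefined_mask = np.asarray(self.undefined_mask, dtype=bool).ravel()
            if self.undefined_mask.shape != self.values.shape:
                raise ValueError("undefined_mask must match values in length")

    @property
    def n_voxels(self) -> int:
        return self.values.size

    def defined_values(self) -> np.ndarray:
        return self.values[~self.undefined_mask]

    def mean(self) -> float:
        """Mean over defined voxels."""
        d = self.defined_values()
        if d.size == 0:
            raise ValueError("no defined voxels to average")
        return float(d.mean())


@dataclass
class ModelComparison:
    """Paired one-tailed t-test on per-subject accuracy differences."""

    differences: np.ndarray
    t_statistic: float
    p_one_tailed: float
    p_corrected: float
    n_comparisons: int
    note: str = ""

    @property
    def df(self) -> int:
        return self.differences.size - 1


def variance_explained(
    Y_test: np.ndarray,
    Yhat: np.ndarray,
    fold_id: int | str = 0,
    convention: str = "uncentered",
) -> VarExplMap:
    """Voxelwise variance explained of predictions on held-out data.

    ``convention="uncentered"`` (default) uses the raw mean squared residual
    in the numerator; ``"centered"`` uses the residual's variance, which
    forgives a constant offset between prediction and target.
    """
    Y_test = np.atleast_2d(np.asarray(Y_test, dtype=float))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    if Y_test.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y_test.shape} vs {Yhat.shape}")
    if Y_test.shape[1] < 2:
        raise ValueError("need at least 2 timepoints to estimate variance")
    if convention not in ("uncentered", "centered"):
        raise ValueError(f"unknown convention {convention!r}")
    resid = Y_test - Yhat
    if convention == "uncentered":
        num = np.mean(resid**2, axis=1)
    else:
        num = np.var(resid, axis=1)  # population variance
    denom = np.var(Y_test, axis=1)
    undefined = denom == 0
    values = np.empty(Y_test.shape[0])
    values[undefined] = np.nan
    values[~undefined] = 1.0 - num[~undefined] / denom[~undefined]
    return VarExplMap(values=values, thresholded=False, fold_id=fold_id,
                      undefined_mask=undefined)


def threshold_nonnegative(vmap: VarExplMap) -> VarExplMap:
    """Set negative variance explained to zero (idempotent)."""
    values = vmap.values.copy()
    defined = ~vmap.undefined_mask
    values[defined] = np.maximum(values[defined], 0.0)
    return replace(vmap, values=values, thresholded=True,
                   undefined_mask=vmap.undefined_mask.copy())


def aggregate_varexpl(maps: Sequence[VarExplMap]) -> tuple[float, VarExplMap]:
    """Average per-fold maps: per-voxel across folds first, then over voxels.

    Returns ``(scalar, mean_map)``. A voxel undefined in some folds is
    averaged over the folds where it is defined; a voxel undefined in every
    fold stays undefined. Averaging voxelwise first makes the scalar
    independent of unequal fold lengths. Mixing thresholded with
    unthresholded maps is an error.
    """
    if not maps:
        raise ValueError("need at least one map")
    states = {m.thresholded for m in maps}
    if len(states) > 1:
        raise ValueError("cannot aggregate maps with mixed threshold states")
    n = maps[0].n_voxels
    if any(m.n_voxels != n for m in maps):
        raise ValueError("all maps must share the same voxel space")
    stacked = np.vstack([m.values for m in maps])
    defined = np.vstack([~m.undefined_mask for m in maps])
    counts = defined.sum(axis=0)
    mean_vals = np.full(n, np.nan)
    ok = counts > 0
    with np.errstate(invalid="ignore"):
        mean_vals[ok] = np.nansum(np.where(defined, stacked, 0.0), axis=0)[ok] / counts[ok]
    mean_map = VarExplMap(values=mean_vals, thresholded=maps[0].thresholded,
                          fold_id="mean", undefined_mask=~ok)
    return mean_map.mean(), mean_map


def _one_tailed_t(diffs: np.ndarray) -> tuple[float, float, str]:
    n = diffs.size
    mean = diffs.mean()
    sd = diffs.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, 0.5, "all differences are exactly zero"
        t = np.inf if mean > 0 else -np.inf
        return float(t), float(stats.t.sf(t, n - 1)), (
            "zero-variance differences with nonzero mean; t reported as +/-inf"
        )
    t = mean / (sd / np.sqrt(n))
    return float(t), float(stats.t.sf(t, n - 1)), ""


def compare_models(
    per_subject_a: Sequence[float],
    per_subject_b: Sequence[float],
    n_comparisons: int = 1,
) -> ModelComparison:
    """Paired one-tailed t-test of model a over model b across subjects.

    Tests whether a's per-subject accuracy exceeds b's (differences a-b,
    df = n_subjects - 1); the p-value is Bonferroni-multiplied by
    ``n_comparisons`` and capped at 1.
    """
    a = np.asarray(per_subject_a, dtype=float).ravel()
    b = np.asarray(per_subject_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("per-subject lists must be paired (equal length)")
    if a.size < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    diffs = a - b
    t, p, note = _one_tailed_t(diffs)
    return ModelComparison(
        differences=diffs,
        t_statistic=t,
        p_one_tailed=p,
        p_corrected=min(1.0, p * n_comparisons),
        n_comparisons=int(n_comparisons),
        note=note,
    )


def best_model_map(
    per_subject_maps: Sequence[Sequence[np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel best-model labels and a conservative t margin.

    Parameters
    ----------
    per_subject_maps : models x subjects nested sequence of per-voxel arrays
        Subject-level mean varExpl maps for each model, aligned voxelwise.

    Returns
    -------
    labels : int array
        For each voxel, the index of the model with the highest
        subject-mean varExpl (ties go to the lowest model index).
    margins : float array
        For each voxel, the minimum across competitors of the paired
        t-statistic (best minus competitor) over subjects — how robustly
        the winner beats its closest rival.
    """
    n_models = len(per_subject_maps)
    if n_models < 2:
        raise ValueError("need at least 2 models")
    # stack to models x subjects x voxels
    stacks = []
    for model_maps in per_subject_maps:
        stacks.append(np.vstack([np.asarray(m, dtype=float).ravel() for m in model_maps]))
    n_subjects, n_voxels = stacks[0].shape
    if any(s.shape != (n_subjects, n_voxels) for s in stacks):
        raise ValueError("inconsistent subject counts or voxel spaces across models")
    data = np.stack(stacks)  # (models, subjects, voxels)
    subj_mean = data.mean(axis=1)  # (models, voxels)
    labels = np.argmax(subj_mean, axis=0)  # argmax takes the lowest index on ties
    margins = np.empty(n_voxels)
    for v in range(n_voxels):
        best = labels[v]
        t_vals = []
        for other in range(n_models):
            if other == best:
                continue
            t, _, _ = _one_tailed_t(data[best, :, v] - data[other, :, v])
            t_vals.append(t)
        margins[v] = min(t_vals)
    return labels, margins


def export_subject_difference_maps(
    maps_a: Sequence[VarExplMap],
    maps_b: Sequence[VarExplMap],
    mask: RoiMask,
    out_dir: str | Path,
    prefix: str = "diff",
) -> list[Path]:
    """Write per-subject (a - b) voxel maps as 3D NIfTI volumes.

    One volume per subject, ready for external group-level nonparametric
    inference. Undefined voxels in either map are written as 0 background.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError(
            f"unpaired subjects: {len(maps_a)} maps for a, {len(maps_b)} for b"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s, (ma, mb) in enumerate(zip(maps_a, maps_b)):
        diff = ma.values - mb.values
        diff[ma.undefined_mask | mb.undefined_mask] = 0.0
        paths.append(
            write_voxel_map(diff, mask, out_dir / f"{prefix}_subject{s:02d}.nii.gz")
        )
    return paths
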