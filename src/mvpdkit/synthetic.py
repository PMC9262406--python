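"""Synthetic multi-run region pairs with a planted linear dependence.

The generator emulates the data model the rest of the package assumes: m
runs of a predictor region (n_x voxels) and a target region (n_y voxels),
where the target is a known linear function of the predictor plus Gaussian
noise. Per run r:

    X_r = baseline_x + S_r          (S_r: AR(1) Gaussian, unit marginal var)
    Y_r = B_true @ S_r + intercept_true + N(0, noise_sd^2)

Predictor voxels carry AR(1) temporal autocorrelation (coefficient
``ar_rho``) to mimic the slow temporal structure of BOLD timecourses, with
the stationary marginal variance normalized to 1 so signal-to-noise is
controlled purely by ``noise_sd``. The mapping acts on the de-baselined
signal and is simultaneous (no temporal lag), matching the modeling
assumption that the target pattern at time t depends on the predictor
pattern at the same t.

``B_true`` has a controllable rank and unit row norms, so under the model
every target voxel's theoretical variance explained is the same closed
form::

    theoretical_varexpl = 1 / (1 + noise_sd^2)

and ``noise_sd = 1`` plants exactly 50% explainable variance. What this
generator does NOT emulate: hemodynamic convolution, physiological noise,
motion, spatial autocorrelation — conclusions from synthetic tests are
about the estimation machinery, not about real fMRI noise structure.

Seeding: the master seed is split per run and per component (predictor
signal vs target noise) through ``numpy.random.SeedSequence(seed).spawn``,
so any single run is regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from mvpdkit.io_volumes import (
    RegionTimecourses,
    RunTimecourse,
    mask_linear_indices,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "noise_sd_for_varexpl",
    "generate_dataset",
    "materialize_as_volumes",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic region pair.

    Defaults describe a desk-scale analogue of a multi-run study: 20
    predictor voxels, 30 target voxels, 4 runs of 400 timepoints,
    full-rank mapping, AR(1) coefficient 0.5 (BOLD-like slow structure),
    baselines of magnitude 100 (raw-BOLD-scale offsets).
    """

    n_x: int = 20
    n_y: int = 30
    m: int = 4
    T_per_run: int = 400
    mapping_rank: int | None = None  # None -> full rank min(n_x, n_y)
    noise_sd: float = 0.0
    ar_rho: float = 0.5
    mean_offsets: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.m, self.T_per_run) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.ar_rho < 1:
            raise ValueError("ar_rho must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        r = self.rank
        if not 1 <= r <= min(self.n_x, self.n_y):
            raise ValueError(
                f"mapping_rank must be in [1, {min(self.n_x, self.n_y)}], got {r}"
            )

    @property
    def rank(self) -> int:
        return self.mapping_rank if self.mapping_rank is not None else min(self.n_x, self.n_y)


@dataclass
class GroundTruth:
    """The planted mapping and its analytically implied accuracy."""

    B_true: np.ndarray
    intercept_true: np.ndarray
    baseline_x: np.ndarray
    theoretical_varexpl: np.ndarray


def noise_sd_for_varexpl(target_varexpl: float) -> float:
    """Noise sd planting a given theoretical varExpl (unit signal rows)."""
    if not 0 < target_varexpl <= 1:
        raise ValueError("target_varexpl must be in (0, 1]")
    return float(np.sqrt(1.0 / target_varexpl - 1.0))


def _planted_mapping(n_y: int, n_x: int, rank: int, rng: np.random.Generator) -> np.ndarray:
    """Rank-``rank`` matrix with unit row norms (generic row scaling
    preserves rank)."""
    for _ in range(100):
        B = rng.standard_normal((n_y, rank)) @ rng.standard_normal((rank, n_x))
        norms = np.linalg.norm(B, axis=1)
        if np.all(norms > 1e-9) and np.linalg.matrix_rank(B) == rank:
            return B / norms[:, None]
    raise RuntimeError("failed to draw a full-row, correct-rank mapping")


def _ar1(rng: np.random.Generator, n: int, T: int, rho: float) -> np.ndarray:
    """AR(1) rows with stationary unit marginal variance."""
    x = np.empty((n, T))
    x[:, 0] = rng.standard_normal(n)
    if T > 1:
        innov = rng.standard_normal((n, T - 1)) * np.sqrt(1.0 - rho**2)
        for t in range(1, T):
            x[:, t] = rho * x[:, t - 1] + innov[:, t - 1]
    return x


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[RegionTimecourses, RegionTimecourses, GroundTruth]:
    """Draw a predictor/target pair with the planted dependence.

    Returns ``(predictor, target, truth)`` where both regions are
    :class:`RegionTimecourses` (mask-less) with runs 0..m-1.
    """
    root = np.random.SeedSequence(spec.seed)
    # child 0: mapping/baselines; children 1..m: per-run, each split into
    # (signal, noise) so single runs regenerate in isolation
    children = root.spawn(spec.m + 1)
    rng0 = np.random.default_rng(children[0])
    B = _planted_mapping(spec.n_y, spec.n_x, spec.rank, rng0)
    baseline_x = rng0.standard_normal(spec.n_x) * spec.mean_offsets
    intercept = rng0.standard_normal(spec.n_y) * spec.mean_offsets

    x_runs, y_runs = [], []
    for r in range(spec.m):
        sig_seq, noise_seq = children[r + 1].spawn(2)
        S = _ar1(np.random.default_rng(sig_seq), spec.n_x, spec.T_per_run, spec.ar_rho)
        X = S + baseline_x[:, None]
        noise = np.random.default_rng(noise_seq).standard_normal(
            (spec.n_y, spec.T_per_run)) * spec.noise_sd
        Y = B @ S + intercept[:, None] + noise
        x_runs.append(RunTimecourse(values=X, run_id=r))
        y_runs.append(RunTimecourse(values=Y, run_id=r))

    # rows of B have unit norm and predictor voxels are independent with
    # unit marginal variance, so signal variance is 1 per target voxel
    signal_var = np.sum(B**2, axis=1)
    theo = signal_var / (signal_var + spec.noise_sd**2)
    truth = GroundTruth(
        B_true=B,
        intercept_true=intercept,
        baseline_x=baseline_x,
        theoretical_varexpl=theo,
    )
    return (
        RegionTimecourses(runs=x_runs),
        RegionTimecourses(runs=y_runs),
        truth,
    )


def _choose_grid(n_total: int) -> tuple[int, int, int]:
    side = int(np.ceil(n_total ** (1.0 / 3.0)))
    while side**3 < n_total:
        side += 1
    return (side, side, side)


def materialize_as_volumes(
    predictor: RegionTimecourses,
    target: RegionTimecourses,
    out_dir: str | Path,
    grid_shape: tuple[int, int, int] | None = None,
) -> dict[str, object]:
    """Write a synthetic dataset as NIfTI files loadable by io_volumes.

    The predictor occupies the first ``n_x`` voxels of the grid in
    linearization order and the target the next ``n_y`` (so the masks are
    disjoint by construction). Functional volumes are stored as float64 so
    a reload through :func:`mvpdkit.io_volumes.load_region_timecourses`
    reproduces the matrices bit-exactly.

    Returns a dict with keys ``func_paths``, ``predictor_mask_path``,
    ``target_mask_path``.
    """
    n_x, n_y = predictor.n_voxels, target.n_voxels
    if predictor.run_ids != target.run_ids:
        raise ValueError("predictor and target must share run ids")
    shape = grid_shape or _choose_grid(n_x + n_y)
    n_cells = int(np.prod(shape))
    if n_cells < n_x + n_y:
        raise ValueError(
            f"grid {shape} has {n_cells} voxels; need {n_x + n_y} for disjoint masks"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)

    def make_mask(start: int, count: int) -> np.ndarray:
        flat = np.zeros(n_cells, dtype=np.uint8)
        flat[start:start + count] = 1
        return flat.reshape(shape, order="F")

    pred_grid = make_mask(0, n_x)
    targ_grid = make_mask(n_x, n_y)
    pred_path = out_dir / "predictor_mask.nii.gz"
    targ_path = out_dir / "target_mask.nii.gz"
    for grid, path in ((pred_grid, pred_path), (targ_grid, targ_path)):
        img = nib.Nifti1Image(grid, affine)
        img.header.set_data_dtype(np.uint8)
        nib.save(img, str(path))

    pred_idx = mask_linear_indices(pred_grid)
    targ_idx = mask_linear_indices(targ_grid)
    func_paths = []
    for xr, yr in zip(predictor.runs, target.runs):
        T = xr.T
        if yr.T != T:
            raise ValueError(f"run {xr.run_id}: predictor/target timepoint mismatch")
        flat = np.zeros((n_cells, T))
        flat[pred_idx] = xr.values
        flat[targ_idx] = yr.values
        vol = flat.reshape(shape + (T,), order="F")
        img = nib.Nifti1Image(vol, affine)
        img.header.set_data_dtype(np.float64)
        path = out_dir / f"func_run{xr.run_id:02d}.nii.gz"
        nib.save(img, str(path))
        func_paths.append(path)

    return {
        "func_paths": func_paths,
        "predictor_mask_path": pred_path,
        "target_mask_path": targ_path,
    }
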