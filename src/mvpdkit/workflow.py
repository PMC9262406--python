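"""Config-driven analysis workflow: specify, load, execute.

An analysis is described by an :class:`AnalysisSpec` (typically a YAML file
with an ``inputinfo`` section naming the per-run functional images, the
predictor and target masks and the output directory, and a ``params``
section with the cross-validation, reduction, model and evaluation
settings). :func:`run_analysis` then loads the data, iterates the
leave-k-run-out folds, fits the chosen model on each training fold,
predicts the held-out run(s) and writes per-fold and fold-mean variance
explained maps, a scalar summary, model checkpoints and a timestamped log
file. Everything is non-interactive so analyses can run as cluster batch
jobs.

Seeding: the master seed deterministically derives all stage seeds
(reducer: master+1, network init/training: master+2, synthetic fixtures:
master itself; all reduced mod 2^31), so a completed run's log suffices to
reproduce it exactly.

The fitting APIs only ever receive training-fold data — test runs are
extracted separately and touched only by ``predict`` — so test-set leakage
is impossible by construction.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from mvpdkit._version import __version__
from mvpdkit import crossval, dimreduce, evaluate, models_linear, models_nn
from mvpdkit.io_volumes import (
    RegionTimecourses,
    RoiMask,
    load_mask,
    load_region_timecourses,
    mask_linear_indices,
    write_voxel_map,
)
from mvpdkit.synthetic import SyntheticSpec, generate_dataset

__all__ = [
    "AnalysisParams",
    "AnalysisSpec",
    "run_analysis",
    "run_selfcheck",
    "run_compare",
    "MODEL_TYPES",
    "SELFCHECK_MODELS",
]

MODEL_TYPES = ("l2_lr", "lasso_lr", "ridge_cv_lr", "pca_lr", "nn_standard", "nn_dense")

_SEED_MOD = 2**31


def _stage_seed(master: int, offset: int) -> int:
    return int((master + offset) % _SEED_MOD)


@dataclass
class AnalysisParams:
    """All analysis settings; defaults follow common MVPD usage."""

    model_type: str = "l2_lr"
    cv_k: int = 1
    dim_reduction: str = "none"  # none | pca | ica
    n_components: int = dimreduce.DEFAULT_N_COMPONENTS
    reduce_target: bool = False
    reg_strength: float = models_linear.DEFAULT_REG_STRENGTH
    strength_list: tuple[float, ...] = models_linear.DEFAULT_STRENGTH_LIST
    n_hidden_layers: int = 1
    hidden_units: int = 100
    batch_norm: bool = True
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 100
    varexpl_convention: str = "uncentered"
    threshold: bool = True
    exclude_predictor_from_target: bool = False
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(
                f"unknown model_type {self.model_type!r}; choose from {MODEL_TYPES}"
            )
        if self.dim_reduction not in ("none", "pca", "ica"):
            raise ValueError(f"unknown dim_reduction {self.dim_reduction!r}")
        self.strength_list = tuple(float(s) for s in self.strength_list)


@dataclass
class AnalysisSpec:
    """Input file paths plus analysis parameters (the two-variable split)."""

    func_paths: list[str]
    predictor_mask: str
    target_mask: str
    output_dir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        info = doc.get("inputinfo", {})
        params = AnalysisParams(**doc.get("params", {}))
        return cls(
            func_paths=[str(p) for p in info["func_paths"]],
            predictor_mask=str(info["predictor_mask"]),
            target_mask=str(info["target_mask"]),
            output_dir=str(info["output_dir"]),
            params=params,
        )

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "inputinfo": {
                "func_paths": list(self.func_paths),
                "predictor_mask": self.predictor_mask,
                "target_mask": self.target_mask,
                "output_dir": self.output_dir,
            },
            "params": asdict(self.params),
        }
        doc["params"]["strength_list"] = list(self.params.strength_list)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def validate_inputs(self) -> None:
        """Check every referenced input exists before any computation."""
        missing = [p for p in [*self.func_paths, self.predictor_mask, self.target_mask]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


# ---------------------------------------------------------------------------
# core fold loop (shared by file-based runs and in-memory selfcheck fixtures)

def _fit_predict_fold(
    X_train_runs: list[np.ndarray],
    Y_train_runs: list[np.ndarray],
    X_test: np.ndarray,
    params: AnalysisParams,
):
    """Fit the configured model on training runs, predict the test fold.

    Returns (Yhat, checkpoint) where checkpoint is an NNArtifact for
    network models and None otherwise.
    """
    X_train = np.hstack(X_train_runs)
    Y_train = np.hstack(Y_train_runs)
    seed_reduce = _stage_seed(params.master_seed, 1)
    seed_nn = _stage_seed(params.master_seed, 2)

    reducer = None
    target_reducer = None
    if params.model_type == "pca_lr":
        reducer = dimreduce.fit_reducer(X_train, "pca", params.n_components)
    elif params.dim_reduction != "none":
        reducer = dimreduce.fit_reducer(
            X_train, params.dim_reduction, params.n_components, seed=seed_reduce
        )
    if params.reduce_target:
        target_reducer = dimreduce.fit_reducer(
            Y_train, params.dim_reduction if params.dim_reduction != "none" else "pca",
            params.n_components, seed=seed_reduce,
        )

    X_feat = reducer.transform(X_train) if reducer is not None else X_train
    Y_fit = target_reducer.transform(Y_train) if target_reducer is not None else Y_train

    if params.model_type in ("l2_lr", "pca_lr"):
        strength = params.reg_strength if params.model_type == "l2_lr" else 0.0
        mapping = models_linear.fit_ridge(
            X_feat, Y_fit, strength, reducer=reducer, target_reducer=target_reducer
        )
        return models_linear.predict(mapping, X_test), None
    if params.model_type == "lasso_lr":
        mapping = models_linear.fit_lasso(
            X_feat, Y_fit, params.reg_strength, reducer=reducer,
            target_reducer=target_reducer,
        )
        return models_linear.predict(mapping, X_test), None
    if params.model_type == "ridge_cv_lr":
        pairs = []
        for Xr, Yr in zip(X_train_runs, Y_train_runs):
            xr = reducer.transform(Xr) if reducer is not None else Xr
            yr = target_reducer.transform(Yr) if target_reducer is not None else Yr
            pairs.append((xr, yr))
        mapping = models_linear.fit_ridge_nested_cv(
            pairs, params.strength_list, reducer=reducer, target_reducer=target_reducer
        )
        return models_linear.predict(mapping, X_test), None

    # network models
    kind = "standard" if params.model_type == "nn_standard" else "dense"
    spec = models_nn.NNArchitectureSpec(
        kind=kind,
        n_hidden_layers=params.n_hidden_layers,
        hidden_units=params.hidden_units,
        input_dim=X_feat.shape[0],
        output_dim=Y_fit.shape[0],
        batch_norm=params.batch_norm,
    )
    cfg = models_nn.TrainingConfig(
        learning_rate=params.learning_rate,
        momentum=params.momentum,
        weight_decay=params.weight_decay,
        batch_size=params.batch_size,
        epochs=params.epochs,
        seed=seed_nn,
    )
    net = models_nn.build_network(spec, seed=seed_nn)
    net = models_nn.train_network(net, X_feat, Y_fit, cfg)
    X_test_feat = reducer.transform(X_test) if reducer is not None else X_test
    Yhat = models_nn.predict_network(net, X_test_feat)
    if target_reducer is not None:
        Yhat = target_reducer.inverse_transform(Yhat)
    return Yhat, net


def _run_folds(
    predictor: RegionTimecourses,
    target: RegionTimecourses,
    params: AnalysisParams,
):
    """Execute the full CV loop in memory.

    Returns (fold_maps, mean_map, scalar, splits, checkpoints).
    """
    m = len(predictor.runs)
    splits = crossval.make_leave_k_run_out(m, params.cv_k)
    fold_maps = []
    checkpoints = {}
    for split in splits:
        X_train_runs = [r.values for r in predictor.runs if r.run_id in split.train_run_ids]
        Y_train_runs = [r.values for r in target.runs if r.run_id in split.train_run_ids]
        X_test = crossval.concatenate_runs(predictor, split.test_run_ids)
        Y_test = crossval.concatenate_runs(target, split.test_run_ids)
        Yhat, ckpt = _fit_predict_fold(X_train_runs, Y_train_runs, X_test, params)
        vmap = evaluate.variance_explained(
            Y_test, Yhat, fold_id=split.fold_id, convention=params.varexpl_convention
        )
        if params.threshold:
            vmap = evaluate.threshold_nonnegative(vmap)
        fold_maps.append(vmap)
        if ckpt is not None:
            checkpoints[split.fold_id] = ckpt
    scalar, mean_map = evaluate.aggregate_varexpl(fold_maps)
    return fold_maps, mean_map, scalar, splits, checkpoints


def run_analysis(spec: AnalysisSpec) -> Path:
    """Run one full analysis from NIfTI inputs to a results directory.

    Layout of the results directory: ``maps/`` (per-fold and mean varExpl
    NIfTI volumes, uncompressed for bitwise reproducibility),
    ``tables/summary.json`` and ``tables/summary.csv`` (scalar summary,
    parameters, folds), ``checkpoints/`` (network models only), and
    ``<TIMESTAMP>_log.txt`` at the root.
    """
    spec.validate_inputs()
    out_dir = Path(spec.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "data loading"
    manifest: list[str] = []
    try:
        pred_mask = load_mask(spec.predictor_mask, label="predictor")
        targ_mask = load_mask(spec.target_mask, label="target")
        if spec.params.exclude_predictor_from_target:
            grid = targ_mask.grid & ~pred_mask.grid
            targ_mask = RoiMask(grid=grid, affine=targ_mask.affine, label="target")
        predictor = load_region_timecourses(spec.func_paths, pred_mask)
        target = load_region_timecourses(spec.func_paths, targ_mask)

        stage = "model fitting and evaluation"
        fold_maps, mean_map, scalar, splits, checkpoints = _run_folds(
            predictor, target, spec.params
        )

        stage = "saving results"
        maps_dir = out_dir / "maps"
        for vmap in fold_maps:
            p = write_voxel_map(
                np.nan_to_num(vmap.values, nan=0.0), targ_mask,
                maps_dir / f"varexpl_fold{vmap.fold_id:02d}.nii",
            )
            manifest.append(str(p))
        p = write_voxel_map(
            np.nan_to_num(mean_map.values, nan=0.0), targ_mask,
            maps_dir / "varexpl_mean.nii",
        )
        manifest.append(str(p))

        ckpt_dir = out_dir / "checkpoints"
        for fold_id, net in checkpoints.items():
            ckpt_dir.mkdir(parents=True, exist_ok=True)
            net.save(ckpt_dir / f"model_fold{fold_id:02d}.npz")
            pd.DataFrame(
                {"epoch": np.arange(len(net.loss_history)), "mse": net.loss_history}
            ).to_csv(ckpt_dir / f"loss_fold{fold_id:02d}.csv", index=False)

        tables_dir = out_dir / "tables"
        tables_dir.mkdir(parents=True, exist_ok=True)
        summary = {
            "toolbox_version": __version__,
            "scalar_varexpl": scalar,
            "n_folds": len(splits),
            "folds": [
                {"fold_id": s.fold_id, "train": list(s.train_run_ids),
                 "test": list(s.test_run_ids)}
                for s in splits
            ],
            "n_undefined_voxels": int(mean_map.undefined_mask.sum()),
            "inputinfo": {
                "func_paths": list(spec.func_paths),
                "predictor_mask": spec.predictor_mask,
                "target_mask": spec.target_mask,
            },
            "params": _params_dict(spec.params),
        }
        with open(tables_dir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        pd.DataFrame([{"model_type": spec.params.model_type,
                       "scalar_varexpl": scalar,
                       "n_folds": len(splits)}]).to_csv(
            tables_dir / "summary.csv", index=False)

        _write_log(out_dir, spec, splits, scalar)
        return out_dir
    except Exception as exc:
        raise RuntimeError(
            f"analysis aborted during {stage}; partial results: {manifest or 'none'}"
        ) from exc


def _params_dict(params: AnalysisParams) -> dict:
    d = asdict(params)
    d["strength_list"] = list(params.strength_list)
    return d


def _write_log(out_dir: Path, spec: AnalysisSpec, splits, scalar: float) -> Path:
    stamp = _dt.datetime.now().strftime("%Y%m%d-%H%M%S")
    lines = [
        f"mvpdkit version {__version__}",
        f"timestamp: {stamp}",
        "",
        "[inputinfo]",
        *[f"func_path[{i}] = {p}" for i, p in enumerate(spec.func_paths)],
        f"predictor_mask = {spec.predictor_mask}",
        f"target_mask = {spec.target_mask}",
        f"output_dir = {spec.output_dir}",
        "",
        "[params]",
        *[f"{k} = {v}" for k, v in _params_dict(spec.params).items()],
        "",
        "[derived seeds]",
        f"master_seed = {spec.params.master_seed}",
        f"reducer_seed = {_stage_seed(spec.params.master_seed, 1)}",
        f"network_seed = {_stage_seed(spec.params.master_seed, 2)}",
        "",
        "[folds]",
        *[f"fold {s.fold_id}: train={list(s.train_run_ids)} test={list(s.test_run_ids)}"
          for s in splits],
        "",
        f"scalar_varexpl = {scalar!r}",
    ]
    path = out_dir / f"{stamp}_log.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# selfcheck

SELFCHECK_MODELS: dict[str, dict] = {
    "l2_lr": {"model_type": "l2_lr"},
    "pca_lr": {"model_type": "pca_lr", "n_components": 3},
    "nn_1layer": {"model_type": "nn_standard", "n_hidden_layers": 1},
    "nn_5layer": {"model_type": "nn_standard", "n_hidden_layers": 5},
    "nn_5layer_dense": {"model_type": "nn_dense", "n_hidden_layers": 5},
}

_SELFCHECK_FIXTURE = SyntheticSpec(
    n_x=10, n_y=15, m=3, T_per_run=120, noise_sd=0.5, ar_rho=0.5, seed=271828
)
_SELFCHECK_NN = {"hidden_units": 50, "epochs": 40, "batch_size": 32}
SELFCHECK_CORRELATION_BAR = 0.95


def _selfcheck_mean_map(model_name: str) -> np.ndarray:
    """Mean thresholded varExpl map of one example model on the fixture."""
    predictor, target, _ = generate_dataset(_SELFCHECK_FIXTURE)
    overrides = dict(SELFCHECK_MODELS[model_name])
    if overrides["model_type"].startswith("nn"):
        overrides.update(_SELFCHECK_NN)
    params = AnalysisParams(master_seed=7, **overrides)
    _, mean_map, _, _, _ = _run_folds(predictor, target, params)
    return mean_map.values


def _reference_path() -> Path:
    return Path(__file__).parent / "data" / "selfcheck_reference.csv"


def run_selfcheck(
    out_dir: str | Path = "testresults",
    reference_csv: str | Path | None = None,
) -> dict:
    """Verify the installation against shipped reference maps.

    Runs the five example models (l2_lr, pca_lr, nn_1layer, nn_5layer,
    nn_5layer_dense) end-to-end on a deterministic synthetic fixture and
    correlates each model's mean varExpl map with the shipped reference
    (itself computed on the same synthetic fixture at packaging time). A
    model whose correlation falls below 0.95 is reported as failing;
    failures are isolated per model. The report is written under
    ``out_dir`` and returned as a dict.
    """
    ref_path = Path(reference_csv) if reference_csv else _reference_path()
    refs = pd.read_csv(ref_path, comment="#")
    report: dict[str, dict] = {}
    for name in SELFCHECK_MODELS:
        try:
            values = _selfcheck_mean_map(name)
            ref = refs[name].to_numpy()
            r = float(np.corrcoef(values, ref)[0, 1])
            report[name] = {"correlation": r, "passed": bool(r >= SELFCHECK_CORRELATION_BAR)}
        except Exception as exc:  # isolate per-model failures
            report[name] = {"correlation": float("nan"), "passed": False,
                            "error": f"{type(exc).__name__}: {exc}"}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [{"model": k, **v} for k, v in report.items()]
    pd.DataFrame(rows).to_csv(out_dir / "selfcheck_report.csv", index=False)
    failing = [k for k, v in report.items() if not v["passed"]]
    lines = [f"selfcheck (correlation bar {SELFCHECK_CORRELATION_BAR}):"]
    for k, v in report.items():
        lines.append(f"  {k}: r={v['correlation']:.4f} "
                     f"{'PASS' if v['passed'] else 'FAIL'}"
                     + (f" ({v['error']})" if "error" in v else ""))
    lines.append("all models passed" if not failing
                 else f"FAILING models: {', '.join(failing)}")
    (out_dir / "selfcheck_report.txt").write_text("\n".join(lines) + "\n")
    return report


# ---------------------------------------------------------------------------
# model comparison across completed analyses

def run_compare(
    results_by_model: dict[str, Sequence[str | Path]],
    out_dir: str | Path,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """Compare completed analyses across models and subjects.

    Parameters
    ----------
    results_by_model : dict model_name -> per-subject result directories
        Each directory must come from :func:`run_analysis`; subject order
        must be consistent across models and all analyses must share fold
        definitions and target mask.
    n_comparisons : int, optional
        Bonferroni divisor; defaults to the full ordered pairwise count
        k*(k-1), counting both directions since the tests are one-tailed.

    Writes a comparison table (CSV), per-subject pairwise difference maps,
    and a best-model map with its minimum-t margin; returns the table.
    """
    names = list(results_by_model)
    if len(names) < 2:
        raise ValueError("need at least 2 models to compare")
    n_subjects = len(results_by_model[names[0]])
    if any(len(v) != n_subjects for v in results_by_model.values()):
        raise ValueError("all models need the same number of subject results")
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")

    scalars: dict[str, list[float]] = {}
    maps: dict[str, list[np.ndarray]] = {}
    folds_ref = None
    mask = None
    for name in names:
        scalars[name], maps[name] = [], []
        for d in results_by_model[name]:
            d = Path(d)
            with open(d / "tables" / "summary.json") as fh:
                summary = json.load(fh)
            if folds_ref is None:
                folds_ref = summary["folds"]
            elif summary["folds"] != folds_ref:
                raise ValueError(f"fold definitions differ in {d}")
            if mask is None:
                mask = load_mask(summary["inputinfo"]["target_mask"], label="target")
            scalars[name].append(float(summary["scalar_varexpl"]))
            vol = np.asanyarray(nib.load(str(d / "maps" / "varexpl_mean.nii")).dataobj)
            maps[name].append(vol.ravel(order="F")[mask_linear_indices(mask.grid)])

    k = len(names)
    n_comp = n_comparisons if n_comparisons is not None else k * (k - 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            cmpres = evaluate.compare_models(scalars[a], scalars[b], n_comparisons=n_comp)
            rows.append({
                "model_a": a, "model_b": b,
                "t": cmpres.t_statistic,
                "p_raw": cmpres.p_one_tailed,
                "p_corrected": cmpres.p_corrected,
                "n_subjects": n_subjects,
                "n_comparisons": n_comp,
            })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "comparison_table.csv", index=False)

    # per-subject difference maps for every unordered pair
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair_dir = out_dir / f"diffmaps_{a}_minus_{b}"
            evaluate.export_subject_difference_maps(
                [evaluate.VarExplMap(values=v, thresholded=True) for v in maps[a]],
                [evaluate.VarExplMap(values=v, thresholded=True) for v in maps[b]],
                mask, pair_dir,
            )

    labels, margins = evaluate.best_model_map([maps[n] for n in names])
    write_voxel_map(labels.astype(float), mask, out_dir / "best_model_labels.nii")
    write_voxel_map(np.clip(margins, -1e30, 1e30), mask, out_dir / "best_model_margin.nii")
    with open(out_dir / "best_model_legend.json", "w") as fh:
        json.dump({i: n for i, n in enumerate(names)}, fh, indent=2)
    return table
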