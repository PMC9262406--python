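"""Leave-k-run-out cross-validation partitions.

fMRI timeseries are temporally autocorrelated, so train/test splits must
respect run boundaries: a fold's test set is a whole run (or k whole runs)
and its training set is the concatenation of the remaining runs. This keeps
every test timepoint temporally disjoint from the training data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from mvpdkit.io_volumes import RegionTimecourses

__all__ = ["CrossValSplit", "make_leave_k_run_out", "concatenate_runs"]


@dataclass(frozen=True)
class CrossValSplit:
    """One train/test partition of the runs."""

    fold_id: int
    train_run_ids: tuple[int, ...]
    test_run_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        train, test = set(self.train_run_ids), set(self.test_run_ids)
        if train & test:
            raise ValueError("train and test runs overlap")
        if not train or not test:
            raise ValueError("train and test sets must both be nonempty")


def make_leave_k_run_out(m: int, k: int = 1) -> list[CrossValSplit]:
    """Enumerate all leave-k-run-out folds over runs 0..m-1.

    One fold per size-k combination of runs taken as the test set, in
    lexicographic order of the test-set ids; k=1 gives the classic
    leave-one-run-out scheme with m folds.
    """
    if m < 2:
        raise ValueError(f"need at least 2 runs for cross-validation, got m={m}")
    if not 1 <= k <= m - 1:
        raise ValueError(f"k must satisfy 1 <= k <= m-1, got k={k} with m={m}")
    run_ids = range(m)
    splits = []
    for fold_id, test in enumerate(itertools.combinations(run_ids, k)):
        train = tuple(r for r in run_ids if r not in test)
        splits.append(CrossValSplit(fold_id=fold_id, train_run_ids=train, test_run_ids=test))
    return splits


def concatenate_runs(region: RegionTimecourses, run_ids) -> np.ndarray:
    """Concatenate the selected runs along time (columns), in run order.

    Returns an ``n_voxels x sum(T_i)`` matrix; the selected runs appear in
    ascending run-id order regardless of the order of ``run_ids``.
    """
    wanted = list(run_ids)
    if not wanted:
        raise ValueError("run_ids must be nonempty")
    known = set(region.run_ids)
    unknown = [r for r in wanted if r not in known]
    if unknown:
        raise KeyError(f"unknown run ids {unknown}; available: {sorted(known)}")
    sel = set(wanted)
    return np.hstack([r.values for r in region.runs if r.run_id in sel])
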