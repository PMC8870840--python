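"""Data preparation: imputation, min-max scaling, redundancy removal,
class balancing, subsampling and repeated stratified splitting.

All statistics (fill values, scaling bounds, removed columns) are fitted
on training rows only and then applied unchanged to held-out rows, so no
information leaks from test folds into the fitted model.

Scaling note: every retained column — numeric values and integer
nominal/ordinal codes alike — is min-max mapped to [0, 1], because the
downstream Gaussian-visible RBM expects inputs in that range.  Codes are
used directly; there is no one-hot expansion.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .datasets import NUMERIC, NOMINAL, ORDINAL, LabeledDataset

__all__ = [
    "PreprocessModel",
    "SplitPlan",
    "UnfittableColumnError",
    "SchemaMismatchError",
    "fit_preprocess",
    "apply_preprocess",
    "balance_classes",
    "subsample_without_replacement",
    "make_splits",
    "iter_folds",
]

ZERO_VARIANCE = "zero_variance"
DUPLICATE = "duplicate"


class UnfittableColumnError(ValueError):
    """A column has no observed values to fit imputation from."""


class SchemaMismatchError(ValueError):
    """Dataset columns do not match the fitted model's schema."""


def _mode(values: np.ndarray) -> float:
    """Most frequent value; ties broken toward the smallest value."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])


def _lower_median(values: np.ndarray) -> float:
    """Median that stays on an observed code for even-length samples."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


@dataclass
class PreprocessModel:
    """Fitted imputation + scaling + column-removal recipe."""

    kinds: tuple[str, ...]
    impute_values: np.ndarray          # per original column
    col_min: np.ndarray                # per original column (observed min)
    col_max: np.ndarray
    removed_idx: tuple[tuple[int, str], ...]  # (column, reason), ascending

    @property
    def n_columns(self) -> int:
        return len(self.kinds)

    @property
    def kept_idx(self) -> np.ndarray:
        removed = {i for i, _ in self.removed_idx}
        return np.array([j for j in range(self.n_columns) if j not in removed],
                        dtype=int)

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(repr(self.kinds).encode())
        h.update(repr(self.removed_idx).encode())
        for arr in (self.impute_values, self.col_min, self.col_max):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def fit_preprocess(data: LabeledDataset) -> PreprocessModel:
    """Fit fill values, scaling bounds and the redundancy removal list.

    Fill values follow the column kind: mean for numeric, mode for
    nominal, median for ordinal, each computed over observed entries
    only.  Removed columns are all zero-variance ones plus, within each
    group of exactly identical columns, every column but the
    lowest-indexed.
    """
    X, mask = data.X, data.missing_mask
    d = data.d
    impute = np.empty(d)
    col_min = np.empty(d)
    col_max = np.empty(d)
    removed: list[tuple[int, str]] = []

    for j in range(d):
        obs = X[~mask[:, j], j]
        if obs.size == 0:
            raise UnfittableColumnError(f"column {j} has no observed values")
        kind = data.kinds[j]
        if kind == NUMERIC:
            impute[j] = obs.mean()
        elif kind == NOMINAL:
            impute[j] = _mode(obs)
        elif kind == ORDINAL:
            impute[j] = _lower_median(obs)
        else:  # pragma: no cover - kinds validated upstream
            raise ValueError(f"unknown kind {kind!r}")
        col_min[j] = obs.min()
        col_max[j] = obs.max()
        if col_min[j] == col_max[j]:
            removed.append((j, ZERO_VARIANCE))

    zero_var = {j for j, _ in removed}
    candidates = [j for j in range(d) if j not in zero_var]
    kept: list[int] = []
    for j in candidates:
        dup_of = None
        for i in kept:
            same_vals = np.array_equal(X[:, i], X[:, j], equal_nan=True)
            if same_vals and np.array_equal(mask[:, i], mask[:, j]):
                dup_of = i
                break
        if dup_of is None:
            kept.append(j)
        else:
            removed.append((j, DUPLICATE))

    removed.sort()
    return PreprocessModel(kinds=data.kinds, impute_values=impute,
                           col_min=col_min, col_max=col_max,
                           removed_idx=tuple(removed))


def apply_preprocess(model: PreprocessModel, data: LabeledDataset) -> LabeledDataset:
    """Impute, drop removed columns, min-max scale to [0, 1] with clipping.

    Idempotent: a dataset already transformed by this model (tracked via
    a fingerprint in ``meta``) is returned unchanged.
    """
    if data.meta.get("preprocess_fingerprint") == model.fingerprint:
        return data.copy()
    if data.d != model.n_columns or data.kinds != model.kinds:
        raise SchemaMismatchError(
            f"dataset schema ({data.d} columns) does not match fitted model "
            f"({model.n_columns} columns)")

    X = data.X.copy()
    for j in range(data.d):
        X[data.missing_mask[:, j], j] = model.impute_values[j]

    keep = model.kept_idx
    X = X[:, keep]
    lo = model.col_min[keep]
    hi = model.col_max[keep]
    X = np.clip((X - lo) / (hi - lo), 0.0, 1.0)

    out = LabeledDataset(
        X=X, y=data.y.copy(),
        kinds=tuple(data.kinds[j] for j in keep),
        missing_mask=np.zeros_like(X, dtype=bool),
        truth=data.truth, meta=dict(data.meta),
    )
    out.meta["preprocess_fingerprint"] = model.fingerprint
    return out


def balance_classes(data: LabeledDataset, seed: int) -> LabeledDataset:
    """Random minority oversampling with replacement to the majority count.

    Original rows are preserved; sampled copies are appended per class in
    ascending class order.  Intended for training folds only.
    """
    if data.n == 0:
        raise ValueError("cannot balance an empty dataset")
    rng = np.random.default_rng(seed)
    counts = data.class_counts()
    majority = counts.max()
    extra: list[np.ndarray] = []
    for c in range(len(counts)):
        deficit = majority - counts[c]
        if deficit > 0:
            members = np.flatnonzero(data.y == c)
            extra.append(rng.choice(members, size=deficit, replace=True))
    if not extra:
        return data.copy()
    idx = np.concatenate([np.arange(data.n)] + extra)
    return data.take(idx)


def subsample_without_replacement(data: LabeledDataset, n_subsamples: int,
                                  fraction: float, seed: int) -> list[LabeledDataset]:
    """Independent random row subsets, each of ⌊fraction·n⌋ distinct rows."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    size = int(np.floor(fraction * data.n))
    return [data.take(rng.choice(data.n, size=size, replace=False))
            for _ in range(n_subsamples)]


@dataclass
class SplitPlan:
    """Fold assignments for repeated (stratified) k-fold cross-validation."""

    n_folds: int
    repetition_seeds: tuple[int, ...]
    fold_assignment: np.ndarray        # (n_repetitions, n) fold index per row
    stratified: dict[int, bool] = field(default_factory=dict)

    @property
    def n_repetitions(self) -> int:
        return self.fold_assignment.shape[0]


def make_splits(data: LabeledDataset, n_folds: int, n_repetitions: int,
                seed: int) -> SplitPlan:
    """Repeated stratified k-fold assignment.

    Rows of each class are shuffled and dealt cyclically across a
    shuffled fold order, with the deal pointer carried over between
    classes.  This keeps overall fold sizes within one row of each other
    and each stratifiable class's per-fold counts within one of its
    global proportion; classes smaller than ``n_folds`` simply land in
    distinct folds (unstratified).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > data.n:
        raise ValueError("n_folds exceeds the number of instances")
    master = np.random.default_rng(seed)
    rep_seeds = tuple(int(s) for s in master.integers(2**31, size=n_repetitions))
    counts = data.class_counts()
    assignment = np.empty((n_repetitions, data.n), dtype=int)
    for r, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(rs)
        fold_order = rng.permutation(n_folds)
        pointer = 0
        for c in range(len(counts)):
            members = rng.permutation(np.flatnonzero(data.y == c))
            for row in members:
                assignment[r, row] = fold_order[pointer % n_folds]
                pointer += 1
    stratified = {c: bool(counts[c] >= n_folds) for c in range(len(counts))}
    return SplitPlan(n_folds=n_folds, repetition_seeds=rep_seeds,
                     fold_assignment=assignment, stratified=stratified)


def iter_folds(plan: SplitPlan, repetition: int):
    """Yield (train_idx, test_idx) for each fold of one repetition."""
    folds = plan.fold_assignment[repetition]
    for f in range(plan.n_folds):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        yield train, test
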