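"""Neuron ranking, pruning without retraining, k-NN evaluation and the
pruning sweep with confidence intervals.

The pipeline trains one RBM per training fold at the full hidden size,
ranks its hidden neurons by a discriminative measure evaluated on the
training activations, and then deletes the lowest-ranked neurons — no
retraining ever follows a prune.  Each retained-count setting is scored
with a k-NN classifier on the held-out fold; repetitions are aggregated
into a mean error and the normal-approximation confidence interval
CI = x̄ ± z·s/√n (sample SD, z = 1.96 for the 95% level).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import preprocess as prep
from . import rbm as rbm_mod
from .datasets import LabeledDataset
from .measures import ScoreVector, score_all
from .rbm import TrainConfig

__all__ = [
    "NeuronRanking",
    "KNNConfig",
    "PruneSweepResult",
    "rank_neurons",
    "prune",
    "knn_predict",
    "error_rate",
    "confidence_interval",
    "hidden_grid",
    "sweep",
    "HIDDEN_MULTIPLIERS",
]

HIDDEN_MULTIPLIERS = (0.5, 1, 2, 4, 6, 8, 16, 32)

_METRIC_MAP = {"euclidean": "euclidean", "chebyshev": "chebyshev",
               "manhattan": "cityblock"}


@dataclass
class NeuronRanking:
    """Descending-score permutation of hidden-neuron indices."""

    measure_name: str
    order: np.ndarray                  # most discriminative first
    scores: ScoreVector

    def reversed(self) -> "NeuronRanking":
        """Anti-ranking (least discriminative first); control experiments."""
        return NeuronRanking(self.measure_name, self.order[::-1].copy(),
                             self.scores)


@dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in _METRIC_MAP:
            raise ValueError(f"metric must be one of {sorted(_METRIC_MAP)}")


def rank_neurons(M: np.ndarray, y: np.ndarray, measure_name: str,
                 seed: int = 0, **measure_kwargs) -> NeuronRanking:
    """Score columns of ``M`` (training activations) and sort descending;
    score ties resolve toward the lower neuron index."""
    sv = score_all(M, y, measure_name, seed=seed, **measure_kwargs)
    order = np.argsort(-sv.scores, kind="stable")
    return NeuronRanking(measure_name, order, sv)


def prune(M: np.ndarray, ranking: NeuronRanking, n_keep: int) -> np.ndarray:
    """Keep the top ``n_keep`` ranked columns, in original column order."""
    M = np.atleast_2d(np.asarray(M))
    h = M.shape[1]
    if not 1 <= n_keep <= h:
        raise ValueError(f"n_keep must be in [1, {h}]")
    keep = np.sort(ranking.order[:n_keep])
    return M[:, keep]


def knn_predict(train_M: np.ndarray, train_y: np.ndarray, test_M: np.ndarray,
                cfg: KNNConfig) -> np.ndarray:
    """Majority-vote k-NN with deterministic tie handling.

    Distance ties at the k boundary resolve toward the lower training
    index; vote ties toward the tied class with the smallest summed
    distance, then the lowest class code.
    """
    train_M = np.atleast_2d(np.asarray(train_M, dtype=float))
    test_M = np.atleast_2d(np.asarray(test_M, dtype=float))
    train_y = np.asarray(train_y, dtype=int)
    if train_M.shape[0] == 0:
        raise ValueError("empty training set")
    if train_M.shape[1] != test_M.shape[1]:
        raise ValueError("train/test column counts differ")
    if cfg.k > train_M.shape[0]:
        raise ValueError("k exceeds the training-set size")

    D = cdist(test_M, train_M, metric=_METRIC_MAP[cfg.metric])
    C = int(train_y.max()) + 1
    pred = np.empty(test_M.shape[0], dtype=int)
    for t in range(test_M.shape[0]):
        nn = np.argsort(D[t], kind="stable")[:cfg.k]
        votes = np.bincount(train_y[nn], minlength=C)
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if len(tied) == 1:
            pred[t] = tied[0]
        else:
            sums = np.array([D[t][nn[train_y[nn] == c]].sum() for c in tied])
            pred[t] = tied[np.argmin(sums)]   # argmin: lowest code on ties
    return pred


def error_rate(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.mean(pred != truth))


def confidence_interval(values, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation interval: mean and halfwidth z·s/√n
    (s = sample SD with n−1 denominator)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values")
    return float(values.mean()), float(z * values.std(ddof=1) / np.sqrt(n))


def hidden_grid(n_features: int,
                multipliers: tuple[float, ...] = HIDDEN_MULTIPLIERS) -> tuple[int, ...]:
    """Hidden-layer sizes: ⌈m·n_features⌉ per multiplier, deduplicated
    ascending (for 9 features: 5, 9, 18, 36, 54, 72, 144, 288)."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return tuple(sorted({ceil(m * n_features) for m in multipliers}))


@dataclass
class PruneSweepResult:
    """Error rates per retained-neuron count across repetitions."""

    measure_name: str
    hidden_size: int
    retained_counts: tuple[int, ...]
    errors: np.ndarray                 # (n_repetitions, n_counts)
    baseline_errors: np.ndarray        # per-repetition error at full size
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    savings: np.ndarray                # 1 − retained / hidden_size

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "measure": self.measure_name,
            "hidden_size": self.hidden_size,
            "retained": list(self.retained_counts),
            "mean_error": self.mean,
            "ci_halfwidth": self.ci_halfwidth,
            "savings_pct": 100.0 * self.savings,
        })

    def long_frame(self) -> pd.DataFrame:
        reps, counts = self.errors.shape
        return pd.DataFrame({
            "measure": self.measure_name,
            "hidden_size": self.hidden_size,
            "repetition": np.repeat(np.arange(reps), counts),
            "retained": np.tile(self.retained_counts, reps),
            "error": self.errors.ravel(),
        })


def _evaluate_fold(train_ds: LabeledDataset, test_ds: LabeledDataset,
                   hidden_size: int, rbm_cfg: TrainConfig, knn_cfg: KNNConfig,
                   measure_name: str, retained_counts: tuple[int, ...],
                   fold_rng: np.random.Generator) -> np.ndarray:
    """Fit preprocessing + RBM on the training fold, rank on training
    activations, and return the test error per retained count."""
    balance_seed, rbm_seed, measure_seed = (
        int(s) for s in fold_rng.integers(2**31, size=3))
    model_prep = prep.fit_preprocess(train_ds)
    tr = prep.apply_preprocess(model_prep, train_ds)
    te = prep.apply_preprocess(model_prep, test_ds)
    tr = prep.balance_classes(tr, seed=balance_seed)

    cfg = TrainConfig(learning_rate=rbm_cfg.learning_rate, epochs=rbm_cfg.epochs,
                      batch_size=rbm_cfg.batch_size, cd_steps=rbm_cfg.cd_steps,
                      weight_init_sd=rbm_cfg.weight_init_sd, seed=rbm_seed)
    model = rbm_mod.init_model(tr.d, hidden_size, cfg)
    model, _ = rbm_mod.cd_train(model, tr.X, cfg)

    M_tr = rbm_mod.hidden_probs(model, tr.X)
    M_te = rbm_mod.hidden_probs(model, te.X)
    ranking = rank_neurons(M_tr, tr.y, measure_name, seed=measure_seed)

    errs = np.empty(len(retained_counts))
    for i, n_keep in enumerate(retained_counts):
        pred = knn_predict(prune(M_tr, ranking, n_keep), tr.y,
                           prune(M_te, ranking, n_keep), knn_cfg)
        errs[i] = error_rate(pred, te.y)
    return errs


def sweep(data: LabeledDataset, rbm_cfg: TrainConfig, knn_cfg: KNNConfig,
          measure_name: str, retained_counts, n_repetitions: int,
          n_folds: int, seed: int, hidden_size: int | None = None) -> PruneSweepResult:
    """Repeated cross-validated pruning sweep.

    Per repetition: a fresh stratified k-fold split; per fold:
    preprocessing, balancing and RBM training on the training rows only,
    neuron ranking on the training activations, then test error for each
    retained count against that single model (the full-size column is the
    baseline).  Fold errors average into one error per repetition and
    count; repetitions aggregate into the mean and 95% CI halfwidth.
    """
    retained_counts = tuple(sorted(int(c) for c in set(retained_counts)))
    h = hidden_size if hidden_size is not None else max(retained_counts)
    if not retained_counts or retained_counts[0] < 1 or retained_counts[-1] > h:
        raise ValueError("retained_counts must lie in 1..hidden_size")
    if retained_counts[-1] != h:
        raise ValueError("retained_counts must include the full hidden size")

    master = np.random.default_rng(seed)
    rep_seeds = master.integers(2**31, size=n_repetitions)
    errors = np.empty((n_repetitions, len(retained_counts)))
    for r in range(n_repetitions):
        rep_rng = np.random.default_rng(int(rep_seeds[r]))
        split_seed = int(rep_rng.integers(2**31))
        plan = prep.make_splits(data, n_folds, 1, split_seed)
        fold_errs = []
        for train_idx, test_idx in prep.iter_folds(plan, 0):
            fold_errs.append(_evaluate_fold(
                data.take(train_idx), data.take(test_idx), h, rbm_cfg,
                knn_cfg, measure_name, retained_counts, rep_rng))
        errors[r] = np.mean(fold_errs, axis=0)

    mean = errors.mean(axis=0)
    if n_repetitions >= 2:
        halfwidth = np.array([confidence_interval(errors[:, i])[1]
                              for i in range(len(retained_counts))])
    else:
        halfwidth = np.zeros(len(retained_counts))
    savings = 1.0 - np.asarray(retained_counts) / h
    return PruneSweepResult(
        measure_name=measure_name, hidden_size=h,
        retained_counts=retained_counts, errors=errors,
        baseline_errors=errors[:, -1].copy(), mean=mean,
        ci_halfwidth=halfwidth, savings=savings)
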