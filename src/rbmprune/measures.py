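"""Eight discriminative measures for scoring columns against class labels.

These rate how well a single column (a raw feature or a hidden-neuron
activation) separates the classes:

* ``fisher`` — between-class scatter over within-class scatter,
  S_i = Σ_j n_j (μ_ij − μ_i)² / Σ_j n_j var_ij;
* ``pcc`` — absolute Pearson correlation with the class indicator
  (mean over one-vs-rest indicators when there are more than 2 classes);
* ``anova`` — one-way F statistic;
* ``ig`` / ``gain_ratio`` / ``su`` — mutual-information measures on the
  discretized column: IG = H(X) − H(X|Y), GR = IG / H(X),
  SU = 2·IG / (H(X) + H(Y)), all in bits;
* ``relieff`` — nearest hit/miss feature weighting, W_f = a − b with
  a = p(diff. value | diff. class) and b = p(diff. value | same class);
* ``one_r`` — one minus the error of the single-column majority rule.

Continuous columns are discretized into equal-width bins over [0, 1] for
the entropy-based measures and One-R, matching activation probabilities.
All eight are oriented so that a higher score means more discriminative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DiscreteJoint",
    "ClassStats",
    "ScoreVector",
    "UndefinedScoreError",
    "MEASURES",
    "LARGE_SCORE",
    "discretize",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "gain_ratio",
    "symmetric_uncertainty",
    "fisher_score",
    "pcc_measure",
    "anova_f",
    "relieff",
    "one_r",
    "score_all",
]

MEASURES = ("fisher", "pcc", "anova", "ig", "gain_ratio", "su", "relieff", "one_r")

#: Sentinel for perfectly separating columns whose within-class spread is
#: exactly zero (the ratio-based scores are formally infinite there).
LARGE_SCORE = 1e12


class UndefinedScoreError(ValueError):
    """The measure is undefined for this input (e.g. zero entropy/variance)."""


@dataclass
class DiscreteJoint:
    """Joint count table over (feature-bin, class) pairs."""

    counts: np.ndarray                 # (n_bins, n_classes)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_codes(cls, x: np.ndarray, y: np.ndarray,
                   n_bins: int | None = None,
                   n_classes: int | None = None) -> "DiscreteJoint":
        x = np.asarray(x, dtype=int)
        y = np.asarray(y, dtype=int)
        nb = n_bins if n_bins is not None else int(x.max()) + 1
        nc = n_classes if n_classes is not None else int(y.max()) + 1
        counts = np.zeros((nb, nc))
        np.add.at(counts, (x, y), 1.0)
        return cls(counts)

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def px(self) -> np.ndarray:
        return self.counts.sum(axis=1) / self.n

    @property
    def py(self) -> np.ndarray:
        return self.counts.sum(axis=0) / self.n


@dataclass
class ClassStats:
    """Per-class count/mean/variance summary of one column."""

    class_counts: np.ndarray
    class_means: np.ndarray
    class_vars: np.ndarray             # population (ddof=0) variances
    grand_mean: float

    @classmethod
    def from_column(cls, x: np.ndarray, y: np.ndarray,
                    n_classes: int | None = None) -> "ClassStats":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        C = n_classes if n_classes is not None else int(y.max()) + 1
        counts = np.bincount(y, minlength=C).astype(float)
        means = np.zeros(C)
        variances = np.zeros(C)
        for c in range(C):
            m = y == c
            if m.any():
                means[c] = x[m].mean()
                variances[c] = x[m].var()
        return cls(counts, means, variances, float(x.mean()))


@dataclass
class ScoreVector:
    measure_name: str
    scores: np.ndarray
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)


def discretize(x: np.ndarray, n_bins: int, lo: float, hi: float) -> np.ndarray:
    """Equal-width bin codes over [lo, hi]; out-of-range values are clipped
    into the end bins and the upper edge is closed (hi lands in the last bin)."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if not lo < hi:
        raise ValueError("need lo < hi")
    x = np.asarray(x, dtype=float)
    codes = np.floor((x - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(codes, 0, n_bins - 1)


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits, with 0·log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def conditional_entropy(joint: DiscreteJoint) -> float:
    """H(X|Y) = Σ_y p(y) H(X | Y=y), in bits (always >= 0)."""
    if joint.n == 0:
        raise ValueError("empty joint table")
    total = 0.0
    for col in joint.counts.T:
        ny = col.sum()
        if ny > 0:
            total += (ny / joint.n) * entropy(col / ny)
    return total


def information_gain(joint: DiscreteJoint) -> float:
    """IG = H(X) − H(X|Y); equals the mutual information, >= 0."""
    if joint.n == 0:
        raise ValueError("empty joint table")
    ig = entropy(joint.px) - conditional_entropy(joint)
    return max(ig, 0.0)


def gain_ratio(joint: DiscreteJoint) -> float:
    """IG normalized by H(X); 1 = X fully determined by Y, 0 = independent."""
    hx = entropy(joint.px)
    if hx == 0.0:
        raise UndefinedScoreError("H(X) = 0: gain ratio undefined")
    return float(np.clip(information_gain(joint) / hx, 0.0, 1.0))


def symmetric_uncertainty(joint: DiscreteJoint) -> float:
    """SU = 2·IG / (H(X) + H(Y)); symmetric in X and Y, in [0, 1]."""
    hx = entropy(joint.px)
    hy = entropy(joint.py)
    if hx + hy == 0.0:
        raise UndefinedScoreError("H(X) + H(Y) = 0: SU undefined")
    return float(np.clip(2.0 * information_gain(joint) / (hx + hy), 0.0, 1.0))


def fisher_score(stats: ClassStats) -> float:
    n_j, mu_j, var_j = stats.class_counts, stats.class_means, stats.class_vars
    if (n_j > 0).sum() < 2:
        raise UndefinedScoreError("need at least 2 non-empty classes")
    numerator = float((n_j * (mu_j - stats.grand_mean) ** 2).sum())
    denominator = float((n_j * var_j).sum())
    if denominator == 0.0:
        raise UndefinedScoreError("zero within-class variance everywhere")
    return numerator / denominator


def pcc_measure(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute Pearson correlation with the one-vs-rest class
    indicators; reduces to |r| against the 0/1 indicator for 2 classes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.ptp(x) == 0:
        raise UndefinedScoreError("constant column")
    C = int(y.max()) + 1
    if C < 2:
        raise UndefinedScoreError("need at least 2 classes")
    vals = []
    for c in range(C):
        ind = (y == c).astype(float)
        if np.ptp(ind) == 0:
            continue
        vals.append(abs(np.corrcoef(x, ind)[0, 1]))
    if not vals:
        raise UndefinedScoreError("labels are constant")
    return float(np.mean(vals))


def anova_f(x: np.ndarray, y: np.ndarray) -> float:
    """One-way F statistic: between-group MS over within-group MS."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise UndefinedScoreError("need at least 2 classes")
    n = len(x)
    grand = x.mean()
    ss_between = 0.0
    ss_within = 0.0
    for c in classes:
        g = x[y == c]
        ss_between += len(g) * (g.mean() - grand) ** 2
        ss_within += ((g - g.mean()) ** 2).sum()
    if ss_between == 0.0:
        return 0.0
    df_within = n - len(classes)
    if ss_within == 0.0 or df_within == 0:
        raise UndefinedScoreError("zero within-group variance")
    return float((ss_between / (len(classes) - 1)) / (ss_within / df_within))


def relieff(X: np.ndarray, y: np.ndarray, k: int = 10, m: int | None = None,
            seed: int = 0) -> ScoreVector:
    """Multi-class ReliefF weights W_f = a − b.

    For each of ``m`` sampled instances the k nearest same-class hits and,
    per other class, k nearest misses are found under Manhattan distance
    on range-normalized columns; miss contributions are weighted by
    P(C) / (1 − P(class(R_i))).  A sampled instance whose class has no
    other member contributes misses only (with a warning).  Weights lie
    in [−1, 1]; constant columns get weight 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    ranges = np.ptp(X, axis=0)
    safe = np.where(ranges > 0, ranges, 1.0)
    Xn = (X - X.min(axis=0)) / safe
    Xn[:, ranges == 0] = 0.0

    rng = np.random.default_rng(seed)
    if m is None or m >= n:
        sampled = np.arange(n)
    else:
        sampled = rng.choice(n, size=m, replace=False)
    m_eff = len(sampled)

    C = int(y.max()) + 1
    priors = np.bincount(y, minlength=C) / n
    D = cdist(Xn, Xn, metric="cityblock")
    W = np.zeros(d)
    for i in sampled:
        ci = y[i]
        order = np.argsort(D[i], kind="stable")
        order = order[order != i]
        hits = order[y[order] == ci][:k]
        if hits.size == 0:
            warnings.warn(
                f"class {ci} has a single member; instance {i} contributes "
                "misses only", stacklevel=2)
        else:
            W -= np.abs(Xn[hits] - Xn[i]).mean(axis=0) / m_eff
        denom = 1.0 - priors[ci]
        if denom <= 0:
            continue
        for c in range(C):
            if c == ci:
                continue
            misses = order[y[order] == c][:k]
            if misses.size == 0:
                continue
            weight = priors[c] / denom
            W += weight * np.abs(Xn[misses] - Xn[i]).mean(axis=0) / m_eff
    return ScoreVector("relieff", W)


def one_r(x_disc: np.ndarray, y: np.ndarray) -> tuple[dict[int, int], float]:
    """One-R rule for a single discretized column.

    Each bin is assigned its majority class (ties toward the lowest class
    code); the cumulative error is the fraction the rule misclassifies.
    """
    x_disc = np.asarray(x_disc, dtype=int)
    y = np.asarray(y, dtype=int)
    if x_disc.size == 0:
        raise ValueError("empty column")
    joint = DiscreteJoint.from_codes(x_disc, y)
    rule: dict[int, int] = {}
    correct = 0.0
    for b in range(joint.counts.shape[0]):
        row = joint.counts[b]
        if row.sum() == 0:
            continue
        c = int(np.argmax(row))          # argmax takes the lowest code on ties
        rule[b] = c
        correct += row[c]
    return rule, float(1.0 - correct / joint.n)


def _entropy_family_score(measure: str, codes: np.ndarray, y: np.ndarray,
                          n_bins: int, n_classes: int) -> float:
    joint = DiscreteJoint.from_codes(codes, y, n_bins=n_bins, n_classes=n_classes)
    if measure == "ig":
        return information_gain(joint)
    if measure == "gain_ratio":
        return gain_ratio(joint)
    return symmetric_uncertainty(joint)


def score_all(M: np.ndarray, y: np.ndarray, measure_name: str,
              n_bins: int = 10, seed: int = 0,
              relieff_k: int = 10, relieff_m: int | None = None) -> ScoreVector:
    """Apply one named measure column-wise over a matrix of columns.

    Entropy-based measures and One-R see the columns discretized into
    ``n_bins`` equal-width bins over [0, 1].  Columns on which a measure
    is undefined fall back to the measure's null value (0), except that a
    perfectly separating column with zero within-class spread gets the
    ``LARGE_SCORE`` sentinel; each fallback emits a warning.
    """
    if measure_name not in MEASURES:
        raise ValueError(f"unknown measure {measure_name!r}; choose from {MEASURES}")
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.isfinite(M).all():
        raise ValueError("columns must be finite")
    y = np.asarray(y, dtype=int)
    C = int(y.max()) + 1

    if measure_name == "relieff":
        k = min(relieff_k, max(1, int(np.bincount(y, minlength=C).max()) - 1))
        return relieff(M, y, k=k, m=relieff_m, seed=seed)

    scores = np.empty(M.shape[1])
    for j in range(M.shape[1]):
        col = M[:, j]
        try:
            if measure_name == "fisher":
                scores[j] = fisher_score(ClassStats.from_column(col, y, C))
            elif measure_name == "pcc":
                scores[j] = pcc_measure(col, y)
            elif measure_name == "anova":
                scores[j] = anova_f(col, y)
            elif measure_name == "one_r":
                _, err = one_r(discretize(col, n_bins, 0.0, 1.0), y)
                scores[j] = 1.0 - err
            else:
                codes = discretize(col, n_bins, 0.0, 1.0)
                scores[j] = _entropy_family_score(measure_name, codes, y,
                                                  n_bins, C)
        except UndefinedScoreError as exc:
            separated = _perfectly_separated(col, y)
            fallback = LARGE_SCORE if separated and measure_name in ("fisher", "anova") \
                else 0.0
            warnings.warn(
                f"{measure_name} undefined on column {j} ({exc}); "
                f"falling back to {fallback}", stacklevel=2)
            scores[j] = fallback
    return ScoreVector(measure_name, scores)


def _perfectly_separated(col: np.ndarray, y: np.ndarray) -> bool:
    """True when the column is constant within every class but the class
    means are not all equal (zero within-class spread, nonzero between)."""
    means = []
    for c in np.unique(y):
        g = col[y == c]
        if np.ptp(g) != 0:
            return False
        means.append(g[0])
    return np.ptp(np.asarray(means)) != 0
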