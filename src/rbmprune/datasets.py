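"""Synthetic labelled tabular datasets with known class-informative structure.

The generator emulates the statistical shape of small clinical
classification tables: mixed numeric / nominal / ordinal columns, class
imbalance (down to singleton classes), missing values, and redundant
(duplicated or constant) columns.  Ground truth — which columns carry
class signal — is retained on the generated dataset, so ranking and
pruning stages can be validated without any external download.

Class-conditional structure:

* informative numeric columns are Gaussian with equally spaced class
  means ``c * effect_size`` and unit within-class SD;
* informative nominal columns draw category codes from a per-class
  Dirichlet-perturbed distribution, with the perturbation scaled by
  ``effect_size``;
* informative ordinal columns discretize the shifted Gaussian latent
  into ordered codes;
* everything else is class-independent noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticSpec",
    "LabeledDataset",
    "InvalidSpecError",
    "generate",
    "profile",
    "write_csv",
    "read_csv",
    "PROFILES",
]

NUMERIC = "numeric"
NOMINAL = "nominal"
ORDINAL = "ordinal"
KINDS = (NUMERIC, NOMINAL, ORDINAL)


class InvalidSpecError(ValueError):
    """Raised when a SyntheticSpec is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative recipe for one synthetic labelled dataset.

    ``n_features`` counts the base columns; duplicated and constant
    columns are appended after them, so the emitted matrix has
    ``n_features + n_duplicate_features + n_constant_features`` columns.
    """

    n_instances: int
    n_features: int
    n_classes: int
    class_counts: tuple[int, ...]
    informative_idx: frozenset[int] = frozenset()
    effect_size: float = 1.0
    feature_kinds: tuple[str, ...] | None = None
    nominal_cardinality: int = 3
    missing_rate: float = 0.0
    n_duplicate_features: int = 0
    n_constant_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_instances <= 0 or self.n_features <= 0:
            raise InvalidSpecError("n_instances and n_features must be positive")
        if self.n_classes < 2:
            raise InvalidSpecError("need at least 2 classes")
        if len(self.class_counts) != self.n_classes:
            raise InvalidSpecError(
                f"class_counts has {len(self.class_counts)} entries, expected {self.n_classes}"
            )
        if sum(self.class_counts) != self.n_instances:
            raise InvalidSpecError(
                f"class_counts sum to {sum(self.class_counts)}, expected {self.n_instances}"
            )
        if any(c <= 0 for c in self.class_counts):
            raise InvalidSpecError("every class needs at least one instance")
        if not set(self.informative_idx) <= set(range(self.n_features)):
            raise InvalidSpecError("informative_idx outside base feature range")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise InvalidSpecError("missing_rate must be in [0, 1)")
        if self.nominal_cardinality < 2:
            raise InvalidSpecError("nominal_cardinality must be >= 2")
        if self.n_duplicate_features < 0 or self.n_constant_features < 0:
            raise InvalidSpecError("appended-feature counts must be >= 0")
        kinds = self.kinds()
        if len(kinds) != self.n_features or any(k not in KINDS for k in kinds):
            raise InvalidSpecError("feature_kinds must give a known kind per base column")

    def kinds(self) -> tuple[str, ...]:
        if self.feature_kinds is None:
            return (NUMERIC,) * self.n_features
        return tuple(self.feature_kinds)

    @property
    def n_columns(self) -> int:
        return self.n_features + self.n_duplicate_features + self.n_constant_features


@dataclass
class LabeledDataset:
    """Feature matrix with per-column kind tags, labels and a missing mask.

    ``X`` stores nominal/ordinal levels as small non-negative integer
    codes (as floats); missing entries are NaN exactly where
    ``missing_mask`` is True.  Labels are contiguous codes ``0..C-1``.
    """

    X: np.ndarray
    y: np.ndarray
    kinds: tuple[str, ...]
    missing_mask: np.ndarray
    truth: SyntheticSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape != self.missing_mask.shape:
            raise ValueError("missing_mask shape mismatch")
        if len(self.kinds) != self.X.shape[1]:
            raise ValueError("kinds length mismatch")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y length mismatch")
        if np.isnan(self.X[~self.missing_mask]).any():
            raise ValueError("NaN outside missing_mask")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.n else 0

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset (copy), preserving provenance."""
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx].copy(),
            y=self.y[idx].copy(),
            kinds=self.kinds,
            missing_mask=self.missing_mask[idx].copy(),
            truth=self.truth,
            meta=dict(self.meta),
        )

    def copy(self) -> "LabeledDataset":
        return self.take(np.arange(self.n))


def _nominal_class_probs(rng: np.random.Generator, card: int, n_classes: int,
                         effect_size: float) -> np.ndarray:
    """Per-class category distributions, Dirichlet-perturbed by effect size."""
    base = np.full(card, 1.0 / card)
    probs = np.empty((n_classes, card))
    for c in range(n_classes):
        pert = rng.dirichlet(np.ones(card))
        p = base + effect_size * pert
        probs[c] = p / p.sum()
    return probs


def _ordinal_codes(latent: np.ndarray, card: int) -> np.ndarray:
    """Cut a latent column at its empirical quantiles into ordered codes."""
    edges = np.quantile(latent, np.linspace(0, 1, card + 1)[1:-1])
    return np.searchsorted(edges, latent, side="left").astype(float)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw one dataset from ``spec``; bit-identical given the same spec."""
    rng = np.random.default_rng(spec.seed)
    n, C = spec.n_instances, spec.n_classes
    y = np.repeat(np.arange(C), spec.class_counts)
    kinds = list(spec.kinds())

    cols: list[np.ndarray] = []
    for j in range(spec.n_features):
        informative = j in spec.informative_idx
        kind = kinds[j]
        if kind == NOMINAL:
            if informative:
                probs = _nominal_class_probs(rng, spec.nominal_cardinality, C,
                                             spec.effect_size)
            else:
                probs = np.full((C, spec.nominal_cardinality),
                                1.0 / spec.nominal_cardinality)
            col = np.empty(n)
            for c in range(C):
                m = y == c
                col[m] = rng.choice(spec.nominal_cardinality, size=m.sum(), p=probs[c])
            cols.append(col)
        else:
            means = y * spec.effect_size if informative else np.zeros(n)
            latent = rng.normal(means, 1.0)
            if kind == ORDINAL:
                cols.append(_ordinal_codes(latent, spec.nominal_cardinality))
            else:
                cols.append(latent)

    for _ in range(spec.n_duplicate_features):
        src = int(rng.integers(spec.n_features))
        cols.append(cols[src].copy())
        kinds.append(kinds[src])
    for _ in range(spec.n_constant_features):
        cols.append(np.zeros(n))
        kinds.append(NUMERIC)

    X = np.column_stack(cols)
    mask = rng.random(X.shape) < spec.missing_rate
    X = X.copy()
    X[mask] = np.nan

    perm = rng.permutation(n)
    return LabeledDataset(X=X[perm], y=y[perm], kinds=tuple(kinds),
                          missing_mask=mask[perm], truth=spec)


#: Shapes and imbalance of the three study datasets (instances, base
#: features, class distribution).  Signal structure (which columns are
#: informative, effect size, missingness) is this package's choice of a
#: realistic emulation, not a property of the originals.
PROFILES: dict[str, SyntheticSpec] = {
    "breast": SyntheticSpec(
        n_instances=286, n_features=9, n_classes=2, class_counts=(201, 85),
        informative_idx=frozenset({0, 1, 2, 3, 4}), effect_size=2.0,
        feature_kinds=(NUMERIC,) * 6 + (NOMINAL, NOMINAL, ORDINAL),
        nominal_cardinality=3, missing_rate=0.01,
    ),
    "cervical": SyntheticSpec(
        n_instances=858, n_features=35, n_classes=2, class_counts=(803, 55),
        informative_idx=frozenset(range(10)), effect_size=2.0,
        feature_kinds=(NUMERIC,) * 30 + (NOMINAL,) * 4 + (ORDINAL,),
        nominal_cardinality=2, missing_rate=0.10,
    ),
    "primary": SyntheticSpec(
        n_instances=339, n_features=17, n_classes=21,
        class_counts=(84, 20, 9, 14, 39, 1, 14, 6, 2, 28, 16,
                      7, 24, 2, 1, 10, 29, 6, 2, 1, 24),
        informative_idx=frozenset({0, 1, 2, 3}), effect_size=1.0,
        feature_kinds=(NUMERIC,) * 4 + (NOMINAL,) * 11 + (ORDINAL,) * 2,
        nominal_cardinality=2, missing_rate=0.04,
    ),
}


def profile(name: str, seed: int = 0) -> SyntheticSpec:
    """Spec matching one of the three study datasets' printed shapes."""
    try:
        base = PROFILES[name]
    except KeyError:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
    return dataclasses.replace(base, seed=seed)


def write_csv(data: LabeledDataset, path, class_column: str = "class") -> None:
    """Emit the dataset as CSV: header row, empty field = missing value."""
    frame = pd.DataFrame(
        {f"f{j}": data.X[:, j] for j in range(data.d)}
    )
    for j, kind in enumerate(data.kinds):
        if kind != NUMERIC:
            col = frame[f"f{j}"]
            frame[f"f{j}"] = col.astype("Int64")
    frame[class_column] = data.y
    frame.to_csv(path, index=False)


def read_csv(path, class_column: str = "class",
             kinds: tuple[str, ...] | None = None) -> LabeledDataset:
    """Read a labelled CSV (header row, empty field = missing).

    Column kinds may be supplied; otherwise integer-valued columns are
    tagged nominal and the rest numeric.
    """
    frame = pd.read_csv(path)
    if class_column not in frame.columns:
        raise ValueError(f"class column {class_column!r} not found")
    y_raw = frame.pop(class_column)
    if y_raw.isna().any():
        raise ValueError("missing values in the class column are not supported")
    codes, _ = pd.factorize(y_raw, sort=True)
    X = frame.to_numpy(dtype=float)
    mask = np.isnan(X)
    if kinds is None:
        inferred = []
        for j in range(X.shape[1]):
            obs = X[~mask[:, j], j]
            is_codes = obs.size > 0 and np.all(obs == np.round(obs)) and obs.min() >= 0
            inferred.append(NOMINAL if is_codes else NUMERIC)
        kinds = tuple(inferred)
    return LabeledDataset(X=X, y=codes, kinds=tuple(kinds), missing_mask=mask)
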