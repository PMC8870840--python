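import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rbmprune.datasets import SyntheticSpec, generate


@pytest.fixture
def small_planted():
    """150x6 two-class dataset with 3 informative columns (effect 2)."""
    spec = SyntheticSpec(n_instances=150, n_features=6, n_classes=2,
                         class_counts=(75, 75),
                         informative_idx=frozenset({0, 1, 2}),
                         effect_size=2.0, seed=7)
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_joint_tables(n_tables: int, seed: int, max_side: int = 6):
    """Random count tables up to max_side x max_side, each with a
    positive total; some cells zero."""
    g = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        shape = (int(g.integers(2, max_side + 1)), int(g.integers(2, max_side + 1)))
        counts = g.integers(0, 12, size=shape).astype(float)
        if counts.sum() > 0:
            tables.append(counts)
    return tables
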