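"""Experiment grid: configuration, validation and execution.

Runs the full study protocol — for each hidden-layer size in the
multiplier grid and each selected measure, a repeated cross-validated
pruning sweep — on a synthetic profile or a user CSV, persisting long and
summary CSV tables plus a JSON run manifest that round-trips the
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import datasets
from .measures import MEASURES
from .prune_eval import HIDDEN_MULTIPLIERS, KNNConfig, hidden_grid, sweep
from .rbm import TrainConfig

__all__ = ["ExperimentConfig", "ConfigError", "validate", "run",
           "retained_grid", "load_config", "save_config"]

logger = logging.getLogger("rbmprune")


class ConfigError(ValueError):
    def __init__(self, problems: list[str]):
        super().__init__("invalid configuration: " + "; ".join(problems))
        self.problems = problems


@dataclass
class ExperimentConfig:
    source: str = "breast"             # profile name or CSV path
    class_column: str = "class"
    measures: tuple[str, ...] = MEASURES
    hidden_multipliers: tuple[float, ...] = HIDDEN_MULTIPLIERS
    n_repetitions: int = 10
    n_folds: int = 10
    knn_k: int = 5
    knn_metric: str = "euclidean"
    learning_rate: float = 0.01
    epochs: int = 100
    batch_size: int = 32
    cd_steps: int = 1
    weight_init_sd: float = 0.01
    seed: int = 0
    output_dir: str = "rbmprune_results"

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["measures"] = list(self.measures)
        out["hidden_multipliers"] = list(self.hidden_multipliers)
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError([f"unknown config keys: {sorted(unknown)}"])
        raw = dict(raw)
        for key in ("measures", "hidden_multipliers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def validate(cfg: ExperimentConfig) -> list[str]:
    """Return every detectable problem (empty list = valid)."""
    problems: list[str] = []
    if not cfg.measures:
        problems.append("measure list is empty")
    for m in cfg.measures:
        if m not in MEASURES:
            problems.append(f"unknown measure {m!r}")
    if cfg.source not in datasets.PROFILES and not Path(cfg.source).is_file():
        problems.append(f"source {cfg.source!r} is neither a profile nor a file")
    if cfg.n_folds < 2:
        problems.append("n_folds must be >= 2")
    if cfg.n_repetitions < 1:
        problems.append("n_repetitions must be >= 1")
    if not cfg.hidden_multipliers:
        problems.append("hidden_multipliers is empty")
    if cfg.knn_k < 1:
        problems.append("knn_k must be >= 1")
    if cfg.knn_metric not in ("euclidean", "chebyshev", "manhattan"):
        problems.append(f"unknown knn metric {cfg.knn_metric!r}")
    if cfg.learning_rate <= 0:
        problems.append("learning_rate must be > 0")
    if cfg.epochs < 0 or cfg.batch_size < 1 or cfg.cd_steps < 1:
        problems.append("invalid RBM training settings")
    if cfg.weight_init_sd < 0:
        problems.append("weight_init_sd must be >= 0")
    return problems


def retained_grid(h: int, max_dense: int = 40, n_sparse: int = 20) -> tuple[int, ...]:
    """Retained-count axis: every count up to ``max_dense`` hidden units,
    otherwise ``n_sparse`` evenly spaced counts including 1 and h."""
    if h <= max_dense:
        return tuple(range(1, h + 1))
    pts = np.unique(np.round(np.linspace(1, h, n_sparse)).astype(int))
    return tuple(int(p) for p in pts)


def _load_data(cfg: ExperimentConfig, seed: int) -> datasets.LabeledDataset:
    if cfg.source in datasets.PROFILES:
        return datasets.generate(datasets.profile(cfg.source, seed=seed))
    return datasets.read_csv(cfg.source, class_column=cfg.class_column)


def run(cfg: ExperimentConfig) -> dict:
    """Execute the full grid; returns the manifest (also written to JSON)."""
    problems = validate(cfg)
    if problems:
        raise ConfigError(problems)

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    started = time.time()
    try:
        seq = np.random.SeedSequence(cfg.seed)
        data_seed = int(seq.generate_state(1)[0] % 2**31)
        data = _load_data(cfg, data_seed)
        logger.info("loaded %s: %d instances, %d columns, %d classes",
                    cfg.source, data.n, data.d, data.n_classes)

        rbm_cfg = TrainConfig(learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                              batch_size=cfg.batch_size, cd_steps=cfg.cd_steps,
                              weight_init_sd=cfg.weight_init_sd, seed=cfg.seed)
        knn_cfg = KNNConfig(k=cfg.knn_k, metric=cfg.knn_metric)
        grid = hidden_grid(data.d, cfg.hidden_multipliers)

        files: list[str] = []
        children = seq.spawn(len(grid) * len(cfg.measures))
        cell = 0
        for h in grid:
            counts = retained_grid(h)
            for measure in cfg.measures:
                cell_seed = int(children[cell].generate_state(1)[0] % 2**31)
                cell += 1
                logger.info("sweep: hidden=%d measure=%s", h, measure)
                result = sweep(data, rbm_cfg, knn_cfg, measure, counts,
                               cfg.n_repetitions, cfg.n_folds, cell_seed,
                               hidden_size=h)
                stem = f"{measure}_h{h}"
                result.summary_frame().to_csv(out / f"{stem}_summary.csv",
                                              index=False)
                result.long_frame().to_csv(out / f"{stem}_long.csv", index=False)
                files += [f"{stem}_summary.csv", f"{stem}_long.csv"]

        manifest = {
            "config": cfg.to_dict(),
            "hidden_grid": list(grid),
            "data": {"n": data.n, "d": data.d, "n_classes": data.n_classes},
            "files": files,
            "wall_clock_s": round(time.time() - started, 3),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
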