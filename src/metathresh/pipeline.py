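"""End-to-end segmentation pipeline and the objective x optimizer method grid.

:func:`segment` wires the full flow for one image: histogram -> metaheuristic
threshold optimization -> (k+1)-class label map -> binary vessel mask.
:func:`run_grid` repeats it for every (objective, optimizer) cell over n runs
that differ only in the optimizer seed (run r uses ``base seed + r``, and the
same seed sequence is reused in every cell so cells form a controlled
comparison), scoring each run against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .evaluation import METRIC_COLUMNS, MetricsReport, build_report
from .histogram import DEFAULT_LEVELS, apply_thresholds, binarize_labels, compute_histogram
from .objectives import OBJECTIVE_NAMES, make_objective
from .optimizers import ALGORITHMS, OptimizationResult, OptimizerConfig, SearchSpace, optimize

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "SegmentationOutput", "segment", "run_grid", "comparison_table", "GRID_CELLS"]

#: the six method cells, in report order
GRID_CELLS = tuple((obj, opt) for obj in OBJECTIVE_NAMES for opt in ALGORITHMS)

_METHOD_LABEL = {"sef": "SEF", "otsu": "MLOT"}


@dataclass(frozen=True)
class RunConfig:
    """One segmentation run: objective, optimizer, k thresholds, vessel rule."""

    objective: str = "otsu"
    optimizer: str = "cs"
    k: int = 2
    levels: int = DEFAULT_LEVELS
    optimizer_config: OptimizerConfig = field(default_factory=OptimizerConfig)
    vessel_labels: tuple[int, ...] | None = None  # None -> top (brightest) class
    n_runs: int = 5

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVE_NAMES:
            raise ValueError(f"objective must be one of {OBJECTIVE_NAMES}")
        if self.optimizer not in ALGORITHMS:
            raise ValueError(f"optimizer must be one of {ALGORITHMS}")
        if not 1 <= self.k <= self.levels - 2:
            raise ValueError(f"k must lie in [1, {self.levels - 2}]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        object.__setattr__(
            self, "optimizer_config", replace(self.optimizer_config, algorithm=self.optimizer)
        )


@dataclass(frozen=True)
class SegmentationOutput:
    thresholds: np.ndarray
    labels: np.ndarray
    mask: np.ndarray
    result: OptimizationResult


def segment(image: np.ndarray, config: RunConfig) -> SegmentationOutput:
    """Segment one grayscale image under ``config``.

    Composes histogram computation, the selected metaheuristic maximizing the
    selected objective, threshold application, and vessel binarization.
    """
    hist = compute_histogram(image, levels=config.levels)
    objective = make_objective(hist, config.objective)
    space = SearchSpace.for_levels(config.k, config.levels)
    result = optimize(objective, space, config.optimizer_config)
    labels = apply_thresholds(image, result.best_thresholds, levels=config.levels)
    mask = binarize_labels(labels, k=config.k, vessel_labels=config.vessel_labels)
    logger.info(
        "segment: %s+%s k=%d thresholds=%s fitness=%.6g (%d evals)",
        config.objective,
        config.optimizer,
        config.k,
        result.best_thresholds.tolist(),
        result.best_fitness,
        result.evaluations,
    )
    return SegmentationOutput(
        thresholds=result.best_thresholds, labels=labels, mask=mask, result=result
    )


def run_grid(
    image: np.ndarray,
    truth: np.ndarray,
    base: RunConfig | None = None,
    n_runs: int | None = None,
    base_seed: int | None = None,
) -> dict[tuple[str, str], MetricsReport]:
    """Score every (objective, optimizer) cell over n seed-varied runs.

    Run r in every cell uses optimizer seed ``base_seed + r``, so cells
    differ only in the objective/optimizer pair.  Returns one
    :class:`MetricsReport` (n rows + average) per cell.
    """
    if truth is None:
        raise ValueError(
            "ground truth is required for the grid; generate a phantom to obtain one"
        )
    base = base or RunConfig()
    n_runs = n_runs if n_runs is not None else base.n_runs
    base_seed = base_seed if base_seed is not None else base.optimizer_config.seed
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != np.asarray(image).shape:
        raise ValueError("truth mask shape must match the image")

    reports: dict[tuple[str, str], MetricsReport] = {}
    for objective, optimizer in GRID_CELLS:
        runs = []
        for r in range(n_runs):
            cfg = replace(
                base,
                objective=objective,
                optimizer=optimizer,
                optimizer_config=base.optimizer_config.with_seed(base_seed + r),
            )
            out = segment(image, cfg)
            runs.append((out.mask, truth))
        reports[(objective, optimizer)] = build_report(runs)
    return reports


def comparison_table(
    reports: dict[tuple[str, str], MetricsReport],
    order: Iterable[tuple[str, str]] = GRID_CELLS,
) -> pd.DataFrame:
    """Average-row comparison across methods (one row per cell, four metrics)."""
    rows, index = [], []
    for cell in order:
        rep = reports[cell]
        index.append(f"{_METHOD_LABEL[cell[0]]}-{cell[1].upper()}")
        rows.append(rep.average)
    df = pd.DataFrame(rows, index=index, columns=list(METRIC_COLUMNS))
    df.index.name = "Methods"
    return df
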