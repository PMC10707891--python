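"""Monte-Carlo operating characteristics of the filtering cascade.

The cascade's thresholds are genetic idealizations — an exact mutant-bulk
index of 1 ignores sequencing error, and the wild-type bound relies on the
realized composition of a finite bulk.  This module quantifies what those
idealizations cost: across seeded replicates of the simulator it measures
sensitivity (how often the causal site survives), false positives by
background class (unlinked / linked / fixed, whose failure modes differ),
and the size of the survivor set, optionally swept over design parameters
such as depth, bulk size and error rate.
"""

from __future__ import annotations

import itertools
import json
import statistics
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .index import STAGE_NAMES, FilterCriteria, run_cascade
from .simulate import SimulationConfig, simulate_experiment

__all__ = [
    "PowerReport",
    "evaluate",
    "mut_index_one_rate",
    "sweep",
]


@dataclass(frozen=True)
class PowerReport:
    """Aggregate cascade performance over simulation replicates.

    ``sensitivity`` — fraction of replicates whose survivor set contains
    the causal site.  ``mean_false_positives`` — mean surviving non-causal
    sites per replicate, with ``fp_by_class`` splitting that mean across
    unlinked, linked (within the cM window used) and fixed background.
    ``median_survivors`` — low median of the survivor-set size (an actual
    replicate value).  ``stage_means`` — mean survivor count per cascade
    stage.
    """

    n_replicates: int
    sensitivity: float
    mean_false_positives: float
    median_survivors: int
    stage_means: dict[str, float]
    fp_by_class: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "sensitivity": self.sensitivity,
            "mean_false_positives": self.mean_false_positives,
            "median_survivors": self.median_survivors,
            "stage_means": self.stage_means,
            "fp_by_class": self.fp_by_class,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _replicate_rng(seed: int, i: int) -> np.random.Generator:
    # deterministic in (seed, i), independent of execution order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def evaluate(
    config: SimulationConfig,
    n_replicates: int,
    criteria: FilterCriteria = FilterCriteria(),
    seed: int = 0,
    linked_window_cm: float = 10.0,
) -> PowerReport:
    """Simulate and filter ``n_replicates`` times; aggregate the outcomes.

    Replicate i draws its random stream from a deterministic function of
    (seed, i), so results are reproducible and independent of execution
    order.  Deterministic given ``seed``.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    hits = 0
    survivor_sizes: list[int] = []
    fp_totals = {"unlinked": 0, "linked": 0, "fixed": 0}
    stage_totals = dict.fromkeys(STAGE_NAMES, 0)
    for i in range(n_replicates):
        variants, truth = simulate_experiment(config, rng=_replicate_rng(seed, i))
        report = run_cascade(variants, config.design, criteria)
        for sc in report.stage_counts:
            stage_totals[sc.name] += sc.n_total
        causal_hit = False
        for iv in report.survivors:
            cls = truth.site_class(iv.variant.chrom, iv.variant.pos, linked_window_cm)
            if cls == "causal":
                causal_hit = True
            else:
                fp_totals[cls] += 1
        hits += causal_hit
        survivor_sizes.append(len(report.survivors))
    n = n_replicates
    return PowerReport(
        n_replicates=n,
        sensitivity=hits / n,
        mean_false_positives=sum(fp_totals.values()) / n,
        median_survivors=int(statistics.median_low(survivor_sizes)),
        stage_means={name: total / n for name, total in stage_totals.items()},
        fp_by_class={cls: total / n for cls, total in fp_totals.items()},
    )


_SWEEP_PARAMS = ("mean_depth", "bulk_size", "error_rate")


def _apply_point(config: SimulationConfig, point: Mapping[str, float]) -> SimulationConfig:
    cfg = config
    for key, value in point.items():
        if key == "mean_depth":
            cfg = replace(
                cfg,
                design=replace(cfg.design, mean_depth_wt=value, mean_depth_mut=value),
            )
        elif key == "bulk_size":
            size = int(value)
            cfg = replace(cfg, design=replace(cfg.design, n_wt=size, n_mut=size))
            if cfg.n_progeny < 8 * size:
                cfg = replace(cfg, n_progeny=8 * size)
        elif key == "error_rate":
            cfg = replace(cfg, error_rate=float(value))
        else:
            raise ConfigurationError(
                f"unknown sweep parameter {key!r}; supported: {_SWEEP_PARAMS}"
            )
    return cfg


def sweep(
    config: SimulationConfig,
    grid: Mapping[str, Sequence[float]],
    n_replicates: int,
    criteria: FilterCriteria = FilterCriteria(),
    seed: int = 0,
    linked_window_cm: float = 10.0,
) -> pd.DataFrame:
    """Evaluate the cascade over a parameter grid (one row per grid point).

    Every grid point reuses the same base seed (common random numbers), so
    paired comparisons across points are low-variance.  Supported
    parameters: ``mean_depth`` (sets both bulks), ``bulk_size`` (sets both
    bulks, growing the progeny cohort if needed) and ``error_rate``.
    """
    if not grid:
        raise ConfigurationError("sweep grid must be non-empty")
    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, values))
        report = evaluate(
            _apply_point(config, point),
            n_replicates,
            criteria,
            seed=seed,
            linked_window_cm=linked_window_cm,
        )
        row = dict(point)
        row.update(
            sensitivity=report.sensitivity,
            mean_false_positives=report.mean_false_positives,
            median_survivors=report.median_survivors,
        )
        for name, mean in report.stage_means.items():
            row[f"mean_{name}"] = mean
        for cls, mean in report.fp_by_class.items():
            row[f"fp_{cls}"] = mean
        rows.append(row)
    return pd.DataFrame(rows)


def mut_index_one_rate(
    depth: int, error_rate: float, n_trials: int, seed: int = 0
) -> float:
    """Monte-Carlo estimate of P(mutant-bulk index = 1) at fixed depth.

    At a site fixed for the mutant allele (bulk frequency 1) covered by
    exactly ``depth`` reads with per-read miscall rate ``error_rate``, the
    index equals 1 only when no read is miscalled, so the exact value is
    (1 - error_rate) ** depth; this estimator uses the simulator's binomial
    read model and serves as its Monte-Carlo counterpart.
    """
    rng = np.random.default_rng(seed)
    alt = rng.binomial(depth, 1.0 - error_rate, size=n_trials)
    return float(np.mean(alt == depth))
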