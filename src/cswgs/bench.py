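"""Hardware-independent benchmark protocols.

Two protocols mirror how real-time hologram engines are judged, with
wall-clock time replaced everywhere by pixel-evaluation counts (the cost
unit the algorithms' own scaling formulas are written in, and the only one
that is reproducible across machines):

* convergence-to-target — how much work each algorithm needs before its
  uniformity reaches a target fraction of a fully converged reference
  (200 WGS iterations);
* fixed budget — the best quality each algorithm can deliver within a fixed
  number of pixel evaluations, emulating a fixed SLM refresh window.

:func:`benchmark_sweep` runs a full factorial of scenarios x algorithms x
compression factors with seed replicates and returns a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .algorithms import (
    AlgorithmConfig,
    RunTrace,
    cswgs_hologram,
    evaluation_cost,
    spot_basis,
    wgs_hologram,
)
from .metrics import QualityReport
from .optics import PupilModel, SpotPattern
from .patterns import PatternSpec, make_pattern

__all__ = [
    "BenchmarkResult",
    "convergence_reference",
    "run_to_target",
    "run_fixed_budget",
    "benchmark_sweep",
    "best_compression",
    "REFERENCE_ITERATIONS",
]

#: Iteration count of the maximum-performance WGS reference.
REFERENCE_ITERATIONS = 200


@dataclass
class BenchmarkResult:
    """One benchmark cell: what was run and what it achieved."""

    scenario: str
    algorithm: str
    compression: float
    iterations: int
    cost: int  # pixel evaluations per projection direction
    converged: bool
    report: QualityReport
    seed_phases: int
    seed_subset: int

    def row(self) -> dict:
        return {
            "scenario": self.scenario,
            "algorithm": self.algorithm,
            "compression": self.compression,
            "iterations": self.iterations,
            "cost": self.cost,
            "converged": self.converged,
            "e": self.report.e,
            "u": self.report.u,
            "v": self.report.v,
            "seed_phases": self.seed_phases,
            "seed_subset": self.seed_subset,
        }


def convergence_reference(
    pattern: SpotPattern,
    pupil: PupilModel,
    seed: int = 0,
    iterations: int = REFERENCE_ITERATIONS,
    basis: np.ndarray | None = None,
) -> tuple[QualityReport, RunTrace]:
    """Maximum-performance reference: a long full-sampling WGS run."""
    config = AlgorithmConfig(algorithm="wgs", iterations=iterations, seed_phases=seed)
    _, trace = wgs_hologram(pattern, pupil, config, basis=basis)
    return trace.reports[-1], trace


def run_to_target(
    pattern: SpotPattern,
    pupil: PupilModel,
    config: AlgorithmConfig,
    target_fraction: float,
    u_reference: float,
    max_iterations: int = REFERENCE_ITERATIONS,
    scenario: str = "",
    basis: np.ndarray | None = None,
) -> BenchmarkResult:
    """Smallest iteration count whose final uniformity reaches the target.

    The target is ``target_fraction * u_reference``.  For WGS a single run
    at ``max_iterations`` suffices: the quality recorded at iteration j is
    exactly what a run stopped after j+1 iterations would deliver.  CS-WGS
    ends with full-sampling polish iterations whose effect depends on the
    total count, so candidate counts are scanned (compressed work is cheap).
    An unreachable target is reported with ``converged=False``, not raised.
    """
    if not (0.0 < target_fraction <= 1.0):
        raise ValueError("target_fraction must lie in (0, 1]")
    target = target_fraction * u_reference
    m, n = pupil.n_pixels, pattern.n_spots
    if basis is None:
        basis = spot_basis(pattern, pupil)

    if config.algorithm in ("rs", "wgs"):
        probe = replace(config, algorithm="wgs", iterations=max_iterations)
        _, trace = wgs_hologram(pattern, pupil, probe, basis=basis)
        u_per_iter = trace.uniformities()
        hits = np.nonzero(u_per_iter >= target)[0]
        if config.algorithm == "rs":
            converged = bool(u_per_iter[0] >= target)
            iters = 1
            report = trace.reports[0]
        elif hits.size:
            converged, iters, report = True, int(hits[0]) + 1, trace.reports[int(hits[0])]
        else:
            converged, iters, report = False, max_iterations, trace.reports[-1]
        cost = evaluation_cost(replace(config, iterations=iters), m, n)
        return BenchmarkResult(
            scenario, config.algorithm, 1.0, iters, cost, converged, report,
            config.seed_phases, config.seed_subset,
        )

    # CS-WGS: rerun per candidate iteration count
    start = config.terminal_full + 1 if config.compression < 1.0 else 1
    last = None
    for iters in range(start, max_iterations + 1):
        trial = replace(config, iterations=iters)
        _, trace = cswgs_hologram(pattern, pupil, trial, basis=basis)
        report = trace.final_report
        last = (iters, report)
        if report.u >= target:
            cost = evaluation_cost(trial, m, n)
            return BenchmarkResult(
                scenario, "cswgs", config.compression, iters, cost, True, report,
                config.seed_phases, config.seed_subset,
            )
    iters, report = last
    cost = evaluation_cost(replace(config, iterations=iters), m, n)
    return BenchmarkResult(
        scenario, "cswgs", config.compression, iters, cost, False, report,
        config.seed_phases, config.seed_subset,
    )


def max_iterations_within(config: AlgorithmConfig, budget: int, m: int, n: int) -> int:
    """Largest iteration count whose predicted cost fits the budget."""
    if budget < m * n:
        raise ValueError("budget is below the cost of a single RS hologram")
    if config.algorithm == "rs":
        return 1
    if config.algorithm == "wgs" or config.compression >= 1.0:
        return max(1, budget // (m * n))
    subset = int(np.ceil(config.compression * m))
    full = config.terminal_full
    minimal = full * m * n + subset * n  # terminal polish + one compressed pass
    if budget < minimal:
        # cannot afford even the minimal compressed run: degrade to full iterations
        return max(1, budget // (m * n))
    return full + (budget - full * m * n) // (subset * n)


def run_fixed_budget(
    pattern: SpotPattern,
    pupil: PupilModel,
    config: AlgorithmConfig,
    budget_evaluations: int,
    scenario: str = "",
    basis: np.ndarray | None = None,
) -> BenchmarkResult:
    """Best quality achievable within a pixel-evaluation budget.

    The budget is per projection direction, the same unit as
    :func:`cswgs.algorithms.evaluation_cost`.  The iteration count is the
    largest whose predicted cost fits; a CS-WGS budget too small for even
    the minimal compressed schedule falls back to plain full-sampling
    iterations (the compressed schedule needs its terminal polish).
    """
    m, n = pupil.n_pixels, pattern.n_spots
    iters = max_iterations_within(config, budget_evaluations, m, n)
    algorithm = config.algorithm
    if algorithm == "cswgs" and (
        config.compression >= 1.0 or iters < config.terminal_full + 1
    ):
        algorithm = "wgs"
    if algorithm == "rs":
        algorithm, iters = "wgs", 1
    run_cfg = replace(config, algorithm=algorithm, iterations=iters)
    runner = cswgs_hologram if run_cfg.algorithm == "cswgs" else wgs_hologram
    _, trace = runner(pattern, pupil, run_cfg, basis=basis)
    cost = evaluation_cost(run_cfg, m, n)
    assert trace.backward_evals == cost <= budget_evaluations
    return BenchmarkResult(
        scenario, config.algorithm, config.compression if config.algorithm == "cswgs" else 1.0,
        iters, cost, True, trace.final_report, config.seed_phases, config.seed_subset,
    )


def benchmark_sweep(
    scenarios: Sequence[PatternSpec],
    algorithms: Sequence[str],
    compressions: Sequence[float],
    replicates: int,
    pupil: PupilModel,
    protocol: str = "target",
    target_fraction: float = 0.92,
    budget_evaluations: int | None = None,
    budget_full_iterations: float = 3.0,
    max_iterations: int = REFERENCE_ITERATIONS,
    reference_iterations: int = REFERENCE_ITERATIONS,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Full factorial sweep; returns one tidy row per run.

    Replicates differ only in the random initial phase offsets (and subset
    permutation), seeded deterministically from ``base_seed``.  Compression
    factors apply to CS-WGS only; RS and WGS contribute one cell each.
    With ``protocol="target"`` each cell reports the work needed to reach
    ``target_fraction`` of the per-replicate 200-iteration WGS reference
    uniformity; with ``protocol="budget"`` each cell reports quality within
    a fixed evaluation budget (default: the cost of
    ``budget_full_iterations`` full WGS iterations).
    """
    if protocol not in ("target", "budget"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if not scenarios or not algorithms or not compressions:
        raise ValueError("scenario, algorithm and compression lists must be non-empty")
    rows = []
    for spec in scenarios:
        pattern = make_pattern(spec)
        basis = spot_basis(pattern, pupil)
        m, n = pupil.n_pixels, pattern.n_spots
        budget = budget_evaluations
        if protocol == "budget" and budget is None:
            budget = int(budget_full_iterations * m * n)
        for rep in range(replicates):
            seed_phases = base_seed + rep
            seed_subset = base_seed + 100_003 + rep
            if protocol == "target":
                u_ref, _ = convergence_reference(
                    pattern, pupil, seed=seed_phases,
                    iterations=reference_iterations, basis=basis,
                )
                u_ref = u_ref.u
            for algorithm in algorithms:
                cells = compressions if algorithm == "cswgs" else [1.0]
                for c in cells:
                    config = AlgorithmConfig(
                        algorithm=algorithm,
                        iterations=3 if algorithm == "cswgs" else 1,
                        compression=c if algorithm == "cswgs" else 1.0,
                        seed_phases=seed_phases,
                        seed_subset=seed_subset,
                    )
                    if protocol == "target":
                        result = run_to_target(
                            pattern, pupil, config, target_fraction, u_ref,
                            max_iterations=max_iterations, scenario=spec.label, basis=basis,
                        )
                    else:
                        result = run_fixed_budget(
                            pattern, pupil, config, budget,
                            scenario=spec.label, basis=basis,
                        )
                    row = result.row()
                    row["replicate"] = rep
                    if protocol == "target":
                        row["u_reference"] = u_ref
                        row["target_fraction"] = target_fraction
                    else:
                        row["budget"] = budget
                    rows.append(row)
    return pd.DataFrame(rows)


def best_compression(sweep: pd.DataFrame, by: str = "u") -> pd.DataFrame:
    """Per scenario, the CS-WGS compression with the best mean metric.

    Mirrors the benchmark convention of reporting only the best-performing
    compression factor per scenario.
    """
    cs = sweep[sweep["algorithm"] == "cswgs"]
    grouped = cs.groupby(["scenario", "compression"])[by].mean().reset_index()
    idx = grouped.groupby("scenario")[by].idxmax()
    return grouped.loc[idx].reset_index(drop=True)
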