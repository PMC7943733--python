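"""Hologram synthesis: random superposition (RS), weighted Gerchberg-Saxton
(WGS), and compressed-sensing WGS (CS-WGS).

All three share one iteration engine.  Iteration 0 builds the RS hologram:
random spot phase offsets ``theta_n`` and target amplitudes, superposed and
reduced to phase.  Each later iteration projects the current hologram onto
the spots (forward fields ``E_n``), updates per-spot weights so that spots
receiving too little power are boosted,

    w_n <- w_n * mean_m(|E_m|) / |E_n|        (uniform-target form)

locks ``theta_n`` to ``arg(E_n)``, and re-superposes.  CS-WGS runs the same
loop but evaluates both projections on a random pixel subset of size
``ceil(c * M)`` for all but the final iterations, which run at full sampling
to polish convergence and produce the phase on every pixel.  Its cost per
projection direction is ``2*M*N + c*M*N*(I - 2)`` pixel evaluations instead
of WGS's ``M*N*I`` — asymptotically the cost of RS while retaining WGS
quality.

Cost accounting is explicit: every projection adds ``(pixels visited) * N``
to the run trace's counters, and :func:`evaluation_cost` predicts the totals
exactly, so benchmarks can budget work in hardware-independent units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import Literal

import numpy as np

from .metrics import QualityReport, quality_report
from .optics import (
    Hologram,
    PupilModel,
    SpotFields,
    SpotPattern,
    spot_phase_matrix,
    wrap_phase,
)

__all__ = [
    "AlgorithmConfig",
    "CompressionPlan",
    "RunTrace",
    "rs_hologram",
    "weight_update",
    "wgs_hologram",
    "cswgs_hologram",
    "evaluation_cost",
    "WEIGHT_CAP",
]

#: Cap on individual weight factors; reached only when a spot field collapses
#: to (near) zero, e.g. on degenerate early iterates of symmetric grids.
WEIGHT_CAP = 1.0e6


@dataclass(frozen=True)
class AlgorithmConfig:
    """Algorithm selection and all knobs that determine a run bit-for-bit.

    Parameters
    ----------
    algorithm
        ``"rs"``, ``"wgs"`` or ``"cswgs"``.
    iterations
        Total iteration count I (iteration 0 is the RS start).  For CS-WGS
        with compression < 1 at least ``terminal_full + 1``.
    compression
        Fraction c of aperture pixels used by compressed projections,
        in (0, 1].  Benchmarks use powers of two from 1/2 down to 1/256.
    seed_phases, seed_subset
        Independent seed streams for the random initial phase offsets and
        for the pixel-subset permutation.
    weight_mode
        ``"target_normalized"`` (default): weights equalise ``|E_n| / a0_n``,
        the fixed point being power shares proportional to the targets.
        ``"literal"``: weights equalise raw ``|E_n|``, appropriate for
        uniform targets only.
    terminal_full
        Number of trailing iterations run at full sampling (2, or 1 for the
        narrower final-polish variant).
    subset_mode
        ``"fixed"`` (default): one seeded permutation drawn at start, its
        prefix reused by every compressed iteration.  ``"redraw"``: a fresh
        subset each compressed iteration.
    """

    algorithm: Literal["rs", "wgs", "cswgs"] = "wgs"
    iterations: int = 1
    compression: float = 1.0
    seed_phases: int = 0
    seed_subset: int = 0
    weight_mode: Literal["target_normalized", "literal"] = "target_normalized"
    terminal_full: int = 2
    subset_mode: Literal["fixed", "redraw"] = "fixed"

    def __post_init__(self) -> None:
        if self.algorithm not in ("rs", "wgs", "cswgs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 < self.compression <= 1.0):
            raise ValueError("compression must lie in (0, 1]")
        if self.terminal_full not in (1, 2):
            raise ValueError("terminal_full must be 1 or 2")
        if self.subset_mode not in ("fixed", "redraw"):
            raise ValueError(f"unknown subset_mode {self.subset_mode!r}")
        if self.weight_mode not in ("target_normalized", "literal"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if (
            self.algorithm == "cswgs"
            and self.compression < 1.0
            and self.iterations < self.terminal_full + 1
        ):
            raise ValueError(
                "CS-WGS with compression < 1 needs at least "
                f"{self.terminal_full + 1} iterations"
            )

    def with_iterations(self, iterations: int) -> "AlgorithmConfig":
        return replace(self, iterations=iterations)


class CompressionPlan:
    """Which pixels each iteration of a CS-WGS run visits.

    A seeded permutation of the active set is drawn once; compressed
    iterations use its prefix of length ``ceil(c * M)`` (identical across
    iterations in ``"fixed"`` mode, redrawn per iteration in ``"redraw"``
    mode).  The trailing ``terminal_full`` iterations use all of Omega.
    """

    def __init__(
        self,
        n_pixels: int,
        compression: float,
        iterations: int,
        seed: int = 0,
        terminal_full: int = 2,
        mode: str = "fixed",
    ) -> None:
        if not (0.0 < compression <= 1.0):
            raise ValueError("compression must lie in (0, 1]")
        self.n_pixels = int(n_pixels)
        self.compression = float(compression)
        self.iterations = int(iterations)
        self.seed = int(seed)
        self.terminal_full = int(terminal_full)
        self.mode = mode
        self.subset_size = int(np.ceil(self.compression * self.n_pixels))
        self._prefix = None
        if self.subset_size < self.n_pixels and mode == "fixed":
            perm = np.random.default_rng(self.seed).permutation(self.n_pixels)
            self._prefix = perm[: self.subset_size]

    def is_full(self, iteration: int) -> bool:
        return (
            self.subset_size >= self.n_pixels
            or iteration >= self.iterations - self.terminal_full
        )

    def indices_for(self, iteration: int) -> np.ndarray | None:
        """Active pixel indices for one iteration; None means all of Omega."""
        if self.is_full(iteration):
            return None
        if self.mode == "fixed":
            return self._prefix
        rng = np.random.default_rng((self.seed, iteration))
        return rng.permutation(self.n_pixels)[: self.subset_size]


@dataclass
class RunTrace:
    """Per-iteration record of a synthesis run.

    ``reports[j]`` is the full-sampling quality of the hologram produced by
    iteration j, or None when iteration j ran compressed (quality is never
    estimated from compressed fields).  The evaluation counters accumulate
    ``(pixels visited) * N`` separately for backward (superposition) and
    forward (spot field) projections; the forward count includes the final
    full evaluation that scores the returned hologram.
    """

    weights: list = dc_field(default_factory=list)
    thetas: list = dc_field(default_factory=list)
    reports: list = dc_field(default_factory=list)
    compressed: list = dc_field(default_factory=list)
    backward_evals: int = 0
    forward_evals: int = 0
    cumulative_evals: list = dc_field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.weights)

    @property
    def total_evals(self) -> int:
        return self.backward_evals + self.forward_evals

    @property
    def final_report(self) -> QualityReport | None:
        for rep in reversed(self.reports):
            if rep is not None:
                return rep
        return None

    def uniformities(self) -> np.ndarray:
        """Per-iteration u, NaN where the iteration ran compressed."""
        return np.array([np.nan if r is None else r.u for r in self.reports])


def weight_update(
    fields: SpotFields,
    weights: np.ndarray,
    target_amplitudes: np.ndarray,
    mode: str = "target_normalized",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One weight/phase/amplitude update from the current spot fields.

    Returns ``(new_weights, new_thetas, new_amplitudes)`` where
    ``new_amplitudes = new_weights * target_amplitudes`` feed the next
    superposition and ``new_thetas = arg(E_n)`` lock each spot's phase to
    what the current hologram delivers.

    In ``"literal"`` mode the drive is the raw magnitude ``|E_n|`` (fixed
    point: all magnitudes equal).  In ``"target_normalized"`` mode it is
    ``|E_n| / a0_n`` (fixed point: power shares proportional to targets),
    which reduces to the literal rule for uniform targets.

    Spots with (near-)zero field would blow the ratio up; their weights are
    clamped at :data:`WEIGHT_CAP` and a warning is emitted.
    """
    w = np.asarray(weights, dtype=float)
    a0 = np.asarray(target_amplitudes, dtype=float)
    mag = fields.magnitudes
    if not (w.shape == a0.shape == mag.shape):
        raise ValueError("weights, targets and fields must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if mode == "literal":
        drive = mag
    elif mode == "target_normalized":
        with np.errstate(divide="ignore", invalid="ignore"):
            drive = np.where(a0 > 0, mag / np.where(a0 > 0, a0, 1.0), np.inf)
    else:
        raise ValueError(f"unknown weight mode {mode!r}")
    finite = np.isfinite(drive)
    mean_drive = float(np.mean(drive[finite])) if np.any(finite) else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        new_w = w * np.where(drive > 0, mean_drive / np.where(drive > 0, drive, 1.0), np.inf)
    if np.any(~np.isfinite(new_w)) or np.any(new_w > WEIGHT_CAP):
        warnings.warn(
            "spot field magnitude (near) zero; weight clamped", RuntimeWarning, stacklevel=2
        )
        new_w = np.where(np.isfinite(new_w), np.minimum(new_w, WEIGHT_CAP), WEIGHT_CAP)
    return new_w, fields.phases.copy(), new_w * a0


def _exp_i(phase: np.ndarray) -> np.ndarray:
    """exp(1j * phase) built via cos/sin to avoid a complex temporary."""
    out = np.empty(phase.shape, dtype=np.complex128)
    np.cos(phase, out=out.real)
    np.sin(phase, out=out.imag)
    return out


def spot_basis(pattern: SpotPattern, pupil: PupilModel) -> np.ndarray:
    """Precompute the (M, N) matrix ``exp(i * phi_n)`` shared by all runs
    on one (pattern, pupil) pair; pass it as ``basis=`` to the synthesis
    functions to amortise it across seeds or iteration counts."""
    return _exp_i(spot_phase_matrix(pattern, pupil))


def _iterate(
    pattern: SpotPattern,
    pupil: PupilModel,
    config: AlgorithmConfig,
    keep_forward: bool = True,
    basis: np.ndarray | None = None,
) -> tuple[Hologram, RunTrace]:
    """Shared engine behind RS, WGS and CS-WGS."""
    n = pattern.n_spots
    m = pupil.n_pixels
    a0 = pattern.amplitude
    if basis is None:
        basis = spot_basis(pattern, pupil)  # (M, N): e^{i phi_n}
    theta = np.random.default_rng(config.seed_phases).uniform(0.0, 2.0 * np.pi, n)
    w = np.ones(n)
    if config.algorithm == "cswgs":
        plan = CompressionPlan(
            m,
            config.compression,
            config.iterations,
            seed=config.seed_subset,
            terminal_full=config.terminal_full,
            mode=config.subset_mode,
        )
    else:
        plan = CompressionPlan(m, 1.0, config.iterations)
    trace = RunTrace()
    phase = None
    for j in range(config.iterations):
        idx = plan.indices_for(j)
        trace.weights.append(w.copy())
        trace.thetas.append(theta.copy())
        trace.compressed.append(idx is not None)
        drive = w * a0 * np.exp(1j * theta)
        if idx is None:
            phase = np.angle(basis @ drive)
            trace.backward_evals += m * n
            if keep_forward or j < config.iterations - 1:
                conj = pupil.amplitude * _exp_i(-phase)
                fields = SpotFields(conj @ basis, True, pupil.amplitude_sum)
                trace.forward_evals += m * n
                trace.reports.append(quality_report(fields, pattern, pupil))
            else:
                fields = None
                trace.reports.append(None)
        else:
            sub = basis[idx]
            phase = np.angle(sub @ drive)
            trace.backward_evals += idx.size * n
            conj = pupil.amplitude[idx] * _exp_i(-phase)
            fields = SpotFields(conj @ sub, False, pupil.amplitude_sum)
            trace.forward_evals += idx.size * n
            trace.reports.append(None)
        trace.cumulative_evals.append(trace.total_evals)
        if j < config.iterations - 1:
            w, theta, _ = weight_update(fields, w, a0, config.weight_mode)
    hologram = Hologram(wrap_phase(phase), pupil.aperture_px)
    return hologram, trace


def rs_hologram(pattern: SpotPattern, pupil: PupilModel, seed: int = 0) -> Hologram:
    """Non-iterative random-superposition hologram.

    Phase offsets ``theta_n`` are drawn i.i.d. uniform on [0, 2*pi) from
    ``seed``; the hologram is the superposition phase with the target
    amplitudes.  Identical to a 1-iteration WGS run with the same seed.
    """
    config = AlgorithmConfig(algorithm="rs", iterations=1, seed_phases=seed)
    hologram, _ = _iterate(pattern, pupil, config, keep_forward=False)
    return hologram


def wgs_hologram(
    pattern: SpotPattern,
    pupil: PupilModel,
    config: AlgorithmConfig,
    basis: np.ndarray | None = None,
) -> tuple[Hologram, RunTrace]:
    """Weighted Gerchberg-Saxton run at full sampling.

    Iteration 0 is the RS start; every iteration's full-sampling quality is
    recorded in the trace, so ``trace.reports[j]`` equals the final quality
    a run stopped after ``j + 1`` iterations would report.
    """
    if config.algorithm not in ("wgs", "rs"):
        config = replace(config, algorithm="wgs")
    return _iterate(pattern, pupil, config, basis=basis)


def cswgs_hologram(
    pattern: SpotPattern,
    pupil: PupilModel,
    config: AlgorithmConfig,
    basis: np.ndarray | None = None,
) -> tuple[Hologram, RunTrace]:
    """Compressed-sensing WGS: subset projections, then full final polish.

    With ``compression == 1`` the subset is all of Omega and the run takes
    exactly the WGS code path (bit-identical output under equal seeds).
    """
    if config.algorithm != "cswgs":
        config = replace(config, algorithm="cswgs")
    return _iterate(pattern, pupil, config, basis=basis)


def evaluation_cost(config: AlgorithmConfig, n_pixels: int, n_spots: int) -> int:
    """Predicted pixel evaluations per projection direction.

    RS: ``M*N`` (single superposition).  WGS: ``M*N*I``.  CS-WGS:
    ``terminal_full`` full iterations plus compressed ones at
    ``ceil(c*M)*N`` each — with the spec subset size this matches the
    measured counters of :func:`cswgs_hologram` exactly.
    """
    if n_pixels <= 0 or n_spots <= 0:
        raise ValueError("pixel and spot counts must be positive")
    m, n, i = n_pixels, n_spots, config.iterations
    if config.algorithm == "rs":
        return m * n
    if config.algorithm == "wgs":
        return m * n * i
    subset = int(np.ceil(config.compression * m))
    if subset >= m:
        return m * n * i
    full_iters = min(config.terminal_full, i)
    return full_iters * m * n + (i - full_iters) * subset * n
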