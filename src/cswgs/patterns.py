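"""Benchmark spot-pattern generators and the spot CSV format.

Two families of synthetic targets cover the benchmark protocols:

* planar square grids of uniform spots (4 to 144 spots) — the worst case for
  uniformity, since the regular geometry breeds strong crosstalk orders;
* random clouds (9 to 99 spots) uniform in a centred cube with optionally
  randomised target intensities — the realistic stand-in for a set of
  neuron somata in a cortical volume.

Grids default to a fixed total span of 200 um regardless of spot count, and
can be rigidly rotated in 3D about their centroid.  Random-cloud target
intensities default to i.i.d. uniform on [0.5, 1] before normalisation.
All generators are fully seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .optics import SpotPattern

__all__ = [
    "PatternSpec",
    "grid_pattern",
    "random_pattern",
    "rotate_pattern",
    "make_pattern",
    "read_spots_csv",
    "write_spots_csv",
    "GRID_SPAN_UM",
    "RANDOM_INTENSITY_RANGE",
]

#: Default total span (edge to edge) of square grids, um.
GRID_SPAN_UM = 200.0
#: Default range of random target intensities before normalisation.
RANDOM_INTENSITY_RANGE = (0.5, 1.0)

SPOT_COLUMNS = ["x_um", "y_um", "z_um", "intensity"]


@dataclass(frozen=True)
class PatternSpec:
    """Declarative description of a benchmark pattern.

    ``kind`` is ``"grid"`` (n_spots a perfect square) or ``"random"``;
    ``intensity_mode`` is ``"uniform"`` or ``"random"``; ``seed`` drives
    coordinates, intensities and (for grids) the optional random rotation.
    """

    kind: str
    n_spots: int
    span_um: float = GRID_SPAN_UM
    cube_side_um: float = 300.0
    intensity_mode: str = "uniform"
    intensity_range: tuple = RANDOM_INTENSITY_RANGE
    rotate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "random"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind == "grid":
            k = int(round(np.sqrt(self.n_spots)))
            if k * k != self.n_spots or k < 2:
                raise ValueError("grid n_spots must be a perfect square >= 4")
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")

    @property
    def label(self) -> str:
        return f"{self.kind}{self.n_spots}"


def grid_pattern(
    k_per_side: int,
    spacing_um: Optional[float] = None,
    rotation: Optional[Rotation] = None,
    center=(0.0, 0.0, 0.0),
) -> SpotPattern:
    """Planar square lattice of k^2 uniform spots, optionally rotated in 3D.

    Without an explicit spacing the lattice spans :data:`GRID_SPAN_UM`
    edge-to-edge.  Rotation is rigid, about the lattice centroid, applied
    before the centre offset.
    """
    if k_per_side < 2:
        raise ValueError("grid needs at least 2 spots per side")
    if spacing_um is None:
        spacing_um = GRID_SPAN_UM / (k_per_side - 1)
    if spacing_um <= 0:
        raise ValueError("grid spacing must be positive")
    line = (np.arange(k_per_side) - (k_per_side - 1) / 2.0) * spacing_um
    gx, gy = np.meshgrid(line, line, indexing="ij")
    coords = np.stack([gx.ravel(), gy.ravel(), np.zeros(k_per_side**2)], axis=1)
    if rotation is not None:
        coords = rotation.apply(coords)
    coords = coords + np.asarray(center, dtype=float)
    return SpotPattern(coords[:, 0], coords[:, 1], coords[:, 2])


def random_pattern(
    n: int,
    cube_side_um: float = 300.0,
    intensity_mode: str = "uniform",
    seed: int = 0,
    intensity_range: tuple = RANDOM_INTENSITY_RANGE,
) -> SpotPattern:
    """n spots i.i.d. uniform in a centred cube of the given side.

    ``intensity_mode="random"`` draws desired powers i.i.d. uniform on
    ``intensity_range`` before normalisation; ``"uniform"`` gives equal
    targets.
    """
    if n < 1:
        raise ValueError("need at least one spot")
    if cube_side_um <= 0:
        raise ValueError("cube side must be positive")
    rng = np.random.default_rng(seed)
    half = cube_side_um / 2.0
    coords = rng.uniform(-half, half, size=(3, n))
    if intensity_mode == "uniform":
        amp = np.ones(n)
    elif intensity_mode == "random":
        lo, hi = intensity_range
        if not (0 <= lo <= hi):
            raise ValueError("intensity range must satisfy 0 <= lo <= hi")
        amp = np.sqrt(rng.uniform(lo, hi, n))
    else:
        raise ValueError(f"unknown intensity mode {intensity_mode!r}")
    return SpotPattern(coords[0], coords[1], coords[2], amp)


def rotate_pattern(pattern: SpotPattern, rotation: Rotation) -> SpotPattern:
    """Rigidly rotate a pattern about its centroid; intensities unchanged."""
    coords = np.stack([pattern.x_um, pattern.y_um, pattern.z_um], axis=1)
    centroid = coords.mean(axis=0)
    rotated = rotation.apply(coords - centroid) + centroid
    return SpotPattern(rotated[:, 0], rotated[:, 1], rotated[:, 2], pattern.amplitude)


def make_pattern(spec: PatternSpec) -> SpotPattern:
    """Materialise a :class:`PatternSpec` into a :class:`SpotPattern`."""
    if spec.kind == "grid":
        k = int(round(np.sqrt(spec.n_spots)))
        rot = None
        if spec.rotate:
            rot = Rotation.random(rng=np.random.default_rng(spec.seed))
        spacing = spec.span_um / (k - 1)
        return grid_pattern(k, spacing_um=spacing, rotation=rot)
    return random_pattern(
        spec.n_spots,
        cube_side_um=spec.cube_side_um,
        intensity_mode=spec.intensity_mode,
        seed=spec.seed,
        intensity_range=spec.intensity_range,
    )


def write_spots_csv(pattern: SpotPattern, path) -> None:
    """Write a pattern as CSV with columns x_um, y_um, z_um, intensity.

    The intensity column holds the normalised desired power fractions
    ``a0**2``; reading the file back reproduces the pattern exactly (the
    pattern constructor renormalises, a no-op on already-normalised data).
    """
    df = pd.DataFrame(
        {
            "x_um": pattern.x_um,
            "y_um": pattern.y_um,
            "z_um": pattern.z_um,
            "intensity": pattern.target_intensity,
        }
    )
    df.to_csv(path, index=False)


def read_spots_csv(path) -> SpotPattern:
    """Read a spot CSV (header required; intensity = desired relative power)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty spot file") from exc
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no spot rows")
    for col in SPOT_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
    if (df["intensity"] < 0).any():
        raise ValueError(f"{path}: negative intensity")
    return SpotPattern(
        df["x_um"].to_numpy(float),
        df["y_um"].to_numpy(float),
        df["z_um"].to_numpy(float),
        np.sqrt(df["intensity"].to_numpy(float)),
    )
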