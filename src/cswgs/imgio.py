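"""Hologram export, gray-level lookup, JSON reports and YAML configuration.

A phase-only SLM is driven through 8-bit gray levels; :class:`GrayLUT` maps
wrapped phase to the gray level whose calibrated phase is nearest (ties
round down).  The default table is linear, ``phase(g) = 2*pi*g/255``;
measured calibration curves load from a 256-entry CSV.

Exported holograms embed the round aperture in the full SLM panel (pixels
outside the aperture at gray 0) as 8-bit grayscale PNG or TIFF.  Every
artifact written here carries the configuration and seeds that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from . import __version__
from .algorithms import AlgorithmConfig
from .optics import Hologram, PupilModel, wrap_phase

__all__ = [
    "GrayLUT",
    "write_hologram_image",
    "read_hologram_image",
    "write_report",
    "load_config",
    "pupil_from_config",
    "algorithm_from_config",
    "config_echo",
]

TWO_PI = 2.0 * np.pi

_WEIGHT_MODE_ALIASES = {
    "literal_eq4": "literal",
    "literal": "literal",
    "target_normalized": "target_normalized",
}


class GrayLUT:
    """Monotone mapping from wrapped phase [0, 2*pi) to gray level 0..255.

    ``phase_of_gray[g]`` is the calibrated phase displayed at gray level g
    (non-decreasing, ``phase_of_gray[0] == 0``).  ``to_gray`` picks the
    nearest calibrated phase, rounding exact midpoints down — with the
    linear default, phase pi maps to gray 127.
    """

    def __init__(self, phase_of_gray: np.ndarray | None = None) -> None:
        if phase_of_gray is None:
            phase_of_gray = TWO_PI * np.arange(256) / 255.0
        table = np.asarray(phase_of_gray, dtype=float)
        if table.shape != (256,):
            raise ValueError("a gray LUT needs exactly 256 phase entries")
        if np.any(np.diff(table) < 0):
            raise ValueError("LUT phases must be non-decreasing")
        self.phase_of_gray = table
        # boundaries: gray g wins on (mid[g-1], mid[g]]; ties at mid go down
        self._midpoints = (table[1:] + table[:-1]) / 2.0

    @classmethod
    def from_csv(cls, path) -> "GrayLUT":
        """Load a 256-entry calibration table (columns ``gray, phase_rad``)."""
        import pandas as pd

        df = pd.read_csv(path)
        if not {"gray", "phase_rad"} <= set(df.columns):
            raise ValueError(f"{path}: LUT CSV needs columns gray, phase_rad")
        table = np.full(256, np.nan)
        table[df["gray"].to_numpy(int)] = df["phase_rad"].to_numpy(float)
        if np.any(np.isnan(table)):
            raise ValueError(f"{path}: LUT CSV must cover all 256 gray levels")
        return cls(table)

    def to_gray(self, phase: np.ndarray) -> np.ndarray:
        """Quantise wrapped phase to gray levels."""
        phase = wrap_phase(np.asarray(phase, dtype=float))
        # side="left": a phase equal to a midpoint stays with the lower gray
        return np.searchsorted(self._midpoints, phase, side="left").astype(np.uint8)

    def to_phase(self, gray: np.ndarray) -> np.ndarray:
        """Calibrated phase of each gray level."""
        return self.phase_of_gray[np.asarray(gray, dtype=int)]


def _panel_offsets(pupil: PupilModel, offset: tuple[int, int] | None) -> tuple[int, int]:
    D = pupil.aperture_px
    if offset is None:
        return (pupil.panel_height_px - D) // 2, (pupil.panel_width_px - D) // 2
    return offset


def write_hologram_image(
    hologram: Hologram,
    pupil: PupilModel,
    path,
    lut: GrayLUT | None = None,
    offset: tuple[int, int] | None = None,
    full_panel: bool = True,
) -> None:
    """Write an 8-bit grayscale hologram image (PNG or TIFF by extension).

    The round aperture is embedded in the panel at ``offset`` (top-left of
    its bounding box; default centred); pixels outside the aperture are 0.
    With ``full_panel=False`` only the aperture bounding box is written.
    The output is a pure function of hologram, LUT and geometry.
    """
    if hologram.phase.size != pupil.n_pixels:
        raise ValueError("hologram does not match this pupil's active set")
    lut = lut or GrayLUT()
    D = pupil.aperture_px
    block = np.zeros((D, D), dtype=np.uint8)
    block[pupil.rows, pupil.cols] = lut.to_gray(hologram.phase)
    if full_panel:
        panel = np.zeros((pupil.panel_height_px, pupil.panel_width_px), dtype=np.uint8)
        r0, c0 = _panel_offsets(pupil, offset)
        panel[r0 : r0 + D, c0 : c0 + D] = block
    else:
        panel = block
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, panel)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, panel)
    else:
        raise ValueError(f"unsupported image extension {path.suffix!r} (use .png or .tif)")


def read_hologram_image(
    path,
    pupil: PupilModel,
    lut: GrayLUT | None = None,
    offset: tuple[int, int] | None = None,
    full_panel: bool = True,
) -> Hologram:
    """Read a hologram image back into phase over the active set."""
    lut = lut or GrayLUT()
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        panel = tifffile.imread(path)
    else:
        panel = iio.imread(path)
    D = pupil.aperture_px
    if full_panel:
        r0, c0 = _panel_offsets(pupil, offset)
        block = panel[r0 : r0 + D, c0 : c0 + D]
    else:
        block = panel
    gray = block[pupil.rows, pupil.cols]
    return Hologram(lut.to_phase(gray), D)


def config_echo(pupil: PupilModel, config: AlgorithmConfig | None = None) -> dict:
    """Provenance block embedded in every report: geometry, algorithm, seeds."""
    echo: dict = {"version": __version__, "geometry": pupil.config_dict()}
    if config is not None:
        echo["algorithm"] = {
            "algorithm": config.algorithm,
            "iterations": config.iterations,
            "compression": config.compression,
            "seed_phases": config.seed_phases,
            "seed_subset": config.seed_subset,
            "weight_normalization": config.weight_mode,
            "terminal_full_iterations": config.terminal_full,
            "subset_mode": config.subset_mode,
        }
    return echo


def write_report(path, report, pupil: PupilModel, config: AlgorithmConfig | None = None) -> None:
    """Serialise a :class:`cswgs.metrics.QualityReport` with full provenance."""
    payload = report.to_dict()
    payload["provenance"] = config_echo(pupil, config)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_config(path) -> dict:
    """Load a YAML config with optional ``geometry`` and ``algorithm`` blocks."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def pupil_from_config(cfg: dict) -> PupilModel:
    """Pupil from the ``geometry`` block (or a flat mapping)."""
    geo = dict(cfg.get("geometry", cfg))
    illum = geo.get("illumination")
    if isinstance(illum, dict):  # nested form: {type: gaussian, waist_mm: 6}
        geo["illumination"] = illum.get("type", "gaussian")
        if "waist_mm" in illum:
            geo["waist_mm"] = illum["waist_mm"]
    return PupilModel.from_config(geo)


def algorithm_from_config(cfg: dict, **overrides) -> AlgorithmConfig:
    """Algorithm config from the ``algorithm`` block, with CLI overrides."""
    block = dict(cfg.get("algorithm", {}))
    block.update({k: v for k, v in overrides.items() if v is not None})
    mode = block.get("weight_normalization", "target_normalized")
    return AlgorithmConfig(
        algorithm=block.get("algorithm", "wgs"),
        iterations=int(block.get("iterations", 1)),
        compression=float(block.get("compression", 1.0)),
        seed_phases=int(block.get("seed_phases", 0)),
        seed_subset=int(block.get("seed_subset", 0)),
        weight_mode=_WEIGHT_MODE_ALIASES[mode],
        terminal_full=int(block.get("terminal_full_iterations", 2)),
        subset_mode=block.get("subset_mode", "fixed"),
    )
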