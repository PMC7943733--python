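"""Pattern-quality metrics: efficiency, per-spot power ratios, uniformity, variance.

Given the simulated intensity fractions ``I_n`` of a hologram and the desired
power fractions ``|a0_n|^2`` of its target pattern:

* efficiency      ``e = sum_n I_n``  — fraction of power landing on the spots;
* power ratio     ``F_n = (I_n / sum I) / (|a0_n|^2 / sum |a0|^2)`` — achieved
  versus desired share for each spot;
* uniformity      ``u = 1 - (max F - min F) / (max F + min F)``;
* variance        ``v = mean((F_n - 1)^2)`` — mean square relative error of
  the power shares.

All three scalars are invariant under positive rescaling of either the
targets or the intensities.  Metrics are always computed from full-sampling
forward fields; compressed CS-WGS estimates carry no absolute scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Any

import numpy as np

from .optics import PupilModel, SpotFields, SpotPattern, intensity_fractions

__all__ = [
    "QualityReport",
    "efficiency",
    "power_ratios",
    "uniformity",
    "variance_metric",
    "quality_report",
]


def efficiency(intensities: np.ndarray) -> float:
    """Total fraction of power directed at the spots, ``e = sum I_n``."""
    I = np.asarray(intensities, dtype=float)
    if np.any(I < 0):
        raise ValueError("intensity fractions must be nonnegative")
    return float(np.sum(I))


def power_ratios(intensities: np.ndarray, target_amplitudes: np.ndarray) -> np.ndarray:
    """Achieved over desired power share per spot.

    Self-normalising: both the intensities and the target amplitudes may be
    supplied on any positive scale.
    """
    I = np.asarray(intensities, dtype=float)
    a0 = np.asarray(target_amplitudes, dtype=float)
    if I.shape != a0.shape:
        raise ValueError("need one target amplitude per intensity")
    total_I = np.sum(I)
    total_t = np.sum(a0**2)
    if total_I <= 0:
        raise ValueError("all spot intensities are zero; power ratios undefined")
    if total_t <= 0:
        raise ValueError("all target amplitudes are zero; power ratios undefined")
    return (I / total_I) / (a0**2 / total_t)


def uniformity(ratios: np.ndarray) -> float:
    """``u = 1 - (max F - min F) / (max F + min F)``; 1 iff all shares equal."""
    F = np.asarray(ratios, dtype=float)
    if np.any(F < 0):
        raise ValueError("power ratios must be nonnegative")
    hi, lo = np.max(F), np.min(F)
    if hi + lo == 0:
        raise ValueError("all power ratios are zero; uniformity undefined")
    return float(1.0 - (hi - lo) / (hi + lo))


def variance_metric(ratios: np.ndarray) -> float:
    """Mean square relative error of the power shares, ``v = mean((F-1)^2)``."""
    F = np.asarray(ratios, dtype=float)
    return float(np.mean((F - 1.0) ** 2))


@dataclass
class QualityReport:
    """Scalar metrics plus the per-spot arrays they derive from."""

    e: float
    u: float
    v: float
    power_ratio: np.ndarray
    intensity: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "e": self.e,
            "u": self.u,
            "v": self.v,
            "power_ratio": np.asarray(self.power_ratio).tolist(),
            "intensity": np.asarray(self.intensity).tolist(),
            "meta": self.meta,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "QualityReport":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            e=d["e"],
            u=d["u"],
            v=d["v"],
            power_ratio=np.asarray(d["power_ratio"]),
            intensity=np.asarray(d["intensity"]),
            meta=d.get("meta", {}),
        )


def quality_report(
    fields: SpotFields,
    pattern: SpotPattern,
    pupil: PupilModel | None = None,
    meta: dict | None = None,
) -> QualityReport:
    """Full quality evaluation of a hologram from its full-sampling fields."""
    I = intensity_fractions(fields, pupil)
    F = power_ratios(I, pattern.amplitude)
    return QualityReport(
        e=efficiency(I),
        u=uniformity(F),
        v=variance_metric(F),
        power_ratio=F,
        intensity=I,
        meta=meta or {},
    )
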