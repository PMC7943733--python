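"""Physical model of the SLM pupil and the pupil-to-spot field relation.

The spatial light modulator (SLM) sits in a pupil plane of the excitation
path.  Displaying a phase pattern ``Phi`` over the round aperture shapes the
focal field so that light concentrates in a set of diffraction-limited spots
at 3D sample coordinates.  This module holds the geometry (:class:`PupilModel`),
the target description (:class:`Spot`, :class:`SpotPattern`), the phase mask
(:class:`Hologram`), and the three primitive operations every synthesis
algorithm is built from:

* :func:`spot_phase` — the ideal single-spot wavefront (tilt + defocus),

  .. math::

     \\phi_n(x', y') = \\frac{2\\pi}{\\lambda f}(x_n x' + y_n y')
                      + \\frac{2\\pi}{\\lambda f^2}(x'^2 + y'^2)\\, z_n

* :func:`superpose` — phase of the interference of the N single-spot
  wavefronts, ``Phi = arg(sum_n a_n exp(i(phi_n + theta_n)))``,

* :func:`forward_fields` — the field each spot receives from a displayed
  hologram, ``E_n = sum_{pupil} A exp(-i(Phi - phi_n))``.

All lengths are micrometres.  Pupil pixel centres sit at
``(i + 0.5 - D/2) * pitch`` so the aperture centre falls between pixels;
the active set Omega contains exactly the pixels whose centre lies inside
the round aperture of diameter ``aperture_px`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PupilModel",
    "Spot",
    "SpotPattern",
    "Hologram",
    "SpotFields",
    "spot_phase",
    "spot_phase_matrix",
    "superpose",
    "forward_fields",
    "intensity_fractions",
    "wrap_phase",
]

TWO_PI = 2.0 * np.pi

#: Reference geometry: 1,152-px round aperture, 9.2 um pitch, 800 nm,
#: Gaussian illumination with 6 mm amplitude waist, 5.4 mm effective focal.
DEFAULT_GEOMETRY = dict(
    panel_width_px=1920,
    panel_height_px=1152,
    aperture_px=1152,
    pitch_um=9.2,
    wavelength_um=0.8,
    focal_um=5400.0,
    illumination="gaussian",
    waist_um=6000.0,
)


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase values into [0, 2*pi)."""
    return np.mod(phi, TWO_PI)


@dataclass(frozen=True)
class PupilModel:
    """SLM geometry, active aperture pixel set and illumination amplitude.

    Parameters
    ----------
    aperture_px
        Diameter of the round active aperture, in pixels.
    pitch_um
        Pixel pitch in micrometres.
    wavelength_um
        Vacuum wavelength in micrometres.
    focal_um
        Effective focal length of the compound optical system seen from the
        SLM plane, in micrometres.
    illumination
        ``"gaussian"`` (amplitude ``exp(-r^2 / waist^2)``) or ``"uniform"``.
    waist_um
        Amplitude waist of the Gaussian illumination at the SLM, in
        micrometres.  Ignored for uniform illumination.
    panel_width_px, panel_height_px
        Full SLM panel size, used only when embedding a hologram for export.

    The illumination amplitude ``A`` is normalised so ``sum(A**2) == 1``
    (unit total power through the aperture).
    """

    aperture_px: int = 1152
    pitch_um: float = 9.2
    wavelength_um: float = 0.8
    focal_um: float = 5400.0
    illumination: str = "gaussian"
    waist_um: float = 6000.0
    panel_width_px: int = 1920
    panel_height_px: int = 1152

    # filled in __post_init__; excluded from comparison/repr
    x_um: np.ndarray = field(init=False, repr=False, compare=False)
    y_um: np.ndarray = field(init=False, repr=False, compare=False)
    amplitude: np.ndarray = field(init=False, repr=False, compare=False)
    rows: np.ndarray = field(init=False, repr=False, compare=False)
    cols: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        D = int(self.aperture_px)
        if D < 2:
            raise ValueError("aperture_px must be at least 2")
        if self.pitch_um <= 0 or self.wavelength_um <= 0 or self.focal_um <= 0:
            raise ValueError("pitch, wavelength and focal length must be positive")
        if self.illumination not in ("gaussian", "uniform"):
            raise ValueError(f"unknown illumination {self.illumination!r}")
        centers = (np.arange(D) + 0.5 - D / 2.0) * self.pitch_um
        X, Y = np.meshgrid(centers, centers, indexing="ij")
        radius = D / 2.0 * self.pitch_um
        mask = X**2 + Y**2 <= radius**2
        rows, cols = np.nonzero(mask)
        x = X[mask]
        y = Y[mask]
        if self.illumination == "gaussian":
            if self.waist_um <= 0:
                raise ValueError("waist_um must be positive for gaussian illumination")
            A = np.exp(-(x**2 + y**2) / self.waist_um**2)
        else:
            A = np.ones_like(x)
        A = A / np.sqrt(np.sum(A**2))
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        object.__setattr__(self, "amplitude", A)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "cols", cols)

    @property
    def n_pixels(self) -> int:
        """Number of active pixels M = |Omega|."""
        return self.x_um.size

    @property
    def amplitude_sum(self) -> float:
        """sum(A) over the aperture; (sum A)^2 normalises spot intensities."""
        return float(np.sum(self.amplitude))

    def scaled(self, aperture_px: int) -> "PupilModel":
        """A reduced (or enlarged) pupil preserving the illumination shape.

        The Gaussian waist is scaled with the aperture diameter so a desk-scale
        pupil truncates the beam at the same relative radius as the reference
        1,152-px geometry.  Wavelength, pitch and focal length are unchanged,
        preserving the sample-space scale of the spot pattern (at reduced
        numerical aperture, i.e. larger diffraction-limited spots).
        """
        scale = aperture_px / self.aperture_px
        return PupilModel(
            aperture_px=aperture_px,
            pitch_um=self.pitch_um,
            wavelength_um=self.wavelength_um,
            focal_um=self.focal_um,
            illumination=self.illumination,
            waist_um=self.waist_um * scale,
            panel_width_px=self.panel_width_px,
            panel_height_px=self.panel_height_px,
        )

    @classmethod
    def from_config(cls, cfg: dict) -> "PupilModel":
        """Build from a flat config mapping (see :mod:`cswgs.config`)."""
        illum = cfg.get("illumination", DEFAULT_GEOMETRY["illumination"])
        waist_mm = cfg.get("waist_mm")
        kwargs = dict(
            aperture_px=int(cfg.get("aperture_px", DEFAULT_GEOMETRY["aperture_px"])),
            pitch_um=float(cfg.get("pitch_um", DEFAULT_GEOMETRY["pitch_um"])),
            focal_um=float(cfg.get("focal_mm", DEFAULT_GEOMETRY["focal_um"] / 1000.0)) * 1000.0,
            illumination=illum,
            panel_width_px=int(cfg.get("panel_width_px", DEFAULT_GEOMETRY["panel_width_px"])),
            panel_height_px=int(cfg.get("panel_height_px", DEFAULT_GEOMETRY["panel_height_px"])),
        )
        if "wavelength_nm" in cfg:
            kwargs["wavelength_um"] = float(cfg["wavelength_nm"]) / 1000.0
        if waist_mm is not None:
            kwargs["waist_um"] = float(waist_mm) * 1000.0
        return cls(**kwargs)

    def config_dict(self) -> dict:
        """Flat mapping mirroring :meth:`from_config` (for provenance echo)."""
        return dict(
            aperture_px=self.aperture_px,
            pitch_um=self.pitch_um,
            wavelength_nm=self.wavelength_um * 1000.0,
            focal_mm=self.focal_um / 1000.0,
            illumination=self.illumination,
            waist_mm=self.waist_um / 1000.0,
            panel_width_px=self.panel_width_px,
            panel_height_px=self.panel_height_px,
        )


@dataclass(frozen=True)
class Spot:
    """A single target focus at sample coordinates (um) with target amplitude."""

    x_um: float
    y_um: float
    z_um: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.x_um, self.y_um, self.z_um, self.amplitude])):
            raise ValueError("spot coordinates and amplitude must be finite")
        if self.amplitude < 0:
            raise ValueError("target amplitude must be nonnegative")


class SpotPattern:
    """An ordered set of N target spots with normalised target amplitudes.

    Target amplitudes ``a0`` are stored normalised to ``sum(a0**2) == 1``.
    The absolute scale of the targets is physically meaningless (any positive
    rescale leaves every hologram iterate unchanged), so normalising makes
    patterns comparable and keeps the intensity fractions on a common scale.
    """

    def __init__(self, x_um, y_um, z_um, amplitude=None) -> None:
        x = np.atleast_1d(np.asarray(x_um, dtype=float))
        y = np.atleast_1d(np.asarray(y_um, dtype=float))
        z = np.atleast_1d(np.asarray(z_um, dtype=float))
        if not (x.shape == y.shape == z.shape) or x.ndim != 1:
            raise ValueError("x, y, z must be equal-length 1-D arrays")
        if x.size < 1:
            raise ValueError("a pattern needs at least one spot")
        if amplitude is None:
            a = np.ones_like(x)
        else:
            a = np.atleast_1d(np.asarray(amplitude, dtype=float))
            if a.shape != x.shape:
                raise ValueError("amplitude must match coordinate length")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(z)):
            raise ValueError("spot coordinates must be finite")
        if np.any(a < 0) or not np.all(np.isfinite(a)):
            raise ValueError("target amplitudes must be finite and nonnegative")
        norm = np.sqrt(np.sum(a**2))
        if norm == 0:
            raise ValueError("at least one target amplitude must be positive")
        self.x_um = x
        self.y_um = y
        self.z_um = z
        self.amplitude = a / norm

    @property
    def n_spots(self) -> int:
        return self.x_um.size

    def __len__(self) -> int:
        return self.n_spots

    @property
    def target_intensity(self) -> np.ndarray:
        """Normalised desired power fractions ``a0**2`` (sums to 1)."""
        return self.amplitude**2

    @property
    def spots(self) -> list[Spot]:
        return [
            Spot(float(x), float(y), float(z), float(a))
            for x, y, z, a in zip(self.x_um, self.y_um, self.z_um, self.amplitude)
        ]

    @classmethod
    def from_spots(cls, spots: Sequence[Spot]) -> "SpotPattern":
        return cls(
            [s.x_um for s in spots],
            [s.y_um for s in spots],
            [s.z_um for s in spots],
            [s.amplitude for s in spots],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpotPattern):
            return NotImplemented
        return (
            np.array_equal(self.x_um, other.x_um)
            and np.array_equal(self.y_um, other.y_um)
            and np.array_equal(self.z_um, other.z_um)
            and np.array_equal(self.amplitude, other.amplitude)
        )


@dataclass(frozen=True)
class Hologram:
    """Phase mask over the active aperture pixels, wrapped to [0, 2*pi)."""

    phase: np.ndarray
    aperture_px: int

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        if phase.ndim != 1:
            raise ValueError("hologram phase must be a 1-D array over Omega")
        object.__setattr__(self, "phase", phase)

    @property
    def n_pixels(self) -> int:
        return self.phase.size


@dataclass(frozen=True)
class SpotFields:
    """Complex field per spot, plus how much of the pupil produced it.

    ``full_sampling`` records whether the fields were computed over all of
    Omega; intensity fractions (and hence every quality metric) are only
    meaningful at full sampling — compressed estimates have arbitrary scale
    and are used solely to steer the iterative algorithms.
    """

    fields: np.ndarray
    full_sampling: bool
    amplitude_sum: float

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.fields)

    @property
    def phases(self) -> np.ndarray:
        return np.angle(self.fields)


def spot_phase(spot: Spot, pupil: PupilModel) -> np.ndarray:
    """Ideal (unwrapped) wavefront phi_n over Omega for a single spot.

    Lateral position enters as a tilt, axial position as a quadratic
    defocus term.  Values are returned unwrapped; wrapping happens only
    when a hologram is assembled.
    """
    k_tilt = TWO_PI / (pupil.wavelength_um * pupil.focal_um)
    k_defocus = TWO_PI / (pupil.wavelength_um * pupil.focal_um**2)
    return k_tilt * (spot.x_um * pupil.x_um + spot.y_um * pupil.y_um) + k_defocus * (
        pupil.x_um**2 + pupil.y_um**2
    ) * spot.z_um


def spot_phase_matrix(pattern: SpotPattern, pupil: PupilModel) -> np.ndarray:
    """All single-spot wavefronts as an (M, N) matrix.

    Vectorised as a rank-3 product: each phi_n is a linear combination of the
    three fixed pixel maps (x', y', x'^2 + y'^2) with spot-dependent
    coefficients.  This matrix is the dominant shared work of every
    algorithm and is precomputed once per (pupil, pattern).
    """
    k_tilt = TWO_PI / (pupil.wavelength_um * pupil.focal_um)
    k_defocus = TWO_PI / (pupil.wavelength_um * pupil.focal_um**2)
    basis = np.stack(
        [k_tilt * pupil.x_um, k_tilt * pupil.y_um, k_defocus * (pupil.x_um**2 + pupil.y_um**2)],
        axis=1,
    )
    coords = np.stack([pattern.x_um, pattern.y_um, pattern.z_um], axis=0)
    return basis @ coords


def superpose(
    spot_phases: np.ndarray,
    amplitudes: np.ndarray,
    phases: np.ndarray,
    aperture_px: int | None = None,
) -> Hologram:
    """Hologram as the phase of the interference of the single-spot wavefronts.

    Parameters
    ----------
    spot_phases
        (M, N) matrix of single-spot wavefronts phi_n (columns).
    amplitudes, phases
        Per-spot amplitudes a_n >= 0 and phase offsets theta_n.

    At pixels where the complex sum vanishes exactly the phase is defined
    as 0 (``arg(0) := 0``).
    """
    spot_phases = np.asarray(spot_phases, dtype=float)
    if spot_phases.ndim == 1:
        spot_phases = spot_phases[:, None]
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    phases = np.atleast_1d(np.asarray(phases, dtype=float))
    n = spot_phases.shape[1]
    if n == 0 or amplitudes.size != n or phases.size != n:
        raise ValueError("need one amplitude and one phase offset per spot")
    if np.any(amplitudes < 0):
        raise ValueError("amplitudes must be nonnegative")
    field = np.exp(1j * spot_phases) @ (amplitudes * np.exp(1j * phases))
    return Hologram(wrap_phase(np.angle(field)), aperture_px or 0)


def forward_fields(
    hologram: Hologram,
    pattern: SpotPattern,
    pupil: PupilModel,
    subset: np.ndarray | None = None,
    spot_phases: np.ndarray | None = None,
) -> SpotFields:
    """Field E_n received by each spot from a displayed hologram.

    ``E_n = sum_{pixels} A * exp(-i(Phi - phi_n))``.  With ``subset`` (integer
    indices into Omega) the sum runs over that subset only — the compressed
    estimator used by CS-WGS, whose scale is arbitrary: only relative
    magnitudes and arguments are meaningful.

    ``spot_phases`` may pass a precomputed :func:`spot_phase_matrix` to avoid
    recomputation in iterative loops.
    """
    if hologram.phase.size != pupil.n_pixels:
        raise ValueError("hologram is not defined on this pupil's active set")
    if spot_phases is None:
        spot_phases = spot_phase_matrix(pattern, pupil)
    conj = pupil.amplitude * np.exp(-1j * hologram.phase)
    if subset is None:
        fields = conj @ np.exp(1j * spot_phases)
        return SpotFields(fields, True, pupil.amplitude_sum)
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("pixel subset must not be empty")
    fields = conj[subset] @ np.exp(1j * spot_phases[subset])
    return SpotFields(fields, False, pupil.amplitude_sum)


def intensity_fractions(fields: SpotFields, pupil: PupilModel | None = None) -> np.ndarray:
    """Fraction of laser power directed to each spot.

    ``I_n = |E_n|^2 / (sum A)^2``, so a perfectly conjugated single spot
    scores exactly 1 and ``sum I_n <= 1`` for well-separated spots.  Only
    defined for fields computed on the full pixel set.
    """
    if not fields.full_sampling:
        raise ValueError(
            "intensity fractions require full-sampling fields; "
            "compressed estimates have arbitrary scale"
        )
    denom = pupil.amplitude_sum if pupil is not None else fields.amplitude_sum
    return np.abs(fields.fields) ** 2 / denom**2
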