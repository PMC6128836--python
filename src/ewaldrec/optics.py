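"""Electron-optical physics.

Contrast transfer, Ewald-sphere geometry and the depth-of-field resolution
limits that govern when curvature correction starts to matter.

Units follow field conventions exactly: lengths in Angstrom, spatial
frequency in 1/Angstrom, accelerating voltage in kilovolt, spherical
aberration in millimetre, angles in degrees unless noted.

Sign conventions (used consistently by the simulator and reconstructor):

* defocus is positive for underfocus;
* the CTF is ``-[sqrt(1-A²)·sin(chi) + A·cos(chi)]`` with
  ``chi = pi·lambda·df·s² - (pi/2)·Cs·lambda³·s⁴ + phase_shift`` so that
  low-resolution contrast is negative (dark particles on a bright
  background).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticsModel",
    "CTFParams",
    "LimitModel",
    "electron_wavelength",
    "ctf_value",
    "complex_beam_ctf",
    "ewald_height",
    "phase_shift_across_particle",
    "resolution_limit",
    "min_box_size",
]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in kV.

    lambda = 12.2639 / sqrt(V + 0.97845e-6 V²) with V in volts.
    """
    if voltage_kv <= 0:
        raise ValueError(f"accelerating voltage must be positive, got {voltage_kv} kV")
    v = voltage_kv * 1e3
    return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)


@dataclass
class OpticsModel:
    """Microscope/detector physics.

    Parameters
    ----------
    voltage_kv : accelerating voltage in kV.
    cs_mm : spherical aberration in mm.
    amplitude_contrast : amplitude-contrast fraction A in [0, 1).
    pixel_size : detector pixel size in Angstrom.
    anisotropy_percent : magnification anisotropy alpha (major/minor axis
        scale difference) in percent, >= 0.
    anisotropy_axis_deg : direction of the magnified axis, degrees.
    wavelength : optional explicit wavelength in Angstrom; when omitted it
        is derived from the voltage.  Toy optics for desk-scale experiments
        set it directly.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    pixel_size: float = 1.0
    anisotropy_percent: float = 0.0
    anisotropy_axis_deg: float = 0.0
    wavelength: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.amplitude_contrast < 1.0):
            raise ValueError("amplitude_contrast must lie in [0, 1)")
        if self.anisotropy_percent < 0:
            raise ValueError("anisotropy_percent must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.wavelength is None:
            self.wavelength = electron_wavelength(self.voltage_kv)
        elif self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class CTFParams:
    """Per-particle CTF parameters; defocus in Angstrom, underfocus positive."""

    defocus_u: float
    defocus_v: float
    astigmatism_angle_deg: float = 0.0
    phase_shift_rad: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.defocus_u) and np.isfinite(self.defocus_v)):
            raise ValueError("defocus values must be finite")

    def defocus_at(self, azimuth_rad):
        """Astigmatic defocus at the given Fourier-space azimuth (radians)."""
        mean = 0.5 * (self.defocus_u + self.defocus_v)
        half = 0.5 * (self.defocus_u - self.defocus_v)
        ang = np.deg2rad(self.astigmatism_angle_deg)
        return mean + half * np.cos(2.0 * (azimuth_rad - ang))

    def with_offset(self, offset: float) -> "CTFParams":
        return CTFParams(
            self.defocus_u + offset,
            self.defocus_v + offset,
            self.astigmatism_angle_deg,
            self.phase_shift_rad,
        )


def _chi(optics: OpticsModel, ctf: CTFParams, s, azimuth_rad, defocus_offset=0.0):
    lam = optics.wavelength
    df = ctf.defocus_at(azimuth_rad) + defocus_offset
    cs = optics.cs_mm * 1e7  # mm -> Angstrom
    s2 = np.square(s)
    return (
        math.pi * lam * df * s2
        - 0.5 * math.pi * cs * lam**3 * s2 * s2
        + ctf.phase_shift_rad
    )


def ctf_value(optics: OpticsModel, ctf: CTFParams, s, azimuth_rad=0.0, defocus_offset=0.0):
    """Contrast transfer value at spatial frequency s (1/A), vectorised.

    Returns -[sqrt(1-A²) sin(chi) + A cos(chi)]; bounded in [-1, 1].
    """
    if np.any(np.asarray(s) < 0):
        raise ValueError("spatial frequency must be >= 0")
    a = optics.amplitude_contrast
    p = math.sqrt(1.0 - a * a)
    chi = _chi(optics, ctf, s, azimuth_rad, defocus_offset)
    return -(p * np.sin(chi) + a * np.cos(chi))


def complex_beam_ctf(optics: OpticsModel, ctf: CTFParams, s, azimuth_rad=0.0):
    """Complex transfer function of the left scattered beam.

    C+ = -(A + i sqrt(1-A²)) e^{-i chi}; the right beam is its conjugate,
    and (C+ + C-)/2 equals the ordinary real CTF.  Within the weak-phase
    model the image transform is I(g) = (C+ F(g, +z) + C- F(g, -z)) / 2
    with z the Ewald height, which is what simple-insertion inverts.
    """
    a = optics.amplitude_contrast
    p = math.sqrt(1.0 - a * a)
    chi = _chi(optics, ctf, s, azimuth_rad)
    return -(a + 1j * p) * np.exp(-1j * chi)


def ewald_height(s, lam: float, exact: bool = False):
    """Height z (1/A) of the Ewald sphere above the central plane at radius s.

    Paraboloid approximation z = lam s²/2 by default; exact sphere
    z = (1 - sqrt(1 - lam² s²))/lam when requested (requires lam·s < 1).
    """
    s = np.asarray(s, dtype=float)
    if exact:
        if np.any(lam * s >= 1.0):
            raise ValueError("exact Ewald height requires lambda * s < 1")
        return (1.0 - np.sqrt(1.0 - (lam * s) ** 2)) / lam
    return 0.5 * lam * s * s


def phase_shift_across_particle(d: float, lam: float, t: float) -> float:
    """Defocus-phase difference (radians) across a particle of diameter t.

    Delta-chi = pi lam t / d² between Fourier coefficients contributed by
    the top and the bottom of the particle at resolution d.
    """
    if d <= 0 or lam <= 0 or t <= 0:
        raise ValueError("d, lambda and t must all be positive")
    return math.pi * lam * t / (d * d)


@dataclass(frozen=True)
class LimitModel:
    """Tolerated-phase-error model for the depth-of-field resolution limit.

    The named estimates differ only in the phase error epsilon they
    tolerate across the particle; the Spence limit corresponds to
    epsilon = pi, giving d = sqrt(lam t).  The DeRosier and
    Downing-Glaeser presets ship as configurable approximations
    (epsilon = pi/2 and pi/4): the sources plot but do not print their
    constants.
    """

    name: str = "spence"
    tolerated_phase_error: float = field(default=math.pi)

    _PRESETS = {"spence": math.pi, "derosier": math.pi / 2, "downing_glaeser": math.pi / 4}

    def __post_init__(self):
        if self.name != "custom":
            if self.name not in self._PRESETS:
                raise ValueError(f"unknown limit model {self.name!r}")
            object.__setattr__(self, "tolerated_phase_error", self._PRESETS[self.name])
        if self.tolerated_phase_error <= 0:
            raise ValueError("tolerated phase error must be positive")


def resolution_limit(limit: LimitModel, lam: float, t: float) -> float:
    """Depth-of-field resolution limit d = sqrt(pi lam t / epsilon) in Angstrom."""
    if lam <= 0 or t <= 0:
        raise ValueError("lambda and t must be positive")
    return math.sqrt(math.pi * lam * t / limit.tolerated_phase_error)


def min_box_size(
    d_target: float,
    defocus_max: float,
    lam: float,
    particle_diameter: float,
    pixel_size: float,
) -> int:
    """Delocalisation-based lower bound on the particle box size, in pixels.

    The CTF delocalises information at resolution d by ~lam·defocus/d to
    either side of the particle; boxing tighter aliases it.  Returns the
    bound ceil[(D + 2 lam defocus_max / d_target) / pixel] rounded up to the
    next even integer.  This is a lower bound, not a reproduction of any
    particular processing choice.
    """
    if min(d_target, defocus_max, lam, particle_diameter, pixel_size) <= 0:
        raise ValueError("all inputs must be positive")
    extent = particle_diameter + 2.0 * lam * defocus_max / d_target
    box = math.ceil(extent / pixel_size)
    return box + (box % 2)
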