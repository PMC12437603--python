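"""Transducer physics: wavelength, PSF-ellipse geometry, microbubble packing
limits, and beam-profile width estimation.

The microbubble (MB) image formed by a linear-array probe is well approximated
by an anisotropic ellipse with an axial extent of one wavelength and a lateral
extent of two wavelengths.  From that ellipse two quantities follow directly:

* the PSF cross-sectional area ``π·λ²/2``, which shrinks quadratically with
  imaging frequency, and
* the maximum *resolvable* MB concentration, obtained by dividing the optimal
  congruent-ellipse packing fraction ``π/√12 ≈ 0.9069`` by that area —
  the densest arrangement in which neighbouring point-target images still do
  not overlap.

Beam profiles (e.g. hydrophone scans of the elevational beam) are summarized
by the full width at half maximum of their RMS-voltage trace.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .errors import DomainError, EstimationError

#: Average soft-tissue sound speed used for wavelength conversions [m/s].
SOUND_SPEED_TISSUE_M_S = 1540.0

#: FWHM of a Gaussian in units of its standard deviation: 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Optimal lattice packing fraction of congruent ellipses (identical to the
#: circle value under an affine map).
ELLIPSE_PACKING_FRACTION = np.pi / np.sqrt(12.0)


@dataclass(frozen=True)
class TransducerSpec:
    """Physical constants of one imaging probe.

    ``center_frequency_mhz`` is the operating frequency used for wavelength
    computations; ``nominal_transmit_mhz`` keeps the rounded data-sheet value
    when the two differ.
    """

    name: str
    center_frequency_mhz: float
    element_count: int
    pitch_mm: float
    aperture_mm: float
    elevational_beamwidth_mm: Optional[float] = None
    nominal_transmit_mhz: Optional[float] = None

    def __post_init__(self):
        if self.center_frequency_mhz <= 0:
            raise DomainError("center frequency must be positive")
        if self.pitch_mm <= 0:
            raise DomainError("pitch must be positive")
        if self.element_count < 1:
            raise DomainError("element count must be >= 1")
        expected = self.element_count * self.pitch_mm
        if abs(self.aperture_mm - expected) > 0.1 * expected:
            raise DomainError(
                f"aperture {self.aperture_mm} mm inconsistent with "
                f"element_count*pitch = {expected:.2f} mm (>10% off)"
            )
        if self.elevational_beamwidth_mm is not None and self.elevational_beamwidth_mm <= 0:
            raise DomainError("elevational beamwidth must be positive")

    def wavelength_um(self, sound_speed_m_s: float = SOUND_SPEED_TISSUE_M_S) -> float:
        return wavelength(sound_speed_m_s, self.center_frequency_mhz)

    def localization_grid_um(self, sound_speed_m_s: float = SOUND_SPEED_TISSUE_M_S) -> float:
        """Isotropic λ/10 grid spacing used for sub-pixel localization."""
        return self.wavelength_um(sound_speed_m_s) / 10.0


#: Probe presets. Apertures and pitches are data-sheet values; the operating
#: frequencies are the ones the wavelength computations are based on
#: (15.625 / 23 / 31.25 MHz), with nominal transmit values 15 / 23 / 31 MHz.
PRESETS: dict[str, TransducerSpec] = {
    "L22-14vX": TransducerSpec(
        name="L22-14vX",
        center_frequency_mhz=15.625,
        element_count=128,
        pitch_mm=0.1,
        aperture_mm=12.8,
        elevational_beamwidth_mm=0.90,
        nominal_transmit_mhz=15.0,
    ),
    "L35-16vX": TransducerSpec(
        name="L35-16vX",
        center_frequency_mhz=23.0,
        element_count=128,
        pitch_mm=0.07,
        aperture_mm=8.9,
        elevational_beamwidth_mm=0.92,
        nominal_transmit_mhz=23.0,
    ),
    "MS-550S": TransducerSpec(
        name="MS-550S",
        center_frequency_mhz=31.25,
        element_count=256,
        pitch_mm=0.055,
        aperture_mm=14.08,
        elevational_beamwidth_mm=0.48,
        nominal_transmit_mhz=31.0,
    ),
}


def get_preset(name: str) -> TransducerSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise DomainError(f"unknown transducer preset '{name}'; known: {sorted(PRESETS)}") from None


@dataclass(frozen=True)
class PSFEllipse:
    """Elliptical point-spread-function footprint (FWHM extents, μm)."""

    axial_fwhm_um: float
    lateral_fwhm_um: float

    def __post_init__(self):
        if self.axial_fwhm_um <= 0 or self.lateral_fwhm_um <= 0:
            raise DomainError("PSF extents must be positive")

    @property
    def area_um2(self) -> float:
        return np.pi * (self.axial_fwhm_um / 2.0) * (self.lateral_fwhm_um / 2.0)


@dataclass(frozen=True)
class BeamProfile:
    """A 1D RMS-voltage beam profile sampled along one spatial axis."""

    positions_mm: np.ndarray
    rms_v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions_mm", np.asarray(self.positions_mm, dtype=float))
        object.__setattr__(self, "rms_v", np.asarray(self.rms_v, dtype=float))
        if self.positions_mm.shape != self.rms_v.shape or self.positions_mm.ndim != 1:
            raise DomainError("positions and rms values must be 1D arrays of equal length")
        if len(self.positions_mm) < 3:
            raise DomainError("profile needs at least 3 samples")
        if np.any(np.diff(self.positions_mm) <= 0):
            raise DomainError("positions must be strictly increasing")
        if np.any(self.rms_v < 0):
            raise DomainError("rms values must be non-negative")
        if not np.any(self.rms_v > 0):
            raise DomainError("profile needs at least one strictly positive value")


def load_beam_profile(path) -> BeamProfile:
    """Read a two-column CSV (position_mm, vrms); a header row is tolerated."""
    positions, values = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            try:
                p, v = float(row[0]), float(row[1])
            except ValueError:
                continue  # header or comment line
            positions.append(p)
            values.append(v)
    return BeamProfile(np.asarray(positions), np.asarray(values))


def wavelength(sound_speed_m_s: float, frequency_mhz: float) -> float:
    """Acoustic wavelength in μm.

    ``c [m/s] / (f [MHz] · 1e6) = c/f [μm]`` — e.g. 1540 m/s at 15.625 MHz
    gives 98.56 μm.
    """
    if sound_speed_m_s <= 0:
        raise DomainError("sound speed must be positive")
    if frequency_mhz <= 0:
        raise DomainError("frequency must be positive")
    return sound_speed_m_s / frequency_mhz


def psf_ellipse(lambda_um: float) -> PSFEllipse:
    """PSF-size model: axial FWHM = λ, lateral FWHM = 2λ (area = πλ²/2)."""
    if lambda_um <= 0:
        raise DomainError("wavelength must be positive")
    return PSFEllipse(axial_fwhm_um=lambda_um, lateral_fwhm_um=2.0 * lambda_um)


def max_mb_density(psf: PSFEllipse) -> float:
    """Maximum resolvable microbubble density [1/mm²].

    Optimal congruent-ellipse packing fraction divided by the PSF footprint:
    the densest MB arrangement whose images remain non-overlapping.
    """
    area = psf.area_um2
    if area <= 0:
        raise DomainError("PSF area must be positive")
    return ELLIPSE_PACKING_FRACTION / (area * 1e-6)  # μm² -> mm²


def _fwhm_1d(positions: np.ndarray, values: np.ndarray) -> float:
    """FWHM of a single-peaked sampled profile by linear interpolation."""
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    i_peak = int(np.argmax(values))
    if i_peak == 0 or i_peak == len(values) - 1:
        raise EstimationError("profile peak lies on an endpoint; cannot bracket half maximum")
    half = values[i_peak] / 2.0

    def cross(idx_range, side):
        prev = i_peak
        for j in idx_range:
            if values[j] < half:
                # linear interpolation between j and the previous (inner) sample
                x0, x1 = positions[j], positions[prev]
                y0, y1 = values[j], values[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = j
        raise EstimationError(f"half maximum not crossed on the {side} side of the peak")

    left = cross(range(i_peak - 1, -1, -1), "left")
    right = cross(range(i_peak + 1, len(values)), "right")
    return float(right - left)


def fwhm(profile: BeamProfile) -> float:
    """Full width at half maximum of an RMS beam profile, in mm."""
    return _fwhm_1d(profile.positions_mm, profile.rms_v)


def measure_psf_fwhm(
    frame: np.ndarray,
    peak: tuple[int, int],
    pixel_dz_um: float,
    pixel_dx_um: float,
    isolation_radius_um: Optional[float] = None,
    average_lines: int = 2,
) -> tuple[float, float]:
    """Axial and lateral FWHM (μm) of an isolated point-target image.

    Takes the intensity profiles through ``peak`` along both axes and applies
    the half-maximum width estimator to each.  Profiles are averaged over
    ``±average_lines`` parallel pixel lines: for a separable (Gaussian-like)
    spot this rescales the amplitude without changing the width, while
    suppressing noise-induced early half-maximum crossings.  If
    ``isolation_radius_um`` is given, any other local maximum brighter than
    25% of the peak within that radius rejects the candidate (overlapping
    neighbour).
    """
    frame = np.asarray(frame, dtype=float)
    iz, ix = peak
    if isolation_radius_um is not None:
        peak_val = frame[iz, ix]
        local_max = (ndimage.maximum_filter(frame, size=3) == frame) & (frame > 0.25 * peak_val)
        zz, xx = np.nonzero(local_max)
        dist = np.hypot((zz - iz) * pixel_dz_um, (xx - ix) * pixel_dx_um)
        others = dist[(dist > 0.5 * min(pixel_dz_um, pixel_dx_um))]
        if np.any(others < isolation_radius_um):
            raise EstimationError("candidate not isolated: neighbouring maximum inside exclusion radius")
    x_lo, x_hi = max(0, ix - average_lines), min(frame.shape[1], ix + average_lines + 1)
    z_lo, z_hi = max(0, iz - average_lines), min(frame.shape[0], iz + average_lines + 1)
    axial = _fwhm_1d(np.arange(frame.shape[0]) * pixel_dz_um, frame[:, x_lo:x_hi].mean(axis=1))
    lateral = _fwhm_1d(np.arange(frame.shape[1]) * pixel_dx_um, frame[z_lo:z_hi, :].mean(axis=0))
    return axial, lateral
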