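"""Closed-form scan-protocol calculators for swept-source OCT.

Pure, deterministic functions: volume timing, Gaussian-spectrum axial
resolution, sampling-limited imaging depth and Gaussian focal spot
size.  Wavelengths are nm, beam diameters and focal lengths mm; results
carry the units stated in each docstring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScanProtocol",
    "volume_acquisition_time",
    "volume_rate",
    "axial_resolution",
    "sampling_imaging_depth",
    "focal_spot_diameter",
]


@dataclass(frozen=True)
class ScanProtocol:
    """Swept-source scan protocol.

    ``sampling_rate_hz`` and ``duty_cycle`` are metadata: they do not
    enter the depth formula but are validated for mutual consistency
    (the digitizer must fit ``samples_per_ascan`` points into the active
    part of one sweep, ``samples / sampling_rate <= duty_cycle / ascan_rate``).
    Set ``sampling_rate_hz=None`` to skip the check.
    """

    ascan_rate_hz: float = 400e3
    duty_cycle: float = 0.5
    n_ascans_per_bscan: int = 800
    n_bscans: int = 780
    samples_per_ascan: int = 2048
    sampling_rate_hz: float | None = 1.72e9
    center_wavelength_nm: float = 1060.0
    bandwidth_nm: float = 70.0  # 6 dB
    beam_diameter_pupil_mm: float = 0.36
    output_power_mw: float = 1.68

    def __post_init__(self) -> None:
        if self.n_ascans_per_bscan < 1 or self.n_bscans < 1 or self.samples_per_ascan < 1:
            raise ValueError("all counts must be >= 1")
        if not self.ascan_rate_hz > 0:
            raise ValueError("A-scan rate must be > 0")
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty cycle must lie in (0, 1]")
        if not self.bandwidth_nm < self.center_wavelength_nm:
            raise ValueError("bandwidth must be smaller than the center wavelength")
        if self.sampling_rate_hz is not None:
            if not self.sampling_rate_hz > 0:
                raise ValueError("sampling rate must be > 0")
            active = self.duty_cycle / self.ascan_rate_hz
            needed = self.samples_per_ascan / self.sampling_rate_hz
            if needed > active * (1 + 1e-9):
                raise ValueError(
                    f"impossible protocol: {self.samples_per_ascan} samples need "
                    f"{needed * 1e6:.3f} us but the active sweep lasts {active * 1e6:.3f} us"
                )

    @classmethod
    def acquisition(cls) -> "ScanProtocol":
        """High-resolution acquisition pattern (800 x 780 A-scans)."""
        return cls()

    @classmethod
    def alignment(cls) -> "ScanProtocol":
        """High-speed alignment pattern (400 x 100 A-scans, 10 Hz volumes)."""
        return cls(n_ascans_per_bscan=400, n_bscans=100)


def volume_acquisition_time(p: ScanProtocol) -> float:
    """Seconds per volume: ``n_ascans_per_bscan * n_bscans / ascan_rate``."""
    return p.n_ascans_per_bscan * p.n_bscans / p.ascan_rate_hz


def volume_rate(p: ScanProtocol) -> float:
    """Volumes per second; exact reciprocal of the acquisition time."""
    return 1.0 / volume_acquisition_time(p)


def axial_resolution(center_wavelength_nm: float, bandwidth_nm: float,
                     medium_index: float = 1.0) -> float:
    """Axial resolution (um, FWHM) for a Gaussian spectrum.

    ``(2 ln 2 / pi) * lambda0**2 / (dlambda * n)`` — the standard
    coherence-length convention for a Gaussian source of FWHM bandwidth
    ``dlambda``.  ``medium_index`` converts the in-air value to tissue.
    """
    if not bandwidth_nm < center_wavelength_nm:
        raise ValueError("bandwidth must be smaller than the center wavelength")
    if not (bandwidth_nm > 0 and center_wavelength_nm > 0 and medium_index > 0):
        raise ValueError("inputs must be positive")
    nm = (2.0 * math.log(2.0) / math.pi) * center_wavelength_nm ** 2 / bandwidth_nm
    return nm / medium_index / 1000.0


def sampling_imaging_depth(center_wavelength_nm: float, sweep_range_nm: float,
                           samples: int) -> float:
    """Sampling-limited imaging depth (mm, in air).

    ``lambda0**2 * N / (4 * sweep_range)`` for N spectral samples across
    the full sweep range.  Note the full sweep range exceeds the 6 dB
    bandwidth, so this is not evaluated with the 6 dB figure.
    """
    if not sweep_range_nm > 0:
        raise ValueError("sweep range must be > 0")
    if samples < 1:
        raise ValueError("need at least one sample")
    nm = center_wavelength_nm ** 2 * samples / (4.0 * sweep_range_nm)
    return nm / 1e6


def focal_spot_diameter(center_wavelength_nm: float, beam_diameter_pupil_mm: float,
                        focal_length_mm: float, medium_index: float = 1.0) -> float:
    """Gaussian 1/e^2 focal spot diameter on the retina (um).

    ``4 * (lambda0 / n) * f / (pi * D)`` for a beam of 1/e^2 diameter D
    at the pupil focused over focal length f in a medium of index n.
    The result is labelled with this convention; other aperture
    conventions shift the value by tens of percent.
    """
    if not (beam_diameter_pupil_mm > 0 and focal_length_mm > 0
            and center_wavelength_nm > 0 and medium_index > 0):
        raise ValueError("inputs must be positive")
    nm = 4.0 * (center_wavelength_nm / medium_index) * focal_length_mm / (
        math.pi * beam_diameter_pupil_mm)
    return nm / 1000.0
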