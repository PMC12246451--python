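"""Microscope calibration procedures as pure computations.

Three quantities routinely need calibrating before the design math can be
trusted: the effective camera length (from Bragg-spot distances of a known
crystal via the camera equation R·d = λ·L), the probe convergence
semi-angle (from the ratio of Bragg-disk spacing to aperture diameter on
the detector), and the scan step (from an imaged row of atoms with known
spacing).  All three are implemented on user-entered measurements; peak
finding on calibration images is out of scope.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "CalibrationKind",
    "CalibrationMeasurement",
    "camera_length_from_spots",
    "semi_angle_from_disks",
    "scan_step_correction",
]


class CalibrationKind(str, enum.Enum):
    SCAN_STEP = "scan_step"
    SEMI_ANGLE = "semi_angle"
    CAMERA_LENGTH = "camera_length"


@dataclass(frozen=True)
class CalibrationMeasurement:
    """One calibration measurement: a known spacing and a measured extent."""

    kind: CalibrationKind
    known_spacing_A: float
    measured_extent: float
    reference_count: int = 1

    def __post_init__(self) -> None:
        if self.known_spacing_A <= 0:
            raise ValueError("known spacing must be positive")
        if self.measured_extent <= 0:
            raise ValueError("measured extent must be positive")


def camera_length_from_spots(r_hkl_mm: float, d_hkl_A: float, lambda_pm: float) -> float:
    """Effective camera length in cm from the camera equation R·d = λ·L.

    ``r_hkl_mm`` is the measured distance of the diffraction spot from the
    direct beam on the detector, ``d_hkl_A`` the known lattice spacing.
    """
    if r_hkl_mm <= 0 or d_hkl_A <= 0 or lambda_pm <= 0:
        raise ValueError("spot distance, spacing and wavelength must be positive")
    # R·d = λ·L  ->  L = R·d/λ  (mm·Å / pm -> convert to cm)
    return r_hkl_mm * 1e-3 * d_hkl_A * 1e-10 / (lambda_pm * 1e-12) * 1e2


def spot_distance_from_camera_length(
    camera_length_cm: float, d_hkl_A: float, lambda_pm: float
) -> float:
    """Inverse of :func:`camera_length_from_spots`: R = λ·L/d, in mm."""
    if camera_length_cm <= 0 or d_hkl_A <= 0 or lambda_pm <= 0:
        raise ValueError("camera length, spacing and wavelength must be positive")
    return lambda_pm * 1e-12 * camera_length_cm * 1e-2 / (d_hkl_A * 1e-10) * 1e3


def semi_angle_from_disks(
    bragg_angle_mrad: float, disk_spacing_px: float, aperture_diameter_px: float
) -> float:
    """Convergence semi-angle (mrad) from Bragg-disk geometry.

    The disk spacing on the detector corresponds to the (known) Bragg
    scattering angle of the calibration crystal; the aperture image
    diameter corresponds to 2α.  Hence α = θ_B · (aperture/2) / spacing.
    """
    if bragg_angle_mrad <= 0 or aperture_diameter_px <= 0:
        raise ValueError("Bragg angle and aperture diameter must be positive")
    if disk_spacing_px <= 0:
        raise ValueError("disk spacing must be positive")
    return bragg_angle_mrad * (aperture_diameter_px / 2.0) / disk_spacing_px


def scan_step_correction(
    nominal_step_A: float, expected_spacing_A: float, measured_pixels_per_repeat: float
) -> float:
    """Correction factor between real and nominal scan step.

    A feature of known real-space extent (e.g. a row of atoms of known
    spacing) is measured in scan pixels; the factor is
    expected / (measured_px · nominal_step).  The corrected step is
    nominal · factor.
    """
    if nominal_step_A <= 0 or expected_spacing_A <= 0 or measured_pixels_per_repeat <= 0:
        raise ValueError("all calibration inputs must be positive")
    return expected_spacing_A / (measured_pixels_per_repeat * nominal_step_A)
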