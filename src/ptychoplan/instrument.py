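"""Core acquisition-parameter model and elementary derived geometry.

The classes here describe one 4D-STEM acquisition: the electron beam
(voltage, convergence semi-angle, defocus, current), the scan raster and
the pixelated detector.  From these, :func:`derive_geometry` produces the
quantities every downstream calculation needs — electron wavelength,
angular pitch of one effective detector pixel, maximum detected angle
(optionally clipped by the differential pumping aperture), bright-field
disk diameter in pixels, detector coverage in multiples of the semi-angle,
and the electron dose budget.

Unit conventions (applied consistently across the package): voltages in
kV, angles in mrad, real-space lengths in Å except defocus (nm) and
detector pitch (µm), camera length in cm, wavelength in pm, current in pA,
dwell time in µs, dose in e/Å².
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from scipy import constants as _const

__all__ = [
    "BeamSetting",
    "ScanSetting",
    "DetectorModel",
    "AcquisitionPlan",
    "DerivedGeometry",
    "Method",
    "electron_wavelength",
    "derive_geometry",
    "dose_budget",
    "geometric_probe_diameter",
]


class Method(str, enum.Enum):
    """Reconstruction family the plan targets."""

    SSB = "SSB"
    ITR = "ITR"


@dataclass(frozen=True)
class BeamSetting:
    """Electron-beam settings.

    Parameters
    ----------
    voltage_kv:
        Accelerating voltage in kV.
    alpha_mrad:
        Probe convergence semi-angle in mrad.
    defocus_nm:
        Defocus magnitude in nm (0 = focused; sign is not tracked).
    current_pa:
        Probe current in pA.
    d0_A:
        Focused probe diameter in Å, using the vendor convention of the
        disk containing 59 % of the total beam intensity.
    """

    voltage_kv: float
    alpha_mrad: float
    defocus_nm: float = 0.0
    current_pa: float = 0.0
    d0_A: float = 0.0

    def __post_init__(self) -> None:
        if self.voltage_kv <= 0:
            raise ValueError("accelerating voltage must be positive")
        if self.alpha_mrad <= 0:
            raise ValueError("convergence semi-angle must be positive")
        if self.defocus_nm < 0:
            raise ValueError("defocus is a magnitude (>= 0)")
        if self.current_pa < 0 or self.d0_A < 0:
            raise ValueError("probe current and d0 must be non-negative")


@dataclass(frozen=True)
class ScanSetting:
    """Scan raster: step (Å), grid size, dwell time (µs) and skipping.

    ``skip`` keeps every ``(skip + 1)``-th position along each axis, the
    post-processing trick used to trade real-space sampling against dose.
    """

    step_A: float
    nx: int = 1
    ny: int = 1
    dwell_us: float = 1.0
    skip: int = 0

    def __post_init__(self) -> None:
        if self.step_A <= 0:
            raise ValueError("scan step must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("scan grid must contain at least one position")
        if self.dwell_us <= 0:
            raise ValueError("dwell time must be positive")
        if self.skip < 0 or int(self.skip) != self.skip:
            raise ValueError("skip must be a non-negative integer")

    @property
    def step_used_A(self) -> float:
        """Effective step after skipping: step × (skip + 1)."""
        return self.step_A * (self.skip + 1)


@dataclass(frozen=True)
class DetectorModel:
    """Pixelated detector geometry and angular calibration inputs.

    ``camera_length_cm`` is the *effective* camera length.  ``binning``
    reduces the native ``n_pixels`` grid; ``padding`` is the number of
    zero pixels added per side post-acquisition (it enlarges the
    reconstruction grid without changing the angular pitch).
    ``paar_mrad`` is the pumping-aperture angle restriction — the hard
    ceiling on the detected scattering angle, when present.
    """

    n_pixels: int
    pitch_um: float
    binning: int = 1
    padding: int = 0
    camera_length_cm: float | None = None
    paar_mrad: float | None = None

    def __post_init__(self) -> None:
        if self.n_pixels < 2:
            raise ValueError("detector needs at least 2 pixels per side")
        if self.pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.binning < 1 or self.n_pixels % self.binning:
            raise ValueError("n_pixels must be divisible by binning")
        if self.padding < 0:
            raise ValueError("padding must be non-negative")
        if self.camera_length_cm is not None and self.camera_length_cm <= 0:
            raise ValueError("camera length must be positive")
        if self.paar_mrad is not None and self.paar_mrad <= 0:
            raise ValueError("PAAR limit must be positive")

    @property
    def pitch_eff_um(self) -> float:
        """Effective pixel pitch including binning."""
        return self.pitch_um * self.binning

    @property
    def half_width_px(self) -> int:
        """Half width M of the (binned) detector array in effective pixels."""
        return (self.n_pixels // self.binning) // 2

    @property
    def padding_factor(self) -> float:
        """Grid enlargement (M + padding)/M used for the reconstruction pixel."""
        m = self.half_width_px
        return (m + self.padding) / m


@dataclass(frozen=True)
class AcquisitionPlan:
    """One complete acquisition: beam + scan + detector + target method."""

    beam: BeamSetting
    scan: ScanSetting
    detector: DetectorModel
    method: Method = Method.ITR


@dataclass(frozen=True)
class DerivedGeometry:
    """Elementary derived quantities for one plan (see module docstring)."""

    wavelength_pm: float
    dtheta_mrad: float
    theta_mrad: float
    theta_unclipped_mrad: float
    bf_disk_px: float
    coverage_alpha: float
    electrons_per_position: float
    dose_e_per_A2: float
    padding_factor: float = 1.0


class ConfigurationError(ValueError):
    """A plan is missing a quantity needed for the requested derivation."""


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic de Broglie wavelength of the beam electrons, in pm.

    λ = h / sqrt(2 m₀ e V (1 + eV / 2 m₀ c²)) with CODATA constants.
    """
    if voltage_kv <= 0:
        raise ValueError("accelerating voltage must be positive")
    v = voltage_kv * 1e3
    ev = _const.e * v
    lam_m = _const.h / math.sqrt(
        2 * _const.m_e * ev * (1 + ev / (2 * _const.m_e * _const.c**2))
    )
    return lam_m * 1e12


def dose_budget(beam: BeamSetting, scan: ScanSetting) -> tuple[float, float]:
    """Electrons per scan position and areal dose in e/Å².

    electrons/position = I·t/e; dose = electrons / ΔR_used², where
    ΔR_used = ΔR·(skip+1) is the effective step.  Skipping positions
    therefore lowers the dose by (skip+1)².
    """
    electrons = beam.current_pa * 1e-12 * scan.dwell_us * 1e-6 / _const.e
    dose = electrons / scan.step_used_A**2
    return electrons, dose


def geometric_probe_diameter(
    beam: BeamSetting, composition: str = "additive"
) -> float:
    """Geometric probe diameter in Å from semi-angle, defocus and d0.

    The defocus cone contributes 2·Δf·tan(α).  The default combines it
    with the focused diameter additively, d0 + 2·Δf·tan(α), which is the
    conservative (larger) estimate; ``composition="quadrature"`` uses
    sqrt(d0² + (2·Δf·tanα)²) instead.
    """
    cone_A = 2.0 * beam.defocus_nm * 10.0 * math.tan(beam.alpha_mrad * 1e-3)
    if composition == "additive":
        return beam.d0_A + cone_A
    if composition == "quadrature":
        return math.hypot(beam.d0_A, cone_A)
    raise ValueError(f"unknown composition {composition!r}")


def derive_geometry(plan: AcquisitionPlan) -> DerivedGeometry:
    """Angular calibration, coverage and dose for one plan.

    Δθ = p_eff / L (small angle) per effective pixel; the maximum detected
    angle θ = M·Δθ at the midpoint of the detector edge, clipped to the
    pumping-aperture limit when one is set.  Padding enlarges the
    reconstruction grid (``padding_factor``) but does not change Δθ.
    """
    det = plan.detector
    if det.camera_length_cm is None:
        raise ConfigurationError("effective camera length is required")
    lam = electron_wavelength(plan.beam.voltage_kv)
    dtheta_mrad = det.pitch_eff_um * 1e-6 / (det.camera_length_cm * 1e-2) * 1e3
    theta_unclipped = det.half_width_px * dtheta_mrad
    theta = theta_unclipped
    if det.paar_mrad is not None:
        theta = min(theta, det.paar_mrad)
    bf_disk_px = 2.0 * plan.beam.alpha_mrad / dtheta_mrad
    electrons, dose = dose_budget(plan.beam, plan.scan)
    return DerivedGeometry(
        wavelength_pm=lam,
        dtheta_mrad=dtheta_mrad,
        theta_mrad=theta,
        theta_unclipped_mrad=theta_unclipped,
        bf_disk_px=bf_disk_px,
        coverage_alpha=theta / plan.beam.alpha_mrad,
        electrons_per_position=electrons,
        dose_e_per_A2=dose,
        padding_factor=det.padding_factor,
    )
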