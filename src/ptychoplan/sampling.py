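"""Sampling, resolution, window and defocus bounds for ptychography design.

The closed-form criteria implemented here connect the acquisition
parameters to what a reconstruction can deliver:

* probe window D_ψ = λ/Δθ — the computational real-space field of the
  reconstructed probe; the probe must fit in half of it (Nyquist),
* lateral resolution r_xy = λ/sin(2α) from the 2α transfer limit,
* maximum direct-method (SSB) scan step ΔR = λ/(2 sin 2α) = r_xy/2,
* iterative-method reconstruction pixel Pix_ITR = λ/θ,
* real-space sampling/overlap ratios of adjacent probe positions,
* the combined real–reciprocal sampling number Ŝ = λ/(2 ΔR Δθ) ≥ 1,
* maximum defocus Δf_max filling half of the probe window,
* minimum multislice slice thickness r_z = λ/(2 sin²(θ/2)).

All formulas use exact trigonometric forms; small-angle versions appear
only as cross-checks in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .instrument import (
    AcquisitionPlan,
    derive_geometry,
    electron_wavelength,
    geometric_probe_diameter,
)

__all__ = [
    "SamplingReport",
    "probe_window",
    "lateral_resolution",
    "ssb_max_step",
    "itr_pixel_size",
    "overlap_metrics",
    "combined_sampling",
    "max_defocus",
    "depth_resolution",
    "nyquist_step",
    "build_report",
]

_PM_TO_A = 1e-2  # 1 pm = 0.01 Å


def probe_window(lambda_pm: float, dtheta_mrad: float) -> tuple[float, float]:
    """Probe window D_ψ = λ/Δθ and maximum probe diameter D_ψ/2, in Å."""
    if dtheta_mrad <= 0:
        raise ValueError("angular pitch must be positive")
    window_A = lambda_pm * _PM_TO_A / (dtheta_mrad * 1e-3)
    return window_A, window_A / 2.0


def lateral_resolution(lambda_pm: float, alpha_mrad: float) -> float:
    """Lateral resolution r_xy = λ/sin(2α) in Å (exact sine form)."""
    two_alpha = 2.0 * alpha_mrad * 1e-3
    if not 0 < two_alpha < math.pi / 2:
        raise ValueError("2α must lie in (0, π/2)")
    return lambda_pm * _PM_TO_A / math.sin(two_alpha)


def ssb_max_step(lambda_pm: float, alpha_mrad: float) -> float:
    """Maximum direct-method scan step λ/(2 sin 2α) in Å (= r_xy/2)."""
    return lateral_resolution(lambda_pm, alpha_mrad) / 2.0


def itr_pixel_size(
    lambda_pm: float, theta_mrad: float, padding_factor: float = 1.0
) -> float:
    """Iterative-method reconstruction pixel λ/θ in Å.

    ``padding_factor`` ≥ 1 models zero-padding the diffraction patterns,
    which shrinks the reconstruction pixel proportionally.
    """
    if theta_mrad <= 0:
        raise ValueError("maximum detected angle must be positive")
    if padding_factor < 1:
        raise ValueError("padding factor must be >= 1")
    return lambda_pm * _PM_TO_A / (theta_mrad * 1e-3) / padding_factor


def overlap_metrics(d_probe_A: float, step_used_A: float) -> tuple[float, float, float]:
    """Real-space sampling ratios of adjacent probe positions.

    Returns (SR_overlap %, SR_linear, SR_areal):
    overlap = (d − ΔR)/d·100 clamped at 0; linear = d/ΔR;
    areal = π(d/2)²/ΔR².  An idealized point probe (d = 0) has zero
    overlap by definition.
    """
    if d_probe_A < 0 or step_used_A <= 0:
        raise ValueError("probe diameter must be >= 0 and step positive")
    if d_probe_A == 0.0:
        return 0.0, 0.0, 0.0
    overlap = max(0.0, (d_probe_A - step_used_A) / d_probe_A * 100.0)
    linear = d_probe_A / step_used_A
    areal = math.pi * (d_probe_A / 2.0) ** 2 / step_used_A**2
    return overlap, linear, areal


def combined_sampling(lambda_pm: float, step_used_A: float, dtheta_mrad: float) -> float:
    """Combined real–reciprocal sampling Ŝ = λ/(2 ΔR Δθ), dimensionless.

    The acquisition satisfies the sampling criterion Δθ·ΔR ≤ λ/2 iff
    Ŝ ≥ 1 (checked identically in x and y for the isotropic grids this
    package models).
    """
    if lambda_pm <= 0 or step_used_A <= 0 or dtheta_mrad <= 0:
        raise ValueError("all inputs must be positive")
    return lambda_pm * _PM_TO_A / (2.0 * step_used_A * dtheta_mrad * 1e-3)


def max_defocus(d_probe_max_A: float, alpha_mrad: float, d0_A: float = 0.0) -> float:
    """Maximum defocus in nm before the probe outgrows half the window.

    Δf_max = (d_probe_max − d0)/(2 tan α) under the additive probe-diameter
    convention, floored at 0 when the focused probe alone already fills the
    window.  With d0 = 0 this is the pure geometric bound.
    """
    if alpha_mrad <= 0:
        raise ValueError("semi-angle must be positive")
    free_A = max(0.0, d_probe_max_A - d0_A)
    return free_A / (2.0 * math.tan(alpha_mrad * 1e-3)) / 10.0


def depth_resolution(lambda_pm: float, theta_mrad: float) -> float:
    """Minimum useful multislice slice thickness r_z = λ/(2 sin²(θ/2)), Å."""
    theta = theta_mrad * 1e-3
    if not 0 < theta < math.pi:
        raise ValueError("θ must lie in (0, π)")
    return lambda_pm * _PM_TO_A / (2.0 * math.sin(theta / 2.0) ** 2)


def nyquist_step(spacing_A: float) -> float:
    """Scan step needed to Nyquist-sample a lattice spacing: spacing/2."""
    if spacing_A <= 0:
        raise ValueError("spacing must be positive")
    return spacing_A / 2.0


@dataclass(frozen=True)
class SamplingReport:
    """Every derived sampling/resolution/dose figure for one plan."""

    wavelength_pm: float
    dtheta_mrad: float
    theta_mrad: float
    coverage_alpha: float
    bf_disk_px: float
    probe_window_A: float
    d_probe_max_A: float
    d_probe_A: float
    lateral_resolution_A: float
    ssb_max_step_A: float
    itr_pixel_A: float
    step_used_A: float
    overlap_pct: float
    sr_linear: float
    sr_areal: float
    s_hat: float
    max_defocus_nm: float
    depth_resolution_A: float
    resolution_gain: float
    electrons_per_position: float
    dose_e_per_A2: float


def build_report(plan: AcquisitionPlan) -> SamplingReport:
    """Evaluate every criterion for one plan and collect the results.

    ``resolution_gain`` = ΔR_used / Pix_ITR: how many reconstruction
    pixels one scan step spans (a gain > 1 means the reconstructed image
    has more pixels than scan positions).  Skipping enters through
    ΔR_used; detector padding through the padding-adjusted Pix_ITR.
    """
    geo = derive_geometry(plan)
    lam = geo.wavelength_pm
    window_A, d_max_A = probe_window(lam, geo.dtheta_mrad)
    d_probe_A = geometric_probe_diameter(plan.beam)
    step_used = plan.scan.step_used_A
    overlap, linear, areal = overlap_metrics(d_probe_A, step_used)
    pix_itr = itr_pixel_size(lam, geo.theta_mrad, geo.padding_factor)
    return SamplingReport(
        wavelength_pm=lam,
        dtheta_mrad=geo.dtheta_mrad,
        theta_mrad=geo.theta_mrad,
        coverage_alpha=geo.coverage_alpha,
        bf_disk_px=geo.bf_disk_px,
        probe_window_A=window_A,
        d_probe_max_A=d_max_A,
        d_probe_A=d_probe_A,
        lateral_resolution_A=lateral_resolution(lam, plan.beam.alpha_mrad),
        ssb_max_step_A=ssb_max_step(lam, plan.beam.alpha_mrad),
        itr_pixel_A=pix_itr,
        step_used_A=step_used,
        overlap_pct=overlap,
        sr_linear=linear,
        sr_areal=areal,
        s_hat=combined_sampling(lam, step_used, geo.dtheta_mrad),
        max_defocus_nm=max_defocus(d_max_A, plan.beam.alpha_mrad, plan.beam.d0_A),
        depth_resolution_A=depth_resolution(lam, geo.theta_mrad),
        resolution_gain=step_used / pix_itr,
        electrons_per_position=geo.electrons_per_position,
        dose_e_per_A2=geo.dose_e_per_A2,
    )
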