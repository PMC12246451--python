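"""Analytic single-side-band (SSB) phase contrast transfer function.

In SSB ptychography the phase of a spatial frequency Q is read out of the
lens-shaped "trotter" regions where the bright-field disk overlaps one
diffracted disk.  With ω = Q/α the dimensionless frequency and all disks
of unit radius (α), the transfer weight is the area of the double-overlap
lens between the central disk and the disk displaced by ω, minus the
triple-overlap region where the opposite disk also intrudes (those pixels
carry contributions of both sidebands and cancel).  The resulting curve
rises from zero at ω = 0 to a maximum near ω = 0.9 and falls back to zero
at ω = 2, where the disks separate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AxisUnit",
    "Normalization",
    "CTFCurve",
    "lens_area",
    "ssb_overlap_area",
    "ssb_ctf",
    "convert_axis",
    "SSB_PEAK_OMEGA",
    "ssb_peak_area",
]

#: Location of the transfer maximum on the ω axis (argmax of the net
#: overlap area; the canonical "0.9 α" of SSB geometry).
SSB_PEAK_OMEGA = 0.9


class AxisUnit(str, enum.Enum):
    OMEGA = "omega"  # multiples of α
    MRAD = "mrad"  # scattering angle
    ANGSTROM = "angstrom"  # real-space spacing λ/Q


class Normalization(str, enum.Enum):
    AREA_RATIO = "area_ratio"  # overlap area / disk area πα²
    MAX_ONE = "max_one"  # peak scaled to exactly 1


@dataclass(frozen=True)
class CTFCurve:
    """Transfer weights on a tagged frequency axis."""

    axis: np.ndarray
    values: np.ndarray
    axis_unit: AxisUnit
    normalization: Normalization | None = None
    alpha_mrad: float | None = None
    lambda_pm: float | None = None

    def __post_init__(self) -> None:
        if self.axis.shape != self.values.shape:
            raise ValueError("axis and values must have equal shapes")


def lens_area(separation: np.ndarray | float) -> np.ndarray | float:
    """Intersection area of two unit disks whose centres are ``separation`` apart.

    2·cos⁻¹(s/2) − (s/2)·sqrt(4 − s²) for s < 2, else 0.
    """
    s = np.asarray(separation, dtype=float)
    s_clipped = np.minimum(s, 2.0)
    area = 2.0 * np.arccos(s_clipped / 2.0) - (s_clipped / 2.0) * np.sqrt(
        4.0 - s_clipped**2
    )
    area = np.where(s >= 2.0, 0.0, area)
    return area if area.ndim else float(area)


def ssb_overlap_area(omega: np.ndarray | float) -> np.ndarray | float:
    """Net single-sideband overlap area at frequency ω, in units of α².

    Double-overlap lens between the central disk and the disk shifted by
    ω, minus the triple-overlap region shared with the disk shifted by
    −ω.  The triple overlap (the intersection of all three disks) equals
    the lens between the two shifted disks, separation 2ω, and vanishes
    for ω ≥ 1.  The whole expression is 0 at ω = 0 (full cancellation)
    and for ω ≥ 2 (disjoint disks).
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("ω must be non-negative")
    double = lens_area(w)
    triple = lens_area(2.0 * w)
    net = np.where(w == 0.0, 0.0, double - triple)
    return net if net.ndim else float(net)


def ssb_peak_area() -> float:
    """Net overlap area at the transfer maximum (ω = 0.9), in α² units."""
    return float(ssb_overlap_area(SSB_PEAK_OMEGA))


def ssb_ctf(
    omega_grid: np.ndarray | None = None,
    alpha_mrad: float | None = None,
    normalization: Normalization | str = Normalization.MAX_ONE,
    lambda_pm: float | None = None,
) -> CTFCurve:
    """SSB transfer curve on an ω grid (default 0…2.5, step 0.001)."""
    if omega_grid is None:
        omega_grid = np.arange(0.0, 2.5 + 1e-12, 0.001)
    omega_grid = np.asarray(omega_grid, dtype=float)
    normalization = Normalization(normalization)
    values = np.asarray(ssb_overlap_area(omega_grid))
    if normalization is Normalization.AREA_RATIO:
        values = values / np.pi
    elif values.max() > 0:
        values = values / values.max()
    return CTFCurve(
        axis=omega_grid,
        values=values,
        axis_unit=AxisUnit.OMEGA,
        normalization=normalization,
        alpha_mrad=alpha_mrad,
        lambda_pm=lambda_pm,
    )


def convert_axis(
    curve: CTFCurve,
    target_unit: AxisUnit | str,
    alpha_mrad: float | None = None,
    lambda_pm: float | None = None,
) -> CTFCurve:
    """Re-express the frequency axis in ω, mrad or Å; values are unchanged.

    Q_mrad = ω·α and d_Å = λ/Q (Q as an angle).  Conversion to Å drops
    zero-frequency points (infinite spacing).  Round trips are identities.
    """
    target = AxisUnit(target_unit)
    alpha = alpha_mrad if alpha_mrad is not None else curve.alpha_mrad
    lam = lambda_pm if lambda_pm is not None else curve.lambda_pm
    axis, values = curve.axis, curve.values

    def to_mrad(ax: np.ndarray, unit: AxisUnit) -> np.ndarray:
        if unit is AxisUnit.MRAD:
            return ax
        if unit is AxisUnit.OMEGA:
            if alpha is None:
                raise ValueError("α is required to convert ω to an angle")
            return ax * alpha
        if lam is None:
            raise ValueError("λ is required to convert Å to an angle")
        return lam * 1e-2 / ax * 1e3  # Q_rad = λ_Å/d_Å, then rad -> mrad

    if target is curve.axis_unit:
        return curve
    q_mrad = to_mrad(axis, curve.axis_unit)
    if target is AxisUnit.MRAD:
        new_axis = q_mrad
    elif target is AxisUnit.OMEGA:
        if alpha is None:
            raise ValueError("α is required to convert an angle to ω")
        new_axis = q_mrad / alpha
    else:
        if lam is None:
            raise ValueError("λ is required to convert an angle to Å")
        keep = q_mrad != 0
        q_mrad, values = q_mrad[keep], values[keep]
        new_axis = lam * 1e-2 / (q_mrad * 1e-3)
    return CTFCurve(
        axis=new_axis,
        values=values,
        axis_unit=target,
        normalization=curve.normalization,
        alpha_mrad=alpha,
        lambda_pm=lam,
    )
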