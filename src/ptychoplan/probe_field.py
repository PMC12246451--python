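"""Fourier-optics probe simulation, probe-window coverage and illumination maps.

The probe is formed by a hard circular aperture of semi-angle α with a
defocus phase χ(k) = π·λ·Δf·k²; no other aberrations and full coherence
are assumed (aberration-corrected instrument).  The real-space wavefield
is the inverse Fourier transform of the aperture function, normalized to
unit total intensity.

From the simulated field the module measures the d59 diameter (smallest
centred circle containing 59 % of the intensity, the vendor convention
for probe size), the fraction of intensity inside a probe window of given
side, and scan-grid illumination maps with their uniformity figure
U = 100·I_min/I_max over the interior of the scanned area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instrument import ScanSetting

__all__ = [
    "ProbeField",
    "IlluminationMap",
    "simulate_probe",
    "probe_d59",
    "window_coverage_fraction",
    "illumination_map",
]


@dataclass(frozen=True)
class ProbeField:
    """Complex probe wavefield on a square real-space grid.

    ``psi`` is normalized so that Σ|ψ|²·pixel_area = 1; the probe is
    centred on the grid (intensity centroid at the array centre for the
    defocus-only probes produced here).
    """

    psi: np.ndarray
    side_A: float
    lambda_pm: float | None = None
    alpha_mrad: float | None = None
    defocus_nm: float | None = None

    def __post_init__(self) -> None:
        if self.psi.ndim != 2 or self.psi.shape[0] != self.psi.shape[1]:
            raise ValueError("probe field must be a square 2D array")
        if self.side_A <= 0:
            raise ValueError("grid side must be positive")

    @property
    def samples(self) -> int:
        return self.psi.shape[0]

    @property
    def pitch_A(self) -> float:
        return self.side_A / self.samples

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.psi) ** 2


class AliasingError(ValueError):
    """Requested probe parameters cannot be represented on the grid."""


def simulate_probe(
    lambda_pm: float,
    alpha_mrad: float,
    defocus_nm: float,
    side_A: float,
    samples: int,
) -> ProbeField:
    """Aperture + defocus probe on a ``samples``² grid of side ``side_A`` Å.

    Raises :class:`AliasingError` when the aperture is sampled by fewer
    than 4 reciprocal-space samples across its diameter, or extends beyond
    the grid's Nyquist frequency.
    """
    lam_A = lambda_pm * 1e-2
    k_alpha = alpha_mrad * 1e-3 / lam_A  # aperture radius as spatial frequency, 1/Å
    dk = 1.0 / side_A
    if 2.0 * k_alpha / dk < 4.0:
        raise AliasingError(
            f"aperture diameter spans {2 * k_alpha / dk:.2f} reciprocal samples; "
            f"need >= 4 (increase side_A above {2 * lam_A / (alpha_mrad * 1e-3):.2f} Å)"
        )
    k_nyquist = samples / (2.0 * side_A)
    if k_alpha > k_nyquist:
        raise AliasingError(
            f"aperture radius {k_alpha:.3f} 1/Å exceeds grid Nyquist "
            f"{k_nyquist:.3f} 1/Å (increase samples)"
        )
    k = np.fft.fftfreq(samples, d=side_A / samples)
    kx, ky = np.meshgrid(k, k, indexing="xy")
    k2 = kx**2 + ky**2
    aperture = (k2 <= k_alpha**2).astype(float)
    chi = np.pi * lam_A * defocus_nm * 10.0 * k2
    psi = np.fft.fftshift(np.fft.ifft2(aperture * np.exp(-1j * chi)))
    pitch = side_A / samples
    norm = np.sqrt(np.sum(np.abs(psi) ** 2) * pitch**2)
    return ProbeField(
        psi=psi / norm,
        side_A=side_A,
        lambda_pm=lambda_pm,
        alpha_mrad=alpha_mrad,
        defocus_nm=defocus_nm,
    )


def _intensity_centroid(intensity: np.ndarray, pitch: float) -> tuple[float, float]:
    total = intensity.sum()
    n = intensity.shape[0]
    coords = (np.arange(n) - n // 2) * pitch
    cx = float((intensity.sum(axis=0) * coords).sum() / total)
    cy = float((intensity.sum(axis=1) * coords).sum() / total)
    return cx, cy


def probe_d59(field: ProbeField, fraction: float = 0.59) -> float:
    """Diameter (Å) of the smallest centred circle holding 59 % intensity.

    The circle is centred on the intensity centroid, so the measure is
    invariant under probe translation.  Resolution is limited to one grid
    pixel; a delta-like field reports one pixel diameter.
    """
    intensity = field.intensity
    pitch = field.pitch_A
    cx, cy = _intensity_centroid(intensity, pitch)
    n = field.samples
    coords = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    r = np.hypot(xx - cx, yy - cy).ravel()
    w = intensity.ravel()
    order = np.argsort(r)
    cum = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cum, fraction))
    radius = r[order][min(idx, r.size - 1)]
    return max(2.0 * radius, pitch)


def window_coverage_fraction(field: ProbeField, window_A: float) -> float:
    """Fraction of probe intensity inside the centred window_A × window_A square.

    The square is centred on the intensity centroid.  Returns 1.0 when the
    window covers the whole grid.
    """
    if window_A <= 0:
        raise ValueError("window side must be positive")
    if window_A >= field.side_A:
        return 1.0
    intensity = field.intensity
    pitch = field.pitch_A
    cx, cy = _intensity_centroid(intensity, pitch)
    n = field.samples
    coords = (np.arange(n) - n // 2) * pitch
    inside_x = np.abs(coords - cx) <= window_A / 2.0
    inside_y = np.abs(coords - cy) <= window_A / 2.0
    mask = np.outer(inside_y, inside_x)
    return float(intensity[mask].sum() / intensity.sum())


@dataclass(frozen=True)
class IlluminationMap:
    """Accumulated scan illumination and its interior uniformity."""

    intensity: np.ndarray
    pitch_A: float
    uniformity_pct: float


def illumination_map(
    field: ProbeField,
    scan: ScanSetting,
    interior_margin_A: float | None = None,
) -> IlluminationMap:
    """Sum of probe intensities placed on the scan grid, plus uniformity U.

    Each probe's intensity is normalized to a total of 1, so the map total
    equals the number of used scan positions.  Scan offsets are rounded to
    the probe grid pitch.  U = 100·I_min/I_max is evaluated on the
    interior of the scanned bounding box, at least one probe diameter
    (d59, or ``interior_margin_A``) away from its edges; an empty interior
    is an error.
    """
    step_px = scan.step_used_A / field.pitch_A
    nx = len(range(0, scan.nx, scan.skip + 1))
    ny = len(range(0, scan.ny, scan.skip + 1))
    probe_int = field.intensity / field.intensity.sum()
    n_probe = field.samples
    extent_x = int(round((nx - 1) * step_px)) + n_probe
    extent_y = int(round((ny - 1) * step_px)) + n_probe
    acc = np.zeros((extent_y, extent_x))
    for iy in range(ny):
        oy = int(round(iy * step_px))
        for ix in range(nx):
            ox = int(round(ix * step_px))
            acc[oy : oy + n_probe, ox : ox + n_probe] += probe_int

    margin_A = interior_margin_A if interior_margin_A is not None else probe_d59(field)
    margin_px = int(np.ceil(margin_A / field.pitch_A))
    # interior of the scanned bounding box (probe centres span the box)
    half = n_probe // 2
    x0, x1 = half + margin_px, extent_x - half - margin_px
    y0, y1 = half + margin_px, extent_y - half - margin_px
    if x1 <= x0 or y1 <= y0:
        raise ValueError("scan area too small: empty interior for uniformity")
    interior = acc[y0:y1, x0:x1]
    i_max = interior.max()
    uniformity = 0.0 if i_max == 0 else 100.0 * interior.min() / i_max
    return IlluminationMap(
        intensity=acc, pitch_A=field.pitch_A, uniformity_pct=uniformity
    )
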