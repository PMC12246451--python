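"""Reference reconstructions: single-side-band, ePIE and the numerical CTF.

These close the loop on the design math: data from :mod:`ptychoplan.synth4d`
are reconstructed and the measured transfer is compared against the
analytic predictions of :mod:`ptychoplan.ctf_ssb` and the sampling bounds.

SSB works in the mixed space G(k, Q) — the Fourier transform of the
recorded intensities over scan position.  For a weak phase object each
scan frequency Q deposits its phase, weighted by the double-disk-overlap
("trotter") area, into the lens-shaped regions where the bright-field
disk meets the disk displaced by ±Q; integrating G over those regions and
inverse-transforming over Q yields the object phase directly.

ePIE is the standard extended ptychographic iterative engine: sequential
per-position projections that factor the exit waves into probe × object.

The numerical iterative-method CTF follows the isolated-scatterer recipe:
simulate a radially symmetric phase bump, reconstruct it, deconvolve the
true bump in Fourier space (regularized division) and azimuthally average
the ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft

from .ctf_ssb import AxisUnit, CTFCurve, ssb_overlap_area, ssb_peak_area
from .instrument import AcquisitionPlan, derive_geometry
from .sampling import ssb_max_step
from .synth4d import (
    Dataset4D,
    PhaseObject,
    _real_probe,
    build_probe_kspace,
    make_atom_object,
    simulate_4dstem,
)

__all__ = [
    "TrotterMask",
    "ReconResult",
    "trotter_masks",
    "ssb_reconstruct",
    "epie_reconstruct",
    "deconvolve_ctf",
    "numerical_itr_ctf",
]


@dataclass(frozen=True)
class TrotterMask:
    """Detector-pixel masks of the ±Q double-overlap regions.

    ``plus`` flags pixels inside the bright-field disk and the disk
    displaced by +Q but outside the disk displaced by −Q (triple-overlap
    pixels are excluded); ``minus`` is the mirror region through DC.
    """

    plus: np.ndarray
    minus: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.plus & self.minus):
            raise ValueError("trotter regions must be disjoint")


@dataclass(frozen=True)
class ReconResult:
    """Reconstructed phase map plus optional probe and error trace."""

    phase: np.ndarray
    pixel_A: float
    obj: np.ndarray | None = None
    probe: np.ndarray | None = None
    error_trace: tuple[float, ...] = ()
    warnings: tuple[str, ...] = ()


def trotter_masks(
    q_invA: tuple[float, float],
    alpha_mrad: float,
    lambda_pm: float,
    dtheta_mrad: float,
    n_k: int,
) -> TrotterMask:
    """Classify detector pixels into the ±Q trotter regions.

    ``q_invA`` is the scan frequency (qx, qy) in 1/Å.  Pixel centres are
    classified against the three disks of radius α centred at 0 and at
    the scattering angles ±Q·λ.  Both masks are empty for |Q| ≥ 2α.
    """
    lam_A = lambda_pm * 1e-2
    alpha = alpha_mrad * 1e-3
    qx_ang, qy_ang = q_invA[0] * lam_A, q_invA[1] * lam_A
    idx = np.arange(n_k) - n_k // 2
    kappa = idx * dtheta_mrad * 1e-3
    ky = kappa[:, None]
    kx = kappa[None, :]
    in_b0 = kx**2 + ky**2 <= alpha**2
    in_bp = (kx - qx_ang) ** 2 + (ky - qy_ang) ** 2 <= alpha**2
    in_bm = (kx + qx_ang) ** 2 + (ky + qy_ang) ** 2 <= alpha**2
    return TrotterMask(plus=in_b0 & in_bp & ~in_bm, minus=in_b0 & in_bm & ~in_bp)


def ssb_reconstruct(data: Dataset4D, normalization: str = "peak") -> ReconResult:
    """Direct single-side-band phase reconstruction.

    The output grid is the scan grid (pixel = the scan step).  Transfer
    normalization: "peak" scales the analytic transfer maximum (ω = 0.9)
    to 1, so a weak sinusoid of amplitude φ₀ at frequency ω is recovered
    with amplitude φ₀·CTF(ω) in the max-one convention; "area" uses the
    overlap-area/disk-area convention instead.
    """
    ny, nx = data.scan_shape
    if ny < 2 or nx < 2:
        raise ValueError("SSB needs at least a 2×2 scan grid")
    warnings: list[str] = []
    max_step = ssb_max_step(data.lambda_pm, data.alpha_mrad)
    if data.step_A > max_step:
        warnings.append(
            f"scan step {data.step_A:.3g} Å exceeds the recommended "
            f"λ/(2 sin 2α) = {max_step:.3g} Å: expect aliased transfer"
        )
    if normalization == "peak":
        a_ref = ssb_peak_area()
    elif normalization == "area":
        a_ref = math.pi
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    intensities = data.data.astype(np.float32)
    totals = intensities.sum(axis=(2, 3), keepdims=True)
    intensities = intensities / totals
    g = scipy.fft.fft2(intensities, axes=(0, 1)) / (ny * nx)

    n_k = data.detector_shape[0]
    lam_A = data.lambda_pm * 1e-2
    alpha = data.alpha_mrad * 1e-3
    dtheta = data.dtheta_mrad * 1e-3
    idx = np.arange(n_k) - n_k // 2
    kappa = idx * dtheta
    disk = kappa[:, None] ** 2 + kappa[None, :] ** 2 <= alpha**2
    a2 = float(np.real(g[0, 0][disk]).mean())

    qy = scipy.fft.fftfreq(ny, d=data.step_A)
    qx = scipy.fft.fftfreq(nx, d=data.step_A)
    pixel_ratio = (dtheta / alpha) ** 2
    spectrum = np.zeros((ny, nx), dtype=complex)
    for iy in range(ny):
        for ix in range(nx):
            if iy == 0 and ix == 0:
                continue
            omega = math.hypot(qx[ix], qy[iy]) * lam_A / alpha
            if omega >= 2.0:
                continue
            masks = trotter_masks(
                (qx[ix], qy[iy]),
                data.alpha_mrad,
                data.lambda_pm,
                data.dtheta_mrad,
                n_k,
            )
            if not masks.plus.any() and not masks.minus.any():
                continue
            g_q = g[iy, ix]
            s = g_q[masks.plus].sum() - g_q[masks.minus].sum()
            spectrum[iy, ix] = s * pixel_ratio / (2j * a2 * a_ref)

    phase = np.real(scipy.fft.ifft2(spectrum) * (ny * nx))
    return ReconResult(phase=phase, pixel_A=data.step_A, warnings=tuple(warnings))


def _wrap_index(center: int, n_patch: int, n_obj: int) -> np.ndarray:
    return (center - n_patch // 2 + np.arange(n_patch)) % n_obj


def epie_reconstruct(
    data: Dataset4D,
    iterations: int = 50,
    beta_object: float = 1.0,
    beta_probe: float = 1.0,
    seed: int | None = None,
    probe_init: np.ndarray | None = None,
    fix_probe: bool = False,
    shuffle: bool = False,
    object_shape: tuple[int, int] | None = None,
) -> ReconResult:
    """Minimal extended ptychographic iterative engine.

    The object lives on the probe-grid pitch λ/(n_k·Δθ) with periodic
    boundaries and is initialized to unit transmission; the probe is
    initialized from the dataset's aperture parameters with a 10 %
    defocus error unless ``probe_init`` is given (``fix_probe`` then
    skips the probe update entirely).  Positions are visited in raster
    order, or in a seeded shuffled order when ``shuffle`` is set.  The
    per-iteration RMS mismatch between modelled and measured amplitudes
    is recorded in ``error_trace``.
    """
    if iterations < 1:
        raise ValueError("at least one iteration is required")
    if np.isnan(data.data).any():
        raise ValueError("dataset contains NaN")
    ny, nx = data.scan_shape
    n_k = data.detector_shape[0]
    lam_A = data.lambda_pm * 1e-2
    dx_A = lam_A / (n_k * data.dtheta_mrad * 1e-3)

    intensities = data.data.astype(np.float64)
    mean_total = intensities.sum(axis=(2, 3)).mean()
    amplitudes = np.sqrt(intensities / mean_total)

    if object_shape is None:
        span_y = int(round((ny - 1) * data.step_A / dx_A)) + 1
        span_x = int(round((nx - 1) * data.step_A / dx_A)) + 1
        # a scan covering the full periodic object keeps the grid at the
        # scan span; isolated scans get a window-sized halo
        n_obj_y = max(n_k, span_y)
        n_obj_x = max(n_k, span_x)
    else:
        n_obj_y, n_obj_x = object_shape
    obj = np.ones((n_obj_y, n_obj_x), dtype=complex)

    if probe_init is not None:
        probe = probe_init.astype(complex).copy()
    else:
        probe = _real_probe(
            build_probe_kspace(
                n_k,
                data.dtheta_mrad,
                data.lambda_pm,
                data.alpha_mrad,
                data.defocus_nm * 1.1,
            )
        )
    probe = probe / np.sqrt(np.sum(np.abs(probe) ** 2))

    # per-position precomputation: wrap indices and measured amplitudes in
    # unshifted (FFT) frequency order, so the inner loop needs no fftshifts
    # on the detector axes
    positions = []
    for iy in range(ny):
        for ix in range(nx):
            oy = int(round(iy * data.step_A / dx_A))
            ox = int(round(ix * data.step_A / dx_A))
            rows = _wrap_index(oy, n_k, n_obj_y)
            cols = _wrap_index(ox, n_k, n_obj_x)
            positions.append(
                (np.ix_(rows, cols), scipy.fft.ifftshift(amplitudes[iy, ix]))
            )
    order = np.arange(len(positions))
    rng = np.random.default_rng(seed) if shuffle else None

    sq_amp_total = float((amplitudes**2).sum())
    errors = []
    for _ in range(iterations):
        if rng is not None:
            rng.shuffle(order)
        sq_err = 0.0
        for j in order:
            sel, amp = positions[j]
            patch = obj[sel]
            exit_wave = probe * patch
            psi = scipy.fft.fft2(scipy.fft.ifftshift(exit_wave), norm="ortho")
            model_amp = np.abs(psi)
            sq_err += float(((model_amp - amp) ** 2).sum())
            with np.errstate(invalid="ignore"):
                psi_new = np.where(model_amp > 0, psi / model_amp, 1.0) * amp
            delta = (
                scipy.fft.fftshift(scipy.fft.ifft2(psi_new, norm="ortho"))
                - exit_wave
            )
            new_patch = patch + beta_object * np.conj(probe) * delta / np.max(
                np.abs(probe) ** 2
            )
            if not fix_probe and beta_probe != 0.0:
                probe = probe + beta_probe * np.conj(patch) * delta / np.max(
                    np.abs(patch) ** 2
                )
            obj[sel] = new_patch
        errors.append(math.sqrt(sq_err / sq_amp_total))

    return ReconResult(
        phase=np.angle(obj),
        pixel_A=dx_A,
        obj=obj,
        probe=probe,
        error_trace=tuple(errors),
        warnings=(),
    )


def numerical_itr_ctf(
    potential_spec: dict | None = None,
    plan: AcquisitionPlan | None = None,
    recon_settings: dict | None = None,
    omega_bin: float = 0.1,
    wiener_floor: float = 1e-3,
) -> CTFCurve:
    """Numerical iterative-method CTF via the isolated-scatterer recipe.

    1. build a radially symmetric Gaussian phase bump (``potential_spec``
       passes amplitude_rad/sigma_A overrides), 2. simulate noiseless 4D
    data for ``plan``, 3. reconstruct with ePIE (``recon_settings``
    overrides iterations/betas/fix_probe), 4. divide reconstructed by
    true phase in Fourier space with a Wiener-style floor at
    ``wiener_floor``·max|denominator|, 5. azimuthally average onto an ω
    axis (bin width ``omega_bin``).

    Raises if the floor invalidates more than half of the frequency
    samples inside the reported axis range.
    """
    if plan is None:
        raise ValueError("an acquisition plan is required")
    geo = derive_geometry(plan)
    n_k = plan.detector.n_pixels // plan.detector.binning
    lam_A = geo.wavelength_pm * 1e-2
    dx_A = lam_A / (n_k * geo.dtheta_mrad * 1e-3)

    span_y = int(round((plan.scan.ny - 1) * plan.scan.step_A / dx_A)) + 1
    span_x = int(round((plan.scan.nx - 1) * plan.scan.step_A / dx_A)) + 1
    n_obj = max(n_k, span_y, span_x)

    # the default scatterer is narrow enough that its spectrum stays above
    # the deconvolution floor out past the 2α aperture limit
    spec = {"amplitude_rad": 0.3, "sigma_A": 1.5 * dx_A}
    if potential_spec:
        spec.update(potential_spec)
    center_A = n_obj * dx_A / 2.0
    truth = make_atom_object(
        shape=(n_obj, n_obj),
        pixel_A=dx_A,
        positions_A=[(center_A, center_A)],
        **spec,
    )

    data = simulate_4dstem(truth, plan)
    settings = {"iterations": 50, "beta_object": 1.0, "beta_probe": 1.0}
    if recon_settings:
        settings.update(recon_settings)
    result = epie_reconstruct(data, object_shape=(n_obj, n_obj), **settings)
    return deconvolve_ctf(
        result.phase,
        truth.phase,
        dx_A,
        geo.wavelength_pm,
        plan.beam.alpha_mrad,
        omega_bin=omega_bin,
        wiener_floor=wiener_floor,
    )


def deconvolve_ctf(
    recon_phase: np.ndarray,
    true_phase: np.ndarray,
    pixel_A: float,
    lambda_pm: float,
    alpha_mrad: float,
    omega_bin: float = 0.1,
    wiener_floor: float = 1e-3,
) -> CTFCurve:
    """Transfer curve from a reconstruction of a known phase map.

    Divides the two phase spectra where the true spectrum exceeds
    ``wiener_floor``·max, then azimuthally averages the real part of the
    ratio onto an ω axis.  Both maps are mean-subtracted first (the DC
    phase offset of a reconstruction is arbitrary).
    """
    if recon_phase.shape != true_phase.shape:
        raise ValueError("phase maps must share a grid")
    rec = recon_phase - recon_phase.mean()
    tru = true_phase - true_phase.mean()
    num = scipy.fft.fft2(rec)
    den = scipy.fft.fft2(tru)
    floor = wiener_floor * np.abs(den).max()
    valid = np.abs(den) >= floor
    ratio = np.zeros_like(num)
    ratio[valid] = num[valid] / den[valid]

    lam_A = lambda_pm * 1e-2
    fy = scipy.fft.fftfreq(true_phase.shape[0], d=pixel_A)[:, None]
    fx = scipy.fft.fftfreq(true_phase.shape[1], d=pixel_A)[None, :]
    omega = np.hypot(fx, fy) * lam_A / (alpha_mrad * 1e-3)

    omega_max = omega[valid].max() if valid.any() else 0.0
    in_range = omega <= omega_max
    if valid.sum() < 0.5 * in_range.sum():
        raise ValueError(
            "deconvolution floor removed more than half of the frequency samples"
        )

    edges = np.arange(0.0, omega_max + omega_bin, omega_bin)
    centers = 0.5 * (edges[:-1] + edges[1:])
    values = np.full(centers.shape, np.nan)
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        sel = valid & (omega >= lo) & (omega < hi)
        if sel.any():
            values[i] = float(np.real(ratio[sel]).mean())
    keep = ~np.isnan(values)
    return CTFCurve(
        axis=centers[keep],
        values=values[keep],
        axis_unit=AxisUnit.OMEGA,
        alpha_mrad=alpha_mrad,
        lambda_pm=lambda_pm,
    )
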