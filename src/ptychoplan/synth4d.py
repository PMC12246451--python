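"""Synthetic weak-phase 4D-STEM data and its corruption operators.

The forward model is a single multiplicative thin phase object: at each
scan position the focused-or-defocused probe (hard aperture + defocus
phase) is multiplied by exp(i·φ(r)) and propagated to the far field; the
recorded pattern is the intensity of that transform.  Optional shot noise
distributes a fixed electron budget per position multinomially over the
detector pixels.  Binning and scan-position skipping are provided as
post-acquisition operators matching how real datasets are reduced.

Grid conventions: the detector is the probe's reciprocal grid (n_k
effective pixels, angular pitch Δθ); diffraction space is centred, with
the DC beam at index n_k//2.  Real space uses the probe-grid pitch
Δx = λ/(n_k·Δθ), and the phase object must be sampled on that pitch.
Scan positions are row-major, 0-based, (scan_y outer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft

from .instrument import (
    AcquisitionPlan,
    BeamSetting,
    DetectorModel,
    Method,
    ScanSetting,
    derive_geometry,
    dose_budget,
    electron_wavelength,
)

__all__ = [
    "PhaseObject",
    "Dataset4D",
    "make_phase_object",
    "make_sinusoid_object",
    "make_atom_object",
    "plan_for_simulation",
    "simulate_4dstem",
    "rebin_patterns",
    "subsample_scan",
    "pacbed",
]


@dataclass(frozen=True)
class PhaseObject:
    """Periodic real-space phase map φ(r) in radians."""

    phase: np.ndarray
    pixel_A: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.phase.ndim != 2:
            raise ValueError("phase map must be 2D")
        if self.pixel_A <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def transmission(self) -> np.ndarray:
        return np.exp(1j * self.phase)


def make_sinusoid_object(
    shape: tuple[int, int],
    pixel_A: float,
    components: list[tuple[float, int, int]],
    description: str = "sinusoid",
) -> PhaseObject:
    """Sum of cosine gratings: components are (amplitude_rad, cycles_x, cycles_y).

    Frequencies are integer cycle counts across the periodic window, so
    each component occupies exactly one Fourier pair.  Frequencies beyond
    the grid Nyquist are rejected.
    """
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx]
    phase = np.zeros(shape)
    for amp, cx, cy in components:
        if abs(cx) > nx // 2 or abs(cy) > ny // 2:
            raise ValueError(f"cycles ({cx}, {cy}) beyond grid Nyquist")
        phase += amp * np.cos(2 * np.pi * (cx * x / nx + cy * y / ny))
    return PhaseObject(phase=phase, pixel_A=pixel_A, description=description)


def make_atom_object(
    shape: tuple[int, int],
    pixel_A: float,
    positions_A: list[tuple[float, float]],
    amplitude_rad: float = 0.3,
    sigma_A: float = 0.5,
    description: str = "gaussian atoms",
) -> PhaseObject:
    """Radially symmetric Gaussian phase bumps on a periodic grid.

    A stand-in potential for transfer-function work: each "atom" is
    amplitude·exp(−r²/2σ²), with r the minimum-image (torus) distance.
    """
    ny, nx = shape
    side_y, side_x = ny * pixel_A, nx * pixel_A
    y = np.arange(ny)[:, None] * pixel_A
    x = np.arange(nx)[None, :] * pixel_A
    phase = np.zeros(shape)
    for px, py in positions_A:
        dx = (x - px + side_x / 2) % side_x - side_x / 2
        dy = (y - py + side_y / 2) % side_y - side_y / 2
        phase += amplitude_rad * np.exp(-(dx**2 + dy**2) / (2 * sigma_A**2))
    return PhaseObject(phase=phase, pixel_A=pixel_A, description=description)


def make_phase_object(kind: str, **kwargs) -> PhaseObject:
    """Dispatching constructor: ``kind`` is "sinusoid" or "atoms"."""
    if kind == "sinusoid":
        return make_sinusoid_object(**kwargs)
    if kind == "atoms":
        return make_atom_object(**kwargs)
    raise ValueError(f"unknown phase-object kind {kind!r}")


@dataclass(frozen=True)
class Dataset4D:
    """Scan-position × detector-pixel intensity stack with calibration metadata.

    ``data`` has axes (scan_y, scan_x, k_y, k_x); diffraction space is
    centred (DC at index n_k//2).  Intensities are expected fractions of
    the per-position total (noiseless, float32) or electron counts
    (Poisson-sampled, int32).
    """

    data: np.ndarray
    step_A: float
    dtheta_mrad: float
    lambda_pm: float
    alpha_mrad: float
    defocus_nm: float = 0.0
    dose_e_per_A2: float | None = None
    electrons_per_position: float | None = None
    seed: int | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("4D dataset must have axes (scan_y, scan_x, k_y, k_x)")

    @property
    def scan_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=self.data)
            ds.attrs["axes"] = "scan_y, scan_x, k_y, k_x"
            f.attrs["layout_version"] = 1
            f.attrs["step_A"] = self.step_A
            f.attrs["dtheta_mrad"] = self.dtheta_mrad
            f.attrs["lambda_pm"] = self.lambda_pm
            f.attrs["alpha_mrad"] = self.alpha_mrad
            f.attrs["defocus_nm"] = self.defocus_nm
            if self.dose_e_per_A2 is not None:
                f.attrs["dose_e_per_A2"] = self.dose_e_per_A2
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path) -> "Dataset4D":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][...],
                step_A=float(f.attrs["step_A"]),
                dtheta_mrad=float(f.attrs["dtheta_mrad"]),
                lambda_pm=float(f.attrs["lambda_pm"]),
                alpha_mrad=float(f.attrs["alpha_mrad"]),
                defocus_nm=float(f.attrs["defocus_nm"]),
                dose_e_per_A2=float(f.attrs["dose_e_per_A2"])
                if "dose_e_per_A2" in f.attrs
                else None,
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )


def plan_for_simulation(
    voltage_kv: float,
    alpha_mrad: float,
    dtheta_mrad: float,
    n_k: int,
    step_A: float,
    nx: int,
    ny: int,
    defocus_nm: float = 0.0,
    current_pa: float = 0.0,
    dwell_us: float = 1.0,
    d0_A: float = 0.0,
    method: Method = Method.ITR,
) -> AcquisitionPlan:
    """Build an AcquisitionPlan realizing a requested angular pitch.

    The detector is modelled with a 100 µm pitch; the effective camera
    length is chosen so that Δθ comes out exactly as requested.
    """
    pitch_um = 100.0
    camera_length_cm = pitch_um * 1e-6 / (dtheta_mrad * 1e-3) * 1e2
    return AcquisitionPlan(
        beam=BeamSetting(
            voltage_kv=voltage_kv,
            alpha_mrad=alpha_mrad,
            defocus_nm=defocus_nm,
            current_pa=current_pa,
            d0_A=d0_A,
        ),
        scan=ScanSetting(step_A=step_A, nx=nx, ny=ny, dwell_us=dwell_us),
        detector=DetectorModel(
            n_pixels=n_k, pitch_um=pitch_um, camera_length_cm=camera_length_cm
        ),
        method=method,
    )


def _centered_k_grids(n_k: int, dtheta_mrad: float, lambda_pm: float):
    """Spatial-frequency grids (1/Å) on the centred detector layout."""
    lam_A = lambda_pm * 1e-2
    idx = np.arange(n_k) - n_k // 2
    k_1d = idx * dtheta_mrad * 1e-3 / lam_A
    ky = k_1d[:, None]
    kx = k_1d[None, :]
    return kx, ky


def build_probe_kspace(
    n_k: int,
    dtheta_mrad: float,
    lambda_pm: float,
    alpha_mrad: float,
    defocus_nm: float,
    shift_A: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Centred reciprocal-space probe: hard aperture × defocus × shift ramp."""
    kx, ky = _centered_k_grids(n_k, dtheta_mrad, lambda_pm)
    lam_A = lambda_pm * 1e-2
    k_alpha = alpha_mrad * 1e-3 / lam_A
    k2 = kx**2 + ky**2
    aperture = (k2 <= k_alpha**2 + 1e-12).astype(complex)
    chi = np.pi * lam_A * defocus_nm * 10.0 * k2
    ramp = np.exp(-2j * np.pi * (kx * shift_A[0] + ky * shift_A[1]))
    a = aperture * np.exp(-1j * chi) * ramp
    return a / np.sqrt(np.sum(np.abs(a) ** 2))


def _real_probe(a_centered: np.ndarray) -> np.ndarray:
    """Centred real-space probe from the centred k-space probe (unitary FFT)."""
    return scipy.fft.fftshift(
        scipy.fft.ifft2(scipy.fft.ifftshift(a_centered), norm="ortho")
    )


def simulate_4dstem(
    obj: PhaseObject,
    plan: AcquisitionPlan,
    poisson_seed: int | None = None,
) -> Dataset4D:
    """Scan the probe over the phase object and record far-field intensities.

    The object must be sampled on the probe-grid pitch λ/(n_k·Δθ); scan
    offsets are split into an integer-pixel patch shift (periodic wrap)
    and a sub-pixel remainder applied to the probe as a reciprocal-space
    phase ramp, so arbitrary scan steps are exact.  Noiseless patterns
    sum to exactly 1 per position.  With ``poisson_seed`` set, the
    electron budget from the plan's current and dwell time is distributed
    multinomially over the pixels of each pattern; the per-position
    generator is seeded as (seed, iy, ix), so patterns are reproducible
    independent of evaluation order.
    """
    geo = derive_geometry(plan)
    n_k = plan.detector.n_pixels // plan.detector.binning
    lam_A = geo.wavelength_pm * 1e-2
    dx_A = lam_A / (n_k * geo.dtheta_mrad * 1e-3)
    if not math.isclose(obj.pixel_A, dx_A, rel_tol=1e-6):
        raise ValueError(
            f"object pixel {obj.pixel_A:.6g} Å must match the probe grid "
            f"pitch λ/(n_k·Δθ) = {dx_A:.6g} Å"
        )
    if min(obj.phase.shape) < n_k:
        raise ValueError("object grid must be at least the probe window size")
    warnings: list[str] = []
    window_A = lam_A / (geo.dtheta_mrad * 1e-3)
    d_geom = plan.beam.d0_A + 2 * plan.beam.defocus_nm * 10.0 * math.tan(
        plan.beam.alpha_mrad * 1e-3
    )
    if d_geom > window_A / 2:
        warnings.append(
            f"probe diameter {d_geom:.3g} Å exceeds half the probe window "
            f"{window_A / 2:.3g} Å: expect aliasing"
        )

    trans = obj.transmission
    ny_obj, nx_obj = trans.shape
    nx, ny = plan.scan.nx, plan.scan.ny
    step = plan.scan.step_A
    electrons, dose = dose_budget(plan.beam, plan.scan)

    sample_noise = poisson_seed is not None
    dtype = np.int32 if sample_noise else np.float32
    data = np.empty((ny, nx, n_k, n_k), dtype=dtype)
    n_electrons = int(round(electrons)) if sample_noise else 0

    # cache probes per distinct sub-pixel remainder (scan steps are often
    # commensurate with the grid, giving few distinct remainders)
    probe_cache: dict[tuple[float, float], np.ndarray] = {}
    for iy in range(ny):
        ry = iy * step
        oy = int(round(ry / dx_A))
        suby = ry - oy * dx_A
        for ix in range(nx):
            rx = ix * step
            ox = int(round(rx / dx_A))
            subx = rx - ox * dx_A
            key = (round(subx / dx_A, 9), round(suby / dx_A, 9))
            probe = probe_cache.get(key)
            if probe is None:
                a = build_probe_kspace(
                    n_k,
                    geo.dtheta_mrad,
                    geo.wavelength_pm,
                    plan.beam.alpha_mrad,
                    plan.beam.defocus_nm,
                    shift_A=(subx, suby),
                )
                probe = _real_probe(a)
                probe_cache[key] = probe
            # patch centred on the probe position: probe centre (index
            # n_k//2) coincides with object pixel (oy, ox)
            patch = np.roll(trans, (n_k // 2 - oy, n_k // 2 - ox), axis=(0, 1))[
                :n_k, :n_k
            ]
            exit_wave = probe * patch
            psi_k = scipy.fft.fftshift(
                scipy.fft.fft2(scipy.fft.ifftshift(exit_wave), norm="ortho")
            )
            pattern = np.abs(psi_k) ** 2
            if sample_noise:
                rng = np.random.default_rng([poisson_seed, iy, ix])
                counts = rng.multinomial(
                    n_electrons, (pattern / pattern.sum()).ravel()
                )
                data[iy, ix] = counts.reshape(n_k, n_k).astype(np.int32)
            else:
                data[iy, ix] = pattern.astype(np.float32)

    return Dataset4D(
        data=data,
        step_A=step,
        dtheta_mrad=geo.dtheta_mrad,
        lambda_pm=geo.wavelength_pm,
        alpha_mrad=plan.beam.alpha_mrad,
        defocus_nm=plan.beam.defocus_nm,
        dose_e_per_A2=dose if plan.beam.current_pa > 0 else None,
        electrons_per_position=electrons if sample_noise else None,
        seed=poisson_seed,
        warnings=tuple(warnings),
    )


def rebin_patterns(data: Dataset4D, factor: int) -> Dataset4D:
    """Block-sum the detector axes by ``factor``; counts are conserved."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("binning factor must be a positive integer")
    ky, kx = data.detector_shape
    if ky % factor or kx % factor:
        raise ValueError(f"detector shape {data.detector_shape} not divisible by {factor}")
    if factor == 1:
        return data
    ny, nx = data.scan_shape
    binned = data.data.reshape(ny, nx, ky // factor, factor, kx // factor, factor).sum(
        axis=(3, 5)
    )
    return replace(data, data=binned.astype(data.data.dtype), dtheta_mrad=data.dtheta_mrad * factor)


def subsample_scan(data: Dataset4D, skip: int) -> Dataset4D:
    """Keep every (skip+1)-th scan position per axis.

    The step metadata grows by (skip+1) and the dose falls by (skip+1)².
    """
    if skip < 0 or int(skip) != skip:
        raise ValueError("skip must be a non-negative integer")
    if skip == 0:
        return data
    kept = data.data[:: skip + 1, :: skip + 1]
    if kept.size == 0:
        raise ValueError("subsampling removed every scan position")
    dose = None if data.dose_e_per_A2 is None else data.dose_e_per_A2 / (skip + 1) ** 2
    return replace(data, data=kept, step_A=data.step_A * (skip + 1), dose_e_per_A2=dose)


def pacbed(data: Dataset4D) -> np.ndarray:
    """Position-averaged diffraction pattern: the mean over scan positions."""
    if data.data.size == 0:
        raise ValueError("empty dataset")
    return data.data.mean(axis=(0, 1))
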