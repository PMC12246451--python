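"""Shared fixtures: synthetic 4D-STEM datasets and reference reconstructions.

All heavy objects are session-scoped so the transfer-function, binning and
parameter-recovery studies share one simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from ptychoplan import (
    electron_wavelength,
    epie_reconstruct,
    make_phase_object,
    numerical_itr_ctf,
    plan_for_simulation,
    simulate_4dstem,
    ssb_reconstruct,
)
from ptychoplan.synth4d import _real_probe, build_probe_kspace

ALPHA_MRAD = 27.42
VOLTAGE_KV = 200.0

#: probe frequencies (multiples of α) probed by the transfer fixture and
#: their cycle counts on the 64-position scan window
TRANSFER_OMEGAS = (0.3, 0.6, 0.9, 1.2, 1.6)
TRANSFER_CYCLES = (3, 6, 9, 12, 16)
TRANSFER_AMP_RAD = 0.02


@pytest.fixture(scope="session")
def lam200() -> float:
    return electron_wavelength(VOLTAGE_KV)


def _grid(lam_pm: float, n_k: int, dtheta_mrad: float):
    lam_A = lam_pm * 1e-2
    dx_A = lam_A / (n_k * dtheta_mrad * 1e-3)
    return dx_A, n_k * dx_A


@pytest.fixture(scope="session")
def transfer_fixture(lam200):
    """Noiseless weak sinusoids at 5 probe frequencies, 64² scan / 64² detector.

    The scan window equals the periodic object window, so every sinusoid
    sits exactly on the scan DFT grid.
    """
    n_k = n_r = 64
    dtheta = ALPHA_MRAD / 10.0  # bright-field disk radius: 10 pixels
    dx_A, window_A = _grid(lam200, n_k, dtheta)
    step_A = window_A / n_r
    obj = make_phase_object(
        "sinusoid",
        shape=(n_k, n_k),
        pixel_A=dx_A,
        components=[(TRANSFER_AMP_RAD, m, 0) for m in TRANSFER_CYCLES],
    )
    plan = plan_for_simulation(
        VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, step_A, n_r, n_r
    )
    data = simulate_4dstem(obj, plan)
    recon = ssb_reconstruct(data)
    spectrum = np.fft.fft2(recon.phase) / (n_r * n_r)
    measured = {
        omega: 2.0 * float(np.abs(spectrum[0, m]))
        for omega, m in zip(TRANSFER_OMEGAS, TRANSFER_CYCLES)
    }
    return {
        "object": obj,
        "plan": plan,
        "data": data,
        "recon": recon,
        "measured_amplitude": measured,
        "dtheta_mrad": dtheta,
        "dx_A": dx_A,
        "n_k": n_k,
    }


@pytest.fixture(scope="session")
def atoms_fixture(lam200):
    """Broadband object (6×6 Gaussian atom lattice), 64² scan / 64² detector."""
    n_k = n_r = 64
    dtheta = ALPHA_MRAD / 10.0
    dx_A, window_A = _grid(lam200, n_k, dtheta)
    pos = [
        (i * window_A / 6 + window_A / 12, j * window_A / 6 + window_A / 12)
        for i in range(6)
        for j in range(6)
    ]
    obj = make_phase_object(
        "atoms",
        shape=(n_k, n_k),
        pixel_A=dx_A,
        positions_A=pos,
        amplitude_rad=0.1,
        sigma_A=0.25,
    )
    plan = plan_for_simulation(VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, n_r, n_r)
    data = simulate_4dstem(obj, plan)
    return {"object": obj, "plan": plan, "data": data, "dx_A": dx_A}


def phase_correlation(phase: np.ndarray, truth: np.ndarray) -> float:
    p = phase - phase.mean()
    t = truth - truth.mean()
    return float(np.corrcoef(p.ravel(), t.ravel())[0, 1])


@pytest.fixture(scope="session")
def epie_recovery(lam200):
    """ePIE parameter recovery on the standard noiseless fixture.

    32² scan positions at twice the grid pitch (Ŝ = 16), 64² detector,
    known probe held fixed, 50 iterations.
    """
    n_k = 64
    n_r = 32
    dtheta = ALPHA_MRAD / 10.0
    dx_A, _ = _grid(lam200, n_k, dtheta)
    obj = make_phase_object(
        "sinusoid",
        shape=(n_k, n_k),
        pixel_A=dx_A,
        components=[(0.05, 5, 0), (0.04, 0, 9), (0.03, 7, 7)],
    )
    plan = plan_for_simulation(
        VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, 2 * dx_A, n_r, n_r
    )
    data = simulate_4dstem(obj, plan)
    probe = _real_probe(build_probe_kspace(n_k, dtheta, lam200, ALPHA_MRAD, 0.0))
    result = epie_reconstruct(
        data,
        iterations=50,
        beta_probe=0.0,
        probe_init=probe,
        fix_probe=True,
        object_shape=(n_k, n_k),
    )
    return {
        "object": obj,
        "data": data,
        "result": result,
        "correlation": phase_correlation(result.phase, obj.phase),
    }


@pytest.fixture(scope="session")
def itr_ctf_curve(lam200):
    """Numerical iterative-method CTF on the standard isolated-scatterer plan."""
    n_k = 64
    dtheta = ALPHA_MRAD / 10.0
    dx_A, _ = _grid(lam200, n_k, dtheta)
    plan = plan_for_simulation(
        VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, 2 * dx_A, 32, 32
    )
    return numerical_itr_ctf(
        plan=plan, recon_settings={"iterations": 30, "beta_probe": 0.0}
    )


@pytest.fixture(scope="session")
def tiny_detector_epie(lam200):
    """ePIE on a 4²-pixel detector with dense real-space sampling (Ŝ = 2)."""
    n_k = 4
    dtheta = ALPHA_MRAD  # bright-field disk diameter: 2 pixels
    dx_A, _ = _grid(lam200, n_k, dtheta)
    n_obj = 64
    window_A = n_obj * dx_A
    pos = [
        (i * window_A / 6 + window_A / 12, j * window_A / 6 + window_A / 12)
        for i in range(6)
        for j in range(6)
    ]
    obj = make_phase_object(
        "atoms",
        shape=(n_obj, n_obj),
        pixel_A=dx_A,
        positions_A=pos,
        amplitude_rad=0.3,
        sigma_A=2 * dx_A,
    )
    plan = plan_for_simulation(
        VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, n_obj, n_obj
    )
    data = simulate_4dstem(obj, plan)
    probe = _real_probe(build_probe_kspace(n_k, dtheta, lam200, ALPHA_MRAD, 0.0))
    result = epie_reconstruct(
        data,
        iterations=30,
        beta_probe=0.0,
        probe_init=probe,
        fix_probe=True,
        seed=1,
        shuffle=True,
        object_shape=(n_obj, n_obj),
    )
    return {
        "object": obj,
        "data": data,
        "result": result,
        "correlation": phase_correlation(result.phase, obj.phase),
    }
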