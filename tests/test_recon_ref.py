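import dataclasses

import numpy as np
import pytest

from ptychoplan import (
    electron_wavelength,
    epie_reconstruct,
    make_phase_object,
    plan_for_simulation,
    simulate_4dstem,
    ssb_overlap_area,
    ssb_reconstruct,
    trotter_masks,
)
from ptychoplan.ctf_ssb import ssb_peak_area
from ptychoplan.recon_ref import deconvolve_ctf
from ptychoplan.synth4d import _real_probe, build_probe_kspace

from .conftest import ALPHA_MRAD, VOLTAGE_KV, _grid, phase_correlation

LAM = electron_wavelength(VOLTAGE_KV)


class TestTrotterMasks:
    def test_disjoint_and_empty_beyond_2alpha(self):
        q = 2.5 * ALPHA_MRAD * 1e-3 / (LAM * 1e-2)
        masks = trotter_masks((q, 0.0), ALPHA_MRAD, LAM, ALPHA_MRAD / 10, 64)
        assert not masks.plus.any() and not masks.minus.any()

    def test_sign_flip_swaps_sidebands(self):
        q = 1.0 * ALPHA_MRAD * 1e-3 / (LAM * 1e-2)
        a = trotter_masks((q, 0.0), ALPHA_MRAD, LAM, ALPHA_MRAD / 10, 64)
        b = trotter_masks((-q, 0.0), ALPHA_MRAD, LAM, ALPHA_MRAD / 10, 64)
        assert np.array_equal(a.plus, b.minus)
        assert np.array_equal(a.minus, b.plus)

    def test_pixel_areas_converge_to_closed_form(self):
        # mean absolute area error over several frequencies shrinks as the
        # detector sampling refines, and ends below 1 %
        omegas = [0.4, 0.8, 1.2, 1.6]
        mean_errors = []
        for n_k, ratio in [(48, 8), (96, 16), (192, 32)]:
            dtheta = ALPHA_MRAD / ratio
            pixel_area = (dtheta / ALPHA_MRAD) ** 2
            errs = []
            for omega in omegas:
                q = omega * ALPHA_MRAD * 1e-3 / (LAM * 1e-2)
                masks = trotter_masks((q, 0.0), ALPHA_MRAD, LAM, dtheta, n_k)
                area = 0.5 * (masks.plus.sum() + masks.minus.sum()) * pixel_area
                errs.append(
                    abs(area - ssb_overlap_area(omega)) / ssb_overlap_area(omega)
                )
            mean_errors.append(float(np.mean(errs)))
        assert mean_errors[0] > mean_errors[1] > mean_errors[2]
        assert mean_errors[2] < 0.01


class TestSSBReconstruction:
    def test_vacuum_gives_zero_phase(self, lam200):
        n_k = 32
        dtheta = ALPHA_MRAD / 5.0
        dx_A, _ = _grid(lam200, n_k, dtheta)
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.0, 1, 0)]
        )
        plan = plan_for_simulation(VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, 8, 8)
        result = ssb_reconstruct(simulate_4dstem(obj, plan))
        assert np.abs(result.phase).max() < 1e-8

    def test_single_frequency_transfer_matches_analytic_ctf(self, lam200):
        # ω = 1.0 sinusoid: recovered amplitude / φ0 = CTF(1.0) in the
        # peak-normalized convention
        n_k, n_r, m = 96, 48, 15
        dtheta = ALPHA_MRAD / 15.0
        dx_A, window_A = _grid(lam200, n_k, dtheta)
        step_A = window_A / n_r
        phi0 = 0.05
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(phi0, m, 0)]
        )
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, step_A, n_r, n_r
        )
        result = ssb_reconstruct(simulate_4dstem(obj, plan))
        spectrum = np.fft.fft2(result.phase) / (n_r * n_r)
        measured = 2 * np.abs(spectrum[0, m])
        expected = phi0 * ssb_overlap_area(1.0) / ssb_peak_area()
        assert measured == pytest.approx(expected, rel=0.02)

    def test_linearity_of_recovered_spectrum(self, lam200):
        n_k, n_r = 64, 32
        dtheta = ALPHA_MRAD / 10.0
        dx_A, window_A = _grid(lam200, n_k, dtheta)
        step_A = window_A / n_r
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, step_A, n_r, n_r
        )

        def recovered(components):
            obj = make_phase_object(
                "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=components
            )
            res = ssb_reconstruct(simulate_4dstem(obj, plan))
            return np.fft.fft2(res.phase) / (n_r * n_r)

        a = recovered([(0.04, 4, 0)])
        b = recovered([(0.03, 0, 7)])
        both = recovered([(0.04, 4, 0), (0.03, 0, 7)])
        scale = np.abs(a).max()
        assert np.abs(both - (a + b)).max() < 0.01 * scale

    def test_transfer_fixture_rms_error(self, transfer_fixture):
        # five probe frequencies on one object: 3 % RMS against the
        # analytic curve (the core validation of the design math)
        measured = transfer_fixture["measured_amplitude"]
        rels = []
        for omega, value in measured.items():
            expected = 0.02 * ssb_overlap_area(omega) / ssb_peak_area()
            rels.append(value / expected - 1.0)
        rms = float(np.sqrt(np.mean(np.square(rels))))
        assert rms < 0.03

    def test_oversized_step_warns(self, lam200):
        n_k = 32
        dtheta = ALPHA_MRAD / 5.0
        dx_A, _ = _grid(lam200, n_k, dtheta)
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.0, 1, 0)]
        )
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, 3 * dx_A, 4, 4
        )
        result = ssb_reconstruct(simulate_4dstem(obj, plan))
        assert any("step" in w for w in result.warnings)

    def test_tiny_scan_rejected(self, lam200):
        dx_A, _ = _grid(lam200, 32, ALPHA_MRAD / 5)
        obj = make_phase_object(
            "sinusoid", shape=(32, 32), pixel_A=dx_A, components=[(0.0, 1, 0)]
        )
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, ALPHA_MRAD / 5, 32, dx_A, 4, 4
        )
        data = simulate_4dstem(obj, plan)
        short = dataclasses.replace(data, data=data.data[:1])
        with pytest.raises(ValueError):
            ssb_reconstruct(short)


class TestEPIE:
    def test_zero_beta_is_identity(self, epie_recovery):
        result = epie_reconstruct(
            epie_recovery["data"],
            iterations=2,
            beta_object=0.0,
            beta_probe=0.0,
            object_shape=(64, 64),
        )
        assert np.allclose(result.obj, 1.0)

    def test_recovery_on_standard_fixture(self, epie_recovery):
        assert epie_recovery["correlation"] > 0.95

    def test_error_trace_decreases(self, epie_recovery):
        trace = epie_recovery["result"].error_trace
        assert trace[-1] < trace[0]
        first10 = trace[:10]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(first10, first10[1:]))

    def test_probe_refinement_reduces_error(self, lam200):
        # defocused dataset reconstructed from a probe guess with a 10 %
        # defocus error: letting ePIE update the probe must help
        n_k = 64
        dtheta = ALPHA_MRAD / 10.0
        dx_A, _ = _grid(lam200, n_k, dtheta)
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A,
            components=[(0.05, 5, 0), (0.04, 0, 9)],
        )
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, 4 * dx_A, 16, 16, defocus_nm=5.0
        )
        data = simulate_4dstem(obj, plan)
        fixed = epie_reconstruct(
            data, iterations=8, beta_probe=0.0, fix_probe=True,
            object_shape=(n_k, n_k),
        )
        refined = epie_reconstruct(
            data, iterations=8, beta_probe=1.0, object_shape=(n_k, n_k)
        )
        assert refined.error_trace[-1] < fixed.error_trace[-1]

    def test_nan_rejected(self, epie_recovery):
        data = epie_recovery["data"]
        bad = data.data.copy()
        bad[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            epie_reconstruct(dataclasses.replace(data, data=bad), iterations=1)


class TestNumericalCTF:
    def test_deconvolution_identity(self):
        truth = make_phase_object(
            "atoms", shape=(64, 64), pixel_A=0.15,
            positions_A=[(4.8, 4.8)], amplitude_rad=0.3, sigma_A=0.3,
        ).phase
        curve = deconvolve_ctf(truth, truth, 0.15, LAM, ALPHA_MRAD)
        assert np.allclose(curve.values, 1.0, atol=1e-9)

    def test_uniform_scaling_gives_flat_curve(self):
        truth = make_phase_object(
            "atoms", shape=(64, 64), pixel_A=0.15,
            positions_A=[(4.8, 4.8)], amplitude_rad=0.3, sigma_A=0.3,
        ).phase
        curve = deconvolve_ctf(0.5 * truth, truth, 0.15, LAM, ALPHA_MRAD)
        assert np.allclose(curve.values, 0.5, atol=1e-9)

    def test_sparse_spectrum_rejected(self):
        # a pure grating has only two non-zero frequency samples: the
        # regularized division is ill-posed over the reported range
        truth = make_phase_object(
            "sinusoid", shape=(64, 64), pixel_A=0.15, components=[(0.3, 5, 0)]
        ).phase
        with pytest.raises(ValueError):
            deconvolve_ctf(truth, truth, 0.15, LAM, ALPHA_MRAD)

    def test_plateau_and_superresolution_tail(self, itr_ctf_curve):
        # iterative-method transfer: plateau out to the 2α aperture limit
        # and a non-zero tail beyond it (noiseless data)
        axis, values = itr_ctf_curve.axis, itr_ctf_curve.values
        plateau = values[(axis > 0.2) & (axis < 1.9)]
        assert np.all(np.abs(plateau - 1.0) < 0.1)
        beyond = values[(axis > 2.0) & (axis < 2.2)]
        assert beyond.size > 0
        assert np.all(beyond > 0.01)


class TestTinyDetector:
    def test_epie_reconstructs_with_4x4_patterns(self, tiny_detector_epie):
        # dense real-space sampling compensates a 4²-pixel detector
        assert tiny_detector_epie["correlation"] > 0.9
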