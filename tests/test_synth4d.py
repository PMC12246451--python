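import dataclasses

import numpy as np
import pytest

from ptychoplan import (
    Dataset4D,
    make_phase_object,
    pacbed,
    plan_for_simulation,
    rebin_patterns,
    simulate_4dstem,
    subsample_scan,
    trotter_masks,
)

from .conftest import ALPHA_MRAD, VOLTAGE_KV, _grid


class TestPhaseObjects:
    def test_sinusoid_occupies_one_fourier_pair(self):
        obj = make_phase_object(
            "sinusoid", shape=(32, 32), pixel_A=0.1, components=[(0.1, 5, 0)]
        )
        spectrum = np.fft.fft2(obj.phase)
        spectrum[0, 0] = 0.0
        nonzero = np.argwhere(np.abs(spectrum) > 1e-9 * np.abs(spectrum).max())
        assert len(nonzero) == 2

    def test_zero_amplitude_is_vacuum(self):
        obj = make_phase_object(
            "sinusoid", shape=(16, 16), pixel_A=0.1, components=[(0.0, 3, 1)]
        )
        assert np.all(obj.phase == 0.0)

    def test_atom_positions_recovered_by_argmax(self):
        obj = make_phase_object(
            "atoms",
            shape=(64, 64),
            pixel_A=0.05,
            positions_A=[(1.0, 1.6), (2.2, 1.6)],  # 1.2 Å apart
            amplitude_rad=0.2,
            sigma_A=0.1,
        )
        iy, ix = np.unravel_index(np.argmax(obj.phase), obj.phase.shape)
        assert (ix * 0.05, iy * 0.05) in [(1.0, 1.6), (2.2, 1.6)]

    def test_frequency_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            make_phase_object(
                "sinusoid", shape=(16, 16), pixel_A=0.1, components=[(0.1, 9, 0)]
            )


@pytest.fixture(scope="module")
def vacuum_data(lam200):
    n_k = 32
    dtheta = ALPHA_MRAD / 5.0
    dx_A, _ = _grid(lam200, n_k, dtheta)
    obj = make_phase_object(
        "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.0, 1, 0)]
    )
    plan = plan_for_simulation(VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, 8, 8)
    return simulate_4dstem(obj, plan), plan


class TestForwardModel:
    def test_vacuum_patterns_are_the_aperture(self, vacuum_data, lam200):
        data, _ = vacuum_data
        first = data.data[0, 0]
        assert np.allclose(data.data, first[None, None], atol=1e-9)
        kappa = (np.arange(32) - 16) * data.dtheta_mrad
        disk = kappa[None, :] ** 2 + kappa[:, None] ** 2 <= ALPHA_MRAD**2 + 1e-9
        # uniform intensity 1/(disk pixel count) inside, nothing outside
        assert np.allclose(first[disk], 1.0 / disk.sum(), rtol=1e-5)
        assert np.abs(first[~disk]).max() < 1e-12
        assert np.allclose(pacbed(data), first)

    def test_energy_conservation(self, vacuum_data):
        data, _ = vacuum_data
        sums = data.data.astype(np.float64).sum(axis=(2, 3))
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_weak_sinusoid_signal_lives_in_overlap_regions(self, lam200):
        n_k = 64
        dtheta = ALPHA_MRAD / 10.0
        dx_A, window_A = _grid(lam200, n_k, dtheta)
        m = 8  # ω = 0.8
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.02, m, 0)]
        )
        plan = plan_for_simulation(VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, 8, 1)
        data = simulate_4dstem(obj, plan)
        vacuum = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.0, m, 0)]
        )
        ref = simulate_4dstem(vacuum, plan)
        # scan position where the grating phase is in quadrature with the
        # probe (q·R = 1/4 cycle): the first-order interference is maximal
        diff = np.abs(data.data[0, 2].astype(np.float64) - ref.data[0, 2])
        masks = trotter_masks(
            (m / window_A, 0.0), ALPHA_MRAD, lam200, dtheta, n_k
        )
        union = masks.plus | masks.minus
        assert diff[union].sum() / diff.sum() > 0.95

    def test_object_grid_mismatch_rejected(self, lam200):
        obj = make_phase_object(
            "sinusoid", shape=(32, 32), pixel_A=0.123, components=[(0.1, 3, 0)]
        )
        plan = plan_for_simulation(VOLTAGE_KV, ALPHA_MRAD, 5.0, 32, 0.1, 4, 4)
        with pytest.raises(ValueError):
            simulate_4dstem(obj, plan)

    def test_oversized_probe_records_warning(self, lam200):
        n_k = 32
        dtheta = ALPHA_MRAD / 5.0
        dx_A, _ = _grid(lam200, n_k, dtheta)
        obj = make_phase_object(
            "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.0, 1, 0)]
        )
        plan = plan_for_simulation(
            VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, 2, 2, defocus_nm=20.0
        )
        data = simulate_4dstem(obj, plan)
        assert any("aliasing" in w for w in data.warnings)


@pytest.fixture(scope="module")
def noisy(lam200):
    n_k = 32
    dtheta = ALPHA_MRAD / 5.0
    dx_A, _ = _grid(lam200, n_k, dtheta)
    obj = make_phase_object(
        "sinusoid", shape=(n_k, n_k), pixel_A=dx_A, components=[(0.1, 3, 0)]
    )
    plan = plan_for_simulation(
        VOLTAGE_KV, ALPHA_MRAD, dtheta, n_k, dx_A, 16, 16,
        current_pa=11.0, dwell_us=5.0,
    )
    return obj, plan


class TestPoissonSampling:
    def test_reproducible_and_seed_sensitive(self, noisy):
        obj, plan = noisy
        a = simulate_4dstem(obj, plan, poisson_seed=7)
        b = simulate_4dstem(obj, plan, poisson_seed=7)
        c = simulate_4dstem(obj, plan, poisson_seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_electron_budget_conserved_per_position(self, noisy):
        obj, plan = noisy
        data = simulate_4dstem(obj, plan, poisson_seed=3)
        totals = data.data.sum(axis=(2, 3))
        assert np.all(totals == round(data.electrons_per_position))

    def test_pacbed_converges_to_noiseless(self, noisy):
        obj, plan = noisy
        noiseless = pacbed(simulate_4dstem(obj, plan))
        data = simulate_4dstem(obj, plan, poisson_seed=11)
        counts = data.data.astype(np.float64)
        counts /= counts.sum(axis=(2, 3), keepdims=True)
        few = counts[:2, :2].mean(axis=(0, 1))
        many = counts.mean(axis=(0, 1))
        rms_few = np.sqrt(((few - noiseless) ** 2).mean())
        rms_many = np.sqrt(((many - noiseless) ** 2).mean())
        assert rms_many < rms_few


class TestCorruptionOperators:
    def test_rebin_identity_and_shape(self):
        data = Dataset4D(
            data=np.ones((2, 2, 192, 192), dtype=np.float32),
            step_A=0.16, dtheta_mrad=0.83, lambda_pm=2.5, alpha_mrad=27.4,
        )
        assert rebin_patterns(data, 1) is data
        binned = rebin_patterns(data, 24)
        assert binned.detector_shape == (8, 8)
        assert binned.dtheta_mrad == pytest.approx(0.83 * 24)

    def test_rebin_conserves_counts(self, vacuum_data):
        data, _ = vacuum_data
        binned = rebin_patterns(data, 8)
        assert binned.data.sum() == pytest.approx(data.data.sum(), rel=1e-6)

    def test_rebin_requires_divisible_factor(self, vacuum_data):
        data, _ = vacuum_data
        with pytest.raises(ValueError):
            rebin_patterns(data, 5)

    def test_subsample_indexing_and_metadata(self):
        data = Dataset4D(
            data=np.zeros((128, 128, 4, 4), dtype=np.float32),
            step_A=0.16, dtheta_mrad=0.83, lambda_pm=2.5, alpha_mrad=27.4,
            dose_e_per_A2=1000.0,
        )
        assert subsample_scan(data, 0) is data
        sub = subsample_scan(data, 4)
        assert sub.scan_shape == (26, 26)
        assert sub.step_A == pytest.approx(0.16 * 5)
        assert sub.dose_e_per_A2 == pytest.approx(1000.0 / 25)

    def test_rebin_and_subsample_commute(self, vacuum_data):
        data, _ = vacuum_data
        a = rebin_patterns(subsample_scan(data, 2), 4)
        b = subsample_scan(rebin_patterns(data, 4), 2)
        assert np.array_equal(a.data, b.data)
        assert a.step_A == b.step_A
        assert a.dtheta_mrad == b.dtheta_mrad

    def test_pacbed_commutes_with_rebin(self, vacuum_data):
        data, _ = vacuum_data
        assert np.allclose(
            pacbed(rebin_patterns(data, 4)),
            rebin_patterns(
                dataclasses.replace(data, data=pacbed(data)[None, None]), 4
            ).data[0, 0],
            rtol=1e-4,
        )


class TestHdf5Layout:
    def test_round_trip(self, vacuum_data, tmp_path):
        data, _ = vacuum_data
        data = dataclasses.replace(data, dose_e_per_A2=123.0, seed=5)
        path = tmp_path / "scan.h5"
        data.to_hdf5(path)
        loaded = Dataset4D.from_hdf5(path)
        assert np.array_equal(loaded.data, data.data)
        assert loaded.step_A == data.step_A
        assert loaded.dtheta_mrad == data.dtheta_mrad
        assert loaded.dose_e_per_A2 == 123.0
        assert loaded.seed == 5
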