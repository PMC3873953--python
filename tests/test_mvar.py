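import numpy as np
import pytest

import oracles
from dtfnet.mvar import (
    MVARModel,
    SingularDesignError,
    fit_mvar,
    select_order_bic,
    transfer_matrix,
)
from dtfnet.synth import CouplingSpec, make_band_resonant_spec, simulate_mvar

FS = 2000.0


class TestFitMVAR:
    def test_white_noise_coefficients_near_zero(self, white_noise_recording):
        model = fit_mvar(white_noise_recording.data, 1, sampling_rate_hz=FS)
        assert np.all(np.abs(model.coeffs) < 0.05)

    def test_ar1_recovery_matches_yule_walker_oracle(self, ar1_recording):
        x = ar1_recording.data[:, 0]
        model = fit_mvar(ar1_recording.data, 1, sampling_rate_hz=FS)
        a_hat = model.coeffs[0, 0, 0]
        assert 0.47 <= a_hat <= 0.53
        # Yule-Walker on the same data: a = r(1) / r(0)
        xc = x - x.mean()
        a_yw = np.dot(xc[1:], xc[:-1]) / np.dot(xc, xc)
        assert np.isclose(a_hat, a_yw, atol=0.005)

    def test_one_way_coupling_recovered(self):
        coeffs = np.array([[[0.5, 0.0], [0.3, 0.4]]])  # lag-1 coupling 0 -> 1
        spec = CouplingSpec(2, 1, coeffs, np.eye(2), sampling_rate_hz=FS)
        x = simulate_mvar(spec, 20000, seed=11).data
        model = fit_mvar(x, 1, sampling_rate_hz=FS)
        assert np.isclose(model.coeffs[0, 1, 0], 0.3, rtol=0.10)
        # absent reverse coupling stays near zero
        assert abs(model.coeffs[0, 0, 1]) < 0.05

    def test_duplicated_channel_raises_named_singularity_error(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2000, 2))
        x = np.column_stack([x, x[:, 0]])  # channel 2 duplicates channel 0
        with pytest.raises(SingularDesignError, match=r"\(0, 2\)"):
            fit_mvar(x, 2, sampling_rate_hz=FS)

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="identifiability"):
            fit_mvar(np.zeros((50, 2)), 5, sampling_rate_hz=FS)

    def test_refit_of_own_simulation_recovers_coefficients(self, two_channel_spec):
        x = simulate_mvar(two_channel_spec, 20000, seed=12).data
        model = fit_mvar(x, two_channel_spec.order, sampling_rate_hz=FS)
        resim = model.simulate(20000, seed=13).data
        refit = fit_mvar(resim, model.order_p, sampling_rate_hz=FS)
        assert np.allclose(refit.coeffs, model.coeffs, atol=0.05)


class TestEstimatorProperties:
    def test_consistency_rmse_decreases_with_n(self, two_channel_spec):
        true = two_channel_spec.coeff_tensor
        rmses = []
        for n in (2000, 8000, 32000):
            errs = []
            for seed in range(3):
                x = simulate_mvar(two_channel_spec, n, seed=100 + seed).data
                m = fit_mvar(x, two_channel_spec.order, sampling_rate_hz=FS)
                errs.append(np.sqrt(np.mean((m.coeffs - true) ** 2)))
            rmses.append(np.mean(errs))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_scale_equivariance(self, two_channel_spec):
        x = simulate_mvar(two_channel_spec, 8000, seed=21).data
        m1 = fit_mvar(x, 2, sampling_rate_hz=FS)
        m2 = fit_mvar(10.0 * x, 2, sampling_rate_hz=FS)
        assert np.allclose(m1.coeffs, m2.coeffs, rtol=1e-8, atol=1e-10)
        assert np.allclose(m2.resid_cov, 100.0 * m1.resid_cov, rtol=1e-8)


class TestOrderSelection:
    def test_white_noise_prefers_minimum_order(self, white_noise_recording):
        p_best, curve = select_order_bic(white_noise_recording.data, 6)
        assert p_best == 1
        assert len(curve) == 6

    def test_bic_curve_has_pmax_entries(self, ar1_recording):
        _, curve = select_order_bic(ar1_recording.data, 4)
        assert len(curve) == 4

    def test_known_order_recovered(self):
        coeffs = np.zeros((3, 2, 2))
        coeffs[0] = [[0.4, 0.2], [0.0, 0.3]]
        coeffs[1] = [[-0.3, 0.0], [0.1, -0.2]]
        coeffs[2] = [[0.2, 0.0], [0.0, 0.25]]
        spec = CouplingSpec(2, 3, coeffs, np.eye(2), sampling_rate_hz=FS)
        x = simulate_mvar(spec, 20000, seed=5).data
        p_best, _ = select_order_bic(x, 8)
        assert p_best == 3


class TestTransferMatrix:
    def test_zero_model_gives_identity(self):
        model = MVARModel(1, np.zeros((1, 3, 3)), np.eye(3), FS, 1000)
        h = transfer_matrix(model, np.linspace(0.0, 900.0, 7))
        assert np.allclose(h.H, np.eye(3)[None], atol=1e-14)

    def test_scalar_ar1_dc_closed_form(self):
        model = MVARModel(1, np.array([[[0.5]]]), np.eye(1), FS, 1000)
        h = transfer_matrix(model, [0.0])
        assert np.isclose(h.H[0, 0, 0], 2.0)

    def test_matches_bruteforce_inversion_on_2x2(self):
        rng = np.random.default_rng(17)
        coeffs = 0.2 * rng.standard_normal((3, 2, 2))
        model = MVARModel(3, coeffs, np.eye(2), FS, 1000)
        freqs = np.linspace(0.5, 990.0, 11)
        h = transfer_matrix(model, freqs)
        for k, f in enumerate(freqs):
            brute = oracles.transfer_2x2_bruteforce(coeffs, FS, f)
            assert np.allclose(h.H[k], brute, atol=1e-10)

    def test_continuity_in_frequency(self, two_channel_spec):
        model = MVARModel(
            two_channel_spec.order, two_channel_spec.coeff_tensor, np.eye(2), FS, 1000
        )
        base = np.array([5.0, 30.0, 65.0])
        h1 = transfer_matrix(model, base)
        h2 = transfer_matrix(model, base + 0.01)
        rel = np.abs(h2.H - h1.H).max() / np.abs(h1.H).max()
        assert rel < 0.05

    def test_out_of_range_frequency_rejected(self):
        model = MVARModel(1, np.zeros((1, 2, 2)), np.eye(2), FS, 1000)
        with pytest.raises(ValueError, match="Nyquist|frequencies"):
            transfer_matrix(model, [1500.0])

    def test_singular_af_raises(self):
        # x(t) = x(t-1): A(0) = 0 exactly at DC
        model = MVARModel(1, np.array([[[1.0]]]), np.eye(1), FS, 1000)
        with pytest.raises(np.linalg.LinAlgError, match="[Ss]ingular"):
            transfer_matrix(model, [0.0])

    def test_near_singular_af_reports_frequency(self):
        coeffs = np.array([[[1.0 - 1e-13, 0.0], [0.0, 0.5]]])
        model = MVARModel(1, coeffs, np.eye(2), FS, 1000)
        with pytest.raises(np.linalg.LinAlgError, match="0.000"):
            transfer_matrix(model, [0.0])
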