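import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov
from scipy.signal import welch

from conftest import make_segments
from dirconn.errors import LengthError
from dirconn.mvar import (
    CovarianceSequence,
    MVARModel,
    check_stability,
    compute_dtf,
    fit_mvar,
    fit_yule_walker,
    lagged_covariance,
    mvar_spectrum,
    select_order_bic,
    transfer_matrix,
)
from dirconn.synthetic import gen_mvar, random_stable_mvar


def analytic_var1_covariances(A, sigma, s_max):
    """R(s) = E[x_t x_{t+s}ᵀ] for a stable VAR(1) from the Lyapunov equation."""
    R0 = solve_discrete_lyapunov(A, sigma)
    R = [R0]
    for s in range(1, s_max + 1):
        R.append(R[-1] @ A.T)  # E[x_t x_{t+s}ᵀ] = R(s-1) Aᵀ
    return CovarianceSequence(R=R)


class TestLaggedCovariance:
    def test_zero_input(self):
        segs = make_segments(np.zeros((6000, 2)))
        R = lagged_covariance(segs, 3)
        for s in range(4):
            np.testing.assert_array_equal(R.R[s], 0.0)

    def test_white_noise_moments(self, white_recording):
        segs = make_segments(white_recording.data)
        R = lagged_covariance(segs, 1)
        tol = 5 / np.sqrt(30000)
        np.testing.assert_allclose(R.R[0], np.eye(2), atol=tol)
        np.testing.assert_allclose(R.R[1], 0.0, atol=tol)

    def test_ar1_stationary_variance(self):
        model = MVARModel(coeffs=[np.array([[0.5]])], noise_cov=np.eye(1), fs=1000.0)
        rec = gen_mvar(model, 120.0, 1000.0, seed=3)
        segs = make_segments(rec.data)
        R = lagged_covariance(segs, 0)
        assert abs(R.R[0][0, 0] - 4.0 / 3.0) < 0.05 * 4 / 3

    def test_lag_exceeding_segment(self, white_recording):
        segs = make_segments(white_recording.data)
        with pytest.raises(LengthError):
            lagged_covariance(segs, 2000)


class TestYuleWalker:
    A_TRUE = np.array([[0.5, 0.1], [0.2, 0.3]])

    def test_exact_recovery_from_analytic_covariances(self):
        R = analytic_var1_covariances(self.A_TRUE, np.eye(2), 1)
        coeffs, sigma = fit_yule_walker(R, 1)
        np.testing.assert_allclose(coeffs[0], self.A_TRUE, atol=1e-8)
        np.testing.assert_allclose(sigma, np.eye(2), atol=1e-8)

    def test_overparameterized_fit_zeroes_extra_lag(self):
        R = analytic_var1_covariances(self.A_TRUE, np.eye(2), 2)
        coeffs, _ = fit_yule_walker(R, 2)
        np.testing.assert_allclose(coeffs[0], self.A_TRUE, atol=1e-8)
        assert np.max(np.abs(coeffs[1])) <= 1e-6

    def test_white_noise_gives_null_model(self):
        R = CovarianceSequence(R=[np.eye(2), np.zeros((2, 2)), np.zeros((2, 2))])
        coeffs, sigma = fit_yule_walker(R, 2)
        for A in coeffs:
            np.testing.assert_allclose(A, 0.0, atol=1e-12)
        np.testing.assert_allclose(sigma, np.eye(2), atol=1e-12)


class TestOrderSelection:
    def test_recovers_strong_ar3(self):
        a = np.array([0.4, -0.35, 0.3])
        model = MVARModel(
            coeffs=[np.array([[c]]) for c in a], noise_cov=np.eye(1), fs=1000.0
        )
        assert check_stability(model) < 1
        hits = 0
        for seed in range(10):
            rec = gen_mvar(model, 30.0, 1000.0, seed=seed)
            p = select_order_bic(make_segments(rec.data), 1, 10)
            hits += p == 3
        assert hits >= 9

    def test_white_noise_selects_minimum(self, white_recording):
        segs = make_segments(white_recording.data)
        assert select_order_bic(segs, 1, 5) == 1

    def test_collapsed_range(self, white_recording):
        segs = make_segments(white_recording.data)
        assert select_order_bic(segs, 7, 7) == 7


class TestStability:
    @pytest.mark.parametrize(
        "a, expected", [(0.5, 0.5), (0.0, 0.0), (1.01, 1.01)]
    )
    def test_scalar_companion(self, a, expected):
        model = MVARModel(coeffs=[np.array([[a]])], noise_cov=np.eye(1), fs=1.0)
        assert check_stability(model) == pytest.approx(expected)


class TestTransferAndDTF:
    freqs = np.arange(0.5, 100.25, 0.25)

    def test_pure_noise_model_has_identity_transfer(self):
        model = MVARModel(coeffs=[], noise_cov=np.eye(2), fs=1000.0)
        H = transfer_matrix(model, self.freqs)
        np.testing.assert_allclose(H.H, np.broadcast_to(np.eye(2), H.H.shape), atol=1e-12)

    def test_scalar_ar1_dc_gain(self):
        model = MVARModel(coeffs=[np.array([[0.5]])], noise_cov=np.eye(1), fs=1000.0)
        H = transfer_matrix(model, np.array([0.0]))
        assert H.H[0, 0, 0] == pytest.approx(2.0)

    def test_transfer_inverts_spectral_matrix(self):
        model = random_stable_mvar(k=2, p=7, seed=4)
        H = transfer_matrix(model, self.freqs)
        dt = 1.0 / model.fs
        for fi in (0, 100, 300):
            f = self.freqs[fi]
            Abar = np.eye(2, dtype=complex)
            for j, A in enumerate(model.coeffs, start=1):
                Abar -= A * np.exp(-2j * np.pi * f * dt * j)
            np.testing.assert_allclose(H.H[fi] @ Abar, np.eye(2), atol=1e-10)

    def test_lower_triangular_system_has_zero_reverse_flow(self):
        A = np.array([[0.5, 0.0], [0.4, 0.7]])
        model = MVARModel(coeffs=[A], noise_cov=np.eye(2), fs=1000.0)
        H = transfer_matrix(model, self.freqs)
        # channel 2 never drives channel 1: H_12 = 0
        np.testing.assert_allclose(H.H[:, 0, 1], 0.0, atol=1e-12)
        dtf = compute_dtf(H)
        np.testing.assert_allclose(dtf.values[:, 0, 1], 0.0, atol=1e-10)
        assert np.all(dtf.values[:, 1, 0] > 0)

    def test_identity_transfer_gives_diagonal_dtf(self):
        model = MVARModel(coeffs=[], noise_cov=np.eye(2), fs=1000.0)
        dtf = compute_dtf(transfer_matrix(model, self.freqs))
        np.testing.assert_allclose(dtf.values, np.broadcast_to(np.eye(2), dtf.values.shape), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_rows_sum_to_one(self, seed):
        model = random_stable_mvar(k=2, p=7, seed=seed)
        dtf = compute_dtf(transfer_matrix(model, self.freqs))
        np.testing.assert_allclose(dtf.values.sum(axis=2), 1.0, atol=1e-10)
        assert np.all((dtf.values >= 0) & (dtf.values <= 1))


class TestSpectrum:
    def test_pure_noise_spectrum_is_flat(self):
        model = MVARModel(coeffs=[], noise_cov=np.eye(2), fs=1000.0)
        S = mvar_spectrum(model, np.arange(0.0, 500.0, 1.0))
        np.testing.assert_allclose(S, np.broadcast_to(np.eye(2) / 1000.0, S.shape), atol=1e-15)

    def test_scalar_ar1_dc_to_nyquist_ratio(self):
        model = MVARModel(coeffs=[np.array([[0.5]])], noise_cov=np.eye(1), fs=1000.0)
        S = mvar_spectrum(model, np.array([0.0, 500.0]))
        assert S[0, 0, 0].real / S[1, 0, 0].real == pytest.approx(9.0)

    def test_parseval_total_power(self):
        model = random_stable_mvar(k=2, p=3, seed=1, target_radius=0.7)
        freqs = np.linspace(0.0, 500.0, 4001)
        S = mvar_spectrum(model, freqs)
        band_power = 2.0 * np.trapezoid(S[:, 0, 0].real, freqs)
        # stationary variance via the companion-form Lyapunov equation
        p, k = model.order, model.k
        C = model.companion()
        Q = np.zeros((p * k, p * k))
        Q[:k, :k] = model.noise_cov
        R0 = solve_discrete_lyapunov(C, Q)[:k, :k]
        assert band_power == pytest.approx(R0[0, 0], rel=0.02)

    def test_welch_spectrum_of_simulation_matches_parametric(self):
        model = random_stable_mvar(k=2, p=7, seed=2)
        rec = gen_mvar(model, 120.0, 1000.0, seed=9)
        fitted = fit_mvar(make_segments(rec.data), 7)
        f, P = welch(rec.data[:, 0], fs=1000.0, nperseg=2000)
        sel = (f >= 3) & (f <= 40)
        grid = f[sel]
        S = mvar_spectrum(fitted, grid)
        est = np.trapezoid(P[sel], grid)
        par = 2.0 * np.trapezoid(S[:, 0, 0].real, grid)
        assert abs(est - par) / par < 0.2
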