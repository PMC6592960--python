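from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import welch

from dirconn.errors import InvalidParameterError, StabilityError
from dirconn.neural_mass import (
    NeuralMassModel,
    drift,
    find_fixed_point,
    linearize,
    model_derived_dtf,
    predict_csd,
    sigmoid_response,
    sigmoid_slope,
    simulate_nmm,
    transfer_function,
)


@pytest.fixture
def model():
    return NeuralMassModel()


def uncoupled_model(**kw):
    """Two isolated sources: no extrinsic connections."""
    return NeuralMassModel(a_fwd=0.0, a_bwd=0.0, **kw)


def isolated_pair_model():
    """All intrinsic and extrinsic gains zero: ten independent pairs."""
    return NeuralMassModel(a_fwd=0.0, a_bwd=0.0, gamma=np.zeros((2, 5)))


def fd_jacobian(x, m, cond, h=1e-6):
    J = np.empty((20, 20))
    for i in range(20):
        e = np.zeros(20)
        e[i] = h
        J[:, i] = (drift(x + e, m, cond) - drift(x - e, m, cond)) / (2 * h)
    return J


class TestSigmoid:
    def test_zero_centred(self):
        assert sigmoid_response(0.0, 2.0, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_saturation_limit(self):
        rho1, rho2 = 2.0, 1.0
        lim = 1 - 1 / (1 + np.exp(rho1 * rho2))
        assert sigmoid_response(1e3, rho1, rho2) == pytest.approx(lim)
        assert np.all(np.diff(sigmoid_response(np.linspace(-5, 5, 100), rho1, rho2)) > 0)

    def test_slope_matches_finite_difference(self):
        rho1, rho2, h = 2.0, 1.0, 1e-6
        for v in (-1.0, 0.0, 0.7, 2.5):
            fd = (sigmoid_response(v + h, rho1, rho2) - sigmoid_response(v - h, rho1, rho2)) / (2 * h)
            assert sigmoid_slope(v, rho1, rho2) == pytest.approx(fd, rel=1e-6)


class TestDrift:
    def test_origin_is_equilibrium_for_any_gains(self, rng):
        for _ in range(5):
            m = NeuralMassModel(
                gamma=rng.uniform(0, 200, (2, 5)),
                a_fwd=rng.uniform(0, 300),
                a_bwd=rng.uniform(0, 300),
            )
            np.testing.assert_allclose(drift(np.zeros(20), m, "W"), 0.0, atol=1e-14)

    def test_isolated_pair_relaxation(self):
        m = isolated_pair_model()
        x = np.zeros(20)
        x[0] = 1.0  # displace one voltage, zero current
        dx = drift(x, m, "W")
        kappa_e = m.kappa_e[0]
        assert dx[0] == pytest.approx(0.0)  # v̇ = i = 0
        assert dx[1] == pytest.approx(-kappa_e**2)  # i̇ = −κ²v
        assert np.all(dx[2:] == 0)

    @pytest.mark.parametrize("cond", ["W", "A"])
    def test_jacobian_matches_finite_differences(self, rng, cond):
        m = NeuralMassModel(b_fwd=-0.7, b_self=np.array([0.2, 0.2]))
        x = rng.normal(0, 0.3, 20)
        J, _, _ = linearize(m, cond, x_star=x, require_stable=False)
        Jfd = fd_jacobian(x, m, cond)
        assert np.max(np.abs(J - Jfd)) / np.max(np.abs(Jfd)) < 1e-6


class TestFixedPoint:
    def test_zero_drive_fixed_point_is_origin(self, model):
        np.testing.assert_array_equal(find_fixed_point(model, "W", u0=0.0), 0.0)

    def test_analytic_steady_state_without_intrinsic_coupling(self):
        m = isolated_pair_model()
        u0 = 0.05
        x_star = find_fixed_point(m, "W", u0=u0)
        expected = m.H_e[0] * m.C * u0 / m.kappa_e[0]  # v* = H·C·u0/κ
        assert x_star[0] == pytest.approx(expected, rel=1e-8)
        assert x_star[10] == pytest.approx(expected, rel=1e-8)
        np.testing.assert_allclose(x_star[1::2], 0.0, atol=1e-10)

    def test_newton_agrees_with_relaxation(self, model):
        from scipy.integrate import solve_ivp

        u0 = 0.02
        x_newton = find_fixed_point(model, "W", u0=u0)
        relax = solve_ivp(
            lambda t, y: drift(y, model, "W", u0),
            (0, 3.0),
            np.zeros(20),
            method="LSODA",
            rtol=1e-11,
            atol=1e-13,
        )
        np.testing.assert_allclose(x_newton, relax.y[:, -1], atol=1e-8)
        assert np.max(np.abs(drift(x_newton, model, "W", u0))) < 1e-10


class TestLinearize:
    def test_isolated_pair_block_is_critically_damped(self):
        m = isolated_pair_model()
        J, _, _ = linearize(m, "W", x_star=np.zeros(20))
        block = J[:2, :2]
        lams = np.linalg.eigvals(block)
        np.testing.assert_allclose(sorted(lams.real), [-m.kappa_e[0]] * 2)
        np.testing.assert_allclose(lams.imag, 0.0, atol=1e-8)

    def test_uncoupled_jacobian_is_pairwise_block_diagonal(self):
        m = isolated_pair_model()
        J, _, _ = linearize(m, "W", x_star=np.zeros(20))
        mask = np.kron(np.eye(10), np.ones((2, 2)))
        assert np.max(np.abs(J * (1 - mask))) == 0.0

    def test_default_model_is_stable(self, model):
        J, _, _ = linearize(model, "W")
        assert np.linalg.eigvals(J).real.max() < 0

    def test_unstable_model_raises(self):
        m = NeuralMassModel(a_fwd=5000.0, a_bwd=5000.0)
        with pytest.raises(StabilityError):
            linearize(m, "W")


class TestTransferFunction:
    def test_uncoupled_sources_give_diagonal_transfer(self):
        m = uncoupled_model()
        J, B, C = linearize(m, "W")
        T = transfer_function(J, B, C, np.arange(1.0, 80.0, 1.0))
        np.testing.assert_allclose(T[:, 0, 1], 0.0, atol=1e-14)
        np.testing.assert_allclose(T[:, 1, 0], 0.0, atol=1e-14)

    def test_single_pair_dc_gain(self):
        kappa, H, g = 250.0, 4.0, 3.0
        J = np.array([[0.0, 1.0], [-(kappa**2), -2 * kappa]])
        B = np.array([[0.0], [kappa * H * g]])
        C = np.array([[1.0, 0.0]])
        T = transfer_function(J, B, C, np.array([1e-9]))
        assert abs(T[0, 0, 0]) == pytest.approx(H * g / kappa, rel=1e-6)

    def test_high_frequency_rolloff(self):
        kappa = 250.0
        J = np.array([[0.0, 1.0], [-(kappa**2), -2 * kappa]])
        B = np.array([[0.0], [1.0]])
        C = np.array([[1.0, 0.0]])
        T = transfer_function(J, B, C, np.array([200.0, 2000.0]))
        # second-order kernel: ≥ 40 dB/decade
        assert abs(T[0, 0, 0]) / abs(T[1, 0, 0]) >= 100 * 0.95


class TestPredictCSD:
    def test_hermitian_with_nonnegative_diagonal(self, model):
        csd = predict_csd(model, "W")
        np.testing.assert_allclose(
            csd.G, np.conj(np.swapaxes(csd.G, 1, 2)), atol=1e-12
        )
        assert np.all(csd.G[:, 0, 0].real >= 0)
        assert np.all(csd.G[:, 1, 1].real >= 0)

    def test_uncoupled_noiseless_cross_spectrum_vanishes(self):
        m = uncoupled_model(alpha_n=np.full(2, -100.0), beta_n=np.full(2, -100.0))
        csd = predict_csd(m, "W")
        np.testing.assert_allclose(csd.G[:, 0, 1], 0.0, atol=1e-30)

    def test_grid_must_exclude_zero(self, model):
        with pytest.raises(InvalidParameterError):
            predict_csd(model, "W", np.arange(0.0, 50.0, 1.0))

    def test_condition_scaling_identity_when_effects_are_zero(self, model):
        gw = predict_csd(model, "W").G
        ga = predict_csd(model, "A").G  # all b = 0: A must equal W
        np.testing.assert_allclose(gw, ga, atol=0, rtol=1e-12)


class TestModelDerivedDTF:
    def test_uncoupled_cross_dtf_zero_and_rows_normalized(self):
        m = uncoupled_model()
        dtf = model_derived_dtf(m, "W")
        np.testing.assert_allclose(dtf.values[:, 0, 1], 0.0, atol=1e-14)
        np.testing.assert_allclose(dtf.values[:, 1, 0], 0.0, atol=1e-14)
        np.testing.assert_allclose(dtf.values.sum(axis=2), 1.0, atol=1e-10)

    def test_forward_gain_monotonically_increases_forward_flow(self):
        band = np.arange(3.0, 40.5, 0.5)
        averages = []
        for af in (32.0, 128.0, 448.0):
            m = NeuralMassModel(a_fwd=af)
            dtf = model_derived_dtf(m, "W", band)
            averages.append(dtf.values[:, 1, 0].mean())  # flow P→F
        assert averages[0] < averages[1] < averages[2]


class TestSimulation:
    def test_seed_reproducibility(self, model):
        a = simulate_nmm(model, "W", duration_s=2.0, seed=42)
        b = simulate_nmm(model, "W", duration_s=2.0, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_innovations_stay_at_fixed_point(self, model):
        silent = replace(
            model,
            alpha_u=np.full(2, -500.0),
            alpha_n=np.full(2, -500.0),
        )
        rec = simulate_nmm(silent, "W", duration_s=1.0, seed=0, measurement_noise=False)
        np.testing.assert_allclose(rec.data, 0.0, atol=1e-12)

    def test_welch_spectrum_matches_linearized_prediction(self, model):
        rec = simulate_nmm(model, "W", duration_s=120.0, seed=5, measurement_noise=False)
        f, P = welch(rec.data[:, 0], fs=rec.fs, nperseg=2000)
        sel = (f >= 3) & (f <= 40)
        grid = f[sel]
        pred = predict_csd(model, "W", grid)
        est = np.trapezoid(P[sel], grid)
        par = np.trapezoid(pred.G[:, 0, 0].real, grid)
        assert abs(est - par) / par < 0.25
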