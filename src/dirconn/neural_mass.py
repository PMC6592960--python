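"""Two-source LFP neural-mass generative model.

Each cortical source comprises three subpopulations — spiny stellate cells
in the granular layer, plus pyramidal cells and inhibitory interneurons in
supragranular/infragranular layers. Every synaptic channel is a
second-order kernel: a (voltage, current) pair obeying

    v̇ = i
    i̇ = κ H d − 2 κ i − κ² v

with rate constant κ (s⁻¹), maximal postsynaptic gain H (mV) and
presynaptic drive d (a weighted sum of sigmoid firing rates plus, for the
stellate population, exogenous input C·u and the stochastic innovation).
The impulse response of such a pair is the critically damped alpha kernel
H κ t e^{−κt}.

Per source the state vector holds five pairs (10 states): stellate
excitatory, pyramidal excitatory, pyramidal inhibitory, interneuron
excitatory, interneuron inhibitory. Population depolarizations are
    stellate: v_st,  pyramidal: v_pe − v_pi,  interneuron: v_ie − v_ii,
and the observed signal is the pyramidal depolarization times an
observation gain.

Between sources, forward connections target the granular layer (stellate
drive) and backward connections target superficial and deep layers
(pyramidal-excitatory and interneuron-excitatory drives); both originate
from the pyramidal output of the other source. Condition-specific effects
(anaesthesia vs wakefulness) scale the forward gain, backward gain and the
inhibitory self-connection γ₅ of each source multiplicatively by exp(b);
b = 0 reproduces wakefulness.

Spectral predictions come from linearizing around the fixed point: with
Jacobian J, innovation input matrix B and observation matrix C, the
innovation-to-output transfer is T(f) = C (2πif·I − J)⁻¹ B and the
predicted cross-spectral density is

    G(f) = T(f) diag(g_u(f)) T(f)ᴴ + diag(g_n(f)),

where g_u(f) = exp(α_u) + exp(β_u)/f parameterizes each source's
innovation spectrum (white + 1/f) and g_n(f) likewise the channel noise.
All spectra are one-sided densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConditioningError,
    FixedPointError,
    InvalidParameterError,
    StabilityError,
)
from .mvar import DTFSpectrum
from .recording import MultichannelRecording

logger = logging.getLogger(__name__)

__all__ = [
    "NeuralMassModel",
    "PredictedCSD",
    "sigmoid_response",
    "sigmoid_slope",
    "drift",
    "find_fixed_point",
    "linearize",
    "transfer_function",
    "predict_csd",
    "model_derived_dtf",
    "simulate_nmm",
]

N_STATES = 20  # 2 sources x 5 pairs x (v, i)
_PAIR_KAPPA_KIND = ["e", "e", "i", "e", "i"]  # stellate, pyr_e, pyr_i, int_e, int_i


@dataclass
class NeuralMassModel:
    """Parameter set for the two-source model.

    Per-source arrays are ordered ``[parietal, frontal]`` (labels
    configurable). ``forward_from`` selects the architecture: the source
    sending the forward connection (0 → model 1 of the architecture space:
    parietal→frontal forward, frontal→parietal backward; 1 → the reverse).
    Condition scalings ``b_*`` act multiplicatively as exp(b) in condition
    A and are inert (exp(0)=1) in condition W.
    """

    H_e: np.ndarray = field(default_factory=lambda: np.array([4.0, 4.0]))  # mV
    H_i: np.ndarray = field(default_factory=lambda: np.array([32.0, 32.0]))  # mV
    kappa_e: np.ndarray = field(default_factory=lambda: np.array([250.0, 250.0]))  # 1/s
    kappa_i: np.ndarray = field(default_factory=lambda: np.array([62.5, 62.5]))  # 1/s
    gamma: np.ndarray = field(
        default_factory=lambda: np.array([[128.0, 128.0, 64.0, 64.0, 16.0]] * 2)
    )  # intrinsic gains γ1..γ5 per source
    rho1: float = 2.0  # sigmoid slope
    rho2: float = 1.0  # sigmoid offset (mV)
    a_fwd: float = 32.0  # extrinsic forward gain
    a_bwd: float = 32.0  # extrinsic backward gain
    b_fwd: float = 0.0  # condition log-scaling of a_fwd
    b_bwd: float = 0.0
    b_self: np.ndarray = field(default_factory=lambda: np.zeros(2))  # per source, on γ5
    C: float = 1.0  # exogenous input gain
    g_obs: np.ndarray = field(default_factory=lambda: np.ones(2))
    alpha_u: np.ndarray = field(default_factory=lambda: np.full(2, np.log(2e-3)))
    beta_u: np.ndarray = field(default_factory=lambda: np.full(2, np.log(2e-4)))
    alpha_n: np.ndarray = field(default_factory=lambda: np.full(2, np.log(1e-9)))
    beta_n: np.ndarray = field(default_factory=lambda: np.full(2, np.log(1e-10)))
    forward_from: int = 0
    source_labels: tuple[str, str] = ("P", "F")

    def __post_init__(self) -> None:
        for name in ("H_e", "H_i", "kappa_e", "kappa_i", "b_self", "g_obs",
                     "alpha_u", "beta_u", "alpha_n", "beta_n"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float).reshape(2, 5)
        if np.any(self.kappa_e <= 0) or np.any(self.kappa_i <= 0):
            raise InvalidParameterError("rate constants must be positive")
        if np.any(self.gamma < 0) or self.a_fwd < 0 or self.a_bwd < 0:
            raise InvalidParameterError("coupling gains must be nonnegative")
        if self.forward_from not in (0, 1):
            raise InvalidParameterError("forward_from must be 0 or 1")

    def scaled(self, **log_scalings: float) -> "NeuralMassModel":
        """Copy with named parameters multiplied by exp(value).

        Keys: ``a_fwd``, ``a_bwd``, ``g5_0``, ``g5_1``, ``H_e_0`` … — see
        :mod:`dirconn.inversion` for the full free-parameter vocabulary.
        """
        m = replace(self)
        m.gamma = self.gamma.copy()
        for name in ("H_e", "H_i", "kappa_e", "kappa_i", "g_obs",
                     "alpha_u", "beta_u", "alpha_n", "beta_n", "b_self"):
            setattr(m, name, getattr(self, name).copy())
        for key, val in log_scalings.items():
            if key in ("a_fwd", "a_bwd", "C"):
                setattr(m, key, getattr(m, key) * np.exp(val))
            elif key == "g_obs":  # shared observation-gain scaling
                m.g_obs *= np.exp(val)
            elif key.startswith("g5_"):
                m.gamma[int(key[-1]), 4] *= np.exp(val)
            elif key.startswith(("H_e_", "H_i_", "kappa_e_", "kappa_i_", "g_obs_")):
                base, idx = key.rsplit("_", 1)
                getattr(m, base)[int(idx)] *= np.exp(val)
            elif key.startswith(("alpha_u_", "beta_u_", "alpha_n_", "beta_n_")):
                base, idx = key.rsplit("_", 1)
                getattr(m, base)[int(idx)] += val  # already log-parameters
            elif key in ("b_fwd", "b_bwd"):
                setattr(m, key, getattr(m, key) + val)  # additive in log space
            elif key.startswith("b_self_"):
                m.b_self[int(key[-1])] += val
            else:
                raise InvalidParameterError(f"unknown scaled parameter {key!r}")
        return m


@dataclass
class PredictedCSD:
    """Cross-spectral density matrices on a frequency grid (one-sided)."""

    freqs: np.ndarray
    G: np.ndarray  # (n_freqs, 2, 2) complex Hermitian

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.G = np.asarray(self.G, dtype=complex)


def sigmoid_response(v, rho1: float, rho2: float):
    """Zero-centred sigmoid firing-rate function.

    ``S(v) = 1/(1+e^{−ρ1(v−ρ2)}) − 1/(1+e^{ρ1ρ2})``; S(0) = 0 by
    construction, strictly increasing, bounded.
    """
    return 1.0 / (1.0 + np.exp(-rho1 * (np.asarray(v, float) - rho2))) - 1.0 / (
        1.0 + np.exp(rho1 * rho2)
    )


def sigmoid_slope(v, rho1: float, rho2: float):
    """dS/dv of :func:`sigmoid_response`."""
    s = 1.0 / (1.0 + np.exp(-rho1 * (np.asarray(v, float) - rho2)))
    return rho1 * s * (1.0 - s)


# ---------------------------------------------------------------------------
# Structural matrices: the drive of each synaptic pair is a linear
# combination of six sigmoid channels S(pot), pot = M x:
#   [S(vp_P), S(vp_F), S(vst_P), S(vst_F), S(vi_P), S(vi_F)]
# ---------------------------------------------------------------------------


def _pair_constants(model: NeuralMassModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-pair (κ, H) arrays of length 10, source-major."""
    kappa = np.empty(10)
    H = np.empty(10)
    for s in range(2):
        for q, kind in enumerate(_PAIR_KAPPA_KIND):
            idx = 5 * s + q
            if kind == "e":
                kappa[idx], H[idx] = model.kappa_e[s], model.H_e[s]
            else:
                kappa[idx], H[idx] = model.kappa_i[s], model.H_i[s]
    return kappa, H


def _potential_matrix() -> np.ndarray:
    """(6, 20) map from states to population depolarizations."""
    M = np.zeros((6, N_STATES))
    for s in range(2):
        off = 10 * s
        M[0 + s, off + 2] = 1.0  # vp = v_pe - v_pi
        M[0 + s, off + 4] = -1.0
        M[2 + s, off + 0] = 1.0  # stellate voltage
        M[4 + s, off + 6] = 1.0  # vi = v_ie - v_ii
        M[4 + s, off + 8] = -1.0
    return M


_M_POT = _potential_matrix()


def _drive_weights(model: NeuralMassModel, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """(10, 6) sigmoid-to-drive weights and (10,) exogenous input weights."""
    if condition not in ("W", "A"):
        raise InvalidParameterError(f"condition must be 'W' or 'A', got {condition!r}")
    cA = 1.0 if condition == "A" else 0.0
    af = model.a_fwd * np.exp(model.b_fwd * cA)
    ab = model.a_bwd * np.exp(model.b_bwd * cA)
    fwd_to = 1 - model.forward_from  # source receiving the forward connection
    bwd_to = model.forward_from  # source receiving the backward connection
    Wd = np.zeros((10, 6))
    cu = np.zeros(10)
    for s in range(2):
        o = 1 - s
        g = model.gamma[s]
        base = 5 * s
        # stellate: intrinsic from own pyramids + forward input + exogenous
        Wd[base + 0, 0 + s] = g[0]
        if s == fwd_to:
            Wd[base + 0, 0 + o] = af
        cu[base + 0] = model.C
        # pyramidal excitatory: from own stellate + backward input
        Wd[base + 1, 2 + s] = g[1]
        if s == bwd_to:
            Wd[base + 1, 0 + o] = ab
        # pyramidal inhibitory: from own interneurons
        Wd[base + 2, 4 + s] = g[3]
        # interneuron excitatory: from own pyramids + backward input
        Wd[base + 3, 0 + s] = g[2]
        if s == bwd_to:
            Wd[base + 3, 0 + o] = ab
        # interneuron inhibitory self-connection (condition-scaled)
        Wd[base + 4, 4 + s] = g[4] * np.exp(model.b_self[s] * cA)
    return Wd, cu


def drift(
    x: np.ndarray, model: NeuralMassModel, condition: str = "W", u: float = 0.0
) -> np.ndarray:
    """Deterministic time derivative of the 20-dimensional state."""
    x = np.asarray(x, dtype=float)
    kappa, H = _pair_constants(model)
    Wd, cu = _drive_weights(model, condition)
    pot = _M_POT @ x
    d = Wd @ sigmoid_response(pot, model.rho1, model.rho2) + cu * u
    dx = np.empty(N_STATES)
    v = x[0::2]
    i = x[1::2]
    dx[0::2] = i
    dx[1::2] = kappa * H * d - 2.0 * kappa * i - kappa**2 * v
    return dx


def find_fixed_point(
    model: NeuralMassModel,
    condition: str = "W",
    u0: float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Equilibrium state for constant drive ``u0``.

    Damped Newton from the origin with the analytic Jacobian; if that
    stalls, a long relaxation integration provides a fresh starting point
    before a second Newton pass. For ``u0 = 0`` the origin is an exact
    equilibrium (the sigmoid is zero-centred).
    """
    x = np.zeros(N_STATES)
    if np.max(np.abs(drift(x, model, condition, u0))) <= tol:
        return x

    def newton(x0: np.ndarray) -> np.ndarray | None:
        x = x0.copy()
        for _ in range(max_iter):
            f = drift(x, model, condition, u0)
            if np.max(np.abs(f)) <= tol:
                return x
            J = _jacobian(x, model, condition)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            f0 = np.linalg.norm(f)
            while lam > 1e-6:
                x_new = x + lam * step
                if np.linalg.norm(drift(x_new, model, condition, u0)) < f0:
                    x = x_new
                    break
                lam /= 2.0
            else:
                return None
        return x if np.max(np.abs(drift(x, model, condition, u0))) <= tol else None

    sol = newton(x)
    if sol is None:
        from scipy.integrate import solve_ivp

        relax = solve_ivp(
            lambda t, y: drift(y, model, condition, u0),
            (0.0, 2.0),
            x,
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        sol = newton(relax.y[:, -1])
    if sol is None:
        raise FixedPointError(
            f"fixed-point search failed (condition={condition}, u0={u0}); "
            "Newton and relaxation both stalled"
        )
    return sol


def _jacobian(x: np.ndarray, model: NeuralMassModel, condition: str) -> np.ndarray:
    """Analytic ∂drift/∂x at state ``x``."""
    kappa, H = _pair_constants(model)
    Wd, _ = _drive_weights(model, condition)
    pot = _M_POT @ np.asarray(x, float)
    dS = sigmoid_slope(pot, model.rho1, model.rho2)
    J = np.zeros((N_STATES, N_STATES))
    # linear pair dynamics
    for q in range(10):
        J[2 * q, 2 * q + 1] = 1.0
        J[2 * q + 1, 2 * q] = -kappa[q] ** 2
        J[2 * q + 1, 2 * q + 1] = -2.0 * kappa[q]
    # drive coupling through the sigmoids: κH · Wd · diag(S') · M
    J[1::2, :] += (kappa * H)[:, None] * (Wd @ (dS[:, None] * _M_POT))
    return J


def linearize(
    model: NeuralMassModel,
    condition: str = "W",
    x_star: np.ndarray | None = None,
    require_stable: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """State Jacobian, innovation input matrix and observation matrix.

    ``B`` injects each source's innovation into its stellate current
    equation scaled by κ_e·H_e·C; ``Cmat`` reads the pyramidal
    depolarization g_obs·(v_pe − v_pi) of each source. Raises a stability
    error if any Jacobian eigenvalue has nonnegative real part.
    """
    if x_star is None:
        x_star = find_fixed_point(model, condition)
    J = _jacobian(x_star, model, condition)
    if require_stable:
        lams = np.linalg.eigvals(J)
        worst = lams[int(np.argmax(lams.real))]
        if worst.real >= 0:
            raise StabilityError(
                f"linearized model unstable: eigenvalue {worst:.4g} has "
                "nonnegative real part"
            )
    B = np.zeros((N_STATES, 2))
    for s in range(2):
        B[10 * s + 1, s] = model.kappa_e[s] * model.H_e[s] * model.C
    Cmat = np.zeros((2, N_STATES))
    for s in range(2):
        Cmat[s, 10 * s + 2] = model.g_obs[s]
        Cmat[s, 10 * s + 4] = -model.g_obs[s]
    return J, B, Cmat


def transfer_function(
    J: np.ndarray, B: np.ndarray, Cmat: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Innovation-to-output transfer T(f) = C (2πif·I − J)⁻¹ B.

    Returns an array of shape (n_freqs, n_out, n_in).
    """
    freqs = np.asarray(freqs, dtype=float)
    n = J.shape[0]
    omega = 2j * np.pi * freqs
    A = omega[:, None, None] * np.eye(n) - J[None, :, :]
    try:
        X = np.linalg.solve(A, np.broadcast_to(B, (freqs.size, *B.shape)))
    except np.linalg.LinAlgError as exc:
        raise ConditioningError(f"resolvent singular on the grid: {exc}") from exc
    return Cmat @ X


def _innovation_spectrum(alpha: np.ndarray, beta: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """White + 1/f spectral density, shape (n_freqs, n_sources)."""
    return np.exp(alpha)[None, :] + np.exp(beta)[None, :] / freqs[:, None]


def predict_csd(
    model: NeuralMassModel, condition: str = "W", freqs: np.ndarray | None = None
) -> PredictedCSD:
    """Predicted cross-spectral density G(f) = T diag(g_u) Tᴴ + diag(g_n)."""
    if freqs is None:
        freqs = np.arange(1.0, 80.0 + 0.5, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise InvalidParameterError("CSD grid must start above 0 Hz (1/f innovations)")
    J, B, Cmat = linearize(model, condition)
    T = transfer_function(J, B, Cmat, freqs)
    gu = _innovation_spectrum(model.alpha_u, model.beta_u, freqs)
    gn = _innovation_spectrum(model.alpha_n, model.beta_n, freqs)
    G = np.einsum("fij,fj,fkj->fik", T, gu, np.conj(T))
    G += np.einsum("fi,ij->fij", gn, np.eye(2))
    G = 0.5 * (G + np.conj(np.swapaxes(G, 1, 2)))  # enforce exact Hermitian symmetry
    return PredictedCSD(freqs=freqs, G=G)


def model_derived_dtf(
    model: NeuralMassModel, condition: str = "W", freqs: np.ndarray | None = None
) -> DTFSpectrum:
    """DTF implied by the generative model's transfer functions.

    The inflow normalization is weighted by each source's innovation
    spectrum: DTF_ij(f) = |T_ij|² g_uj / Σ_m |T_im|² g_um, so rows sum to 1
    exactly as in the data-driven DTF.
    """
    if freqs is None:
        freqs = np.arange(1.0, 80.0 + 0.5, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise InvalidParameterError("grid must start above 0 Hz")
    J, B, Cmat = linearize(model, condition)
    T = transfer_function(J, B, Cmat, freqs)
    gu = _innovation_spectrum(model.alpha_u, model.beta_u, freqs)
    num = (np.abs(T) ** 2) * gu[:, None, :]
    values = num / num.sum(axis=2, keepdims=True)
    return DTFSpectrum(
        freqs=freqs,
        values=values,
        normalized=True,
        channel_labels=list(model.source_labels),
    )


# ---------------------------------------------------------------------------
# Stochastic simulation (Euler–Maruyama, numba-accelerated when available)
# ---------------------------------------------------------------------------

try:  # pragma: no cover - trivial import guard
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _euler_kernel(x0, kappa, kH, Wd, cu_u, rho1, rho2, noise, noise_rows,
                  dt, n_sub, n_out, obs_w):  # pragma: no cover - jit code
    n_states = x0.size
    x = x0.copy()
    y = np.zeros((n_out, 2))
    s_off = 1.0 / (1.0 + np.exp(rho1 * rho2))
    step = 0
    for m in range(n_out):
        acc0 = 0.0
        acc1 = 0.0
        for _ in range(n_sub):
            # potentials and sigmoid channels
            vp0 = x[2] - x[4]
            vp1 = x[12] - x[14]
            vst0 = x[0]
            vst1 = x[10]
            vi0 = x[6] - x[8]
            vi1 = x[16] - x[18]
            s = np.empty(6)
            s[0] = 1.0 / (1.0 + np.exp(-rho1 * (vp0 - rho2))) - s_off
            s[1] = 1.0 / (1.0 + np.exp(-rho1 * (vp1 - rho2))) - s_off
            s[2] = 1.0 / (1.0 + np.exp(-rho1 * (vst0 - rho2))) - s_off
            s[3] = 1.0 / (1.0 + np.exp(-rho1 * (vst1 - rho2))) - s_off
            s[4] = 1.0 / (1.0 + np.exp(-rho1 * (vi0 - rho2))) - s_off
            s[5] = 1.0 / (1.0 + np.exp(-rho1 * (vi1 - rho2))) - s_off
            for q in range(10):
                d = cu_u[q]
                for c in range(6):
                    d += Wd[q, c] * s[c]
                v = x[2 * q]
                cur = x[2 * q + 1]
                x[2 * q] = v + dt * cur
                x[2 * q + 1] = cur + dt * (
                    kH[q] * d - 2.0 * kappa[q] * cur - kappa[q] ** 2 * v
                )
            for src in range(2):
                x[noise_rows[src]] += noise[step, src]
            step += 1
            acc0 += obs_w[0] * (x[2] - x[4])
            acc1 += obs_w[1] * (x[12] - x[14])
            if np.abs(x).max() > 1e6:
                return y, step  # caller raises
        y[m, 0] = acc0 / n_sub
        y[m, 1] = acc1 / n_sub
    return y, -1


def simulate_nmm(
    model: NeuralMassModel,
    condition: str = "W",
    duration_s: float = 30.0,
    fs: float = 1000.0,
    seed: int = 0,
    u: float = 0.0,
    burn_in_s: float = 1.0,
    measurement_noise: bool = True,
    x0: np.ndarray | None = None,
) -> MultichannelRecording:
    """Euler–Maruyama simulation of the stochastic model.

    The integration step is ≤ 1/(8·κ_max); white innovations realise the
    white component exp(α_u) of each source's innovation spectrum (the 1/f
    component is a spectral-fit construct and is not simulated). Substeps
    are averaged within each output bin; optional white measurement noise
    realises exp(α_n). Bit-reproducible for a given seed.
    """
    kappa, H = _pair_constants(model)
    Wd, cu = _drive_weights(model, condition)
    kmax = kappa.max()
    n_sub = max(1, int(np.ceil(8.0 * kmax / fs)))
    dt = 1.0 / (fs * n_sub)
    n_out = int(round(duration_s * fs))
    n_burn = int(round(burn_in_s * fs))
    n_steps = (n_out + n_burn) * n_sub

    rng = np.random.default_rng(seed)
    # innovation increment: κ_e H_e C · w(t), w white with one-sided PSD exp(α_u)
    sig = (
        model.kappa_e
        * model.H_e
        * model.C
        * np.sqrt(np.exp(model.alpha_u) / 2.0)
        * np.sqrt(dt)
    )
    noise = rng.standard_normal((n_steps, 2)) * sig[None, :]
    noise_rows = np.array([1, 11], dtype=np.int64)  # stellate current states

    x_init = np.zeros(N_STATES) if x0 is None else np.asarray(x0, float).copy()
    y, bad = _euler_kernel(
        x_init,
        kappa,
        kappa * H,
        Wd,
        cu * u,
        model.rho1,
        model.rho2,
        noise,
        noise_rows,
        dt,
        n_sub,
        n_out + n_burn,
        model.g_obs,
    )
    if bad >= 0:
        raise StabilityError(
            f"simulation diverged at step {bad} (t={bad * dt:.3f} s); "
            "state norm exceeded 1e6"
        )
    y = y[n_burn:]
    if measurement_noise:
        # white channel noise with one-sided PSD exp(α_n) up to fs/2
        sd_n = np.sqrt(np.exp(model.alpha_n) * fs / 2.0)
        y = y + rng.standard_normal(y.shape) * sd_n[None, :]
    return MultichannelRecording(
        data=y,
        fs=fs,
        channel_labels=list(model.source_labels),
        condition=condition,
        modality="SYNTH",
    )
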