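"""Multivariate autoregressive (MVAR) modelling and the directed transfer function.

An order-``p`` MVAR model describes a k-channel process driven by white
innovations,

    x_t = A_1 x_{t-1} + ... + A_p x_{t-p} + e_t,      e_t ~ N(0, Σ)

(regression form; the equivalent moving-equality form Σ_j Â_j x_{t-j} = e_t
has Â_0 = I and Â_j = −A_j). Coefficients are estimated by solving the
multichannel Yule–Walker normal equations on segment-pooled, biased lagged
covariances, and the model order is chosen by the Bayesian Information
Criterion.

In the frequency domain the model's spectral coefficient matrix is

    Ā(f) = I − Σ_j A_j exp(−i 2π f Δt j),       Δt = 1/fs,

and its inverse H(f) = Ā(f)⁻¹ is the spectral transfer matrix. The
normalized directed transfer function (DTF)

    DTF_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²

quantifies information inflow j → i at each frequency, lies in [0, 1], and
sums to 1 over the sources j feeding each target i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConditioningError,
    InvalidParameterError,
    LengthError,
    RankError,
)
from .recording import SegmentSet

__all__ = [
    "MVARModel",
    "CovarianceSequence",
    "SpectralTransfer",
    "DTFSpectrum",
    "default_freq_grid",
    "lagged_covariance",
    "fit_yule_walker",
    "fit_mvar",
    "select_order_bic",
    "check_stability",
    "transfer_matrix",
    "compute_dtf",
    "mvar_spectrum",
]

#: Default analysis grid: 0.5–100 Hz in 0.25 Hz steps (covers the 3–40 Hz
#: statistics band with margin).
def default_freq_grid(f_lo: float = 0.5, f_hi: float = 100.0, df: float = 0.25) -> np.ndarray:
    return np.arange(f_lo, f_hi + 0.5 * df, df)


@dataclass
class MVARModel:
    """Fitted or specified MVAR model in regression form."""

    coeffs: list[np.ndarray]  # p matrices, each (k, k): x_t = Σ A_j x_{t-j} + e_t
    noise_cov: np.ndarray  # (k, k) innovation covariance
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = [np.asarray(A, dtype=float) for A in self.coeffs]
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        k = self.noise_cov.shape[0]
        for A in self.coeffs:
            if A.shape != (k, k):
                raise InvalidParameterError("coefficient/noise dimension mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-10):
            raise InvalidParameterError("noise covariance must be symmetric")

    @property
    def order(self) -> int:
        return len(self.coeffs)

    @property
    def k(self) -> int:
        return self.noise_cov.shape[0]

    def companion(self) -> np.ndarray:
        """(pk x pk) companion matrix of the lag polynomial."""
        p, k = self.order, self.k
        if p == 0:
            return np.zeros((0, 0))
        C = np.zeros((p * k, p * k))
        C[:k, :] = np.hstack(self.coeffs)
        if p > 1:
            C[k:, :-k] = np.eye((p - 1) * k)
        return C


@dataclass
class CovarianceSequence:
    """Lagged covariances R(s) = E[x_t x_{t+s}ᵀ] for s = 0 … s_max."""

    R: list[np.ndarray]  # R[s], each (k, k)

    @property
    def s_max(self) -> int:
        return len(self.R) - 1

    @property
    def k(self) -> int:
        return self.R[0].shape[0]


@dataclass
class SpectralTransfer:
    """Transfer matrices H(f) = Ā(f)⁻¹ on a frequency grid."""

    freqs: np.ndarray
    H: np.ndarray  # (n_freqs, k, k) complex


@dataclass
class DTFSpectrum:
    """Directed transfer function values; ``values[f, i, j]`` is flow j → i."""

    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, k, k) real
    normalized: bool = True
    channel_labels: list[str] = field(default_factory=list)


def lagged_covariance(segments: SegmentSet, s_max: int) -> CovarianceSequence:
    """Biased (1/N) lagged covariance, mean-removed per segment, segment-averaged."""
    seg_len = segments.seg_len
    if s_max >= seg_len:
        raise LengthError(f"s_max={s_max} >= segment length {seg_len}")
    k = segments.n_channels
    R = [np.zeros((k, k)) for _ in range(s_max + 1)]
    for seg in segments.segments:
        x = seg - seg.mean(axis=0, keepdims=True)
        n = x.shape[0]
        for s in range(s_max + 1):
            # R(s) = E[x_t x_{t+s}ᵀ], biased normalisation 1/n
            R[s] += (x[: n - s].T @ x[s:]) / n
    for s in range(s_max + 1):
        R[s] /= segments.n_segments
    return CovarianceSequence(R=R)


def fit_yule_walker(R: CovarianceSequence, p: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Solve the multichannel Yule–Walker equations for order ``p``.

    With Γ(s) = E[x_t x_{t−s}ᵀ] = R(s)ᵀ, the normal equations are
    Γ(s) = Σ_j A_j Γ(s−j) for s = 1…p; the innovation covariance follows
    from Σ = R(0) − Σ_j A_j R(j).

    Returns ``(coeffs, noise_cov)``; does not package fs (see
    :func:`fit_mvar` for the recording-level entry point).
    """
    if R.s_max < p:
        raise LengthError(f"covariance sequence has {R.s_max} lags, need {p}")
    k = R.k
    if p == 0:
        return [], R.R[0].copy()

    def gamma(s: int) -> np.ndarray:
        # Γ(s) = E[x_t x_{t-s}ᵀ]; Γ(-s) = Γ(s)ᵀ
        if s >= 0:
            return R.R[s].T
        return R.R[-s]

    # Block-Toeplitz system: [Γ(1) … Γ(p)] = [A_1 … A_p] · G,
    # G[(i,j) block] = Γ(i−j) with i the column-block index.
    G = np.empty((p * k, p * k))
    for i in range(p):
        for j in range(p):
            G[j * k : (j + 1) * k, i * k : (i + 1) * k] = gamma(i - j)
    rhs = np.hstack([gamma(s) for s in range(1, p + 1)])  # (k, pk)
    if np.linalg.cond(G) > 1e12:
        raise RankError(
            "Yule–Walker block-Toeplitz system is numerically singular; "
            "try a lower model order"
        )
    A_stack = np.linalg.solve(G.T, rhs.T).T  # (k, pk)
    coeffs = [A_stack[:, j * k : (j + 1) * k].copy() for j in range(p)]
    sigma = R.R[0].copy()
    for j, A in enumerate(coeffs, start=1):
        sigma -= A @ R.R[j]
    sigma = 0.5 * (sigma + sigma.T)
    return coeffs, sigma


def fit_mvar(segments: SegmentSet, p: int) -> MVARModel:
    """Fit an order-``p`` MVAR model to a segment set by Yule–Walker."""
    R = lagged_covariance(segments, p)
    coeffs, sigma = fit_yule_walker(R, p)
    return MVARModel(coeffs=coeffs, noise_cov=sigma, fs=segments.fs)


def select_order_bic(segments: SegmentSet, p_min: int = 1, p_max: int = 20) -> int:
    """Model order minimising BIC = N·ln det Σ_p + ln(N)·p·k².

    ``N`` is the total pooled sample count; ties break toward the smaller
    order.
    """
    if p_min > p_max or p_min < 1:
        raise InvalidParameterError(f"invalid order range [{p_min}, {p_max}]")
    if p_max >= segments.seg_len / 2:
        raise InvalidParameterError("p_max must be below half the segment length")
    N = segments.n_segments * segments.seg_len
    k = segments.n_channels
    R = lagged_covariance(segments, p_max)
    best_p, best_bic = p_min, np.inf
    for p in range(p_min, p_max + 1):
        _, sigma = fit_yule_walker(CovarianceSequence(R=R.R[: p + 1]), p)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        bic = N * logdet + np.log(N) * p * k * k
        if bic < best_bic - 1e-12:  # strict improvement; ties keep smaller p
            best_p, best_bic = p, bic
    return best_p


def check_stability(model: MVARModel) -> float:
    """Spectral radius of the companion matrix (< 1 ⇒ stationary/stable)."""
    C = model.companion()
    if C.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvals(C))))


def transfer_matrix(model: MVARModel, freqs: np.ndarray) -> SpectralTransfer:
    """Spectral transfer matrix H(f) = (I − Σ_j A_j e^{−i2πfΔt·j})⁻¹."""
    freqs = np.asarray(freqs, dtype=float)
    k, p = model.k, model.order
    dt = 1.0 / model.fs
    Abar = np.broadcast_to(np.eye(k, dtype=complex), (freqs.size, k, k)).copy()
    for j, A in enumerate(model.coeffs, start=1):
        phase = np.exp(-2j * np.pi * freqs * dt * j)
        Abar -= phase[:, None, None] * A
    conds = np.linalg.cond(Abar)
    if np.any(conds > 1e12):
        f_bad = freqs[int(np.argmax(conds))]
        raise ConditioningError(f"spectral matrix numerically singular near {f_bad} Hz")
    H = np.linalg.inv(Abar)
    return SpectralTransfer(freqs=freqs, H=H)


def compute_dtf(
    H: SpectralTransfer,
    normalized: bool = True,
    channel_labels: list[str] | None = None,
) -> DTFSpectrum:
    """DTF from a spectral transfer matrix.

    Normalized form divides each |H_ij|² by the total inflow Σ_m |H_im|² so
    rows sum to 1 and values lie in [0, 1]; unnormalized returns |H_ij|².
    """
    power = np.abs(H.H) ** 2
    if normalized:
        denom = power.sum(axis=2, keepdims=True)
        if np.any(denom == 0):
            raise ConditioningError("zero total inflow encountered in DTF normalization")
        power = power / denom
    return DTFSpectrum(
        freqs=H.freqs,
        values=power,
        normalized=normalized,
        channel_labels=channel_labels or [],
    )


def mvar_spectrum(model: MVARModel, freqs: np.ndarray) -> np.ndarray:
    """Parametric power spectral matrix S(f) = H(f) Σ H(f)ᴴ / fs.

    Two-sided density: integrating the diagonal over [−fs/2, fs/2] (i.e.
    2× the integral over [0, fs/2]) recovers the process variance.
    Returns an array of shape (n_freqs, k, k).
    """
    H = transfer_matrix(model, freqs).H
    S = H @ model.noise_cov @ np.conj(np.swapaxes(H, 1, 2))
    return S / model.fs
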