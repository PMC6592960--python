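"""Synthetic study data: MVAR surrogates and neural-mass condition pairs.

Everything the test suite and the packaged analysis scenarios consume is
generated here, deterministically from a master seed. Two generators:

* ``mvar`` — linear vector-autoregressive surrogates with exactly known
  directed structure (oracles for estimator tests);
* ``nmm`` — the two-source neural-mass model of
  :mod:`dirconn.neural_mass`, rendered per condition (wakefulness W with
  all condition scalings inert; anaesthesia A with the scenario's
  ``b`` scalings applied) and per modality: a clean ECoG-like observation
  and a degraded "reconstructed source" observation (linear channel
  mixing, additive white noise, 60 Hz low-pass) standing in for the
  mixing and bandwidth loss of EEG source reconstruction.

Seed policy: the master seed spawns per-condition/per-modality substreams
by fixed prime offsets, so every recording is a pure function of
(spec, seed) and conditions/modalities use independent noise streams
while the two modalities of one condition share the same underlying
source trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import InvalidParameterError, StabilityError
from .mvar import MVARModel, check_stability
from .neural_mass import NeuralMassModel, simulate_nmm
from .recording import MultichannelRecording

__all__ = [
    "ScenarioSpec",
    "gen_mvar",
    "random_stable_mvar",
    "gen_condition_pair",
    "degrade_to_reconstructed",
    "anaesthesia_scenario",
    "null_scenario",
]

_COND_PRIME = 15485863
_MODE_PRIME = 32452843


def _substream(master: int, condition_index: int, modality_index: int = 0) -> int:
    """Deterministic substream seed (documented derivation; < 2**31)."""
    return (int(master) + condition_index * _COND_PRIME + modality_index * _MODE_PRIME) % (
        2**31 - 1
    )


@dataclass
class ScenarioSpec:
    """Complete description of a synthetic two-condition study."""

    generator: str = "nmm"  # "mvar" | "nmm"
    model: NeuralMassModel | MVARModel = field(default_factory=NeuralMassModel)
    duration_s: float = 30.0
    fs: float = 1000.0
    seed: int = 7
    mixing: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.3], [0.3, 1.0]])
    )
    noise_snr_db: float = 10.0  # degraded-channel additive noise level
    lowpass_hz: float = 60.0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        if abs(np.linalg.det(self.mixing)) < 1e-12:
            raise InvalidParameterError("mixing matrix must be nonsingular")


def gen_mvar(
    model: MVARModel, duration_s: float, fs: float, seed: int, burn_in_s: float = 2.0
) -> MultichannelRecording:
    """Simulate a stable MVAR process with Gaussian innovations.

    A 2 s burn-in is discarded so the returned series is (approximately)
    stationary. Reproducible for a given seed.
    """
    rho = check_stability(model)
    if rho >= 1.0:
        raise StabilityError(f"MVAR model unstable: spectral radius {rho:.4f} >= 1")
    rng = np.random.default_rng(seed)
    k, p = model.k, model.order
    n_burn = int(round(burn_in_s * fs))
    n = int(round(duration_s * fs)) + n_burn
    L = np.linalg.cholesky(model.noise_cov + 1e-15 * np.eye(k))
    e = rng.standard_normal((n, k)) @ L.T
    x = np.zeros((n, k))
    coeffs = model.coeffs
    for t in range(n):
        acc = e[t].copy()
        for j, A in enumerate(coeffs, start=1):
            if t - j >= 0:
                acc += A @ x[t - j]
        x[t] = acc
    return MultichannelRecording(
        data=x[n_burn:], fs=fs, channel_labels=[f"ch{i}" for i in range(k)],
        modality="SYNTH",
    )


def random_stable_mvar(
    k: int = 2,
    p: int = 7,
    fs: float = 1000.0,
    seed: int = 0,
    target_radius: float = 0.85,
    coeff_scale: float = 0.4,
) -> MVARModel:
    """Random MVAR model rescaled to a prescribed companion spectral radius.

    Coefficients are drawn i.i.d. Gaussian with geometrically decaying lag
    scale, then each lag-j matrix is multiplied by c^j, which rescales
    every companion eigenvalue by c and pins the spectral radius exactly
    at ``target_radius``.
    """
    rng = np.random.default_rng(seed)
    coeffs = [rng.normal(0.0, coeff_scale / (j + 1), size=(k, k)) for j in range(p)]
    model = MVARModel(coeffs=coeffs, noise_cov=np.eye(k), fs=fs)
    rho = check_stability(model)
    if rho > 0:
        c = target_radius / rho
        coeffs = [A * c ** (j + 1) for j, A in enumerate(coeffs)]
    return MVARModel(coeffs=coeffs, noise_cov=np.eye(k), fs=fs)


def degrade_to_reconstructed(
    rec: MultichannelRecording,
    mixing: np.ndarray,
    noise_sd: float,
    lowpass_hz: float = 60.0,
    seed: int = 0,
) -> MultichannelRecording:
    """Emulate EEG source reconstruction: mix, band-limit, add noise.

    ``output = lowpass(mixing · sources) + white noise``; the low-pass is
    zero-phase (forward–backward Butterworth, order 5) and is skipped when
    the cutoff is at or above Nyquist. Sampling rate and temporal order
    are never altered.
    """
    mixing = np.asarray(mixing, dtype=float)
    if abs(np.linalg.det(mixing)) < 1e-12:
        raise InvalidParameterError("mixing matrix must be nonsingular")
    mixed = rec.data @ mixing.T
    if lowpass_hz < rec.fs / 2:
        b, a = butter(5, lowpass_hz, btype="low", fs=rec.fs)
        mixed = filtfilt(b, a, mixed, axis=0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mixed = mixed + rng.standard_normal(mixed.shape) * noise_sd
    return replace(rec, data=mixed, modality="RS")


def gen_condition_pair(
    spec: ScenarioSpec,
) -> dict[str, dict[str, MultichannelRecording]]:
    """Render the scenario: ``{condition: {modality: recording}}``.

    Condition W uses the scenario model with all condition scalings inert;
    condition A applies them. Each condition is rendered twice from the
    same source trajectories: clean ("ECOG") and degraded ("RS").
    """
    if spec.generator == "mvar":
        out: dict[str, dict[str, MultichannelRecording]] = {}
        for ci, cond in enumerate(("W", "A")):
            rec = gen_mvar(
                spec.model, spec.duration_s, spec.fs, _substream(spec.seed, ci)
            )
            rec = replace(rec, condition=cond, modality="ECOG")
            out[cond] = {"ECOG": rec, "RS": _degrade(spec, rec, ci)}
        return out
    if spec.generator != "nmm":
        raise InvalidParameterError(f"unknown generator {spec.generator!r}")

    model: NeuralMassModel = spec.model
    out = {}
    for ci, cond in enumerate(("W", "A")):
        sources = simulate_nmm(
            model,
            condition=cond,
            duration_s=spec.duration_s,
            fs=spec.fs,
            seed=_substream(spec.seed, ci),
            measurement_noise=False,
        )
        sources = replace(sources, condition=cond)
        # clean modality: sources + white channel noise at the model's alpha_n
        rng = np.random.default_rng(_substream(spec.seed, ci, 1))
        sd_n = np.sqrt(np.exp(model.alpha_n) * spec.fs / 2.0)
        clean = replace(
            sources,
            data=sources.data + rng.standard_normal(sources.data.shape) * sd_n,
            modality="ECOG",
        )
        out[cond] = {"ECOG": clean, "RS": _degrade(spec, sources, ci)}
    return out


def _degrade(spec: ScenarioSpec, sources: MultichannelRecording, ci: int):
    mixed_rms = np.sqrt(np.mean((sources.data @ spec.mixing.T) ** 2))
    noise_sd = mixed_rms / 10 ** (spec.noise_snr_db / 20.0)
    return degrade_to_reconstructed(
        sources,
        spec.mixing,
        noise_sd,
        spec.lowpass_hz,
        seed=_substream(spec.seed, ci, 2),
    )


def anaesthesia_scenario(seed: int = 7) -> ScenarioSpec:
    """Packaged anaesthesia scenario (the study's headline structure).

    Architecture model 1 (parietal→frontal forward, frontal→parietal
    backward). The extrinsic gains are set so both cross-directions carry
    appreciable directed flow in wakefulness (band-averaged DTF of order
    0.1, forward above backward, as in the study's DTF curves); under
    anaesthesia the forward gain is halved (b_fwd = −0.7, exp(−0.7) ≈ 0.50)
    and the inhibitory self-connections of both sources are moderately
    increased (b_self = +0.2).
    """
    model = NeuralMassModel(
        a_fwd=448.0,
        a_bwd=64.0,
        b_fwd=-0.7,
        b_self=np.array([0.2, 0.2]),
        forward_from=0,
    )
    return ScenarioSpec(generator="nmm", model=model, seed=seed)


def null_scenario(seed: int = 7) -> ScenarioSpec:
    """Same generative model with every condition scaling zeroed."""
    spec = anaesthesia_scenario(seed)
    model = replace(spec.model, b_fwd=0.0, b_bwd=0.0, b_self=np.zeros(2))
    return replace(spec, model=model)
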