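# Methods

`dirconn` infers directed coupling between two cortical sources — a
frontal (F) and a parietal (P) region — from two 30 s multichannel
recordings, one per condition (wakefulness W, anaesthesia A), through two
complementary tracks. This note records the models, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Data-driven track: MVAR and the directed transfer function

Each recording is cut into 15 non-overlapping 2 s segments at 1000 Hz.
Per segment an order-p vector autoregression

    x_t = Σ_{j=1..p} A_j x_{t−j} + e_t,   e_t ~ N(0, Σ)

is estimated by solving the multichannel Yule–Walker equations on biased
(1/N) lagged covariances, mean-removed per segment. The default order is
p = 7; `select_order_bic` chooses p by minimising
N·ln det Σ_p + ln(N)·p·k² with ties broken toward smaller p. The
Yule–Walker route (rather than least squares) follows directly from the
moment equations of the AR model; on 2 s × 15-segment data the two
estimators differ negligibly, and the pooled-covariance form lets one
model serve all segments when desired.

The spectral transfer matrix is H(f) = (I − Σ_j A_j e^{−i2πfΔt·j})⁻¹
with Δt = 1/fs, and the normalized directed transfer function

    DTF_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²

measures the inflow fraction j → i; rows sum to 1 and entries lie in
[0, 1]. Analysis grid: 0.5–100 Hz in 0.25 Hz steps; statistics use the
3–40 Hz band.

Condition contrasts: each segment contributes one band-averaged DTF value
per direction; W and A samples (15 vs 15, unpaired) are compared with a
two-sided Wilcoxon rank-sum test (exact enumeration for tiny samples,
tie- and continuity-corrected normal approximation otherwise), and
Benjamini–Hochberg FDR is applied jointly across the whole family of
direction × modality contrasts tested in one call (4 in the standard
design). A per-segment band summary was chosen over per-frequency-bin
testing: it avoids a multiplicity explosion across ~150 bins and matches
a band-level claim about 3–40 Hz modulation. The reported effect sign is
median(A) − median(W).

## Model-based track: two-source neural-mass model of the CSD

Each source is a three-population LFP-style neural mass: spiny stellate
cells (granular layer), pyramidal cells and inhibitory interneurons.
Every synaptic channel is a critically damped second-order kernel,

    v̇ = i,    i̇ = κH·d − 2κi − κ²v,

with κ_e = 250 s⁻¹, H_e = 4 mV for excitatory and κ_i = 62.5 s⁻¹,
H_i = 32 mV for inhibitory channels. Firing rates pass through the
zero-centred sigmoid S(v) = 1/(1+e^{−ρ₁(v−ρ₂)}) − 1/(1+e^{ρ₁ρ₂}) with
ρ₁ = 2, ρ₂ = 1 mV, so the origin is always an equilibrium of the
undriven system. Intrinsic gains default to γ₁…γ₅ = 128, 128, 64, 64, 16
(pyramidal→stellate, stellate→pyramidal, pyramidal→interneuron,
interneuron→pyramidal, interneuron self-inhibition). Ten states per
source (five voltage/current pairs), twenty in total.

Between sources, the forward connection targets the granular layer (the
stellate drive of the receiving source) and the backward connection
targets superficial and deep layers (pyramidal-excitatory and
interneuron-excitatory drives); both originate from the sender's
pyramidal output. The architecture flag selects which source sends
forward: model 1 = parietal→frontal forward with frontal→parietal
backward; model 2 the reverse. Condition effects scale the forward gain,
backward gain and each source's inhibitory self-connection γ₅
multiplicatively by exp(b); b = 0 reproduces wakefulness exactly, so the
W and A predictions coincide when no effect is enabled. The intrinsic
("self") effect was attached to γ₅ — of the intrinsic gains it most
directly controls the source's excitation/inhibition balance, which is
the natural single-parameter reading of an anaesthesia-induced change in
self-inhibition; attaching it to all γ or to the observation gain are
alternatives the data cannot distinguish at two sources.

Observation: y_s = g_obs·(v_pe − v_pi), the pyramidal depolarization.
Innovations drive each source's stellate current equation scaled by
κ_e·H_e·C; their spectra are parameterized as white + 1/f,
g_u(f) = exp(α_u) + exp(β_u)/f, and likewise the channel noise g_n(f).
All spectra are one-sided densities; the fitting grid starts above 0 Hz
because of the 1/f term.

Predictions come from linearization at the fixed point (the origin for
zero exogenous drive; otherwise found by damped Newton with an analytic
Jacobian, falling back to relaxation integration):
T(f) = C(2πif·I − J)⁻¹B and G(f) = T·diag(g_u)·Tᴴ + diag(g_n).
The model-derived DTF applies the DTF normalization to T weighted by the
innovation spectra, DTF_ij = |T_ij|²g_uj / Σ_m |T_im|²g_um — unlike the
MVAR estimate, it uses the estimated (non-white) innovation spectra.

Simulation is Euler–Maruyama at step ≤ 1/(8κ_max) (0.5 ms at the
defaults), white innovations realising the white component of g_u,
substeps averaged into output bins, optional white measurement noise
realising exp(α_n). The 1/f innovation component is a spectral-fit
construct and is not simulated; the default β_u keeps it a small
fraction of the white power so that simulation and linear prediction
agree to within a few percent in band-integrated power.

## Inversion and model selection

Free parameters are log-scalings around the nominal model (extrinsic
gains, per-source γ₅, H, κ, shared observation gain, innovation/noise
spectral parameters) with N(0, 1/16) shrinkage priors, plus the enabled
condition effects b with N(0, 1) priors; a model's disabled parameters
are pinned (excluded). Features are the real and imaginary parts of the
upper-triangular Welch CSD (1 s Hann windows, 50% overlap, averaged over
windows and segments, interpolated to the fitting grid of 1–80 Hz in
1 Hz steps), stacked over conditions and rescaled by the data's RMS;
observation error is i.i.d. Gaussian with scalar log-precision λ under a
broad Gaussian hyperprior anchored on the data variance.

The free energy (Laplace approximation to the log evidence) is maximised
by damped Gauss–Newton ascent: numeric central-difference Jacobians with
step 1e-4·(1+|θ|), ridge damping ×10 whenever a candidate step lowers F,
Newton updates of λ in alternation, stopping when |ΔF| < 0.01 on three
consecutive accepted steps or after the iteration cap. The F trace over
accepted steps is non-decreasing by construction. The residual sum of
squares is floored at n·10⁻²⁴ so noiseless self-generated data cannot
drive the precision to overflow. An unstable candidate (any Jacobian
eigenvalue with nonnegative real part) is treated as a rejected step.

Fixed-effects Bayesian model selection converts free energies into
posterior probabilities p(m) ∝ exp(F_m). The two-stage pipeline first
selects the architecture on condition-W data alone (condition effects
pinned), then inverts all 2⁴ = 16 condition-effect models jointly on W+A
under the winning architecture. The 16-model space covers every on/off
combination of {forward, backward, self-F, self-P}; a 4-model preset
(extrinsic effects only: forward, backward, neither, both) is available
through `build_condition_effect_space` subsets if desired. The full
model's fit warm-starts the other 15 (the free energy is unchanged by
the starting point; only the search path is). The inversion skeleton is
the nominal wakefulness model of the family under study — in this
framework prior expectations of coupling strengths are part of the model
specification, not of the data.

Condition effects are reported as exp(b)·100, i.e. percent of the
wakefulness connection strength.

## Synthetic data: what it emulates, and what it does not

The packaged anaesthesia scenario generates 30 s per condition at
1000 Hz from architecture model 1 with extrinsic gains a_fwd = 448,
a_bwd = 64 — chosen once so that both cross-directions carry appreciable
directed flow in wakefulness (band-averaged DTF ≈ 0.15 forward, ≈ 0.11
backward), as invasive recordings of this pathway show — and condition
effects b_fwd = −0.7 (forward gain halved under anaesthesia) and
b_self = +0.2 on both sources. A null scenario zeroes all effects.

Each condition is rendered in two modalities from the same source
trajectories: a clean ECoG-like observation (white channel noise at the
model's α_n, ≈2% of in-band signal power) and a degraded
"reconstructed source" observation — linear channel mixing (leakage
0.3), additive white noise at 10 dB SNR, and a zero-phase 60 Hz low-pass
(order-5 Butterworth, forward–backward). The degradation is a
deliberately minimal stand-in for EEG source reconstruction: it
reproduces the two salient consequences (instantaneous mixing and
bandwidth loss) but none of the geometry — no leadfields, no
inverse-operator spatial bias, no depth dependence. Passing tests on the
degraded modality therefore show robustness to mixing and band-limited
noise, not fidelity to any particular reconstruction algorithm.

Seed policy: a master seed spawns per-condition and per-modality
substreams by fixed prime offsets, so every dataset is a pure function
of (scenario, seed).

## Preprocessing

For full multichannel arrays the chain is common-average reference →
zero-phase IIR notch (default 50 Hz, Q = 35, forward–backward) →
per-channel ℓ1 trend filtering → optional robust-z artifact masking
(median/MAD, default threshold 8, disabled for synthetic data) →
segmentation. ℓ1 trend filtering minimises ½‖x−t‖² + λ‖D²t‖₁ via a
primal-dual interior-point method on the dual box-constrained QP
(banded Newton systems, duality-gap tolerance 1e-8 relative); λ defaults
to 10× the signal variance per 2 s window since the method itself fixes
no scale. Once analysis is restricted to a two-source pair, the
average reference is deliberately not re-applied — averaging the two
analysis channels would mix the sources under test.

## Problem sizes used by the test suite

Monte-Carlo checks run at the study's native data size (30 s, 15 × 2 s
segments) with: 100 random stable models for the DTF normalization
identity; 20 seeds for zero-coupling, coefficient/DTF recovery, and
forward-effect detection; 200 replicates for the null false-positive
rate; 10 seeds for parameter recovery and for each of the two
model-recovery studies (the 16-model study inverts 160 models in total).
These sizes give conservative binomial margins at the stated thresholds
while keeping the default suite a matter of minutes.

## Known limitations

* Two sources only; no hidden (e.g. thalamic) sources, so reciprocal
  intrinsic/extrinsic explanations can trade off.
* The observation model is diagonal (one gain per source). Instantaneous
  channel mixing — the defining artefact of the degraded modality — is
  therefore outside the model class: when fitting mixed data the
  inversion absorbs the zero-lag cross-power into the least-lagged
  coupling (the single-kernel backward connection), inflating it. The
  condition effects (notably the forward decrease) are recovered with
  the correct sign regardless, but the absolute forward/backward flow
  ordering of the fitted model is not trustworthy on mixed data. This is
  the model-based face of the familiar volume-conduction confound.
* The Welch features are treated as i.i.d. Gaussian with a single scalar
  precision; no frequency- or channel-specific error model.
* Gradients are numeric; a fit with all parameters free costs
  ~2·d model evaluations per iteration (d ≈ 25).
* The MVAR track assumes white innovations and segment-stationarity;
  slow within-condition drifts are only addressed by the detrending
  stage.
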