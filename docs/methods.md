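# Methods

## Generative model

### Neural mass

The source is a canonical microcircuit of four neuronal populations:
excitatory granular (spiny stellate) cells `ss`, superficial pyramidal
cells `sp`, inhibitory interneurons `ii` and deep pyramidal cells `dp`.
Each population k carries a mean postsynaptic potential v_k and current
v̇_k obeying the second-order synaptic kernel

    v̈_k = T_k·u_k − 2·T_k·v̇_k − T_k²·v_k ,

with rate constant T_k (Hz) and presynaptic drive u_k. Firing rate is the
centred sigmoid S(v) = 1/(1+e^{−γv}) − ½, so the resting state is exactly
the origin and the linearisation there is exact; S′(0) = γ/4.

The ten intrinsic connections (signs fixed by the source population):

| connection | from → to | sign | prior mean (Hz) |
|---|---|---|---|
| g1  | ss → ss | − | 800 |
| g2  | sp → ss | − | 600 |
| g3  | ii → ss | − | 1600 |
| g4  | ii → ii | − | 800 |
| g5  | ss → ii | + | 800 |
| g6  | dp → ii | + | 400 |
| g7  | sp → sp | − | 400 |
| g8  | ss → sp | + | 800 |
| g9  | ii → dp | − | 400 |
| g10 | dp → dp | − | 200 |

Afferent input drives the granular population; the observation is a
weighted average of the pyramidal potentials (0.6·sp + 0.4·dp, weights
config-exposed — only the shape of the read-out matters, its sign and
scale cancel in the spectrum). This wiring ships as a configuration table
(`szdcm.cmc.WIRING`); tests depend only on the class labels of the
connections, not on the specific edges.

Remaining parameters: rate constants T₁…T₄ with prior means
(250, 170, 80, 70) Hz; sigmoid slope γ = 0.67; conduction delay d = 1 ms on
between-population edges; input spectrum amplitude a₁ = 1 and power-law
exponent a₂ = 1 with eight discrete-cosine innovations d₁…d₈ (prior mean
1); measurement-noise amplitude b₁ = 1 and exponent b₂ = 1.

All parameters are estimated through log-scaling latents, θ = θ̄·e^φ.
Latent prior variances: 0.0625 for T and g, 0.03125 for γ and d,
0.0078125 for a, b and the innovations. φ = 0 is exactly the prior-mean
model. The latent map is bijective onto positive parameters.

### Spectral forward model

Within an epoch the circuit is assumed to sit in a quasi-steady state
(the adiabatic assumption: fast neuronal states equilibrate within 2 s
while synaptic parameters drift between epochs). The predicted
single-channel spectrum on the 1–40 Hz grid (0.5 Hz spacing, the
resolution of a 2000 ms epoch) is

    S(f) = κ·|H(f)|²·g_u(f) + σ_n·g_n(f)
    g_u(f) = a₁·f^(−a₂)·exp(Σ_k d_k·χ_k(f))
    g_n(f) = b₁·f^(−b₂)

where χ are the first eight non-constant columns of an orthonormal DCT
over the frequency grid (the constant component of log g_u is already
carried by a₁). H(f) is the transfer function of the *delayed* linearised
dynamics, computed from the exact per-frequency resolvent

    H(f) = Cᵀ (i2πf·I − A_self − A_cross·e^{−i2πf·d})⁻¹ B ,

with A_cross the between-population coupling block. A first-order delay
operator (I − D∘J)⁻¹J was evaluated as an alternative and found to
deviate by up to ~45% in power from the exact delayed response at these
coupling strengths; it is retained only as the stability gate (`jacobian`
with `delay_adjust=True`): parameters whose delay-adjusted Jacobian has an
eigenvalue with non-negative real part are rejected during optimisation.

Two fixed scales pin the (arbitrary) physical units: κ is chosen once per
grid so that the prior-mean model predicts unit mean power over the band,
and σ_n = 0.01 places the prior-mean noise floor 20 dB below the signal.
Both are pure unit conventions; the estimable amplitudes a₁ and b₁
modulate around them.

## Inversion

### Variational Laplace (one epoch)

Gauss–Newton ascent on the variational free energy

    F = log p(y | μ) − KL(q ‖ prior) + log p(λ)

with q = N(μ, Q) the Laplace posterior, Q the inverse Gauss–Newton
curvature, and a Gaussian likelihood over the spectral data. The error
covariance is Σ = e^{−λ}·W·V·W: λ is a log-precision hyperparameter
(hyperprior N(0, 16), weakly informative), V an AR(1) correlation across
neighbouring frequencies (coefficient ρ, default 0.5, estimated by
bounded search on F), and W a fixed diagonal heteroscedastic scale — a
Savitzky–Golay-smoothed profile of the observed spectrum, normalised to
geometric mean one. W reflects that the sampling error of a K-taper
spectral estimate scales with the spectrum itself; without it, the 1/f
range of the data lets a few low-frequency bins dominate the fit.

Numerics: prediction gradients by central finite differences on φ (step
10⁻⁴, one-sided at stability boundaries); Levenberg–Marquardt damping
multiplied by 10 on rejection and divided by 4 on acceptance; accepted
steps never decrease F, and a step that destabilises the forward model is
treated as a rejection. Convergence is declared when a near-undamped step
improves F by less than 0.01 nats (a heavily damped micro-step is not
convergence), with a cap of 64 iterations. Inversions are deterministic:
repeated runs on identical inputs are bit-identical.

### Belief updating (across epochs)

Epoch 1 is inverted under the table priors. For epoch i > 1 the prior is
the *prediction step* N(μ_{i−1}, Q_{i−1} + R_i) — exact Gaussian algebra,
no approximation — where R_i = (1+η_i)·R₀ is diagonal and zero at
non-volatile entries, so non-volatile posteriors can only contract.
Processing is strictly causal (a filtering scheme; no backward pass).

R₀ defaults to a **uniform step variance of 0.0625** (SD 0.25 latent
units per 2-s epoch) on every volatile latent. A step scale proportional
to the heterogeneous prior variances was evaluated and rejected: it makes
the endogenous-input walk ~30× slower than the connectivity walks on the
same latent axis, which cannot follow an e-fold input drift over a few
epochs. The uniform scale says: any drifting parameter may move about one
connectivity prior-SD per epoch, before volatility inflation.

The volatility is parameterised as 1+η = e^η̃ with η̃ ~ N(0, 1) shared
across the volatile latents, and estimated once per epoch *before* the
parameter update by maximising a linearised evidence: with the forward
model linearised at μ_{i−1}, the marginal likelihood of the new epoch
under the predicted prior is Gaussian with covariance
J(Q + e^η̃R₀)Jᵀ + Σ_y, so the bounded search over η̃ ∈ [−3, 3] costs ~12
closed-form evaluations. Its curvature at the maximum gives the posterior
spread of η̃ (delta method for η); a flat objective returns the prior with
a wide spread, flagged.

### Temporal-basis (standard) scheme

All epochs inverted at once: each volatile latent's trajectory is
expanded on n_basis (default 8, capped at the number of epochs)
orthonormal DCT columns over epoch index; the joint latent vector holds
the constant latents plus the coefficients. Coefficient priors: the DC
coefficient inherits the table prior variance, higher coefficients get
that variance divided by n_basis. Noise hyperparameters are shared across
epochs (block AR(1) covariance). The Jacobian is assembled by chain rule
from per-epoch finite differences, so its cost is independent of n_basis.
n_basis = 1 reduces exactly to a constant-parameter model.

### Model comparison

Eight models — all subsets of {inhibitory, excitatory, endogenous}
volatility — are inverted on identical data (guarded by a data
fingerprint) and ranked by total free energy relative to the null model;
a margin of 3 nats is flagged as strong evidence (odds ≈ 20:1).

## Preprocessing

Zero-phase 5th-order Butterworth bandpass 0.5–70 Hz, 50 Hz notch
(Q = 30), optional common-average re-reference; division into
non-overlapping 2000 ms epochs (trailing partial epoch dropped);
per-epoch spectra by multitaper (time–bandwidth 3, five tapers; Hermitian
cross-spectral matrices for multichannel data). Epoch length can be
checked with a complex-Gaussian-wavelet criterion (`cgau4`, order
config-exposed): the retained fraction of time–frequency energy captured
by each window's time-averaged spectral profile, with the largest window
retaining ≥ 90% selected. Induced spectra from repeated, onset-aligned
seizures are averaged per epoch index (shorter sequences contribute up to
their length; `n_avg` records the count). Before inversion a sequence is
scaled by a single constant so its mean auto-spectral power is one —
per-epoch normalisation would destroy between-epoch power changes, which
are informative. Sources with only a beamformed/virtual channel are
supported by construction; source localisation itself is out of scope.

## Synthetic data

The simulator integrates the nonlinear CMC by forward Euler (dt = 1/fs,
default fs = 16384 Hz) with the conduction delay realised as a ring
buffer on the between-population firing rates. The endogenous input is
Gaussian noise spectrally shaped to g_u by FFT (exact target spectrum;
power law clamped flat below 0.5 Hz), scaled to keep the sigmoid in its
quasi-linear range — the fluctuation amplitude is an arbitrary unit that
cancels in the observation gain, and the spectral model is a
linearisation, so the generator is kept in the regime the model assumes.
Measurement noise shaped to g_n is added to the pyramidal read-out. The
default rate is set by integrator accuracy: forward Euler's effective
evaluation of the resolvent at iω − ω²·dt/2 inflates high-frequency power,
and dt = 1/16384 closes the simulate→predict loop within 10% mean
relative error over the band (a numba-compiled kernel makes this cheap; a
pure-Python fallback exists). A `linearise` flag replaces the sigmoid by
its slope for oracle comparisons against the linear spectral prediction.

Drift scenarios move one parameter class on the latent axis along a
sigmoid rising 0 → 1 over the recording (steepness 12/duration, so the
endpoints are within 1% of 0 and 1 at the first/last epoch midpoints);
inhibitory and excitatory scenarios drift all three class connections in
common, the endogenous scenario drifts the input amplitude a₁. Step,
constant and user-supplied schedules are available. `multi_seizure`
produces independent noise realisations of one schedule with seeds
derived deterministically from a master seed.

**What the generator emulates and what it does not.** It reproduces the
study conditions — 14 s, one channel, three sigmoid-drift scenarios, and
multi-seizure repetition for induced-spectrum averaging — with the same
circuit that the inversion assumes. Real recordings add model mismatch
(different cytoarchitecture, spatially extended sources, volume
conduction, artefacts, non-Gaussian noise) and seizure-to-seizure
variability in the parameter trajectory itself. Passing recovery tests
therefore demonstrates internal consistency of the estimator under its
own assumptions, not clinical validity.

## Validation harness choices

- Trajectory recovery is scored on averaged induced spectra over ten
  simulated seizures per seed, mirroring the empirical protocol of
  averaging repeated seizures for reliable spectral estimates; a single
  2-s epoch of one realisation carries too much sampling error (K = 5
  tapers → ~45% per-frequency SD) for amplitude-faithful tracking.
- The recovered "endogenous input" trajectory is the band-mean log input
  spectral density relative to baseline, not the a₁ latent alone: under a
  random-walk prior, amplitude, exponent and innovations trade off freely
  inside g_u (spreading a change over many latents is KL-cheaper), so
  only their combined gain is identified.
- Scheme-agreement checks run on noiseless epoch spectra (the spectral
  prediction evaluated along the drift), where the variance-explained
  ceiling is 1 and any disagreement is attributable to the schemes.
- Problem sizes: 7-epoch sequences (14 s), five seeds per scenario,
  200-s oracle simulations, ten-seizure averages — small enough for a
  laptop-scale run of the full battery (~10 min) while leaving all
  qualitative behaviour intact.

## Known limitations

- Single source only; between-region coupling and spatial seizure spread
  are collapsed into the afferent input.
- The spectral likelihood discards phase trajectories; seizures defined
  by waveform morphology (spike-and-wave) are poorly represented.
- The filtering scheme lags fast drifts by design (no smoothing pass);
  the temporal-basis scheme shrinks trajectory amplitude when data are
  weak, because higher basis coefficients carry deliberately tight
  priors.
- The volatility estimate is a point estimate from a linearised evidence;
  it is re-estimated each epoch and not smoothed across epochs.
- Euler integration requires fine steps; at coarse rates (≤ 2048 Hz) the
  simulated spectra are biased upward at high frequencies.
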