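"""Ground-truth seizure-like recordings from the CMC model with drifting
parameters.

The generator integrates the stochastic CMC dynamics (Euler, dt = 1/fs)
while the latent of one parameter class follows a slow schedule — by
default a sigmoid rising from 0 to 1 over the recording, emulating a
gradual loss of excitatory–inhibitory balance around seizure onset.  The
endogenous input is Gaussian noise spectrally shaped to the model's
power-law input spectrum, and measurement noise shaped to the noise
spectrum is added to the pyramidal read-out, so that long constant-
parameter simulations reproduce the linearised spectral prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, rfft, rfftfreq

from .cmc import (CMCParameters, POPULATIONS, ParameterSpace, _EDGES,
                  firing_rate, observation_vector)
from .forward import (EpochSpectrum, FrequencyGrid, NOISE_FLOOR, default_grid,
                      input_spectrum, noise_spectrum, predict_csd, signal_gain,
                      spectral_basis)
from .preprocess import Recording

__all__ = [
    "DriftSchedule",
    "DRIFT_TARGETS",
    "simulate_recording",
    "drift_scenario",
    "multi_seizure",
    "ideal_epoch_spectra",
]

# Latents that carry the drift for each scenario.  Connectivity drifts
# apply the same latent displacement to every connection of the class;
# the endogenous scenario drifts the input amplitude.
DRIFT_TARGETS = {
    "inhibitory": ("g3", "g4", "g9"),
    "excitatory": ("g5", "g6", "g8"),
    "endogenous": ("a1",),
}

SIGMOID_STEEPNESS = 12.0   # units of 1/duration; end values within 1% of 0/1

# RMS scale of the endogenous drive.  The spectral model is a linearisation
# about the fixed point, so the simulated fluctuations are kept small
# enough for the sigmoid to operate in its linear range; the absolute unit
# is arbitrary and cancels in the observation gain.
INPUT_SCALE = 0.1


@dataclass
class DriftSchedule:
    """Slow trajectory of one parameter class on the latent scale."""

    target_class: str
    shape: str = "sigmoid"          # sigmoid | step | constant | custom
    amplitude: float = 1.0
    duration_s: float = 14.0
    step_time_s: float | None = None
    custom: tuple = ()              # (times, values) for shape="custom"

    def __post_init__(self) -> None:
        if self.target_class not in DRIFT_TARGETS:
            raise ValueError(f"unknown drift class {self.target_class!r}")
        if self.shape not in ("sigmoid", "step", "constant", "custom"):
            raise ValueError(f"unknown schedule shape {self.shape!r}")

    def latent_at(self, t):
        """Drift value at time t (seconds), vectorised."""
        t = np.asarray(t, dtype=float)
        if self.shape == "constant":
            return np.zeros_like(t)
        if self.shape == "sigmoid":
            r = SIGMOID_STEEPNESS / self.duration_s
            return self.amplitude / (1.0 + np.exp(-r * (t - self.duration_s / 2)))
        if self.shape == "step":
            t0 = self.step_time_s if self.step_time_s is not None else self.duration_s / 2
            return self.amplitude * (t >= t0).astype(float)
        times, values = self.custom
        return np.interp(t, times, values)

    def epoch_trajectory(self, n_epochs: int, epoch_s: float = 2.0) -> np.ndarray:
        """True latent drift sampled at epoch midpoints."""
        mid = (np.arange(n_epochs) + 0.5) * epoch_s
        return self.latent_at(mid)


def _shaped_noise(spectrum_fn, n: int, fs: float, rng: np.random.Generator,
                  f_lo: float = 0.5) -> np.ndarray:
    """Gaussian noise with one-sided PSD given by ``spectrum_fn(f)``."""
    freqs = rfftfreq(n, 1.0 / fs)
    S = spectrum_fn(np.maximum(freqs, f_lo))  # clamp the power law below f_lo
    S[0] = 0.0                                # no DC power
    white = rng.standard_normal(n)
    return irfft(rfft(white) * np.sqrt(S * fs / 2.0), n=n)


def _band_spectrum_fn(a1, a2, dvec, grid: FrequencyGrid):
    """g_u extended off-grid: power law with innovations interpolated in-band."""
    chi = spectral_basis(grid, np.asarray(dvec).size)
    mod_grid = chi @ np.asarray(dvec, dtype=float)

    def fn(f):
        mod = np.interp(f, grid.values, mod_grid)
        return a1 * np.asarray(f, dtype=float) ** (-a2) * np.exp(mod)

    return fn


def _euler_kernel(n, dt, u, scale, M0s, M0c, Mds, Mdc, T, gamma, n_delay, C4,
                  linear):
    """Forward-Euler integration with delayed between-population coupling.

    With ``linear`` the sigmoid is replaced by its slope at the fixed
    point (γ/4·v): the linearised stochastic dynamics.
    """
    x = np.zeros(8)
    v_out = np.empty(n)
    S_hist = np.zeros((n_delay, 4))
    for i in range(n):
        if linear:
            S = 0.25 * gamma * x[:4]
        else:
            S = 1.0 / (1.0 + np.exp(-gamma * x[:4])) - 0.5
        S_del = S_hist[i % n_delay]
        drive = (M0s @ S + M0c @ S_del + scale[i] * (Mds @ S + Mdc @ S_del))
        drive[0] += u[i]
        S_hist[i % n_delay] = S
        dw = T * drive - 2.0 * T * x[4:] - T * T * x[:4]
        x[:4] += dt * x[4:]
        x[4:] += dt * dw
        vmax = np.abs(x).max()
        if not np.isfinite(vmax) or vmax > 1e6:
            return v_out, i
        v_out[i] = C4 @ x[:4]
    return v_out, -1


try:  # jit-compiled integrator when numba is available
    from numba import njit
    _euler_loop = njit(cache=True)(_euler_kernel)
except ImportError:  # pragma: no cover - exercised only without numba
    _euler_loop = _euler_kernel


def simulate_recording(params0: CMCParameters, schedule: DriftSchedule,
                       fs: float = 16384.0, duration_s: float = 14.0,
                       seed: int = 0, grid: FrequencyGrid | None = None,
                       burn_in_s: float = 2.0,
                       measurement_noise: bool = True,
                       linearise: bool = False) -> Recording:
    """Integrate the stochastic CMC with a drifting parameter class.

    Returns a single-channel :class:`Recording`; deterministic for a fixed
    seed.  A short burn-in settles the initial transient and is discarded.
    """
    if fs < 256:
        raise ValueError("sampling rate must be at least 256 Hz")
    if duration_s < 2.0:
        raise ValueError("duration must cover at least one epoch")
    grid = grid or default_grid()
    space = ParameterSpace()
    rng = np.random.default_rng(seed)
    n_burn = int(round(burn_in_s * fs))
    n = int(round(duration_s * fs)) + n_burn
    dt = 1.0 / fs
    t = np.arange(n) * dt - burn_in_s
    drift = schedule.latent_at(np.clip(t, 0.0, schedule.duration_s))

    # endogenous input shaped to g_u at the baseline parameters, scaled to
    # keep the sigmoid in its quasi-linear range (the unit cancels below)
    u = INPUT_SCALE * _shaped_noise(
        _band_spectrum_fn(params0.a1, params0.a2, params0.dvec, grid), n, fs, rng)
    targets = DRIFT_TARGETS[schedule.target_class]
    if "a1" in targets:
        u = u * np.exp(drift / 2.0)           # amplitude drift of the input

    # coupling split by (constant | drifted class) and (self | delayed
    # between-population): drive = M_self @ S(t) + M_cross @ S(t − d) + u
    g_idx = {int(lbl[1:]) - 1 for lbl in targets if lbl.startswith("g")}
    M0s, M0c, Mds, Mdc = (np.zeros((4, 4)) for _ in range(4))
    for gidx, src, dst, sgn in _EDGES:
        drifted = gidx in g_idx
        selfed = src == dst
        M = (Mds if selfed else Mdc) if drifted else (M0s if selfed else M0c)
        M[dst, src] += sgn * params0.g[gidx]
    scale = np.exp(drift)

    n_delay = max(int(round(params0.delay * 1e-3 * fs)), 1)
    C4 = observation_vector()[:4]
    v_out, bad = _euler_loop(n, dt, u, scale, M0s, M0c, Mds, Mdc,
                             params0.T.astype(float), params0.gamma,
                             n_delay, C4, linearise)
    if bad >= 0:
        raise RuntimeError(f"unstable simulated trajectory at sample {bad} "
                           f"(t = {t[bad]:.3f} s)")

    y = np.sqrt(signal_gain(grid)) / INPUT_SCALE * v_out
    if measurement_noise:
        y = y + _shaped_noise(
            lambda f: NOISE_FLOOR * params0.b1 * np.asarray(f, float) ** (-params0.b2),
            n, fs, rng)
    y = y[n_burn:]
    return Recording(y[None, :], fs, ["source"],
                     [("seizure", 0.0, duration_s)])


def drift_scenario(kind: str, seed: int = 0, fs: float = 16384.0,
                  duration_s: float = 14.0, amplitude: float = 1.0):
    """A 14-s single-channel seizure simulation with sigmoid drift 0 → 1.

    Returns ``(recording, truth)`` where ``truth`` is the drift sampled at
    the midpoints of the 2000 ms epochs, for recovery scoring.
    """
    space = ParameterSpace()
    params0 = space.to_natural(np.zeros(space.dim))
    schedule = DriftSchedule(target_class=kind, shape="sigmoid",
                             amplitude=amplitude, duration_s=duration_s)
    rec = simulate_recording(params0, schedule, fs=fs, duration_s=duration_s,
                             seed=seed)
    truth = schedule.epoch_trajectory(int(duration_s // 2))
    return rec, truth


def multi_seizure(n: int, scenario: str, seed: int = 0, **kwargs) -> list:
    """n independent noise realisations of the same drift schedule.

    Child seeds are derived deterministically from the master seed; all
    recordings share the true trajectory exactly.
    """
    if n < 1:
        raise ValueError("need at least one seizure")
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    return [drift_scenario(scenario, seed=int(s), **kwargs)[0] for s in child_seeds]


def ideal_epoch_spectra(kind: str, n_epochs: int = 7, epoch_s: float = 2.0,
                        grid: FrequencyGrid | None = None,
                        amplitude: float = 1.0,
                        duration_s: float | None = None) -> list:
    """Noiseless per-epoch spectra along a sigmoid drift.

    The linearised spectral prediction is evaluated at the epoch-midpoint
    parameters — the sampling-error-free analogue of a simulated seizure,
    used where the spectral likelihood should be exact.
    """
    grid = grid or default_grid()
    duration_s = duration_s if duration_s is not None else n_epochs * epoch_s
    space = ParameterSpace()
    schedule = DriftSchedule(target_class=kind, shape="sigmoid",
                             amplitude=amplitude, duration_s=duration_s)
    truth = schedule.epoch_trajectory(n_epochs, epoch_s)
    idx = [space.index(lbl) for lbl in DRIFT_TARGETS[kind]]
    out = []
    for val in truth:
        phi = np.zeros(space.dim)
        phi[idx] = val
        out.append(predict_csd(space.to_natural(phi), grid))
    return out, truth
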