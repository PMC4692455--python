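"""Spectral forward model: parameters → predicted complex cross-spectra.

Within an epoch the source is assumed to sit in a quasi-steady state, so
the nonlinear neural mass can be linearised about its fixed point.  The
predicted spectrum is then

    S(f) = κ |H(f)|² g_u(f) + σ_n g_n(f),

with H the transfer function of the delayed linearised dynamics, g_u a
power-law input spectrum modulated by discrete-cosine innovations, g_n a
power-law measurement-noise spectrum, κ a fixed unit-normalisation gain
(the predicted spectrum at prior-mean parameters has unit mean power) and
σ_n a fixed noise-floor scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import dct

from .cmc import (CMCParameters, ParameterSpace, input_vector, jacobian,
                  linear_parts, observation_vector)

__all__ = [
    "FrequencyGrid",
    "EpochSpectrum",
    "default_grid",
    "spectral_basis",
    "input_spectrum",
    "noise_spectrum",
    "transfer_function",
    "predict_csd",
    "signal_gain",
    "NOISE_FLOOR",
]

# Noise-floor scale σ_n: measurement-noise power relative to the
# unit-normalised signal at prior means (b1 = 1 gives a −20 dB floor).
NOISE_FLOOR = 0.01


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing analysis frequencies (Hz), positive throughout."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(np.diff(vals) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if vals[0] <= 0:
            raise ValueError("frequencies must be positive (power law undefined at 0)")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size


def default_grid(fmin: float = 1.0, fmax: float = 40.0, df: float = 0.5) -> FrequencyGrid:
    """1–40 Hz at 0.5 Hz spacing (the resolution of a 2000 ms epoch)."""
    return FrequencyGrid(np.arange(fmin, fmax + df / 2, df))


@dataclass
class EpochSpectrum:
    """Complex (cross-)spectral data for one epoch on a fixed grid.

    ``csd`` has shape (n_freq,) for a single channel or
    (n_freq, n_ch, n_ch) for multichannel data (Hermitian per frequency).
    """

    grid: FrequencyGrid
    csd: np.ndarray
    n_avg: int = 1

    def __post_init__(self) -> None:
        self.csd = np.asarray(self.csd, dtype=complex)
        if self.csd.shape[0] != len(self.grid):
            raise ValueError("csd length does not match frequency grid")

    @property
    def auto(self) -> np.ndarray:
        """Real auto-spectra (diagonal for multichannel data)."""
        if self.csd.ndim == 1:
            return self.csd.real
        return np.einsum("fii->fi", self.csd).real

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.values.tolist(),
            "csd_real": np.real(self.csd).tolist(),
            "csd_imag": np.imag(self.csd).tolist(),
            "n_avg": int(self.n_avg),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpochSpectrum":
        return cls(FrequencyGrid(np.array(d["grid"])),
                   np.array(d["csd_real"]) + 1j * np.array(d["csd_imag"]),
                   n_avg=d.get("n_avg", 1))


def spectral_basis(grid: FrequencyGrid, n_basis: int = 8) -> np.ndarray:
    """Orthonormal discrete-cosine basis over the grid, DC column excluded.

    The constant component of the log input spectrum is already carried by
    the amplitude a1, so the innovations span the first ``n_basis``
    non-constant cosines.  Columns satisfy χᵀχ = I.
    """
    n = len(grid)
    if n_basis >= n:
        raise ValueError("need more grid points than basis functions")
    eye = np.eye(n)
    full = dct(eye, axis=0, norm="ortho")  # rows: cosine functions
    return full[1:n_basis + 1].T  # (n, n_basis)


def input_spectrum(a1: float, a2: float, dvec: np.ndarray,
                   grid: FrequencyGrid) -> np.ndarray:
    """Endogenous input spectrum g_u(f) = a1 f^(−a2) exp(Σ_k d_k χ_k(f))."""
    if a1 <= 0:
        raise ValueError("input amplitude a1 must be positive")
    f = grid.values
    dvec = np.asarray(dvec, dtype=float)
    chi = spectral_basis(grid, dvec.size)
    return a1 * f ** (-a2) * np.exp(chi @ dvec)


def noise_spectrum(b1: float, b2: float, grid: FrequencyGrid) -> np.ndarray:
    """Measurement-noise spectrum g_n(f) = b1 f^(−b2)."""
    if b1 <= 0:
        raise ValueError("noise amplitude b1 must be positive")
    return b1 * grid.values ** (-b2)


class UnstableModelError(ValueError):
    """Raised when the linearised model has an unstable eigenvalue."""


def transfer_function(params: CMCParameters, grid: FrequencyGrid,
                      observation_weights: dict | None = None) -> np.ndarray:
    """Transfer function of the delayed linearised model.

    H(f) = Cᵀ (i2πf I − A_self − A_cross e^{−i2πf d})⁻¹ B, with the
    between-population coupling A_cross subject to the conduction delay d.
    Stability is gated on the delay-adjusted Jacobian: an eigenvalue with
    non-negative real part raises :class:`UnstableModelError`.
    """
    lam = np.linalg.eigvals(jacobian(params))
    if lam.real.max() >= 0:
        bad = lam[np.argmax(lam.real)]
        raise UnstableModelError(
            f"unstable linearised model: eigenvalue {bad:.3f} has non-negative real part")
    A, Ac = linear_parts(params)
    B = input_vector(params)
    C = observation_vector(observation_weights)
    omega = 2j * np.pi * grid.values
    d_sec = params.delay * 1e-3
    # batched per-frequency resolvent of the delayed system
    M = (omega[:, None, None] * np.eye(8)[None] - A[None]
         - Ac[None] * np.exp(-omega * d_sec)[:, None, None])
    rhs = np.broadcast_to(B.astype(complex)[:, None], (len(grid), 8, 1)).copy()
    return np.linalg.solve(M, rhs)[:, :, 0] @ C


_GAIN_CACHE: dict = {}


def signal_gain(grid: FrequencyGrid) -> float:
    """Unit-normalisation gain κ.

    Chosen once per grid so that the predicted auto-spectrum at the
    prior-mean parameters has mean power 1 over the analysis band; this
    fixes the (otherwise arbitrary) physical units of the read-out.
    """
    key = (round(grid.values[0], 9), round(grid.values[-1], 9), len(grid))
    if key not in _GAIN_CACHE:
        space = ParameterSpace()
        p0 = space.to_natural(np.zeros(space.dim))
        H = transfer_function(p0, grid)
        gu = input_spectrum(p0.a1, p0.a2, p0.dvec, grid)
        _GAIN_CACHE[key] = 1.0 / float(np.mean(np.abs(H) ** 2 * gu))
    return _GAIN_CACHE[key]


def predict_csd(params: CMCParameters, grid: FrequencyGrid,
                observation_weights: dict | None = None,
                noise_floor: float = NOISE_FLOOR) -> EpochSpectrum:
    """Predicted single-channel spectrum S(f) = κ|H|²g_u + σ_n g_n."""
    H = transfer_function(params, grid, observation_weights)
    gu = input_spectrum(params.a1, params.a2, params.dvec, grid)
    gn = noise_spectrum(params.b1, params.b2, grid)
    s = signal_gain(grid) * np.abs(H) ** 2 * gu + noise_floor * gn
    return EpochSpectrum(grid, s.astype(complex))
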