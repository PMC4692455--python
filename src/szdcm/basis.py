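"""Standard joint inversion with a discrete-cosine temporal basis.

Instead of filtering epoch by epoch, all epochs are inverted at once:
each volatile parameter's latent trajectory is expanded on ``n_basis``
orthonormal cosine functions of epoch index, and a single variational-
Laplace inversion estimates the constant latents plus the expansion
coefficients.  The likelihood is the product over epochs of the spectral
likelihood with epoch-specific parameters from the expansion; noise
hyperparameters are shared across epochs.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct

from .cmc import GaussianDensity, ParameterSpace, build_prior
from .forward import predict_csd
from .laplace import _ArNoise, _fd_jacobian, gauss_newton_vl, spectral_weights
from .updating import Trajectory, normalise_sequence, sequence_fingerprint

__all__ = ["dct_matrix", "invert_joint", "BasisExpansion"]


def dct_matrix(n_epochs: int, n_basis: int) -> np.ndarray:
    """Orthonormal discrete-cosine basis over epochs, (n_epochs, n_basis).

    Columns satisfy χᵀχ = I; the first column is the constant
    1/√n_epochs.
    """
    if n_basis > n_epochs:
        raise ValueError(
            f"cannot expand {n_epochs} epochs on {n_basis} basis functions")
    full = dct(np.eye(n_epochs), axis=0, norm="ortho")   # rows = cosines
    return full[:n_basis].T


class BasisExpansion:
    """Layout of the joint latent vector for the temporal-basis scheme.

    Joint vector = [constant latents] ++ [n_basis coefficients per
    volatile latent]; per-epoch latents are recovered through the linear
    maps ``epoch_map(i)``.
    """

    def __init__(self, volatile_spec, n_epochs: int, n_basis: int = 8,
                 space: ParameterSpace | None = None):
        self.space = space or ParameterSpace()
        self.volatile_spec = tuple(sorted(volatile_spec))
        self.n_epochs = n_epochs
        self.n_basis = n_basis
        self.chi = dct_matrix(n_epochs, n_basis)
        mask = self.space.volatile_mask(self.volatile_spec)
        self.vol_idx = np.where(mask)[0]
        self.const_idx = np.where(~mask)[0]
        self.dim = self.const_idx.size + self.vol_idx.size * n_basis
        self._maps = [self._epoch_map(i) for i in range(n_epochs)]

    def _epoch_map(self, i: int) -> np.ndarray:
        """T_i with φ_epoch_i = T_i @ φ_joint."""
        T = np.zeros((self.space.dim, self.dim))
        for col, j in enumerate(self.const_idx):
            T[j, col] = 1.0
        off = self.const_idx.size
        for v, j in enumerate(self.vol_idx):
            T[j, off + v * self.n_basis:off + (v + 1) * self.n_basis] = self.chi[i]
        return T

    def epoch_map(self, i: int) -> np.ndarray:
        return self._maps[i]

    def prior(self) -> GaussianDensity:
        """Joint prior: constants inherit the table prior; the DC
        coefficient of each volatile latent inherits it too, higher
        coefficients are zero-mean with that variance divided by n_basis
        (keeping total trajectory variance commensurate)."""
        var = np.empty(self.dim)
        var[:self.const_idx.size] = self.space.prior_vars[self.const_idx]
        off = self.const_idx.size
        for v, j in enumerate(self.vol_idx):
            pv = self.space.prior_vars[j]
            var[off + v * self.n_basis] = pv
            var[off + v * self.n_basis + 1:off + (v + 1) * self.n_basis] = (
                pv / self.n_basis)
        return GaussianDensity(np.zeros(self.dim), np.diag(var))

    def epoch_posterior(self, joint: GaussianDensity, i: int) -> GaussianDensity:
        T = self._maps[i]
        cov = T @ joint.cov @ T.T
        return GaussianDensity(T @ joint.mean, 0.5 * (cov + cov.T))


def invert_joint(epochs, volatile_spec=(), n_basis: int = 8,
                 space: ParameterSpace | None = None, normalise: bool = True,
                 max_iter: int = 64, f_tol: float = 0.01,
                 heteroscedastic: bool = True) -> Trajectory:
    """Joint variational-Laplace inversion of all epochs.

    With ``n_basis = 1`` this reduces exactly to a constant-parameter
    model over the whole sequence.  Requires at least ``n_basis`` epochs.
    """
    epochs = list(epochs)
    fingerprint = sequence_fingerprint(epochs)
    if normalise:
        epochs = normalise_sequence(epochs)
    n_epochs = len(epochs)
    space = space or ParameterSpace()
    exp = BasisExpansion(volatile_spec, n_epochs, n_basis, space)
    grid = epochs[0].grid
    n_f = len(grid)

    def epoch_predict(phi):
        return predict_csd(space.to_natural(phi), grid).csd.real

    def predict_fn(phi_joint):
        return np.concatenate([
            epoch_predict(exp.epoch_map(i) @ phi_joint) for i in range(n_epochs)])

    def jacobian_fn(phi_joint, h0):
        # chain rule: finite differences on the 28 per-epoch latents,
        # mapped to the joint coefficients — FD cost independent of n_basis
        blocks = []
        for i in range(n_epochs):
            T = exp.epoch_map(i)
            phi_i = T @ phi_joint
            J_i = _fd_jacobian(epoch_predict, phi_i, h0[i * n_f:(i + 1) * n_f])
            blocks.append(J_i @ T)
        return np.vstack(blocks)

    y = np.concatenate([ep.csd.real for ep in epochs])
    weights = None
    if heteroscedastic:
        weights = np.concatenate([spectral_weights(ep.csd.real) for ep in epochs])
    noise = _ArNoise(n_f, n_blocks=n_epochs)
    res = gauss_newton_vl(y, predict_fn, exp.prior(), noise=noise,
                          max_iter=max_iter, f_tol=f_tol,
                          weights=weights, jacobian_fn=jacobian_fn)

    posteriors = [exp.epoch_posterior(res.posterior, i) for i in range(n_epochs)]
    from .forward import EpochSpectrum
    predicted = [EpochSpectrum(grid, epoch_predict(p.mean).astype(complex))
                 for p in posteriors]
    return Trajectory(posteriors=posteriors,
                      free_energies=np.array([res.free_energy]),
                      volatility=[None] * n_epochs,
                      predicted=predicted, observed=epochs,
                      scheme="standard", model_spec=tuple(sorted(volatile_spec)),
                      space=space, data_fingerprint=fingerprint,
                      f_traces=[list(res.f_trace)])
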