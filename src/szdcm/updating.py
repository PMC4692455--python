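"""Bayesian belief updating of slowly varying synaptic parameters.

Volatile parameters perform a random walk between epochs,

    θ_i = θ_{i−1} + ε_{i−1},   ε ~ N(0, R_i),   R_i = (1 + η_i) R_0,

so the prior for epoch i is the previous posterior with its covariance
inflated: N(μ_{i−1}, Q_{i−1} + R_i) (the *prediction* step).  Inverting
epoch i under that prior is the *update* step.  Entries of R_0 are zero
for non-volatile parameters, whose posteriors therefore converge.  The
volatility η_i is estimated afresh in each epoch by maximising a
linearised approximation to the epoch's free energy — a bounded scalar
search costing a handful of function evaluations.

Processing is strictly causal: epoch i sees only data from epochs 1..i
(a filtering, not a smoothing, scheme).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cmc import GaussianDensity, ParameterSpace, build_prior
from .forward import EpochSpectrum, UnstableModelError, predict_csd
from .laplace import (HyperParameters, InversionResult, _ArNoise,
                      _fd_jacobian, invert_epoch, spectral_weights,
                      variance_explained)

__all__ = [
    "RandomWalkSpec",
    "VolatilityState",
    "Trajectory",
    "predict_prior",
    "estimate_volatility",
    "run_updating",
    "normalise_sequence",
]

logger = logging.getLogger(__name__)

# Random-walk variance of a volatile latent per 2-s epoch (latent scale,
# i.e. log-scaling units).  A step SD of 0.25 lets a parameter move about
# one connectivity prior-SD per epoch, enough to follow seizure-onset
# drifts of an e-fold over a few epochs; the volatility estimate shrinks
# or inflates it per epoch.
R0_STEP_VAR = 0.0625

ETA_TILDE_BOUNDS = (-3.0, 3.0)   # search range for η̃ = log(1 + η)


@dataclass
class RandomWalkSpec:
    """Random-walk prior on the volatile latents.

    ``R0`` is diagonal with zeros at non-volatile entries; the volatility
    η scales it as R_i = (1 + η_i) R_0 with 1 + η = exp(η̃) and
    η̃ ~ N(eta_mean, eta_var).
    """

    R0: np.ndarray
    eta_mean: float = 0.0
    eta_var: float = 1.0

    def __post_init__(self) -> None:
        self.R0 = np.asarray(self.R0, dtype=float)
        if self.R0.ndim == 1:
            self.R0 = np.diag(self.R0)
        if np.any(np.diag(self.R0) < 0):
            raise ValueError("R0 diagonal entries must be non-negative")

    @classmethod
    def from_classes(cls, volatile_spec, space: ParameterSpace | None = None,
                     step_var: float = R0_STEP_VAR) -> "RandomWalkSpec":
        """Uniform per-epoch step variance on the volatile latents, else 0.

        The step size is uniform on the log-scaling axis rather than
        proportional to the (heterogeneous) prior variances: a drifting
        input amplitude must be able to move as fast as a drifting
        connection strength.
        """
        space = space or ParameterSpace()
        diag = np.zeros(space.dim)
        diag[space.class_indices(volatile_spec)] = step_var
        return cls(np.diag(diag))

    def realised(self, eta: float) -> np.ndarray:
        """R_i = (1 + η) R_0."""
        if 1.0 + eta <= 0:
            raise ValueError("1 + η must be positive")
        return (1.0 + eta) * self.R0


@dataclass
class VolatilityState:
    """Per-epoch volatility estimate and the realised random-walk covariance."""

    eta: float
    eta_sd: float
    R_i: np.ndarray
    flat: bool = False   # True when the epoch was uninformative about η


def predict_prior(posterior_prev: GaussianDensity, R_i: np.ndarray) -> GaussianDensity:
    """Prediction step: N(μ_{i−1}, Q_{i−1} + R_i), exact algebra."""
    R_i = np.asarray(R_i, dtype=float)
    if R_i.ndim == 1:
        R_i = np.diag(R_i)
    if R_i.shape != posterior_prev.cov.shape:
        raise ValueError("R_i dimensions do not match the posterior")
    if np.any(np.diag(R_i) < 0):
        raise ValueError("R_i must have a non-negative diagonal")
    return GaussianDensity(posterior_prev.mean.copy(), posterior_prev.cov + R_i)


def estimate_volatility(posterior_prev: GaussianDensity, data_i: EpochSpectrum,
                        spec: RandomWalkSpec, predict_fn=None,
                        hyper: HyperParameters | None = None) -> VolatilityState:
    """Optimise η for the coming epoch by maximising a linearised evidence.

    The forward model is linearised at the previous posterior mean; the
    marginal likelihood of the new epoch under the predicted prior
    N(μ, Q + e^η̃ R_0) is then Gaussian with covariance
    J (Q + e^η̃ R_0) Jᵀ + Σ_y and has a closed form, so the bounded search
    over η̃ costs only a few cheap evaluations.  The posterior spread of η̃
    comes from the curvature of the objective at its maximum.
    """
    if predict_fn is None:
        space = ParameterSpace()
        grid = data_i.grid

        def predict_fn(phi):
            return predict_csd(space.to_natural(phi), grid).csd.real

    hyper = hyper or HyperParameters()
    y = data_i.csd.real
    w = spectral_weights(y)
    raw_predict = predict_fn
    predict_fn = lambda phi: raw_predict(phi) / w  # noqa: E731
    y = y / w
    mu, Q = posterior_prev.mean, posterior_prev.cov
    try:
        h = predict_fn(mu)
    except UnstableModelError:
        # no usable linearisation: fall back to the prior volatility
        return VolatilityState(eta=float(np.expm1(spec.eta_mean)),
                               eta_sd=float(np.sqrt(spec.eta_var)),
                               R_i=spec.realised(float(np.expm1(spec.eta_mean))),
                               flat=True)
    J = _fd_jacobian(predict_fn, mu, h)
    e = y - h
    noise = _ArNoise(y.size)
    Vinv_scaled = np.exp(hyper.log_precision) * noise._matrices(hyper.ar_coefficient)[0]
    Sigma_y = np.linalg.inv(Vinv_scaled)

    def log_evidence(eta_tilde: float) -> float:
        P = Q + np.exp(eta_tilde) * spec.R0
        S = J @ P @ J.T + Sigma_y
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf
        alpha = np.linalg.solve(S, e)
        return float(-0.5 * (e @ alpha + logdet)
                     - 0.5 * (eta_tilde - spec.eta_mean) ** 2 / spec.eta_var)

    res = minimize_scalar(lambda t: -log_evidence(t), bounds=ETA_TILDE_BOUNDS,
                          method="bounded", options={"maxiter": 12, "xatol": 0.02})
    eta_tilde = float(res.x)
    # curvature → approximate posterior spread of η̃
    d = 0.05
    f0, fp, fm = (log_evidence(eta_tilde), log_evidence(eta_tilde + d),
                  log_evidence(eta_tilde - d))
    curv = -(fp - 2 * f0 + fm) / d ** 2
    flat = not np.isfinite(curv) or curv <= 1e-6
    if flat:
        eta_tilde = spec.eta_mean
        sd_tilde = float(np.sqrt(spec.eta_var))
    else:
        sd_tilde = float(1.0 / np.sqrt(curv))
    eta = float(np.expm1(eta_tilde))
    # delta-method spread on η = e^η̃ − 1
    return VolatilityState(eta=eta, eta_sd=float(np.exp(eta_tilde) * sd_tilde),
                           R_i=spec.realised(eta), flat=flat)


@dataclass
class Trajectory:
    """Per-epoch posteriors and diagnostics from a sequential inversion."""

    posteriors: list                      # GaussianDensity per epoch
    free_energies: np.ndarray             # F_i per epoch (joint F in epoch 0
                                          # for the temporal-basis scheme)
    volatility: list                      # VolatilityState or None per epoch
    predicted: list                       # EpochSpectrum per epoch
    observed: list                        # EpochSpectrum per epoch (normalised)
    scheme: str = "updating"
    model_spec: tuple = ()
    space: ParameterSpace = field(default_factory=ParameterSpace)
    data_fingerprint: str = ""
    f_traces: list = field(default_factory=list)   # accepted-F trace per inversion

    @property
    def n_epochs(self) -> int:
        return len(self.posteriors)

    @property
    def total_free_energy(self) -> float:
        return float(np.sum(self.free_energies))

    def latent_means(self) -> np.ndarray:
        """(n_epochs, n_latents) posterior means."""
        return np.array([p.mean for p in self.posteriors])

    def latent_sds(self) -> np.ndarray:
        return np.array([p.sd() for p in self.posteriors])

    def class_trajectory(self, cls: str, targets=None):
        """Per-epoch posterior mean and SD of a class summary latent.

        Connectivity classes are summarised by the average log-scaling
        latent of their connections (the truth drifts them in common).
        The endogenous class is summarised by the band-mean log input
        spectral density relative to baseline — the effective afferent
        input gain — since amplitude, exponent and innovations trade off
        freely inside the input spectrum.  ``targets`` overrides the
        summarised labels with a plain latent average.
        """
        from .cmc import VOLATILE_CLASSES
        if targets is None and cls == "endogenous":
            return self._input_gain_trajectory()
        labels = targets if targets is not None else VOLATILE_CLASSES[cls]
        idx = np.array([self.space.index(l) for l in labels])
        w = np.zeros(self.space.dim)
        w[idx] = 1.0 / idx.size
        mean = np.array([p.mean @ w for p in self.posteriors])
        sd = np.array([np.sqrt(w @ p.cov @ w) for p in self.posteriors])
        return mean, sd

    def _input_gain_trajectory(self):
        """Band-mean log input spectrum relative to the prior mean.

        mean_f log g_u = φ_a1 − a2(φ)·mean_f log f + mean_f(χ d); the SD
        follows by linear (delta-method) propagation of the posterior.
        """
        from .forward import spectral_basis
        grid = self.observed[0].grid if self.observed else self.predicted[0].grid
        mlf = float(np.mean(np.log(grid.values)))
        chi_mean = spectral_basis(grid, 8).mean(axis=0)
        ia1, ia2 = self.space.index("a1"), self.space.index("a2")
        idvec = [self.space.index(f"d{k}") for k in range(1, 9)]
        means, sds = [], []
        for p in self.posteriors:
            a2 = np.exp(p.mean[ia2])      # prior mean of a2 is 1
            dvec = np.exp(p.mean[idvec])
            val = p.mean[ia1] - (a2 - 1.0) * mlf + chi_mean @ (dvec - 1.0)
            grad = np.zeros(self.space.dim)
            grad[ia1] = 1.0
            grad[ia2] = -a2 * mlf
            grad[idvec] = chi_mean * dvec
            means.append(val)
            sds.append(np.sqrt(grad @ p.cov @ grad))
        return np.array(means), np.array(sds)

    def variance_explained(self) -> float:
        return variance_explained(self.observed, self.predicted)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.posteriors):
            sd = p.sd()
            for j, lbl in enumerate(self.space.labels):
                rows.append({"epoch": i, "parameter": lbl,
                             "posterior_mean": p.mean[j], "posterior_sd": sd[j]})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        d = {
            "scheme": self.scheme,
            "model_spec": list(self.model_spec),
            "data_fingerprint": self.data_fingerprint,
            "free_energies": np.asarray(self.free_energies).tolist(),
            "eta": [None if v is None else v.eta for v in self.volatility],
            "eta_sd": [None if v is None else v.eta_sd for v in self.volatility],
            "posterior_means": [p.mean.tolist() for p in self.posteriors],
            "posterior_covs": [p.cov.tolist() for p in self.posteriors],
            "predicted": [s.to_dict() for s in self.predicted],
            "observed": [s.to_dict() for s in self.observed],
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "Trajectory":
        d = json.loads(Path(path).read_text())
        post = [GaussianDensity(np.array(m), np.array(c))
                for m, c in zip(d["posterior_means"], d["posterior_covs"])]
        vol = [None if e is None else VolatilityState(e, s, np.zeros((len(post[0].mean),) * 2))
               for e, s in zip(d["eta"], d["eta_sd"])]
        return cls(posteriors=post,
                   free_energies=np.array(d["free_energies"]),
                   volatility=vol,
                   predicted=[EpochSpectrum.from_dict(s) for s in d["predicted"]],
                   observed=[EpochSpectrum.from_dict(s) for s in d["observed"]],
                   scheme=d["scheme"], model_spec=tuple(d["model_spec"]),
                   data_fingerprint=d.get("data_fingerprint", ""))


def sequence_fingerprint(epochs) -> str:
    """Hash of the spectral data, used to guard model comparisons."""
    import hashlib
    h = hashlib.sha256()
    for ep in epochs:
        h.update(np.ascontiguousarray(ep.csd).tobytes())
        h.update(np.ascontiguousarray(ep.grid.values).tobytes())
    return h.hexdigest()[:16]


def normalise_sequence(epochs) -> list:
    """Scale a sequence so the mean auto-spectral power over epochs is 1.

    One common scale for the whole sequence (between-epoch power changes
    are informative and must be preserved).
    """
    scale = float(np.mean([np.mean(ep.auto) for ep in epochs]))
    if scale <= 0:
        raise ValueError("cannot normalise a sequence with non-positive power")
    return [EpochSpectrum(ep.grid, ep.csd / scale, n_avg=ep.n_avg) for ep in epochs]


def run_updating(epochs, volatile_spec=(), spec: RandomWalkSpec | None = None,
                 space: ParameterSpace | None = None, normalise: bool = True,
                 estimate_eta: bool = True, max_iter: int = 64,
                 f_tol: float = 0.01) -> Trajectory:
    """Recursive prediction/update over a sequence of epoch spectra.

    Epoch 1 is inverted under the table priors; each later epoch under the
    prediction-step prior derived from the previous posterior.  Returns the
    full trajectory of posteriors, free energies and volatility estimates.
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("need at least one epoch")
    space = space or ParameterSpace()
    spec = spec or RandomWalkSpec.from_classes(volatile_spec, space)
    fingerprint = sequence_fingerprint(epochs)
    if normalise:
        epochs = normalise_sequence(epochs)
    grid = epochs[0].grid

    def predict_fn(phi):
        return predict_csd(space.to_natural(phi), grid).csd.real

    prior = build_prior(volatile_spec, space)
    posteriors, Fs, vols, preds, traces = [], [], [], [], []
    hyper = None
    for i, data in enumerate(epochs):
        if i == 0:
            vol = None
            prior_i = prior
        else:
            if estimate_eta:
                vol = estimate_volatility(posteriors[-1], data, spec,
                                          predict_fn=predict_fn, hyper=hyper)
                R_i = vol.R_i
            else:
                vol = VolatilityState(eta=0.0, eta_sd=0.0, R_i=spec.R0)
                R_i = spec.R0
            prior_i = predict_prior(posteriors[-1], R_i)
        res = invert_epoch(data, prior_i, predict_fn=predict_fn,
                           hyperprior=hyper, max_iter=max_iter, f_tol=f_tol)
        if not res.converged:
            logger.warning("epoch %d: inversion flagged non-converged", i)
        posteriors.append(res.posterior)
        Fs.append(res.free_energy)
        vols.append(vol)
        preds.append(res.predicted)
        traces.append(list(res.f_trace))
        hyper = res.hyper
        logger.info("epoch %d: F=%.2f, iters=%d, η=%s", i, res.free_energy,
                    res.n_iterations, "-" if vol is None else f"{vol.eta:.2f}")
    return Trajectory(posteriors=posteriors, free_energies=np.array(Fs),
                      volatility=vols, predicted=preds, observed=epochs,
                      scheme="updating", model_spec=tuple(sorted(volatile_spec)),
                      space=space, data_fingerprint=fingerprint,
                      f_traces=traces)
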