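"""Canonical-microcircuit (CMC) neural mass model of a cortical source.

The model comprises four neuronal subpopulations — excitatory granular
(spiny stellate) cells ``ss``, superficial pyramidal cells ``sp``,
inhibitory interneurons ``ii`` and deep pyramidal cells ``dp`` — coupled by
ten intrinsic connections.  Each population obeys a second-order synaptic
convolution

    v̈_k = T_k u_k − 2 T_k v̇_k − T_k² v_k,

where ``T_k`` is the population rate constant (Hz) and ``u_k`` the
g-weighted sum of presynaptic firing rates.  Firing rate is a centred
sigmoid of membrane potential, so the resting state sits exactly at the
origin and linearisation there is exact.  Afferent input drives the
granular population; the observed signal is a weighted average of the
superficial and deep pyramidal potentials.

Parameters live on a log-scaling latent axis: θ_j = θ̄_j · exp(φ_j), with
θ̄ the prior means.  Priors over φ are zero-mean Gaussians with diagonal
covariance (see :func:`build_prior`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import root

__all__ = [
    "POPULATIONS",
    "WIRING",
    "VOLATILE_CLASSES",
    "PARAM_LABELS",
    "CMCParameters",
    "ParameterSpace",
    "GaussianDensity",
    "build_prior",
    "firing_rate",
    "flow",
    "equilibrium",
    "jacobian",
]

POPULATIONS = ("ss", "sp", "ii", "dp")

# Intrinsic wiring: (connection label, source pop, target pop, sign).
# Sign −1 marks connections arising from inhibitory sources or recurrent
# self-inhibition (gain normalisation); +1 marks excitatory projections.
WIRING = (
    ("g1", "ss", "ss", -1),
    ("g2", "sp", "ss", -1),
    ("g3", "ii", "ss", -1),
    ("g4", "ii", "ii", -1),
    ("g5", "ss", "ii", +1),
    ("g6", "dp", "ii", +1),
    ("g7", "sp", "sp", -1),
    ("g8", "ss", "sp", +1),
    ("g9", "ii", "dp", -1),
    ("g10", "dp", "dp", -1),
)

# Parameter classes that may fluctuate from epoch to epoch.
VOLATILE_CLASSES = {
    "inhibitory": ("g3", "g4", "g9"),
    "excitatory": ("g5", "g6", "g8"),
    "endogenous": ("a1", "a2", "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8"),
}

PARAM_LABELS = (
    "T1", "T2", "T3", "T4",
    "g1", "g2", "g3", "g4", "g5", "g6", "g7", "g8", "g9", "g10",
    "gamma", "delay",
    "a1", "a2", "b1", "b2",
    "d1", "d2", "d3", "d4", "d5", "d6", "d7", "d8",
)

# Prior means in natural units (rate constants and connection strengths in
# Hz, delay in ms, spectral amplitudes/exponents dimensionless).
_PRIOR_MEANS = {
    "T1": 250.0, "T2": 170.0, "T3": 80.0, "T4": 70.0,
    "g1": 800.0, "g2": 600.0, "g3": 1600.0, "g4": 800.0, "g5": 800.0,
    "g6": 400.0, "g7": 400.0, "g8": 800.0, "g9": 400.0, "g10": 200.0,
    "gamma": 0.67, "delay": 1.0,
    "a1": 1.0, "a2": 1.0, "b1": 1.0, "b2": 1.0,
    **{f"d{i}": 1.0 for i in range(1, 9)},
}

# Prior variances on the log-scaling latents.
_PRIOR_VARS = {
    **{f"T{i}": 0.0625 for i in range(1, 5)},
    **{f"g{i}": 0.0625 for i in range(1, 11)},
    "gamma": 0.03125, "delay": 0.03125,
    "a1": 0.0078125, "a2": 0.0078125, "b1": 0.0078125, "b2": 0.0078125,
    **{f"d{i}": 0.0078125 for i in range(1, 9)},
}

# Default observation weights on the pyramidal potentials.
OBSERVATION_WEIGHTS = {"sp": 0.6, "dp": 0.4}


@dataclass
class CMCParameters:
    """Model parameters in natural units."""

    T: np.ndarray            # (4,) rate constants, Hz
    g: np.ndarray            # (10,) connection strengths, Hz
    gamma: float             # sigmoid slope
    delay: float             # intrinsic conduction delay, ms
    a1: float                # input spectral amplitude
    a2: float                # input power-law exponent
    b1: float                # noise spectral amplitude
    b2: float                # noise power-law exponent
    dvec: np.ndarray         # (8,) spectral innovation coefficients

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.dvec = np.asarray(self.dvec, dtype=float)
        if self.T.shape != (4,) or self.g.shape != (10,):
            raise ValueError("T must have 4 entries and g 10 entries")
        if self.dvec.shape != (8,):
            raise ValueError("dvec must have 8 entries")
        if np.any(self.T <= 0) or np.any(self.g <= 0):
            raise ValueError("rate constants and connection strengths must be positive")
        if self.gamma <= 0 or self.delay < 0 or self.a1 <= 0 or self.b1 <= 0:
            raise ValueError("gamma, a1, b1 must be positive and delay non-negative")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([
            self.T, self.g,
            [self.gamma, self.delay, self.a1, self.a2, self.b1, self.b2],
            self.dvec,
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "CMCParameters":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_LABELS),):
            raise ValueError(f"expected vector of length {len(PARAM_LABELS)}")
        return cls(T=vec[:4], g=vec[4:14], gamma=vec[14], delay=vec[15],
                   a1=vec[16], a2=vec[17], b1=vec[18], b2=vec[19], dvec=vec[20:28])


@dataclass
class GaussianDensity:
    """Gaussian density over latent parameters (prior or posterior)."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.size
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape inconsistent with mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")

    @property
    def dim(self) -> int:
        return self.mean.size

    def sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def copy(self) -> "GaussianDensity":
        return GaussianDensity(self.mean.copy(), self.cov.copy())


@dataclass
class ParameterSpace:
    """Bijective log-scaling map between latents φ and natural parameters.

    φ = 0 corresponds exactly to the prior means; θ_j = θ̄_j exp(φ_j).
    """

    labels: tuple = PARAM_LABELS
    prior_means: np.ndarray = field(
        default_factory=lambda: np.array([_PRIOR_MEANS[k] for k in PARAM_LABELS]))
    prior_vars: np.ndarray = field(
        default_factory=lambda: np.array([_PRIOR_VARS[k] for k in PARAM_LABELS]))

    @property
    def dim(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def class_indices(self, classes) -> np.ndarray:
        """Latent indices belonging to the given volatile classes."""
        idx = []
        for c in classes:
            if c not in VOLATILE_CLASSES:
                raise ValueError(
                    f"unknown parameter class {c!r}; expected one of "
                    f"{sorted(VOLATILE_CLASSES)}")
            idx.extend(self.index(lbl) for lbl in VOLATILE_CLASSES[c])
        return np.array(sorted(idx), dtype=int)

    def volatile_mask(self, classes) -> np.ndarray:
        mask = np.zeros(self.dim, dtype=bool)
        mask[self.class_indices(classes)] = True
        return mask

    @classmethod
    def from_table(cls, table: dict | str | Path) -> "ParameterSpace":
        """Space with prior means/variances overridden from a JSON table.

        ``table`` maps parameter labels to {"prior_mean": ...,
        "log_prior_variance": ...} (the format written by
        :func:`save_prior_table`); unlisted parameters keep their defaults.
        """
        if not isinstance(table, dict):
            table = json.loads(Path(table).read_text())
        unknown = set(table) - set(PARAM_LABELS)
        if unknown:
            raise ValueError(f"unknown parameters in prior table: {sorted(unknown)}")
        means = {**_PRIOR_MEANS,
                 **{k: v["prior_mean"] for k, v in table.items()}}
        vars_ = {**_PRIOR_VARS,
                 **{k: v["log_prior_variance"] for k, v in table.items()}}
        return cls(prior_means=np.array([means[k] for k in PARAM_LABELS]),
                   prior_vars=np.array([vars_[k] for k in PARAM_LABELS]))

    def to_natural(self, phi: np.ndarray) -> CMCParameters:
        theta = self.prior_means * np.exp(np.asarray(phi, dtype=float))
        return CMCParameters.from_vector(theta)

    def to_latent(self, params: CMCParameters) -> np.ndarray:
        return np.log(params.as_vector() / self.prior_means)


def build_prior(volatile_spec=(), space: ParameterSpace | None = None) -> GaussianDensity:
    """Prior over latents: zero mean, diagonal covariance from the prior table.

    ``volatile_spec`` names the parameter classes allowed to drift between
    epochs; it is validated here and attached to the returned density as
    ``volatile_mask``.
    """
    space = space or ParameterSpace()
    prior = GaussianDensity(np.zeros(space.dim), np.diag(space.prior_vars))
    prior.volatile_mask = space.volatile_mask(volatile_spec)
    return prior


def firing_rate(v, gamma: float):
    """Centred sigmoid rate function S(v) = 1/(1+exp(−γv)) − 1/2.

    Bounded in (−1/2, 1/2), monotone, S(0) = 0, S′(0) = γ/4.
    """
    return 1.0 / (1.0 + np.exp(-gamma * np.asarray(v, dtype=float))) - 0.5


def _wiring_arrays():
    lbl_to_gidx = {f"g{i}": i - 1 for i in range(1, 11)}
    pop = {p: i for i, p in enumerate(POPULATIONS)}
    return [(lbl_to_gidx[lbl], pop[src], pop[dst], sgn)
            for lbl, src, dst, sgn in WIRING]


_EDGES = _wiring_arrays()


def flow(x: np.ndarray, params: CMCParameters, u: float = 0.0) -> np.ndarray:
    """Deterministic flow of the 8-state CMC (4 potentials, 4 currents)."""
    x = np.asarray(x, dtype=float)
    v, w = x[:4], x[4:]
    S = firing_rate(v, params.gamma)
    drive = np.zeros(4)
    for gi, src, dst, sgn in _EDGES:
        drive[dst] += sgn * params.g[gi] * S[src]
    drive[0] += u  # afferent input to the granular population
    dv = w
    dw = params.T * drive - 2.0 * params.T * w - params.T ** 2 * v
    return np.concatenate([dv, dw])


def equilibrium(params: CMCParameters, x0: np.ndarray | None = None) -> np.ndarray:
    """Fixed point of the flow with zero exogenous drive.

    With the centred sigmoid the origin is always an equilibrium; a root
    finder is still run so that perturbed wirings or future sigmoid variants
    remain supported.
    """
    x0 = np.zeros(8) if x0 is None else np.asarray(x0, dtype=float)
    sol = root(lambda x: flow(x, params), x0, tol=1e-12)
    resid = np.linalg.norm(flow(sol.x, params))
    if resid > 1e-8:
        raise RuntimeError(f"equilibrium search did not converge (residual {resid:.2e})")
    return sol.x


def jacobian(params: CMCParameters, x_star: np.ndarray | None = None,
             delay_adjust: bool = True) -> np.ndarray:
    """Delay-adjusted Jacobian of the flow at an equilibrium.

    The conduction delay d enters through the first-order operator
    Jᵈ = (I − D∘J)⁻¹ J with D carrying d (in seconds) on the
    between-population coupling entries.
    """
    x_star = np.zeros(8) if x_star is None else np.asarray(x_star, dtype=float)
    v = x_star[:4]
    # derivative of the centred sigmoid
    ex = np.exp(-params.gamma * v)
    dS = params.gamma * ex / (1.0 + ex) ** 2
    J = np.zeros((8, 8))
    J[:4, 4:] = np.eye(4)
    for k in range(4):
        J[4 + k, k] -= params.T[k] ** 2
        J[4 + k, 4 + k] = -2.0 * params.T[k]
    for gi, src, dst, sgn in _EDGES:
        J[4 + dst, src] += params.T[dst] * sgn * params.g[gi] * dS[src]
    if delay_adjust and params.delay > 0:
        D = np.zeros((8, 8))
        d_sec = params.delay * 1e-3
        for gi, src, dst, sgn in _EDGES:
            if src != dst:
                D[4 + dst, src] = d_sec
        M = np.eye(8) - D * J
        if abs(np.linalg.det(M)) < 1e-12:
            raise np.linalg.LinAlgError("singular delay correction operator")
        J = np.linalg.solve(M, J)
    return J


def linear_parts(params: CMCParameters, x_star: np.ndarray | None = None):
    """Linearised flow split into instantaneous and delayed coupling.

    Returns (A_self, A_cross) with A_self + A_cross the undelayed
    Jacobian; A_cross collects the between-population couplings, which
    are subject to the conduction delay.
    """
    x_star = np.zeros(8) if x_star is None else np.asarray(x_star, dtype=float)
    v = x_star[:4]
    ex = np.exp(-params.gamma * v)
    dS = params.gamma * ex / (1.0 + ex) ** 2
    A = np.zeros((8, 8))
    A[:4, 4:] = np.eye(4)
    for k in range(4):
        A[4 + k, k] -= params.T[k] ** 2
        A[4 + k, 4 + k] = -2.0 * params.T[k]
    Ac = np.zeros((8, 8))
    for gi, src, dst, sgn in _EDGES:
        M = A if src == dst else Ac
        M[4 + dst, src] += params.T[dst] * sgn * params.g[gi] * dS[src]
    return A, Ac


def observation_vector(weights: dict | None = None) -> np.ndarray:
    """Read-out vector C over the 8 states (weights on pyramidal potentials)."""
    weights = OBSERVATION_WEIGHTS if weights is None else weights
    C = np.zeros(8)
    for popname, wt in weights.items():
        C[POPULATIONS.index(popname)] = wt
    return C


def input_vector(params: CMCParameters) -> np.ndarray:
    """Input-injection vector B: afferent drive enters the granular current."""
    B = np.zeros(8)
    B[4 + POPULATIONS.index("ss")] = params.T[0]
    return B


def wiring_table() -> list[dict]:
    """The intrinsic wiring as a serialisable configuration table."""
    return [{"connection": lbl, "source": src, "target": dst, "sign": sgn}
            for lbl, src, dst, sgn in WIRING]


def save_prior_table(path: str | Path) -> None:
    """Write the prior table (means and latent variances) as JSON."""
    tbl = {k: {"prior_mean": _PRIOR_MEANS[k], "log_prior_variance": _PRIOR_VARS[k]}
           for k in PARAM_LABELS}
    Path(path).write_text(json.dumps(tbl, indent=2))
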