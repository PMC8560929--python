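"""Hierarchical generative model over SEEG log-power observations.

The joint density factorizes into hypothesis-conditioned priors on the
parameter vector theta, a deterministic (delta-transition) prior on the
latent 2D Epileptor source states, and a Gaussian observation likelihood:

* theta = (x0 per region, x(t0), z(t0), K, tau0, alpha, beta, eps1, eps2),
  a flat vector of length 3N + 6;
* the latent trajectory Y is obtained by integrating the coupled 2D
  Epileptor from (x(t0), z(t0)) with RK4 steps of 0.1 between the T
  observation instants, so Y carries no free parameters of its own;
* each observed log-power sample s_i(t_j) is normal with mean
  alpha * log<G_i, exp(x(t_j))> + beta and SD eps1; the augmented
  per-channel total power rho_i is normal around the second sample moment
  of the model-predicted log power with SD eps2, pulling the predicted
  power profile towards the observed total power.

The excitability prior encodes the clinical EZ hypothesis: N(-1.5, 1) for
hypothesis regions, N(-3.0, 1) elsewhere.  Gradients of the log posterior
are analytic (reverse-mode through the RK4 recursion; see `_kernels`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr

from . import _kernels
from .dynamics import DivergenceError
from .features import DataFeatures
from .forward import GainMatrix

__all__ = [
    "ThetaParameters",
    "PriorSpec",
    "LatentTrajectory",
    "Observation",
    "pack_theta",
    "unpack_theta",
    "make_priors",
    "log_prior",
    "predict_latent_states",
    "log_likelihood",
    "log_posterior",
    "log_posterior_with_grad",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: RK4 step used for the latent state transition
DEFAULT_LATENT_DT = 0.1
#: state-magnitude bound treated as integration divergence
LATENT_STATE_BOUND = 1.0e3


@dataclass
class ThetaParameters:
    """Free parameters of the generative model (flattened length 3N + 6)."""

    x0: np.ndarray
    x_init: np.ndarray
    z_init: np.ndarray
    K: float
    tau0: float
    alpha: float
    beta: float
    eps1: float
    eps2: float

    def __post_init__(self):
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.x_init = np.atleast_1d(np.asarray(self.x_init, dtype=float))
        self.z_init = np.atleast_1d(np.asarray(self.z_init, dtype=float))
        n = self.x0.shape[0]
        if self.x_init.shape[0] != n or self.z_init.shape[0] != n:
            raise ValueError("x0, x_init, z_init must share the region count")

    @property
    def n_regions(self) -> int:
        return self.x0.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "x0": self.x0.tolist(),
            "x_init": self.x_init.tolist(),
            "z_init": self.z_init.tolist(),
            "K": self.K, "tau0": self.tau0, "alpha": self.alpha,
            "beta": self.beta, "eps1": self.eps1, "eps2": self.eps2,
        })

    @classmethod
    def from_json(cls, text: str) -> "ThetaParameters":
        d = json.loads(text)
        return cls(
            x0=np.array(d["x0"]), x_init=np.array(d["x_init"]),
            z_init=np.array(d["z_init"]), K=d["K"], tau0=d["tau0"],
            alpha=d["alpha"], beta=d["beta"], eps1=d["eps1"], eps2=d["eps2"],
        )


def pack_theta(theta: ThetaParameters) -> np.ndarray:
    """Flatten to (x0 block, x_init block, z_init block, K, tau0, alpha,
    beta, eps1, eps2); length 3N + 6."""
    return np.concatenate([
        theta.x0, theta.x_init, theta.z_init,
        [theta.K, theta.tau0, theta.alpha, theta.beta, theta.eps1, theta.eps2],
    ])


def unpack_theta(vec: np.ndarray, n_regions: int) -> ThetaParameters:
    vec = np.asarray(vec, dtype=float)
    n = n_regions
    if vec.shape != (3 * n + 6,):
        raise ValueError(f"expected length {3 * n + 6}, got {vec.shape}")
    return ThetaParameters(
        x0=vec[:n].copy(),
        x_init=vec[n:2 * n].copy(),
        z_init=vec[2 * n:3 * n].copy(),
        K=float(vec[3 * n]),
        tau0=float(vec[3 * n + 1]),
        alpha=float(vec[3 * n + 2]),
        beta=float(vec[3 * n + 3]),
        eps1=float(vec[3 * n + 4]),
        eps2=float(vec[3 * n + 5]),
    )


@dataclass
class PriorSpec:
    """Per-parameter normal priors on the flat theta vector.

    ``truncated`` marks parameters restricted to the positive half-line
    (K, tau0, eps1, eps2); their densities are renormalized truncated
    normals.  ``hypothesis`` records the EZ-hypothesis region set the x0
    block was conditioned on.
    """

    mean: np.ndarray
    sd: np.ndarray
    truncated: np.ndarray  # bool mask
    hypothesis: tuple[int, ...] = ()
    n_regions: int = 0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.truncated = np.asarray(self.truncated, dtype=bool)
        if not (self.mean.shape == self.sd.shape == self.truncated.shape):
            raise ValueError("mean, sd, truncated must share a shape")
        if np.any(self.sd <= 0):
            raise ValueError("prior SDs must be positive")

    @property
    def mean_theta(self) -> ThetaParameters:
        return unpack_theta(self.mean, self.n_regions)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "truncated": self.truncated.astype(int).tolist(),
            "hypothesis": list(self.hypothesis),
            "n_regions": self.n_regions,
        }))

    @classmethod
    def load(cls, path) -> "PriorSpec":
        d = json.loads(Path(path).read_text())
        return cls(
            mean=np.array(d["mean"]), sd=np.array(d["sd"]),
            truncated=np.array(d["truncated"], dtype=bool),
            hypothesis=tuple(d["hypothesis"]), n_regions=d["n_regions"],
        )


def make_priors(hypothesis: Sequence[int], n_regions: int) -> PriorSpec:
    """Hypothesis-conditioned priors.

    x0 ~ N(-1.5, 1) for regions in the EZ hypothesis, N(-3.0, 1) otherwise;
    x(t0) ~ N(-2.0, 10), z(t0) ~ N(3.5, 10), K ~ N(1, 10), tau0 ~ N(20, 10),
    alpha ~ N(1, 10), beta ~ N(0, 10), eps1 ~ N(1, 10), eps2 ~ N(1, 10);
    K, tau0, eps1, eps2 truncated below at zero.
    """
    hypothesis = tuple(sorted(set(int(i) for i in hypothesis)))
    for i in hypothesis:
        if not 0 <= i < n_regions:
            raise ValueError(f"hypothesis region {i} out of range")
    n = n_regions
    mean = np.empty(3 * n + 6)
    sd = np.empty(3 * n + 6)
    mean[:n] = -3.0
    for i in hypothesis:
        mean[i] = -1.5
    sd[:n] = 1.0
    mean[n:2 * n] = -2.0
    sd[n:2 * n] = 10.0
    mean[2 * n:3 * n] = 3.5
    sd[2 * n:3 * n] = 10.0
    mean[3 * n:] = [1.0, 20.0, 1.0, 0.0, 1.0, 1.0]  # K, tau0, alpha, beta, eps1, eps2
    sd[3 * n:] = 10.0
    truncated = np.zeros(3 * n + 6, dtype=bool)
    truncated[[3 * n, 3 * n + 1, 3 * n + 4, 3 * n + 5]] = True  # K, tau0, eps1, eps2
    return PriorSpec(
        mean=mean, sd=sd, truncated=truncated,
        hypothesis=hypothesis, n_regions=n,
    )


def _theta_vec(theta) -> np.ndarray:
    if isinstance(theta, ThetaParameters):
        return pack_theta(theta)
    return np.asarray(theta, dtype=float)


def log_prior(theta, priors: PriorSpec, on_violation: str = "neg_inf") -> float:
    """Sum of (truncated-)normal log densities of the flat theta vector.

    Truncated terms include the renormalization constant -log Phi(mu/sigma).
    A parameter at or below a truncation bound yields -inf (or raises when
    ``on_violation='raise'``).
    """
    v = _theta_vec(theta)
    if np.any(v[priors.truncated] <= 0.0):
        if on_violation == "raise":
            raise ValueError("theta violates a truncation bound")
        return -np.inf
    z = (v - priors.mean) / priors.sd
    lp = float(np.sum(-0.5 * z ** 2 - np.log(priors.sd) - 0.5 * _LOG_2PI))
    # renormalizers: -log P(X > 0) = -log Phi(mu/sigma) for each truncated term
    t = priors.truncated
    lp -= float(np.sum(log_ndtr(priors.mean[t] / priors.sd[t])))
    return lp


def grad_log_prior(theta, priors: PriorSpec) -> np.ndarray:
    v = _theta_vec(theta)
    return -(v - priors.mean) / priors.sd ** 2


@dataclass
class LatentTrajectory:
    """Deterministic latent source states at the T observation instants.

    ``x`` and ``z`` are (N, T); column j is the state at observation t_j,
    one RK4 transition after t_{j-1} (t_0 is the initial condition in
    theta and is not a column).
    """

    x: np.ndarray
    z: np.ndarray
    dt: float = DEFAULT_LATENT_DT

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.z = np.atleast_2d(np.asarray(self.z, dtype=float))
        if self.x.shape != self.z.shape:
            raise ValueError("x and z must share a shape")

    @property
    def n_regions(self) -> int:
        return self.x.shape[0]

    @property
    def n_times(self) -> int:
        return self.x.shape[1]

    @property
    def Y(self) -> np.ndarray:
        """2N x T matrix with interleaved rows (x_1, z_1, x_2, z_2, ...)."""
        out = np.empty((2 * self.n_regions, self.n_times))
        out[0::2] = self.x
        out[1::2] = self.z
        return out


@dataclass
class Observation:
    """Fitted data: log-power features plus the gain matrix that maps the
    N model regions onto the M recorded channels."""

    features: DataFeatures
    gain: GainMatrix

    def __post_init__(self):
        if self.gain.G.shape[0] != self.features.n_channels:
            raise ValueError("gain rows must match the channel count")

    @property
    def n_channels(self) -> int:
        return self.features.n_channels

    @property
    def n_regions(self) -> int:
        return self.gain.G.shape[1]

    @property
    def n_times(self) -> int:
        return self.features.n_times


def _forward_latent(theta: ThetaParameters, C: np.ndarray, T: int,
                    dt: float, substeps: int):
    ys, status = _kernels.rk4_forward(
        np.ascontiguousarray(theta.x_init),
        np.ascontiguousarray(theta.z_init),
        np.ascontiguousarray(theta.x0),
        float(theta.K), float(theta.tau0), 3.1,
        np.ascontiguousarray(C), T, substeps, dt, LATENT_STATE_BOUND,
    )
    return ys, status


def predict_latent_states(
    theta: ThetaParameters,
    connectome,
    T: int = 300,
    dt: float = DEFAULT_LATENT_DT,
    substeps: int = 1,
) -> LatentTrajectory:
    """Integrate the 2D Epileptor prior dynamics through the T observation
    instants.  Deterministic: the delta state-transition prior makes Y a
    function of theta alone.  Raises :class:`DivergenceError` if the state
    leaves the admissible region."""
    if T < 1:
        raise ValueError("T must be >= 1")
    C = getattr(connectome, "weights", connectome)
    C = np.asarray(C, dtype=float)
    ys, status = _forward_latent(theta, C, T, dt, substeps)
    if status >= 0:
        raise DivergenceError(int(status))
    xs = ys[substeps::substeps, 0, :].T  # (N, T), columns t_1..t_T
    zs = ys[substeps::substeps, 1, :].T
    return LatentTrajectory(x=xs.copy(), z=zs.copy(), dt=dt * substeps)


def _likelihood_terms(theta: ThetaParameters, x_lat: np.ndarray,
                      obs: Observation):
    """Common pieces of the likelihood and its gradient."""
    G = obs.gain.G
    S = obs.features.S  # (T, M)
    rho = obs.features.rho
    T, M = S.shape
    ex = np.exp(x_lat)  # (N, T)
    den = G @ ex  # (M, T)
    if np.any(den <= 0.0):
        raise ValueError("gain row with zero mass: <G_i, e^x> must be positive")
    mean = theta.alpha * np.log(den) + theta.beta  # (M, T)
    resid = S.T - mean  # (M, T)
    # augmented feature: observed total power vs the second sample moment of
    # the model-predicted log power (this is what makes rho informative)
    rho_mean = np.mean(mean ** 2, axis=1)
    rho_resid = rho - rho_mean
    return G, S, T, M, ex, den, mean, resid, rho_resid


def log_likelihood(theta: ThetaParameters, latent: LatentTrajectory,
                   obs: Observation) -> float:
    """Gaussian observation log density of (S, rho) given theta and Y."""
    if latent.n_times != obs.n_times:
        raise ValueError("latent trajectory and features disagree on T")
    if theta.eps1 <= 0 or theta.eps2 <= 0:
        return -np.inf
    _, _, T, M, _, _, _, resid, rho_resid = _likelihood_terms(
        theta, latent.x, obs)
    e1, e2 = theta.eps1, theta.eps2
    ll = -0.5 * float(np.sum((resid / e1) ** 2)) \
        - T * M * (np.log(e1) + 0.5 * _LOG_2PI)
    ll += -0.5 * float(np.sum((rho_resid / e2) ** 2)) \
        - M * (np.log(e2) + 0.5 * _LOG_2PI)
    return ll


def log_posterior(
    theta,
    obs: Observation,
    priors: PriorSpec,
    connectome,
    dt: float = DEFAULT_LATENT_DT,
    substeps: int = 1,
) -> float:
    """Unnormalized log posterior: log_prior + log_likelihood(predict(theta)).

    Integration divergence maps to -inf.
    """
    n = priors.n_regions
    tp = theta if isinstance(theta, ThetaParameters) else unpack_theta(theta, n)
    lp = log_prior(tp, priors)
    if not np.isfinite(lp):
        return -np.inf
    try:
        latent = predict_latent_states(tp, connectome, T=obs.n_times,
                                       dt=dt, substeps=substeps)
    except DivergenceError:
        return -np.inf
    return lp + log_likelihood(tp, latent, obs)


def log_posterior_with_grad(
    theta_flat: np.ndarray,
    obs: Observation,
    priors: PriorSpec,
    connectome,
    dt: float = DEFAULT_LATENT_DT,
    substeps: int = 1,
) -> tuple[float, np.ndarray]:
    """Log posterior and its analytic gradient w.r.t. the flat theta vector.

    The likelihood gradient with respect to the dynamical parameters is
    obtained by the adjoint sweep through the RK4 recursion; auxiliary
    parameters (alpha, beta, eps1, eps2) have closed-form terms.  Raises
    :class:`DivergenceError` when the latent integration diverges (the
    optimizer treats that as an infeasible point).
    """
    theta_flat = np.asarray(theta_flat, dtype=float)
    n = priors.n_regions
    tp = unpack_theta(theta_flat, n)
    if np.any(theta_flat[priors.truncated] <= 0.0):
        raise ValueError("theta violates a truncation bound")
    C = getattr(connectome, "weights", connectome)
    C = np.ascontiguousarray(np.asarray(C, dtype=float))
    T = obs.n_times
    ys, status = _forward_latent(tp, C, T, dt, substeps)
    if status >= 0:
        raise DivergenceError(int(status))
    x_lat = np.ascontiguousarray(ys[substeps::substeps, 0, :].T)

    G, S, T, M, ex, den, mean, resid, rho_resid = _likelihood_terms(
        tp, x_lat, obs)
    e1, e2 = tp.eps1, tp.eps2
    w = resid / e1 ** 2  # (M, T)

    ll = -0.5 * float(np.sum((resid / e1) ** 2)) \
        - T * M * (np.log(e1) + 0.5 * _LOG_2PI) \
        - 0.5 * float(np.sum((rho_resid / e2) ** 2)) \
        - M * (np.log(e2) + 0.5 * _LOG_2PI)
    lp = log_prior(tp, priors)
    total = lp + ll

    # rho pulls the predicted mean towards the observed total power
    w_rho = (rho_resid / e2 ** 2)[:, None] * (2.0 * mean / T)  # (M, T)
    w_tot = w + w_rho

    # gradient: auxiliary parameters
    g_alpha = float(np.sum(w_tot * np.log(den)))
    g_beta = float(np.sum(w_tot))
    g_eps1 = float(np.sum(resid ** 2) / e1 ** 3 - T * M / e1)
    g_eps2 = float(np.sum(rho_resid ** 2) / e2 ** 3 - M / e2)

    # dL/dx(t_j): alpha * e^x * (G^T (w_tot / den)) per column
    lam_x = (tp.alpha * ex * (G.T @ (w_tot / den))).T  # (T, N)
    gx0, gxi, gzi, gK, gtau0 = _kernels.rk4_adjoint(
        np.ascontiguousarray(ys), np.ascontiguousarray(lam_x),
        np.ascontiguousarray(tp.x0), float(tp.K), float(tp.tau0), 3.1,
        C, substeps, dt,
    )
    grad = np.concatenate([
        gx0, gxi, gzi, [gK, gtau0, g_alpha, g_beta, g_eps1, g_eps2]
    ])
    grad = grad + grad_log_prior(theta_flat, priors)
    return total, grad
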