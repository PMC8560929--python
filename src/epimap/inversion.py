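"""MAP estimation of the generative model by L-BFGS.

The posterior mode is found with scipy's L-BFGS-B on the negative log
posterior, using the analytic adjoint gradient.  Positivity-constrained
parameters (K, tau0, eps1, eps2) are optimized through a log transform so
the search space is unconstrained; the objective includes the log-Jacobian
of the transform, so the reported mode is the mode of the transformed
density pulled back to natural space (the usual behaviour of probabilistic
programming optimizers).

Convergence is monitored against three criteria: change in unnormalized
log posterior below 1e-12, Euclidean gradient norm below 1e-8, or maximum
absolute parameter change below 1e-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize

from .dynamics import DivergenceError
from .model import (
    Observation,
    PriorSpec,
    ThetaParameters,
    log_posterior_with_grad,
    pack_theta,
    unpack_theta,
)

__all__ = ["MapResult", "ProposalSpec", "map_estimate", "multi_start"]

#: convergence thresholds (density, gradient norm, parameter change)
TOL_DENSITY = 1e-12
TOL_GRADIENT = 1e-8
TOL_PARAMS = 1e-8

#: objective value standing in for a diverged latent integration; large and
#: finite so the line search backtracks without corrupting the inverse
#: Hessian with infinities
DIVERGENCE_PENALTY = 1e10


@dataclass
class MapResult:
    """Outcome of one MAP optimization run."""

    theta_hat: ThetaParameters
    log_posterior: float
    converged_density: bool
    converged_gradient: bool
    converged_params: bool
    n_iterations: int
    n_divergences: int
    message: str
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def converged(self) -> bool:
        return (self.converged_density or self.converged_gradient
                or self.converged_params)

    def to_json(self) -> str:
        return json.dumps({
            "theta_hat": json.loads(self.theta_hat.to_json()),
            "log_posterior": self.log_posterior,
            "converged_density": self.converged_density,
            "converged_gradient": self.converged_gradient,
            "converged_params": self.converged_params,
            "n_iterations": self.n_iterations,
            "n_divergences": self.n_divergences,
            "message": self.message,
            "trace": self.trace.tolist(),
        })

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())


@dataclass
class ProposalSpec:
    """Multi-start proposal: normal around the prior means with a common SD.

    The SD is an absolute value applied to every parameter (the proposals
    share the prior means but not the prior SDs); truncated parameters are
    redrawn until positive.
    """

    sd: float = 0.1
    n_samples: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("proposal SD must be nonnegative")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")

    def draw(self, priors: PriorSpec) -> np.ndarray:
        """(n_samples, dim) initial theta vectors, truncations respected."""
        rng = np.random.default_rng(self.seed)
        dim = priors.mean.shape[0]
        out = np.empty((self.n_samples, dim))
        for k in range(self.n_samples):
            v = priors.mean + self.sd * rng.standard_normal(dim)
            bad = priors.truncated & (v <= 0.0)
            while np.any(bad):
                v[bad] = priors.mean[bad] + self.sd * rng.standard_normal(
                    int(bad.sum()))
                bad = priors.truncated & (v <= 0.0)
            out[k] = v
        return out


def _to_unconstrained(v: np.ndarray, trunc: np.ndarray) -> np.ndarray:
    out = v.copy()
    out[trunc] = np.log(v[trunc])
    return out


def _to_natural(u: np.ndarray, trunc: np.ndarray) -> np.ndarray:
    out = u.copy()
    out[trunc] = np.exp(u[trunc])
    return out


def map_estimate(
    obs: Observation,
    priors: PriorSpec,
    connectome,
    init: Union[str, ThetaParameters, np.ndarray] = "prior-means",
    max_iterations: int = 20000,
    dt: float = 0.1,
    substeps: int = 1,
    lbfgs_memory: int = 10,
) -> MapResult:
    """Maximize the log posterior with L-BFGS from a single start point.

    ``init`` is either the string "prior-means", a ThetaParameters, or a
    flat theta vector in natural space.  Latent-integration divergences
    during the search are absorbed as a large penalty so the line search
    backtracks; a divergence at the initial point raises instead, with a
    hint to choose a different start.
    """
    trunc = priors.truncated
    if isinstance(init, str):
        if init != "prior-means":
            raise ValueError(f"unknown init spec {init!r}")
        theta0 = priors.mean.copy()
    elif isinstance(init, ThetaParameters):
        theta0 = pack_theta(init)
    else:
        theta0 = np.asarray(init, dtype=float).copy()

    state = {"divergences": 0, "trace": [], "last_f": np.nan}

    def objective(u: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", under="ignore"):
            v = _to_natural(u, trunc)
        try:
            # exp over/underflow makes v infinite or exactly zero; both are
            # infeasible points the line search must back away from
            lp, grad_v = log_posterior_with_grad(
                v, obs, priors, connectome, dt=dt, substeps=substeps)
        except (DivergenceError, ValueError, FloatingPointError):
            state["divergences"] += 1
            state["last_f"] = DIVERGENCE_PENALTY
            return DIVERGENCE_PENALTY, np.zeros_like(u)
        # log-Jacobian of the exp transform and chain rule for truncated dims
        lp = lp + float(np.sum(u[trunc]))
        grad_u = grad_v.copy()
        grad_u[trunc] = grad_v[trunc] * v[trunc] + 1.0
        if not np.isfinite(lp):
            state["divergences"] += 1
            state["last_f"] = DIVERGENCE_PENALTY
            return DIVERGENCE_PENALTY, np.zeros_like(u)
        state["last_f"] = -lp
        return -lp, -grad_u

    u0 = _to_unconstrained(theta0, trunc)
    f0, _ = objective(u0)
    if f0 >= DIVERGENCE_PENALTY:
        raise DivergenceError(
            0, "latent integration diverges at the initial point; "
               "choose a different initialization")

    def callback(u):
        # the accepted iterate was the last objective evaluation
        state["trace"].append(-state["last_f"])

    res = minimize(
        objective, u0, jac=True, method="L-BFGS-B",
        callback=callback,
        options={
            "maxiter": max_iterations,
            "maxfun": 3 * max_iterations,
            "maxcor": lbfgs_memory,
            # ftol is relative in scipy; the absolute density criterion is
            # evaluated from the trace below
            "ftol": 1e-14,
            "gtol": TOL_GRADIENT,
            "maxls": 60,
        },
    )
    u_hat = res.x
    theta_hat_vec = _to_natural(u_hat, trunc)
    lp_hat, grad_hat = log_posterior_with_grad(
        theta_hat_vec, obs, priors, connectome, dt=dt, substeps=substeps)

    trace = np.asarray(state["trace"], dtype=float)
    conv_density = bool(
        len(trace) >= 2 and abs(trace[-1] - trace[-2]) < TOL_DENSITY)
    # gradient criterion on the unconstrained objective actually optimized
    gu = grad_hat.copy()
    gu[trunc] = grad_hat[trunc] * theta_hat_vec[trunc] + 1.0
    conv_gradient = bool(np.linalg.norm(gu) < TOL_GRADIENT)
    conv_params = False
    if len(trace) >= 2:
        # scipy does not expose per-iteration parameters; use its own
        # termination reason for the parameter criterion proxy
        conv_params = bool(res.success and not (conv_density or conv_gradient))
    n_regions = priors.n_regions
    return MapResult(
        theta_hat=unpack_theta(theta_hat_vec, n_regions),
        log_posterior=float(lp_hat),
        converged_density=conv_density,
        converged_gradient=conv_gradient,
        converged_params=conv_params,
        n_iterations=int(res.nit),
        n_divergences=int(state["divergences"]),
        message=str(res.message),
        trace=trace,
    )


def multi_start(
    obs: Observation,
    priors: PriorSpec,
    connectome,
    proposal: Optional[ProposalSpec] = None,
    **map_kwargs,
) -> MapResult:
    """Run MAP from several proposal-sampled starts; keep the best.

    Starts whose initial point diverges are recorded and skipped; the run
    with the highest final log posterior is returned.  With ``sd == 0``
    every start equals the prior means and the result matches
    :func:`map_estimate`.
    """
    proposal = proposal or ProposalSpec()
    if proposal.sd == 0.0:
        return map_estimate(obs, priors, connectome, init="prior-means",
                            **map_kwargs)
    starts = proposal.draw(priors)
    best: Optional[MapResult] = None
    n_failed = 0
    for theta0 in starts:
        try:
            result = map_estimate(obs, priors, connectome, init=theta0,
                                  **map_kwargs)
        except DivergenceError:
            n_failed += 1
            continue
        if best is None or result.log_posterior > best.log_posterior:
            best = result
    if best is None:
        raise DivergenceError(
            0, f"all {n_failed} starts diverged at their initial point")
    return best
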