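"""Epileptor vector fields and fixed-step integrators on a brain network.

Two flavours of the Epileptor neural-mass model live here:

* the full 5-variable oscillator (plus one auxiliary state carrying a slow
  convolution term) used to *generate* realistic seizure data, and
* its 2-variable reduction (fast variable ``x`` as a proxy of source log
  power, slow permittivity ``z``) used inside the generative model for
  inference.

Nodes are coupled through the permittivity variable: the time derivative of
``z_i`` picks up ``-K * sum_j C_ij (x_j - x_i)`` scaled by ``1/tau0``, so a
seizing neighbour (high ``x_j``) pushes ``z_i`` down and drags region ``i``
towards its own seizure onset.

All integrators are deterministic fixed-step schemes (Heun and classical
RK4); identical inputs give bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import fsolve

__all__ = [
    "Epileptor2DParams",
    "Epileptor5DParams",
    "Trajectory",
    "DivergenceError",
    "derivatives_5d",
    "derivatives_2d",
    "integrate_heun",
    "integrate_rk4",
    "fixed_point_2d",
    "fixed_point_5d",
    "estimate_seizure_threshold_2d",
    "seizure_threshold_linear_stability",
]

#: magnitude at which an integration is declared divergent
DEFAULT_STATE_BOUND = 1.0e3


class DivergenceError(RuntimeError):
    """Raised when a trajectory leaves the admissible region of state space.

    Attributes
    ----------
    step : int
        Index of the integration step at which the bound was exceeded.
    """

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"state diverged at integration step {step}")


def _as_weights(connectome) -> np.ndarray:
    """Accept either a Connectome-like object or a plain ndarray."""
    w = getattr(connectome, "weights", connectome)
    return np.asarray(w, dtype=float)


@dataclass
class Epileptor5DParams:
    """Parameters of the coupled 5D Epileptor network.

    ``x0`` is the per-region excitability; an isolated node seizes
    autonomously for ``x0`` above roughly -2.1.  ``tau0`` sets the slow
    permittivity timescale, ``tau2`` the intermediate spike-and-wave
    timescale, and ``gamma`` the decay rate of the low-pass convolution of
    ``x1`` feeding the intermediate subsystem.
    """

    x0: np.ndarray
    K: float
    C: np.ndarray
    tau0: float = 2857.0
    tau2: float = 10.0
    I1: float = 3.1
    I2: float = 0.45
    gamma: float = 0.01

    def __post_init__(self):
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.C = _as_weights(self.C)
        n = self.x0.shape[0]
        if n < 1:
            raise ValueError("need at least one region")
        if self.C.shape != (n, n):
            raise ValueError(f"connectome shape {self.C.shape} != ({n}, {n})")
        if np.any(self.C < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("connectome diagonal must be zero")
        if not (self.tau0 > 0 and self.tau2 > 0 and self.gamma > 0):
            raise ValueError("tau0, tau2, gamma must be positive")
        if not np.all(np.isfinite(self.x0)):
            raise ValueError("x0 must be finite")

    @property
    def n_regions(self) -> int:
        return self.x0.shape[0]


@dataclass
class Epileptor2DParams:
    """Parameters of the coupled 2D (reduced) Epileptor network.

    The reduction keeps the fast variable ``x`` (proxy of source log power)
    and the permittivity ``z``; ``tau0`` here is on the scale of the fitted
    feature window (prior mean 20), much shorter than the 5D value.
    """

    x0: np.ndarray
    K: float
    C: np.ndarray
    tau0: float = 20.0
    I1: float = 3.1

    def __post_init__(self):
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.C = _as_weights(self.C)
        n = self.x0.shape[0]
        if n < 1:
            raise ValueError("need at least one region")
        if self.C.shape != (n, n):
            raise ValueError(f"connectome shape {self.C.shape} != ({n}, {n})")
        if np.any(self.C < 0):
            raise ValueError("connectome weights must be nonnegative")
        if np.any(np.diag(self.C) != 0):
            raise ValueError("connectome diagonal must be zero")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        if not np.all(np.isfinite(self.x0)):
            raise ValueError("x0 must be finite")

    @property
    def n_regions(self) -> int:
        return self.x0.shape[0]


@dataclass
class Trajectory:
    """Sampled trajectory: ``times`` (T,) and ``states`` (T, ...) snapshots."""

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if len(self.times) != len(self.states):
            raise ValueError("state count must equal time count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def save_npz(self, path) -> None:
        np.savez_compressed(path, times=self.times, states=self.states)

    @classmethod
    def load_npz(cls, path) -> "Trajectory":
        with np.load(path) as f:
            return cls(times=f["times"], states=f["states"])

    def save_txt(self, path) -> None:
        """Delimited text: first column time, remaining columns flat state."""
        flat = self.states.reshape(len(self.times), -1)
        np.savetxt(path, np.column_stack([self.times, flat]))


# ---------------------------------------------------------------------------
# vector fields
# ---------------------------------------------------------------------------

def derivatives_5d(state: np.ndarray, params: Epileptor5DParams) -> np.ndarray:
    """Time derivative of the coupled 5D Epileptor network.

    ``state`` is a (6, N) array with rows ``x1, y1, z, x2, y2, u``; ``u`` is
    the auxiliary state realizing the convolution term ``g(x1)`` as the ODE
    ``du/dt = x1 - gamma*u`` so that ``g = 0.002*u`` enters the ``x2``
    equation.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise DivergenceError(-1, "non-finite state passed to derivatives_5d")
    x1, y1, z, x2, y2, u = state
    p = params

    # piecewise f1(x1, x2): cubic below 0, z-dependent linear-in-x1 above
    f1 = np.where(
        x1 < 0.0,
        x1 ** 3 - 3.0 * x1 ** 2,
        (x2 - 0.6 * (z - 4.0) ** 2) * x1,
    )
    f2 = np.where(x2 < -0.25, 0.0, 6.0 * (x2 + 0.25))

    coupling = p.K * (p.C @ x1 - p.C.sum(axis=1) * x1)  # sum_j K C_ij (x1_j - x1_i)

    dx1 = y1 - f1 - z + p.I1
    dy1 = 1.0 - 5.0 * x1 ** 2 - y1
    dz = (4.0 * (x1 - p.x0) - z - coupling) / p.tau0
    dx2 = -y2 + x2 - x2 ** 3 + p.I2 + 0.002 * u - 0.3 * (z - 3.5)
    dy2 = (-y2 + f2) / p.tau2
    du = x1 - p.gamma * u
    return np.stack([dx1, dy1, dz, dx2, dy2, du])


def derivatives_2d(
    x: np.ndarray, z: np.ndarray, params: Epileptor2DParams
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivative (dx, dz) of the coupled 2D Epileptor network."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
        raise DivergenceError(-1, "non-finite state passed to derivatives_2d")
    p = params
    coupling = p.K * (p.C @ x - p.C.sum(axis=1) * x)
    dx = 1.0 - x ** 3 - 2.0 * x ** 2 - z + p.I1
    dz = (4.0 * (x - p.x0) - z - coupling) / p.tau0
    return dx, dz


def _derivatives_2d_stacked(state: np.ndarray, params: Epileptor2DParams) -> np.ndarray:
    dx, dz = derivatives_2d(state[0], state[1], params)
    return np.stack([dx, dz])


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def _check_bound(y: np.ndarray, step: int, bound: float) -> None:
    if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > bound:
        raise DivergenceError(step)


def integrate_heun(
    deriv_fn: Callable[[np.ndarray], np.ndarray],
    init_state: np.ndarray,
    dt: float,
    duration: float,
    record_every: int = 1,
    state_bound: float = DEFAULT_STATE_BOUND,
    noise_sd=0.0,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Explicit Heun (trapezoidal predictor-corrector) integration.

    Runs ``n = round(duration/dt)`` steps from t=0, recording every
    ``record_every``-th state (the initial state is always recorded).
    ``noise_sd`` (scalar or array broadcastable to the state shape, e.g.
    per-state-variable SDs) optionally adds Euler-Maruyama style additive
    noise ``sqrt(dt)*noise_sd*xi`` after each step; the deterministic
    limit ``noise_sd=0`` is the default.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    n_steps = int(round(duration / dt))
    y = np.array(init_state, dtype=float)
    _check_bound(y, 0, state_bound)
    noise_sd = np.asarray(noise_sd, dtype=float)
    noisy = bool(np.any(noise_sd > 0.0))
    if noisy and rng is None:
        rng = np.random.default_rng()

    times = [0.0]
    states = [y.copy()]
    sqrt_dt = np.sqrt(dt)
    for k in range(1, n_steps + 1):
        f0 = deriv_fn(y)
        y_pred = y + dt * f0
        _check_bound(y_pred, k, state_bound)
        f1 = deriv_fn(y_pred)
        y = y + 0.5 * dt * (f0 + f1)
        if noisy:
            y = y + sqrt_dt * noise_sd * rng.standard_normal(y.shape)
        _check_bound(y, k, state_bound)
        if k % record_every == 0:
            times.append(k * dt)
            states.append(y.copy())
    return Trajectory(np.array(times), np.array(states))


def integrate_rk4(
    deriv_fn: Callable[[np.ndarray], np.ndarray],
    init_state: np.ndarray,
    dt: float,
    n_steps: int,
    record_every: int = 1,
    state_bound: float = DEFAULT_STATE_BOUND,
) -> Trajectory:
    """Classical fourth-order Runge-Kutta integration for ``n_steps`` steps."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    y = np.array(init_state, dtype=float)
    _check_bound(y, 0, state_bound)
    times = [0.0]
    states = [y.copy()]
    for k in range(1, n_steps + 1):
        k1 = deriv_fn(y)
        k2 = deriv_fn(y + 0.5 * dt * k1)
        k3 = deriv_fn(y + 0.5 * dt * k2)
        k4 = deriv_fn(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        _check_bound(y, k, state_bound)
        if k % record_every == 0:
            times.append(k * dt)
            states.append(y.copy())
    return Trajectory(np.array(times), np.array(states))


# ---------------------------------------------------------------------------
# fixed points and the seizure threshold
# ---------------------------------------------------------------------------

def fixed_point_2d(x0: float, I1: float = 3.1) -> tuple[float, float]:
    """Stable fixed point of an isolated 2D Epileptor node.

    Solves ``1 - x^3 - 2x^2 - z + I1 = 0`` and ``z = 4(x - x0)``
    simultaneously and returns the stable (leftmost real) root.  Raises if
    no real root lies on the stable left branch (the node is then seizing).
    """
    # 1 - x^3 - 2x^2 + I1 = 4(x - x0)  =>  x^3 + 2x^2 + 4x - (1 + I1 + 4 x0) = 0
    roots = np.roots([1.0, 2.0, 4.0, -(1.0 + I1 + 4.0 * x0)])
    real = np.sort(roots[np.abs(roots.imag) < 1e-9].real)
    if len(real) == 0:  # cubic with positive discriminant always has >=1 real root
        raise RuntimeError("no real fixed point found")
    x_star = float(real[0])
    # stability of the leftmost root: trace = -3x^2 - 4x - 1/tau0 < 0 needs
    # x < -4/3 (up to the O(1/tau0) correction); otherwise the node seizes.
    if x_star > -4.0 / 3.0:
        raise ValueError(f"no stable fixed point for x0={x0} (node is seizing)")
    z_star = 4.0 * (x_star - x0)
    return x_star, z_star


def fixed_point_5d(
    x0: float,
    params: Optional[Epileptor5DParams] = None,
    z_value: Optional[float] = None,
) -> np.ndarray:
    """Interictal rest state of an isolated 5D Epileptor node (6-vector).

    With ``z_value=None`` this is the true stable fixed point.  With a
    ``z_value`` the permittivity is clamped there and the remaining five
    states are equilibrated on it — an interictal baseline whose slow
    variable then drifts under the full dynamics.  The root search is
    seeded from the 2D fixed point.
    """
    if params is None:
        params = Epileptor5DParams(x0=np.array([x0]), K=0.0, C=np.zeros((1, 1)))
    p = Epileptor5DParams(
        x0=np.array([x0]), K=0.0, C=np.zeros((1, 1)),
        tau0=params.tau0, tau2=params.tau2, I1=params.I1, I2=params.I2,
        gamma=params.gamma,
    )
    x_guess, z_guess = fixed_point_2d(min(x0, -3.0), params.I1)
    if z_value is None:
        def residual(v):
            return derivatives_5d(v.reshape(6, 1), p).ravel()

        v0 = np.array([
            x_guess, 1.0 - 5.0 * x_guess ** 2, z_guess, -1.0, 0.0,
            x_guess / p.gamma,
        ])
        sol, info, ier, msg = fsolve(residual, v0, full_output=True)
        if ier != 1:
            raise RuntimeError(f"5D fixed-point search failed: {msg}")
        return sol

    def residual(v):
        full = np.array([v[0], v[1], z_value, v[2], v[3], v[4]])
        d = derivatives_5d(full.reshape(6, 1), p).ravel()
        return d[[0, 1, 3, 4, 5]]  # equilibrate all but the clamped z

    v0 = np.array([
        x_guess, 1.0 - 5.0 * x_guess ** 2, -1.0, 0.0, x_guess / p.gamma
    ])
    sol, info, ier, msg = fsolve(residual, v0, full_output=True)
    if ier != 1:
        raise RuntimeError(f"5D rest-state search failed: {msg}")
    return np.array([sol[0], sol[1], z_value, sol[2], sol[3], sol[4]])


def seizure_threshold_linear_stability(tau0: float = 20.0, I1: float = 3.1) -> float:
    """Critical x0 from linear stability of the isolated 2D node.

    The fixed point loses stability where the Jacobian trace
    ``-3x^2 - 4x - 1/tau0`` changes sign; substituting the nullclines gives
    the critical excitability in closed form.  Independent cross-check for
    the simulation-based bisection estimate.
    """
    disc = 16.0 - 12.0 / tau0
    x_star = (-4.0 - np.sqrt(disc)) / 6.0  # left stability boundary, ~ -4/3
    z_star = 1.0 - x_star ** 3 - 2.0 * x_star ** 2 + I1
    return float(x_star - z_star / 4.0)


def _node_seizes(
    x0: float,
    tau0: float,
    I1: float,
    dt: float,
    duration: float,
    onset_threshold: float,
) -> bool:
    """Simulate one isolated 2D node and report whether x crosses threshold."""
    params = Epileptor2DParams(
        x0=np.array([x0]), K=0.0, C=np.zeros((1, 1)), tau0=tau0, I1=I1
    )
    try:
        x_init, z_init = fixed_point_2d(min(x0, -3.0), I1)
    except ValueError:
        x_init, z_init = -2.0, 3.5
    # start near (but not exactly at) quiescence so instabilities can grow
    y0 = np.array([[x_init + 0.05], [z_init]])
    try:
        traj = integrate_heun(
            lambda y: _derivatives_2d_stacked(y, params), y0, dt, duration,
            record_every=10,
        )
    except DivergenceError:
        return True  # blow-up counts as leaving quiescence
    return bool(np.any(traj.states[:, 0, 0] > onset_threshold))


def estimate_seizure_threshold_2d(
    search_interval: tuple[float, float] = (-3.0, -1.0),
    tol: float = 1e-3,
    tau0: float = 20.0,
    I1: float = 3.1,
    dt: float = 0.1,
    duration: float = 1000.0,
    onset_threshold: float = 0.0,
) -> float:
    """Bisection estimate of the critical excitability of an isolated node.

    For each candidate ``x0`` an isolated (K=0) 2D Epileptor is integrated
    from near its quiescent state and classified as seizing if the fast
    variable crosses ``onset_threshold`` upward.  The interval must bracket
    the transition (quiescent at the lower end, seizing at the upper end).
    Returns the midpoint of the final bracket.
    """
    lo, hi = search_interval
    if not lo < hi:
        raise ValueError("search interval must satisfy lo < hi")
    seize = lambda v: _node_seizes(v, tau0, I1, dt, duration, onset_threshold)
    if seize(lo) or not seize(hi):
        raise ValueError(
            "interval does not bracket the seizing/quiescent transition"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if seize(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
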