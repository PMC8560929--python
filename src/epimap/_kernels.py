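"""Numba kernels for the latent 2D Epileptor trajectory and its adjoint.

The generative model needs, at every optimizer iteration, the deterministic
latent trajectory (T observation instants, RK4 substeps in between) and the
gradient of the observation likelihood with respect to the dynamical
parameters (x0 per region, initial state, global coupling K, timescale
tau0).  The gradient is computed by reverse-mode differentiation through
the RK4 recursion: stage states are recomputed from the stored substep
start states during the backward sweep, and a hand-derived vector-Jacobian
product of the 2D Epileptor vector field is applied at each stage.

Everything is written with explicit loops and preallocated buffers; for
the network sizes this model targets (tens to a few hundred regions) the
step loop is allocation-free.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rk4_forward", "rk4_adjoint"]


@njit(cache=True, fastmath=False)
def _field_into(x, z, x0, K, tau0, I1, C, rowsum, dx, dz):
    """2D Epileptor vector field written into (dx, dz)."""
    n = x.shape[0]
    for i in range(n):
        cpl = -rowsum[i] * x[i]
        for j in range(n):
            cpl += C[i, j] * x[j]
        dx[i] = 1.0 - x[i] ** 3 - 2.0 * x[i] ** 2 - z[i] + I1
        dz[i] = (4.0 * (x[i] - x0[i]) - z[i] - K * cpl) / tau0


@njit(cache=True)
def rk4_forward(x_init, z_init, x0, K, tau0, I1, C, n_obs, substeps, h, bound):
    """Integrate the coupled 2D Epileptor with classical RK4.

    Runs ``n_obs * substeps`` steps of size ``h`` from (x_init, z_init) and
    stores the state at every substep boundary: the returned array ``ys``
    has shape (n_obs*substeps + 1, 2, N) with ys[0] the initial state.
    Returns (ys, status); status is -1 on success, else the index of the
    step at which the state magnitude exceeded ``bound``.
    """
    n = x_init.shape[0]
    rowsum = np.sum(C, axis=1)
    total = n_obs * substeps
    ys = np.empty((total + 1, 2, n))
    x = x_init.copy()
    z = z_init.copy()
    ys[0, 0] = x
    ys[0, 1] = z
    k1x = np.empty(n); k1z = np.empty(n)
    k2x = np.empty(n); k2z = np.empty(n)
    k3x = np.empty(n); k3z = np.empty(n)
    k4x = np.empty(n); k4z = np.empty(n)
    tx = np.empty(n); tz = np.empty(n)
    for k in range(1, total + 1):
        _field_into(x, z, x0, K, tau0, I1, C, rowsum, k1x, k1z)
        for i in range(n):
            tx[i] = x[i] + 0.5 * h * k1x[i]
            tz[i] = z[i] + 0.5 * h * k1z[i]
        _field_into(tx, tz, x0, K, tau0, I1, C, rowsum, k2x, k2z)
        for i in range(n):
            tx[i] = x[i] + 0.5 * h * k2x[i]
            tz[i] = z[i] + 0.5 * h * k2z[i]
        _field_into(tx, tz, x0, K, tau0, I1, C, rowsum, k3x, k3z)
        for i in range(n):
            tx[i] = x[i] + h * k3x[i]
            tz[i] = z[i] + h * k3z[i]
        _field_into(tx, tz, x0, K, tau0, I1, C, rowsum, k4x, k4z)
        ok = True
        for i in range(n):
            x[i] = x[i] + (h / 6.0) * (k1x[i] + 2.0 * k2x[i]
                                       + 2.0 * k3x[i] + k4x[i])
            z[i] = z[i] + (h / 6.0) * (k1z[i] + 2.0 * k2z[i]
                                       + 2.0 * k3z[i] + k4z[i])
            ys[k, 0, i] = x[i]
            ys[k, 1, i] = z[i]
            if not (np.isfinite(x[i]) and np.isfinite(z[i])) or \
                    abs(x[i]) > bound or abs(z[i]) > bound:
                ok = False
        if not ok:
            return ys, k
    return ys, -1


@njit(cache=True)
def _vjp_into(x, z, cx, cz, x0, K, tau0, I1, C, rowsum, gx, gz, gx0, acc):
    """Vector-Jacobian product of the field, written into (gx, gz).

    Parameter-gradient contributions accumulate into ``gx0`` (per region)
    and ``acc`` (acc[0] += dK, acc[1] += dtau0).
    """
    n = x.shape[0]
    for i in range(n):
        cpl = -rowsum[i] * x[i]
        ctc = -rowsum[i] * cz[i]
        for j in range(n):
            cpl += C[i, j] * x[j]
            ctc += C[j, i] * cz[j]
        dz_i = (4.0 * (x[i] - x0[i]) - z[i] - K * cpl) / tau0
        gx[i] = cx[i] * (-3.0 * x[i] ** 2 - 4.0 * x[i]) \
            + (4.0 * cz[i] - K * ctc) / tau0
        gz[i] = -cx[i] - cz[i] / tau0
        gx0[i] -= 4.0 * cz[i] / tau0
        acc[0] -= cz[i] * cpl / tau0   # dK
        acc[1] -= cz[i] * dz_i / tau0  # dtau0


@njit(cache=True)
def rk4_adjoint(ys, lam_x, x0, K, tau0, I1, C, substeps, h):
    """Reverse sweep of the RK4 recursion.

    ``ys`` is the substep-state array from :func:`rk4_forward`; ``lam_x``
    (n_obs, N) is the gradient of the log likelihood with respect to the
    latent x at each observation instant (the likelihood does not touch z).
    Returns (gx0, gx_init, gz_init, gK, gtau0).
    """
    n_obs, n = lam_x.shape
    rowsum = np.sum(C, axis=1)
    ax = np.zeros(n)
    az = np.zeros(n)
    gx0 = np.zeros(n)
    acc = np.zeros(2)
    k1x = np.empty(n); k1z = np.empty(n)
    k2x = np.empty(n); k2z = np.empty(n)
    y2x = np.empty(n); y2z = np.empty(n)
    y3x = np.empty(n); y3z = np.empty(n)
    y4x = np.empty(n); y4z = np.empty(n)
    cx = np.empty(n); cz = np.empty(n)
    g4x = np.empty(n); g4z = np.empty(n)
    g3x = np.empty(n); g3z = np.empty(n)
    g2x = np.empty(n); g2z = np.empty(n)
    g1x = np.empty(n); g1z = np.empty(n)
    total = n_obs * substeps
    for k in range(total, 0, -1):
        if k % substeps == 0:
            obs_idx = k // substeps - 1
            for i in range(n):
                ax[i] += lam_x[obs_idx, i]
        x = ys[k - 1, 0]
        z = ys[k - 1, 1]
        # recompute stage states
        _field_into(x, z, x0, K, tau0, I1, C, rowsum, k1x, k1z)
        for i in range(n):
            y2x[i] = x[i] + 0.5 * h * k1x[i]
            y2z[i] = z[i] + 0.5 * h * k1z[i]
        _field_into(y2x, y2z, x0, K, tau0, I1, C, rowsum, k2x, k2z)
        for i in range(n):
            y3x[i] = x[i] + 0.5 * h * k2x[i]
            y3z[i] = z[i] + 0.5 * h * k2z[i]
        # k3 is needed only through y4; reuse k1 buffers for k3
        _field_into(y3x, y3z, x0, K, tau0, I1, C, rowsum, k1x, k1z)
        for i in range(n):
            y4x[i] = x[i] + h * k1x[i]
            y4z[i] = z[i] + h * k1z[i]

        # stage 4
        for i in range(n):
            cx[i] = (h / 6.0) * ax[i]
            cz[i] = (h / 6.0) * az[i]
        _vjp_into(y4x, y4z, cx, cz, x0, K, tau0, I1, C, rowsum, g4x, g4z,
                  gx0, acc)
        # stage 3
        for i in range(n):
            cx[i] = (h / 3.0) * ax[i] + h * g4x[i]
            cz[i] = (h / 3.0) * az[i] + h * g4z[i]
        _vjp_into(y3x, y3z, cx, cz, x0, K, tau0, I1, C, rowsum, g3x, g3z,
                  gx0, acc)
        # stage 2
        for i in range(n):
            cx[i] = (h / 3.0) * ax[i] + 0.5 * h * g3x[i]
            cz[i] = (h / 3.0) * az[i] + 0.5 * h * g3z[i]
        _vjp_into(y2x, y2z, cx, cz, x0, K, tau0, I1, C, rowsum, g2x, g2z,
                  gx0, acc)
        # stage 1
        for i in range(n):
            cx[i] = (h / 6.0) * ax[i] + 0.5 * h * g2x[i]
            cz[i] = (h / 6.0) * az[i] + 0.5 * h * g2z[i]
        _vjp_into(x, z, cx, cz, x0, K, tau0, I1, C, rowsum, g1x, g1z,
                  gx0, acc)

        for i in range(n):
            ax[i] += g1x[i] + g2x[i] + g3x[i] + g4x[i]
            az[i] += g1z[i] + g2z[i] + g3z[i] + g4z[i]
    return gx0, ax, az, acc[0], acc[1]
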