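"""Inner integration kernels for the 2D-Epileptor likelihood.

The forward Euler recursion and its adjoint sweep are strictly
sequential in time, which makes them the only hot loops in the
inversion.  They are compiled with numba when available; the NumPy
fallback is mathematically identical (tests exercise the active one).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False, fastmath=False)
def euler_forward(x0, xinit, zinit, K, C, rowsum, I1, dt, tau0, stim, T):
    """Forward Euler of the 2D Epileptor; returns (x, z, ok)."""
    L = x0.shape[0]
    x = np.empty((T, L))
    z = np.empty((T, L))
    for i in range(L):
        x[0, i] = xinit[i]
        z[0, i] = zinit[i]
    ok = True
    for t in range(T - 1):
        for i in range(L):
            coup = 0.0
            for j in range(L):
                coup += C[i, j] * x[t, j]
            coup -= rowsum[i] * x[t, i]
            xt = x[t, i]
            dx = I1 - xt**3 - 2.0 * xt**2 - z[t, i] + stim[t, i]
            dz = (4.0 * (xt - x0[i]) - z[t, i] + K * coup) / tau0
            x[t + 1, i] = xt + dt * dx
            z[t + 1, i] = z[t, i] + dt * dz
            if not np.isfinite(x[t + 1, i]) or abs(x[t + 1, i]) > 1e6:
                ok = False
        if not ok:
            break
    return x, z, ok


@njit(cache=False, fastmath=False)
def euler_adjoint(x, obs_grad_x, C, rowsum, K, dt, tau0, stim):
    """Reverse-mode sweep; returns (g_xinit, g_zinit, g_x0, g_K, g_stim).

    ``g_stim`` is the gradient with respect to a scalar coefficient
    multiplying the (unscaled) stimulation pattern ``stim`` added to x'.
    """
    T, L = x.shape
    ax = np.empty(L)
    az = np.zeros(L)
    for i in range(L):
        ax[i] = obs_grad_x[T - 1, i]
    g_x0 = np.zeros(L)
    g_K = 0.0
    g_stim = 0.0
    c_over = dt / tau0
    ax_new = np.empty(L)
    az_new = np.empty(L)
    for t in range(T - 2, -1, -1):
        for i in range(L):
            coup = 0.0
            for j in range(L):
                coup += C[i, j] * x[t, j]
            coup -= rowsum[i] * x[t, i]
            g_x0[i] += az[i] * c_over * (-4.0)
            g_K += az[i] * coup * c_over
            g_stim += ax[i] * dt * stim[t, i]
        for i in range(L):
            cta = 0.0
            for j in range(L):
                cta += C[j, i] * az[j]
            xt = x[t, i]
            ax_new[i] = obs_grad_x[t, i] \
                + ax[i] * (1.0 + dt * (-3.0 * xt**2 - 4.0 * xt)) \
                + az[i] * c_over * (4.0 - K * rowsum[i]) \
                + c_over * K * cta
            az_new[i] = ax[i] * (-dt) + az[i] * (1.0 - c_over)
        for i in range(L):
            ax[i] = ax_new[i]
            az[i] = az_new[i]
    return ax, az, g_x0, g_K, g_stim
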