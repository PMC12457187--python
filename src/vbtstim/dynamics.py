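"""Epileptor dynamics: the 4-state stimulation field model and its 2D reduction.

The field model extends the phenomenological Epileptor with an accumulation
variable ``m`` that low-pass filters the stimulation input ``I_stim`` and,
once it crosses ``m_thresh``, switches a Heaviside term in the slow
permittivity equation that can move the node across the seizure threshold::

    x' = y - f1(x, z, m) - z + I_ext + I_stim
         + gamma_lc * sum_j S(g_ij) H(x_j, theta_lc)
         + gamma_gc * sum_l W_kl H(X_l, theta_gc)
    y' = c - d x^2 - y
    z' = r (4 (x - x0 + n H(m - m_thresh)) - z) + f2(z)
    m' = r (I_stim - m)

with f1 = a x^3 - b x^2 for x < 0 and -(m + 0.6 (z - 4)^2) x for x >= 0,
f2 = -0.1 z^7 for z < 0 else 0, H(v, th) = 1 iff v >= th, and the local
coupling kernel S(g) = exp(-|g|) / 2 over geodesic neighbor distances.

Sign convention of the Heaviside drive: with ``n`` positive the term raises
z, which *stabilizes* the node; the seizure-promoting direction is ``n``
negative.  Empirically (single-node sweeps with the default parameters) the
unstimulated seizure threshold sits near x0 = -1.2 and shifts to about
-2.2 when the Heaviside term is active with n = -1, so the canonical
excitability values -1.6 (epileptogenic: quiescent alone, seizes under
stimulation) and -2.5 (healthy: never seizes) behave as intended.  The
printed default remains ``n = 1``; stimulation studies in this package use
:data:`N_SEIZURE_PROMOTING`.

One model time unit corresponds to :data:`SECONDS_PER_TIME_UNIT` seconds
when simulated signals are given a physical sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.sparse import csr_matrix, diags

__all__ = [
    "EpileptorParams",
    "FieldState",
    "SourceActivity",
    "Reduced2DParams",
    "epileptor_rhs",
    "simulate_field",
    "simulate_reduced_2d",
    "local_coupling_matrix",
    "interictal_state",
    "node_seizes",
    "x0_seizure_threshold",
    "m_bifurcation_sweep",
    "heaviside",
    "laplacian_kernel",
]

#: physical duration of one model time unit, seconds.  Chosen so the fast
#: Epileptor discharges land in the tens-of-Hz band typical of ictal EEG.
SECONDS_PER_TIME_UNIT = 0.05

#: seizure-promoting sign of the Heaviside drive in z' (see module docstring)
N_SEIZURE_PROMOTING = -1.0

#: calibrated excitabilities for the 4D field model (single-node sweeps):
#: healthy tissue never seizes, epileptogenic tissue is quiescent without
#: stimulation but inside the Heaviside-shifted seizure regime
X0_FIELD_HEALTHY = -2.5
X0_FIELD_EPILEPTOGENIC = -1.6

#: canonical excitabilities on the reduced 2D scale
X0_2D_HEALTHY = -2.5
X0_2D_EPILEPTOGENIC = -1.6


def heaviside(x, theta):
    """H(x, theta) = 1 iff x >= theta (array-aware)."""
    return (np.asarray(x) >= theta).astype(float)


def laplacian_kernel(g):
    """Local coupling kernel S(g) = exp(-|g|) / 2."""
    return 0.5 * np.exp(-np.abs(g))


@dataclass
class EpileptorParams:
    """Parameters of the Epileptor-Stimulation field model (printed defaults).

    ``x0`` may be a scalar or a per-node array; ``lc_scale`` is a per-region
    multiplier of the local coupling rows (heterogeneity; within the EZN
    local connectivity may be set two to five times higher than elsewhere).
    ``b`` is the quadratic coefficient of the x < 0 branch of f1, absent
    from the printed defaults; 2 follows the original Epileptor.
    """

    I_ext: float = 3.1
    c: float = 1.0
    d: float = 5.0
    r: float = 1.0
    a: float = 1.0
    b: float = 2.0
    n: float = 1.0
    m_thresh: float = 1.8
    gamma_gc: float = 0.1
    gamma_lc: float = 0.8
    theta_gc: float = -1.0
    theta_lc: float = -1.0
    x0: float | np.ndarray = X0_FIELD_HEALTHY
    lc_scale: float | np.ndarray = 1.0

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not np.isfinite(self.m_thresh):
            raise ValueError("m_thresh must be finite")
        if np.any(np.asarray(self.lc_scale) <= 0):
            raise ValueError("lc_scale must be positive")


@dataclass
class FieldState:
    """State of the field model at one instant (per-node arrays)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    m: np.ndarray
    t: float = 0.0

    @classmethod
    def from_arrays(cls, x, y, z, m, t=0.0):
        return cls(*(np.atleast_1d(np.asarray(v, dtype=float))
                     for v in (x, y, z, m)), t=t)

    def copy(self):
        return FieldState(self.x.copy(), self.y.copy(), self.z.copy(),
                          self.m.copy(), self.t)


@dataclass
class SourceActivity:
    """Node-by-time activity of the fast variable x on a uniform grid."""

    times: np.ndarray
    values: np.ndarray  # (n_nodes, n_times)
    node_kind: str = "vertex"  # "vertex" | "region"

    def __post_init__(self):
        if self.values.shape[1] != len(self.times):
            raise ValueError("values and times are inconsistent")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def region_mean(self, region_of_vertex: np.ndarray, n_regions: int) -> "SourceActivity":
        """Average vertex activity within regions -> region-level activity."""
        if self.node_kind != "vertex":
            raise ValueError("already region-level")
        counts = np.bincount(region_of_vertex, minlength=n_regions).astype(float)
        sums = np.zeros((n_regions, self.values.shape[1]))
        np.add.at(sums, region_of_vertex, self.values)
        return SourceActivity(times=self.times,
                              values=sums / np.maximum(counts, 1.0)[:, None],
                              node_kind="region")

    def to_hdf5(self, path, **metadata):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("values", data=self.values)
            f.attrs["node_kind"] = self.node_kind
            for k, v in metadata.items():
                f.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path):
        import h5py
        with h5py.File(path, "r") as f:
            return cls(times=f["times"][()], values=f["values"][()],
                       node_kind=str(f.attrs["node_kind"]))


# ---------------------------------------------------------------------------
# right-hand sides


def _f1(x, z, m, p: EpileptorParams):
    neg = p.a * x**3 - p.b * x**2
    pos = -(m + 0.6 * (z - 4.0) ** 2) * x
    return np.where(x < 0, neg, pos)


def _f2(z):
    return np.where(z < 0, -0.1 * z**7, 0.0)


def epileptor_rhs(state: FieldState, params: EpileptorParams, I_stim,
                  lc_matrix: csr_matrix | None = None,
                  W: np.ndarray | None = None,
                  region_of_node: np.ndarray | None = None):
    """Time derivatives (dx, dy, dz, dm) of the field model at ``state``.

    ``lc_matrix`` is the precomputed (lc_scale-scaled) local coupling
    matrix of S(g_ij) weights; ``W`` and ``region_of_node`` drive the
    global coupling through per-region mean activity.
    """
    p = params
    x, y, z, m = state.x, state.y, state.z, state.m
    I_stim = np.asarray(I_stim, dtype=float)

    coupling = 0.0
    if lc_matrix is not None and p.gamma_lc != 0.0:
        coupling = coupling + p.gamma_lc * (lc_matrix @ heaviside(x, p.theta_lc))
    if W is not None and p.gamma_gc != 0.0:
        L = W.shape[0]
        counts = np.bincount(region_of_node, minlength=L).astype(float)
        X = np.bincount(region_of_node, weights=x, minlength=L) / np.maximum(counts, 1.0)
        coupling = coupling + p.gamma_gc * (W @ heaviside(X, p.theta_gc))[region_of_node]

    dx = y - _f1(x, z, m, p) - z + p.I_ext + I_stim + coupling
    dy = p.c - p.d * x**2 - y
    H = heaviside(m, p.m_thresh)
    dz = p.r * (4.0 * (x - np.asarray(p.x0) + p.n * H) - z) + _f2(z)
    dm = p.r * (I_stim - m)
    return dx, dy, dz, dm


class NonFiniteStateError(RuntimeError):
    """Integration produced a non-finite state; carries node and time."""

    def __init__(self, node: int, t: float):
        super().__init__(f"non-finite state at node {node}, t = {t:.4f}")
        self.node = node
        self.t = t


def _stim_column(stimulus, step: int, n_nodes: int):
    if stimulus is None:
        return 0.0
    if hasattr(stimulus, "at_step"):
        return stimulus.at_step(step)
    arr = np.asarray(stimulus)
    if arr.ndim == 2:
        return arr[:, step]
    return arr[step]


def simulate_field(
    params: EpileptorParams,
    n_nodes: int,
    dt: float,
    T: float,
    stimulus=None,
    init: FieldState | None = None,
    lc_matrix: csr_matrix | None = None,
    W: np.ndarray | None = None,
    region_of_node: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    clamp_m: float | np.ndarray | None = None,
    record_every: int = 1,
) -> tuple[SourceActivity, FieldState]:
    """Integrate the field model with fixed-step Heun over ``[0, T]``.

    Optional additive noise (stochastic Heun) acts on the fast variables
    x and y only.  ``clamp_m`` holds the accumulation variable fixed
    (bifurcation studies).  ``stimulus`` is anything exposing
    ``at_step(i) -> per-node input`` (see stimulation.StimulusInput), a
    dense (n_nodes, n_steps) array, or None.  Aborts with node/time
    diagnostics on the first non-finite state.
    """
    n_steps = int(round(T / dt))
    if init is None:
        st = interictal_state(params, n_nodes)
    else:
        st = init.copy()
    if clamp_m is not None:
        st.m = np.broadcast_to(np.asarray(clamp_m, float), (n_nodes,)).copy()
    rng = np.random.default_rng(seed)

    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    values = np.empty((n_nodes, n_rec))
    times[0] = st.t
    values[:, 0] = st.x
    i_rec = 1

    # overflow inside a diverging step is caught by the explicit
    # non-finite check below; silence the transient warnings
    errstate = np.errstate(over="ignore", invalid="ignore")
    errstate.__enter__()
    for i in range(n_steps):
        I_now = _stim_column(stimulus, i, n_nodes)
        I_next = _stim_column(stimulus, min(i + 1, n_steps - 1), n_nodes)
        d1 = epileptor_rhs(st, params, I_now, lc_matrix, W, region_of_node)
        if noise_sd > 0:
            xi_x = rng.standard_normal(n_nodes)
            xi_y = rng.standard_normal(n_nodes)
        pred = FieldState(st.x + dt * d1[0], st.y + dt * d1[1],
                          st.z + dt * d1[2], st.m + dt * d1[3], st.t + dt)
        if noise_sd > 0:
            pred.x += np.sqrt(dt) * noise_sd * xi_x
            pred.y += np.sqrt(dt) * noise_sd * xi_y
        if clamp_m is not None:
            pred.m = st.m
        d2 = epileptor_rhs(pred, params, I_next, lc_matrix, W, region_of_node)
        st.x += 0.5 * dt * (d1[0] + d2[0])
        st.y += 0.5 * dt * (d1[1] + d2[1])
        st.z += 0.5 * dt * (d1[2] + d2[2])
        if clamp_m is None:
            st.m += 0.5 * dt * (d1[3] + d2[3])
        if noise_sd > 0:
            st.x += np.sqrt(dt) * noise_sd * xi_x
            st.y += np.sqrt(dt) * noise_sd * xi_y
        st.t += dt
        bad = ~(np.isfinite(st.x) & np.isfinite(st.y)
                & np.isfinite(st.z) & np.isfinite(st.m))
        if np.any(bad):
            errstate.__exit__(None, None, None)
            raise NonFiniteStateError(int(np.argmax(bad)), st.t)
        if (i + 1) % record_every == 0:
            times[i_rec] = st.t
            values[:, i_rec] = st.x
            i_rec += 1
    errstate.__exit__(None, None, None)

    activity = SourceActivity(times=times[:i_rec], values=values[:, :i_rec],
                              node_kind="vertex")
    return activity, st


# ---------------------------------------------------------------------------
# reduced 2D Epileptor


@dataclass
class Reduced2DParams:
    """Reduced 2D Epileptor: x' = I1 - x^3 - 2 x^2 - z;
    z' = (1/tau0)(4 (x - x0) - z + K sum_j C_ij (x_j - x_i))."""

    x0: np.ndarray
    C: np.ndarray
    I1: float = 3.1
    tau0: float = 30.0
    K: float = 1.0

    def __post_init__(self):
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")
        self.x0 = np.atleast_1d(np.asarray(self.x0, dtype=float))
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (len(self.x0), len(self.x0)):
            raise ValueError("C must be (L, L) matching x0")


def reduced_2d_rhs(x, z, p: Reduced2DParams):
    rowsum = p.C.sum(axis=1)
    dx = p.I1 - x**3 - 2.0 * x**2 - z
    dz = (4.0 * (x - p.x0) - z + p.K * (p.C @ x - rowsum * x)) / p.tau0
    return dx, dz


def simulate_reduced_2d(params: Reduced2DParams, init: tuple[np.ndarray, np.ndarray],
                        dt: float, T: float) -> SourceActivity:
    """Deterministic fixed-step Heun integration of the 2D reduction."""
    x = np.array(init[0], dtype=float)
    z = np.array(init[1], dtype=float)
    n_steps = int(round(T / dt))
    L = len(x)
    values = np.empty((L, n_steps + 1))
    values[:, 0] = x
    for i in range(n_steps):
        dx1, dz1 = reduced_2d_rhs(x, z, params)
        dx2, dz2 = reduced_2d_rhs(x + dt * dx1, z + dt * dz1, params)
        x = x + 0.5 * dt * (dx1 + dx2)
        z = z + 0.5 * dt * (dz1 + dz2)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z))):
            raise NonFiniteStateError(int(np.argmax(~np.isfinite(x))), (i + 1) * dt)
        values[:, i + 1] = x
    return SourceActivity(times=np.arange(n_steps + 1) * dt, values=values,
                          node_kind="region")


# ---------------------------------------------------------------------------
# local coupling


def local_coupling_matrix(geo, lc_scale=1.0,
                          region_of_vertex: np.ndarray | None = None) -> csr_matrix:
    """Sparse vertex-by-vertex S(g_ij) weights, rows scaled per region.

    The self term (g = 0) is excluded; weights beyond the neighborhood
    cutoff are exactly zero by construction.
    """
    S = geo.dist.copy()
    S.data = laplacian_kernel(S.data)
    lc = np.asarray(lc_scale, dtype=float)
    if lc.ndim == 0:
        return (S * float(lc)).tocsr()
    if region_of_vertex is None:
        raise ValueError("per-region lc_scale needs region_of_vertex")
    row_scale = lc[region_of_vertex]
    return (diags(row_scale) @ S).tocsr()


# ---------------------------------------------------------------------------
# fixed points, thresholds, bifurcation utilities


def _z_of_x(x: float, x0: float, p: EpileptorParams, H: float) -> float:
    """Solve r(4(x - x0 + nH) - z) + f2(z) = 0 for z at given x."""
    target = 4.0 * (x - x0 + p.n * H)
    if target >= 0:
        return target  # f2 = 0 branch
    g = lambda z: p.r * (target - z) - 0.1 * z**7
    return brentq(g, -10.0, 0.0, xtol=1e-12)


def interictal_state(params: EpileptorParams, n_nodes: int = 1,
                     H: float = 0.0) -> FieldState:
    """Numerically located resting fixed point (m = 0, I_stim = 0).

    Solves the decoupled single-node equilibrium on the x < 0 branch by
    root finding and broadcasts it to all nodes (per-node x0 supported).
    Falls back to a generic down-state if no quiescent root exists.
    """
    p = params
    x0s = np.broadcast_to(np.asarray(p.x0, dtype=float), (n_nodes,))
    xs, ys, zs = np.empty(n_nodes), np.empty(n_nodes), np.empty(n_nodes)
    cache: dict[float, tuple[float, float, float]] = {}
    for i, x0 in enumerate(x0s):
        key = float(x0)
        if key not in cache:
            def resid(x):
                z = _z_of_x(x, key, p, H)
                y = p.c - p.d * x**2
                return y - (p.a * x**3 - p.b * x**2) - z + p.I_ext
            try:
                lo, hi = -4.0, -1e-9
                if resid(lo) * resid(hi) > 0:
                    raise ValueError
                xf = brentq(resid, lo, hi, xtol=1e-12)
                cache[key] = (xf, p.c - p.d * xf**2, _z_of_x(xf, key, p, H))
            except ValueError:
                cache[key] = (-1.8, p.c - p.d * 1.8**2, 3.0)
        xs[i], ys[i], zs[i] = cache[key]
    return FieldState(xs, ys, zs, np.zeros(n_nodes), 0.0)


def node_seizes(params: EpileptorParams, clamp_m: float | None = None,
                T: float = 60.0, dt: float = 0.01,
                threshold: float = 0.0) -> bool:
    """Whether a single decoupled node crosses x > threshold within T.

    A run that diverges after entering the up-state also counts as seizing
    (the crossing is detected before the abort by integrating in segments).
    """
    try:
        act, _ = simulate_field(params, n_nodes=1, dt=dt, T=T,
                                clamp_m=clamp_m, record_every=1)
        return bool(np.any(act.values > threshold))
    except NonFiniteStateError:
        return True  # blow-up only happens from the seizing up-state


def x0_seizure_threshold(params: EpileptorParams, clamp_m: float,
                         lo: float = -4.0, hi: float = 0.0,
                         tol: float = 1e-2, T: float = 60.0,
                         dt: float = 0.01) -> float:
    """Smallest x0 (within tol) at which a clamped-m node seizes.

    Bisection over x0; seizing is monotone increasing in x0 for this model.
    """
    p_lo = replace(params, x0=lo)
    p_hi = replace(params, x0=hi)
    if node_seizes(p_lo, clamp_m, T, dt) or not node_seizes(p_hi, clamp_m, T, dt):
        raise ValueError("bracket does not straddle the seizure threshold")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if node_seizes(replace(params, x0=mid), clamp_m, T, dt):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def m_bifurcation_sweep(params: EpileptorParams, m_grid,
                        T: float = 60.0, dt: float = 0.01):
    """Clamp m at each grid value; return (smallest seizing m, mask).

    The transition is expected at the smallest grid value >= m_thresh when
    x0 lies between the Heaviside-off and Heaviside-on seizure thresholds.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    mask = np.array([node_seizes(params, clamp_m=m, T=T, dt=dt) for m in m_grid])
    first = float(m_grid[np.argmax(mask)]) if mask.any() else np.nan
    return first, mask
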