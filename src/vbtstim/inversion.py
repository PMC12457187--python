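"""Bayesian inversion of envelope features with the reduced 2D Epileptor.

The generative model integrates the 2D Epileptor (per region i)

    x_i' = I1 - x_i^3 - 2 x_i^2 - z_i
    z_i' = (1/tau0) (4 (x_i - x0_i) - z_i + K sum_j C_ij (x_j - x_i))

with forward Euler on the (decimated) feature grid and maps the fast
variable through each modality's gain plus an affine observation model,

    pred_k(t) = alpha * sum_j g_jk x_j(t) + beta,

with iid Gaussian observation noise of scale sigma.  EEG blocks use the
elementwise-absolute gain.  The multimodal log likelihood is the sum of
the per-modality log likelihoods of the same source trajectory.

Free parameters: per-region excitabilities x0 and initial states x(t0),
z(t0), the global coupling scale K, per-modality alpha and beta, and
sigma.  Excitabilities and z(t0) are sampled in the eigenbasis V of
G^T G (G stacked channels-by-regions), which decorrelates the directions
the sensors actually see; V is orthonormal so priors and posteriors map
back and forth without Jacobian corrections.

Priors (identical across regions -- the prior belief is that every
region is healthy): x0 ~ N(-2.5, 1); x(t0), z(t0) ~ N around the healthy
fixed point; K and sigma half-normal (sampled on the log scale with the
exact Jacobian); alpha, beta weakly informative normal.

Gradients of the log posterior are computed exactly by reverse-mode
accumulation through the Euler recursion (adjoint states for x and z),
which makes MAP optimization and NUTS sampling cheap in pure NumPy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .features import TargetBundle
from .hmc import effective_sample_size, sample_nuts, split_rhat

__all__ = [
    "PriorConfig",
    "GenerativeModel",
    "Reparameterization",
    "Posterior",
    "reparameterize",
    "build_generative_model",
    "log_likelihood",
    "log_posterior_and_grad",
    "map_estimate",
    "sample_posterior",
    "convergence_diagnostics",
    "posterior_trajectories",
]


@dataclass
class PriorConfig:
    """Priors of the inversion; identical across regions by construction."""

    x0_mean: float = -2.5
    x0_sd: float = 1.0
    xinit_mean: float = -1.8
    xinit_sd: float = 0.5
    zinit_mean: float = 3.5
    zinit_sd: float = 0.5
    K_scale: float = 1.0  # half-normal
    #: alpha is positive (envelopes rise with source power); lognormal prior
    alpha_log_mean: float = 0.0
    alpha_log_sd: float = 1.0
    beta_mean: float = 0.0
    beta_sd: float = 10.0
    sigma_scale: float = 1.0  # half-normal
    #: stimulation-input gain is positive; lognormal prior on its log
    stim_log_mean: float = -1.0
    stim_log_sd: float = 1.5


@dataclass
class Reparameterization:
    """Orthonormal eigenbasis V of G^T G; x0* = V^T x0."""

    V: np.ndarray
    eigenvalues: np.ndarray

    def to_star(self, v: np.ndarray) -> np.ndarray:
        return self.V.T @ v

    def from_star(self, vstar: np.ndarray) -> np.ndarray:
        return self.V @ vstar


def reparameterize(gain) -> Reparameterization:
    """Eigenvectors of G^T G for a channels-by-sources G.

    Accepts a GainMatrix (sources x channels; transposed internally) or a
    raw (channels, sources) array.  Eigenvalues ascend; each eigenvector's
    sign is fixed by making its largest-magnitude component positive.
    Rank-deficient gains still yield a complete orthonormal basis.
    """
    G = np.asarray(getattr(gain, "values", gain), dtype=float)
    if hasattr(gain, "values"):
        G = G.T  # GainMatrix stores sources x sensors
    if G.size == 0:
        raise ValueError("empty gain matrix")
    A = G.T @ G
    eigvals, V = np.linalg.eigh(A)
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return Reparameterization(V=V * signs, eigenvalues=eigvals)


@dataclass
class GenerativeModel:
    """Everything the likelihood needs, plus the parameter layout."""

    L: int
    gains: list[np.ndarray]  # per block, (L, C_b); EEG already absolute
    targets: list[np.ndarray]  # per block, (C_b, T)
    modalities: list[str]
    dt: float
    tau0: float
    I1: float
    C: np.ndarray  # (L, L) connectome for the coupling term
    priors: PriorConfig
    repar: Reparameterization
    #: optional (T, L) stimulation pattern added to x' as c * stim_input;
    #: its scalar gain c is then a free parameter of the inversion
    stim_input: np.ndarray | None = None

    def __post_init__(self):
        if any(g.shape[0] != self.L for g in self.gains):
            raise ValueError("gain source dimension must equal L")
        if self.stim_input is not None:
            self.stim_input = np.asarray(self.stim_input, dtype=float)
            if self.stim_input.shape != (self.n_times, self.L):
                raise ValueError("stim_input must be (n_times, L)")

    @property
    def has_stim(self) -> bool:
        return self.stim_input is not None

    @property
    def n_blocks(self) -> int:
        return len(self.gains)

    @property
    def n_times(self) -> int:
        return self.targets[0].shape[1]

    @property
    def dim(self) -> int:
        return 3 * self.L + 1 + 2 * self.n_blocks + 1 + int(self.has_stim)

    # ---- parameter packing -------------------------------------------------

    def unpack(self, theta: np.ndarray) -> dict:
        L, B = self.L, self.n_blocks
        x0star = theta[:L]
        xinit = theta[L:2 * L]
        zinitstar = theta[2 * L:3 * L]
        u_K = theta[3 * L]
        u_alpha = theta[3 * L + 1:3 * L + 1 + B]
        beta = theta[3 * L + 1 + B:3 * L + 1 + 2 * B]
        u_stim = float(theta[3 * L + 1 + 2 * B]) if self.has_stim else None
        u_sigma = theta[-1]
        exp = lambda u: np.exp(np.minimum(u, 50.0))  # overflow-safe
        return dict(x0=self.repar.from_star(x0star), xinit=xinit,
                    zinit=self.repar.from_star(zinitstar),
                    K=float(exp(u_K)), alpha=exp(u_alpha), beta=beta,
                    sigma=float(exp(u_sigma)),
                    stim_coeff=float(exp(u_stim)) if self.has_stim else 0.0,
                    x0star=x0star, zinitstar=zinitstar, u_alpha=u_alpha,
                    u_stim=u_stim, u_K=float(u_K), u_sigma=float(u_sigma))

    def pack(self, x0, xinit, zinit, K, alpha, beta, sigma,
             stim_coeff: float | None = None) -> np.ndarray:
        parts = [
            self.repar.to_star(np.asarray(x0, float)),
            np.asarray(xinit, float),
            self.repar.to_star(np.asarray(zinit, float)),
            [np.log(K)], np.log(np.atleast_1d(alpha)), np.atleast_1d(beta),
        ]
        if self.has_stim:
            parts.append([np.log(0.37 if stim_coeff is None
                                 else float(stim_coeff))])
        parts.append([np.log(sigma)])
        return np.concatenate(parts)


def build_generative_model(
    bundle: TargetBundle,
    connectome_weights: np.ndarray,
    dt: float = 0.1,
    tau0: float = 30.0,
    I1: float = 3.1,
    priors: PriorConfig | None = None,
    normalize_gain: bool = True,
    stim_input: np.ndarray | None = None,
) -> GenerativeModel:
    """Assemble the generative model from an aligned target bundle.

    Gains are normalized to unit maximum magnitude per block so the
    observation scale is carried by alpha alone.  The reparameterization
    eigenbasis is computed from all blocks' channels stacked.
    """
    gains, targets, modalities = [], [], []
    for blk in bundle.blocks:
        g = np.asarray(blk.gain, dtype=float)
        if normalize_gain and np.abs(g).max() > 0:
            g = g / np.abs(g).max()
        gains.append(g)
        targets.append(np.asarray(blk.values, dtype=float))
        modalities.append(blk.modality)
    L = gains[0].shape[0]
    stacked = np.hstack(gains)  # (L, sum C_b)
    repar = reparameterize(stacked.T)  # channels x regions
    return GenerativeModel(L=L, gains=gains, targets=targets,
                           modalities=modalities, dt=dt, tau0=tau0, I1=I1,
                           C=np.asarray(connectome_weights, float),
                           priors=priors or PriorConfig(), repar=repar,
                           stim_input=stim_input)


# ---------------------------------------------------------------------------
# forward simulation and likelihood


def _stim_array(model: GenerativeModel) -> np.ndarray:
    if model.stim_input is not None:
        return np.asarray(model.stim_input, dtype=float)
    return np.zeros((model.n_times, model.L))


def _forward_2d(model: GenerativeModel, x0, xinit, zinit, K,
                stim_coeff: float = 0.0):
    """Euler-integrate the 2D Epileptor on the feature grid -> x (T, L)."""
    rowsum = model.C.sum(axis=1)
    x, z, ok = _kernels.euler_forward(
        np.asarray(x0, float), np.asarray(xinit, float),
        np.asarray(zinit, float), float(K), model.C, rowsum,
        model.I1, model.dt, model.tau0, stim_coeff * _stim_array(model),
        model.n_times)
    if not ok:
        return None, None
    return x, z


def log_likelihood(model: GenerativeModel, theta: np.ndarray) -> float:
    """Gaussian log likelihood of the target bundle at parameter ``theta``.

    The multimodal value is exactly the sum of the per-block values of
    the shared source trajectory.
    """
    p = model.unpack(theta)
    x, _ = _forward_2d(model, p["x0"], p["xinit"], p["zinit"], p["K"],
                       p["stim_coeff"])
    if x is None:
        return -np.inf
    sigma = p["sigma"]
    ll = 0.0
    for b in range(model.n_blocks):
        pred = p["alpha"][b] * (x @ model.gains[b]) + p["beta"][b]
        resid = pred - model.targets[b].T
        n = resid.size
        ll += -0.5 * np.sum((resid / sigma) ** 2) - n * np.log(sigma) \
            - 0.5 * n * np.log(2 * np.pi)
    return float(ll)


def log_posterior_and_grad(model: GenerativeModel,
                           theta: np.ndarray) -> tuple[float, np.ndarray]:
    """Log posterior and its exact gradient (adjoint through Euler).

    Returns (-inf, zeros) when the trajectory leaves the finite range,
    which the sampler treats as a rejected (divergent) proposal.
    """
    pr = model.priors
    p = model.unpack(theta)
    L, B, T, dt = model.L, model.n_blocks, model.n_times, model.dt
    x0, xinit, zinit = p["x0"], p["xinit"], p["zinit"]
    K, alpha, beta, sigma = p["K"], p["alpha"], p["beta"], p["sigma"]
    stim_coeff = p["stim_coeff"]
    rowsum = model.C.sum(axis=1)

    x, z = _forward_2d(model, x0, xinit, zinit, K, stim_coeff)
    if x is None:
        return -np.inf, np.zeros(model.dim)

    lp = 0.0
    obs_grad_x = np.zeros((T, L))
    g_alpha = np.zeros(B)
    g_beta = np.zeros(B)
    g_sigma = 0.0
    for b in range(B):
        Gb = model.gains[b]
        xg = x @ Gb  # (T, C_b)
        pred = alpha[b] * xg + beta[b]
        resid = pred - model.targets[b].T
        n = resid.size
        lp += -0.5 * np.sum((resid / sigma) ** 2) - n * np.log(sigma) \
            - 0.5 * n * np.log(2 * np.pi)
        dP = -resid / sigma**2  # dlp/dpred
        g_alpha[b] = np.sum(dP * xg)
        g_beta[b] = np.sum(dP)
        g_sigma += np.sum(resid**2) / sigma**3 - n / sigma
        obs_grad_x += alpha[b] * (dP @ Gb.T)

    # adjoint sweep through the Euler recursion
    g_xinit, g_zinit, g_x0, g_K, g_stim = _kernels.euler_adjoint(
        x, obs_grad_x, model.C, rowsum, K, dt, model.tau0,
        _stim_array(model))

    # priors (region space; V is orthonormal so no Jacobian)
    lp += -0.5 * np.sum(((x0 - pr.x0_mean) / pr.x0_sd) ** 2)
    g_x0 += -(x0 - pr.x0_mean) / pr.x0_sd**2
    lp += -0.5 * np.sum(((xinit - pr.xinit_mean) / pr.xinit_sd) ** 2)
    g_xinit += -(xinit - pr.xinit_mean) / pr.xinit_sd**2
    lp += -0.5 * np.sum(((zinit - pr.zinit_mean) / pr.zinit_sd) ** 2)
    g_zinit += -(zinit - pr.zinit_mean) / pr.zinit_sd**2
    # lognormal alpha: sample u = log alpha with a normal prior on u
    u_alpha = p["u_alpha"]
    lp += -0.5 * np.sum(((u_alpha - pr.alpha_log_mean) / pr.alpha_log_sd) ** 2)
    g_ualpha = g_alpha * alpha - (u_alpha - pr.alpha_log_mean) / pr.alpha_log_sd**2
    lp += -0.5 * np.sum(((beta - pr.beta_mean) / pr.beta_sd) ** 2)
    g_beta += -(beta - pr.beta_mean) / pr.beta_sd**2
    # half-normal on K and sigma, sampled on the log scale (+ Jacobian u)
    lp += -0.5 * (K / pr.K_scale) ** 2 + p["u_K"]
    g_uK = -(K / pr.K_scale) ** 2 + 1.0 + g_K * K
    lp += -0.5 * (sigma / pr.sigma_scale) ** 2 + p["u_sigma"]
    g_us = -(sigma / pr.sigma_scale) ** 2 + 1.0 + g_sigma * sigma

    parts = [model.repar.to_star(g_x0), g_xinit,
             model.repar.to_star(g_zinit), [g_uK], g_ualpha, g_beta]
    if model.has_stim:
        u_stim = p["u_stim"]
        lp += -0.5 * ((u_stim - pr.stim_log_mean) / pr.stim_log_sd) ** 2
        parts.append([g_stim * stim_coeff
                      - (u_stim - pr.stim_log_mean) / pr.stim_log_sd**2])
    parts.append([g_us])
    return float(lp), np.concatenate(parts)


# ---------------------------------------------------------------------------
# MAP estimation


@dataclass
class MapResult:
    theta: np.ndarray
    logp: float
    success: bool
    message: str = ""


def _random_init(model: GenerativeModel, rng: np.random.Generator) -> np.ndarray:
    pr = model.priors
    L, B = model.L, model.n_blocks
    x0 = pr.x0_mean + 0.5 * pr.x0_sd * rng.standard_normal(L)
    xinit = pr.xinit_mean + 0.3 * rng.standard_normal(L)
    zinit = pr.zinit_mean + 0.3 * rng.standard_normal(L)
    K = float(np.exp(0.5 * rng.standard_normal()) * 0.3)
    alpha = np.exp(0.3 * rng.standard_normal(B))
    beta = 0.3 * rng.standard_normal(B)
    sigma = float(np.exp(0.3 * rng.standard_normal()) * 0.5)
    stim_coeff = float(np.exp(-1.0 + 0.5 * rng.standard_normal())) \
        if model.has_stim else None
    return model.pack(x0, xinit, zinit, K, alpha, beta, sigma, stim_coeff)


def map_estimate(model: GenerativeModel, n_restarts: int = 50,
                 n_keep: int = 8, seed: int | None = None,
                 maxiter: int = 400) -> list[MapResult]:
    """Multi-start MAP: L-BFGS from randomized inits, best ``n_keep`` kept.

    Results are sorted by decreasing log posterior.  Raises if every
    restart fails, carrying the per-restart messages.
    """
    if n_keep > n_restarts:
        raise ValueError("n_keep must be <= n_restarts")
    rng = np.random.default_rng(seed)
    results: list[MapResult] = []
    failures: list[str] = []
    for _ in range(n_restarts):
        theta0 = _random_init(model, rng)

        def neg(theta):
            lp, g = log_posterior_and_grad(model, theta)
            if not np.isfinite(lp):
                return 1e12, np.zeros_like(theta)
            return -lp, -g

        res = minimize(neg, theta0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter})
        lp, _ = log_posterior_and_grad(model, res.x)
        if np.isfinite(lp):
            results.append(MapResult(theta=res.x, logp=lp,
                                     success=bool(res.success),
                                     message=str(res.message)))
        else:
            failures.append(str(res.message))
    if not results:
        raise RuntimeError("all MAP restarts failed: " + "; ".join(failures))
    results.sort(key=lambda r: r.logp, reverse=True)
    return results[:n_keep]


# ---------------------------------------------------------------------------
# posterior sampling


@dataclass
class Posterior:
    """Posterior draws in region space with sampler statistics."""

    model: GenerativeModel
    theta: np.ndarray  # (n_chains, n_draws, dim)
    logp: np.ndarray  # (n_chains, n_draws)
    n_divergent: int
    step_sizes: list[float] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def _map_draws(self, key: str) -> np.ndarray:
        nc, nd, _ = self.theta.shape
        flat = self.theta.reshape(nc * nd, -1)
        out = np.stack([self.model.unpack(th)[key] for th in flat])
        return out.reshape(nc, nd, *out.shape[1:])

    @property
    def x0(self) -> np.ndarray:  # (chains, draws, L)
        L = self.model.L
        x0star = self.theta[..., :L]
        return x0star @ self.model.repar.V.T

    @property
    def xinit(self) -> np.ndarray:
        L = self.model.L
        return self.theta[..., L:2 * L]

    @property
    def zinit(self) -> np.ndarray:
        L = self.model.L
        return self.theta[..., 2 * L:3 * L] @ self.model.repar.V.T

    @property
    def K(self) -> np.ndarray:
        return np.exp(self.theta[..., 3 * self.model.L])

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.theta[..., -1])

    def parameter_chains(self) -> dict[str, np.ndarray]:
        """Scalar parameter chains (chains, draws) keyed by name."""
        out = {}
        x0 = self.x0
        for i in range(self.model.L):
            out[f"x0[{i}]"] = x0[..., i]
        out["K"] = self.K
        out["sigma"] = self.sigma
        B = self.model.n_blocks
        base = 3 * self.model.L + 1
        for b in range(B):
            out[f"alpha[{b}]"] = np.exp(self.theta[..., base + b])
            out[f"beta[{b}]"] = self.theta[..., base + B + b]
        if self.model.has_stim:
            out["stim_coeff"] = np.exp(self.theta[..., base + 2 * B])
        return out

    def to_hdf5(self, path, **metadata):
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("theta", data=self.theta)
            f.create_dataset("logp", data=self.logp)
            f.create_dataset("x0", data=self.x0)
            f.attrs["n_divergent"] = self.n_divergent
            for k, v in metadata.items():
                f.attrs[k] = v


def _hessian_diag_inv_mass(model: GenerativeModel, theta: np.ndarray,
                           h: float = 1e-4) -> np.ndarray:
    """Inverse-mass seed: diagonal of the negative-log-posterior Hessian.

    Central differences of the exact gradient; clipped positive so flat
    or concave-up directions fall back to unit mass.
    """
    diag = np.empty(len(theta))
    for i in range(len(theta)):
        tp = theta.copy(); tp[i] += h
        tm = theta.copy(); tm[i] -= h
        _, gp = log_posterior_and_grad(model, tp)
        _, gm = log_posterior_and_grad(model, tm)
        diag[i] = -(gp[i] - gm[i]) / (2 * h)
    bad = ~np.isfinite(diag) | (diag <= 1e-8)
    diag[bad] = 1.0
    return 1.0 / diag


def sample_posterior(model: GenerativeModel, inits: list[np.ndarray],
                     n_chains: int = 16, draws: int = 500, warmup: int = 500,
                     seed: int | None = None, max_treedepth: int = 8,
                     target_accept: float = 0.9, hessian_mass: bool = True,
                     divergence_warn_frac: float = 0.1) -> Posterior:
    """NUTS over the reparameterized space, inits cycled over chains.

    The reference policy runs 16 chains from 8 MAP-optimized initial
    conditions (two chains per init).  By default each chain's diagonal
    mass matrix is fixed from the Hessian of the log posterior at its
    initial point (MAP seeding makes this a good preconditioner; warmup
    variance re-estimation is then disabled as it is unreliable on the
    multimodal seizure posterior).  Divergences above the warning
    fraction are reported but the run is still returned.
    """
    if not inits:
        raise ValueError("need at least one initial point")
    ss = np.random.SeedSequence(seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_chains)]
    all_draws, all_logp, steps = [], [], []
    n_div = 0
    if hessian_mass:
        masses = {i: _hessian_diag_inv_mass(model, np.asarray(th, float))
                  for i, th in enumerate(inits)}
    for c in range(n_chains):
        theta0 = np.asarray(inits[c % len(inits)], dtype=float)
        inv_mass0 = masses[c % len(inits)] if hessian_mass else None
        res = sample_nuts(lambda th: log_posterior_and_grad(model, th),
                          theta0, n_draws=draws, n_warmup=warmup,
                          seed=chain_seeds[c], max_treedepth=max_treedepth,
                          target_accept=target_accept,
                          adapt_mass=not hessian_mass, inv_mass0=inv_mass0)
        all_draws.append(res.draws)
        all_logp.append(res.logp)
        steps.append(res.step_size)
        n_div += res.n_divergent
    total = n_chains * (draws + warmup)
    if n_div > divergence_warn_frac * total:
        warnings.warn(f"{n_div} divergent transitions out of {total}")
    return Posterior(model=model, theta=np.stack(all_draws),
                     logp=np.stack(all_logp), n_divergent=n_div,
                     step_sizes=steps)


def convergence_diagnostics(posterior: Posterior) -> pd.DataFrame:
    """Split-chain scale reduction factor and ESS per scalar parameter."""
    chains = posterior.parameter_chains()
    rows = []
    single = posterior.n_chains < 2
    if single:
        warnings.warn("single chain: scale reduction factor unavailable")
    for name, c in chains.items():
        rows.append({
            "parameter": name,
            "rhat": np.nan if single else split_rhat(c),
            "ess": effective_sample_size(c),
            "mean": float(c.mean()),
            "sd": float(c.std()),
        })
    return pd.DataFrame(rows)


def posterior_trajectories(posterior: Posterior,
                           max_samples: int = 500,
                           seed: int | None = None) -> np.ndarray:
    """Source trajectories x(t) for a subsample of posterior draws.

    Returns (n_samples, L, T); the basis of epileptogenicity values.
    Vectorized Euler across draws.
    """
    model = posterior.model
    nc, nd, dim = posterior.theta.shape
    flat = posterior.theta.reshape(nc * nd, dim)
    rng = np.random.default_rng(seed)
    if len(flat) > max_samples:
        idx = rng.choice(len(flat), size=max_samples, replace=False)
        flat = flat[idx]
    S, L, T = len(flat), model.L, model.n_times
    V = model.repar.V
    x0 = flat[:, :L] @ V.T
    x = flat[:, L:2 * L].copy()
    z = (flat[:, 2 * L:3 * L] @ V.T)
    K = np.exp(flat[:, 3 * L])[:, None]
    if model.has_stim:
        cstim = np.exp(flat[:, 3 * L + 1 + 2 * model.n_blocks])[:, None]
    rowsum = model.C.sum(axis=1)
    out = np.empty((S, L, T))
    out[:, :, 0] = x
    dt = model.dt
    for t in range(T - 1):
        dx = model.I1 - x**3 - 2.0 * x**2 - z
        if model.has_stim:
            dx = dx + cstim * model.stim_input[t][None, :]
        dz = (4.0 * (x - x0) - z + K * (x @ model.C.T - rowsum * x)) / model.tau0
        x = x + dt * dx
        z = z + dt * dz
        np.clip(x, -1e6, 1e6, out=x)
        np.clip(z, -1e6, 1e6, out=z)
        out[:, :, t + 1] = x
    return out
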