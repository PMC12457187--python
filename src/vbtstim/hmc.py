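"""Adaptive Hamiltonian Monte Carlo (No-U-Turn sampler) and MCMC diagnostics.

A self-contained gradient-based sampler in the Stan family: dynamic
trajectory length via the No-U-Turn criterion (slice variant, recursive
doubling to a maximum depth), dual-averaging step-size adaptation toward a
target acceptance statistic, and diagonal mass-matrix estimation from the
second half of warmup.  The interface is a pluggable backend: any callable
``logp_and_grad(theta) -> (float, ndarray)`` can be sampled.

Diagnostics implement the classic split-chain potential scale reduction
factor and the initial-positive-sequence effective sample size; identical
chains give a scale reduction factor of exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NutsResult",
    "sample_nuts",
    "split_rhat",
    "effective_sample_size",
]

_MAX_DELTA_H = 1000.0  # divergence threshold on the energy error


@dataclass
class NutsResult:
    """Draws (n_draws, dim) of one chain plus sampler statistics."""

    draws: np.ndarray
    logp: np.ndarray
    step_size: float
    n_divergent: int
    accept_mean: float


def _leapfrog(theta, rho, grad, eps, logp_and_grad, inv_mass):
    rho = rho + 0.5 * eps * grad
    theta = theta + eps * rho * inv_mass
    lp, grad = logp_and_grad(theta)
    rho = rho + 0.5 * eps * grad
    return theta, rho, lp, grad


def _find_reasonable_step(theta, lp, grad, logp_and_grad, rng, inv_mass):
    eps = 1.0
    rho = rng.standard_normal(len(theta)) / np.sqrt(inv_mass)
    t1, r1, lp1, _ = _leapfrog(theta, rho, grad, eps, logp_and_grad, inv_mass)
    h0 = lp - 0.5 * np.sum(rho**2 * inv_mass)
    h1 = lp1 - 0.5 * np.sum(r1**2 * inv_mass)
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        t1, r1, lp1, _ = _leapfrog(theta, rho, grad, eps, logp_and_grad, inv_mass)
        h1 = lp1 - 0.5 * np.sum(r1**2 * inv_mass)
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) <= direction * np.log(0.5):
            break
    return eps


def sample_nuts(logp_and_grad, theta0: np.ndarray, n_draws: int = 500,
                n_warmup: int = 500, seed: int | None = None,
                max_treedepth: int = 8, target_accept: float = 0.8,
                adapt_mass: bool = True,
                inv_mass0: np.ndarray | None = None) -> NutsResult:
    """Run one NUTS chain from ``theta0``.

    Dual averaging adapts the step size during warmup; a diagonal mass
    matrix is estimated from the second half of warmup when
    ``adapt_mass`` (``inv_mass0`` seeds it, e.g. from a Hessian diagonal
    at a MAP point).  Fully deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    theta = np.array(theta0, dtype=float)
    dim = len(theta)
    lp, grad = logp_and_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    inv_mass = np.ones(dim) if inv_mass0 is None else np.asarray(inv_mass0, float)
    eps = _find_reasonable_step(theta, lp, grad, logp_and_grad, rng, inv_mass)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    n_div = 0
    accept_sum, accept_n = 0.0, 0
    welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)

    def tree(theta, rho, grad, logu, direction, depth, h0):
        """Recursive doubling; returns subtree state and a sample."""
        nonlocal n_div
        if depth == 0:
            t1, r1, lp1, g1 = _leapfrog(theta, rho, grad, direction * eps,
                                        logp_and_grad, inv_mass)
            h1 = lp1 - 0.5 * np.sum(r1**2 * inv_mass) if np.isfinite(lp1) else -np.inf
            n_ok = int(logu <= h1)
            diverged = (h0 - h1) > _MAX_DELTA_H or not np.isfinite(h1)
            if diverged:
                n_div += 1
            alpha = min(1.0, np.exp(min(0.0, h1 - h0)))
            return (t1, r1, g1, lp1), (t1, r1, g1, lp1), (t1, lp1, g1), n_ok, \
                not diverged, alpha, 1
        minus, plus, sample, n_ok, cont, alpha, n_alpha = tree(
            theta, rho, grad, logu, direction, depth - 1, h0)
        if cont:
            if direction == -1:
                minus, _, sample2, n2, cont2, a2, na2 = tree(
                    minus[0], minus[1], minus[2], logu, direction, depth - 1, h0)
            else:
                _, plus, sample2, n2, cont2, a2, na2 = tree(
                    plus[0], plus[1], plus[2], logu, direction, depth - 1, h0)
            if n2 > 0 and rng.random() < n2 / max(n_ok + n2, 1):
                sample = sample2
            n_ok += n2
            alpha += a2
            n_alpha += na2
            dtheta = plus[0] - minus[0]
            cont = cont2 and np.dot(dtheta, minus[1] * inv_mass) >= 0 \
                and np.dot(dtheta, plus[1] * inv_mass) >= 0
        return minus, plus, sample, n_ok, cont, alpha, n_alpha

    total = n_warmup + n_draws
    for it in range(total):
        rho0 = rng.standard_normal(dim) / np.sqrt(inv_mass)
        h0 = lp - 0.5 * np.sum(rho0**2 * inv_mass)
        logu = h0 + np.log(rng.random())
        minus = (theta, rho0, grad, lp)
        plus = (theta, rho0, grad, lp)
        sample = (theta, lp, grad)
        n_ok, cont, depth = 1, True, 0
        alpha_sum, n_alpha = 0.0, 0
        while cont and depth < max_treedepth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == -1:
                minus, _, sample2, n2, cont2, a2, na2 = tree(
                    minus[0], minus[1], minus[2], logu, direction, depth, h0)
            else:
                _, plus, sample2, n2, cont2, a2, na2 = tree(
                    plus[0], plus[1], plus[2], logu, direction, depth, h0)
            if cont2 and n2 > 0 and rng.random() < min(1.0, n2 / n_ok):
                sample = sample2
            n_ok += n2
            alpha_sum += a2
            n_alpha += na2
            dtheta = plus[0] - minus[0]
            cont = cont2 and np.dot(dtheta, minus[1] * inv_mass) >= 0 \
                and np.dot(dtheta, plus[1] * inv_mass) >= 0
            depth += 1
        theta, lp, grad = sample
        accept_stat = alpha_sum / max(n_alpha, 1)

        if it < n_warmup:
            frac = 1.0 / (it + 1 + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(it + 1) / gamma * h_bar
            w = (it + 1) ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if adapt_mass and it >= n_warmup // 2:
                welford_n += 1
                delta = theta - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (theta - welford_mean)
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
                if adapt_mass and welford_n > 10:
                    var = welford_m2 / (welford_n - 1)
                    inv_mass = np.maximum(var, 1e-8)
        else:
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = lp
            accept_sum += accept_stat
            accept_n += 1

    return NutsResult(draws=draws, logp=logps, step_size=eps,
                      n_divergent=n_div,
                      accept_mean=accept_sum / max(accept_n, 1))


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of one parameter.

    ``chains`` is (n_chains, n_draws).  Identical chains (zero between-
    and within-chain variance) return exactly 1.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    n = chains.shape[1] // 2
    if n < 1:
        raise ValueError("need at least 2 draws per chain")
    if np.all(chains == chains[0]):
        return 1.0  # exact copies carry no between-chain disagreement
    halves = np.vstack([chains[:, :n], chains[:, n:2 * n]])
    m = halves.shape[0]
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1) if m > 1 else 0.0
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def _autocovariance(x: np.ndarray) -> np.ndarray:
    n = len(x)
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    return acov


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS of one parameter via Geyer's initial positive sequence.

    ``chains`` is (n_chains, n_draws); autocorrelations are combined
    across chains using the within/between variance decomposition.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if n < 4:
        return float(m * n)
    acov = np.stack([_autocovariance(c) for c in chains])
    chain_var = acov[:, 0] * n / (n - 1)
    mean_var = chain_var.mean()
    var_plus = mean_var * (n - 1) / n
    if m > 1:
        var_plus += chains.mean(axis=1).var(ddof=1)
    if var_plus == 0:
        return float(m * n)
    rho = 1.0 - (mean_var - acov.mean(axis=0)) / var_plus
    # Geyer: sum consecutive pairs while they stay positive
    tau = 0.0
    for k in range(1, n - 2, 2):
        pair = rho[k] + rho[k + 1]
        if pair < 0:
            break
        tau += pair
    ess = m * n / (1.0 + 2.0 * tau)
    return float(min(ess, m * n * 10))
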