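"""Gradient-based MCMC: Hamiltonian Monte Carlo with adaptation.

A compact sampler for the smooth, unconstrained posteriors this package
produces: leapfrog HMC with a jittered number of steps, dual-averaging
step-size adaptation towards a target acceptance rate, and a dense mass
matrix seeded from the finite-difference Hessian at the posterior mode
and refined from warmup draws. The dense mass matters: the intercept of
the latent intensity, the thinning intercept and the detection rate are
only jointly identified, and their posterior ridge defeats a diagonal
preconditioner. Chains are independent and fully determined by their
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


def map_estimate(logpost_and_grad, x0: np.ndarray, maxiter: int = 500) -> np.ndarray:
    """Posterior mode via L-BFGS on the negative log posterior."""

    def neg(theta):
        lp, g = logpost_and_grad(theta)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(theta)
        return -lp, -g

    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x


def hessian(logpost_and_grad, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Negative Hessian by central differences of the gradient, symmetrised."""
    dim = len(x)
    H = np.empty((dim, dim))
    for i in range(dim):
        e = np.zeros(dim)
        e[i] = h
        _, gp = logpost_and_grad(x + e)
        _, gm = logpost_and_grad(x - e)
        H[i] = -(gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def hessian_diag(logpost_and_grad, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Diagonal of the negative Hessian (cheap curvature probe)."""
    return np.clip(np.diag(hessian(logpost_and_grad, x, h)), 1e-4, 1e6)


def _regularise_cov(S: np.ndarray, shrink: float = 0.1) -> np.ndarray:
    """Shrink a sample covariance toward its diagonal and jitter it SPD."""
    d = np.clip(np.diag(S), 1e-10, None)
    S = (1 - shrink) * S + shrink * np.diag(d)
    S[np.diag_indices_from(S)] += 1e-8 * d
    return S


def _chol_from_precision(H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Given a precision-like SPD matrix H, return (Sigma, A) with
    Sigma = H^{-1} and A = chol(Sigma) (lower)."""
    d = np.sqrt(np.clip(np.diag(H), 1e-8, None))
    Hs = H / np.outer(d, d)
    # ensure positive definiteness of the scaled matrix
    w, V = np.linalg.eigh(Hs)
    w = np.clip(w, 1e-6, None)
    Hs = (V * w) @ V.T
    Sigma = np.linalg.inv(Hs) / np.outer(d, d)
    return Sigma, np.linalg.cholesky(_regularise_cov(Sigma, 0.0))


@dataclass
class HMCResult:
    """Draws and sampler statistics for one set of chains.

    ``draws`` has shape (chains, n_samples, dim); warmup is discarded.
    """

    draws: np.ndarray
    accept_rate: np.ndarray
    step_size: np.ndarray


def _leapfrog(f, x, p, grad, eps, L, Sigma):
    p = p + 0.5 * eps * grad
    lp = -np.inf
    for _ in range(L):
        x = x + eps * (Sigma @ p)
        lp, grad = f(x)
        if not np.isfinite(lp):
            return x, p, lp, grad
        p = p + eps * grad
    p = p - 0.5 * eps * grad
    return x, p, lp, grad


def _hmc_chain(f, x0, n_warmup, n_samples, rng, target_accept, max_leapfrog, Sigma, A):
    """One chain. ``Sigma`` is the inverse mass (position scale), ``A`` its
    lower Cholesky; momenta are drawn by solving A' p = xi."""
    dim = len(x0)
    x = x0.copy()
    lp, grad = f(x)

    eps = 0.5
    mu = np.log(10 * eps)
    log_eps_bar, Hbar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_iter = 0

    win_lo, win_hi = int(0.15 * n_warmup), int(0.85 * n_warmup)
    window: list[np.ndarray] = []

    draws = np.empty((n_samples, dim))
    n_accept = 0
    for it in range(n_warmup + n_samples):
        L = int(rng.integers(1, max_leapfrog + 1))
        xi = rng.standard_normal(dim)
        p0 = linalg.solve_triangular(A, xi, lower=True, trans="T")
        H0 = -lp + 0.5 * float(p0 @ (Sigma @ p0))
        x1, p1, lp1, grad1 = _leapfrog(f, x, p0, grad, eps, L, Sigma)
        if np.isfinite(lp1):
            H1 = -lp1 + 0.5 * float(p1 @ (Sigma @ p1))
            a = float(np.exp(min(H0 - H1, 0.0)))
        else:
            a = 0.0
        if rng.random() < a:
            x, lp, grad = x1, lp1, grad1
            if it >= n_warmup:
                n_accept += 1

        if it < n_warmup:
            adapt_iter += 1
            frac = 1.0 / (adapt_iter + t0)
            Hbar = (1 - frac) * Hbar + frac * (target_accept - a)
            log_eps = mu - np.sqrt(adapt_iter) / gamma * Hbar
            eta = adapt_iter ** (-kappa)
            log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
            eps = float(np.exp(log_eps))
            if win_lo <= it < win_hi:
                window.append(x.copy())
            if it == win_hi - 1 and len(window) >= max(20, dim // 2):
                S = _regularise_cov(np.cov(np.asarray(window).T), shrink=0.2)
                Sigma = S
                A = np.linalg.cholesky(Sigma)
                eps = float(np.exp(log_eps_bar))
                mu = np.log(10 * eps)
                Hbar, adapt_iter = 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = x

    return draws, n_accept / max(n_samples, 1), eps


def sample_hmc(
    logpost_and_grad,
    x0: np.ndarray,
    n_chains: int = 4,
    n_warmup: int = 500,
    n_samples: int = 500,
    seed: int = 0,
    target_accept: float = 0.85,
    max_leapfrog: int = 24,
    jitter: float = 0.05,
    hess: np.ndarray | None = None,
) -> HMCResult:
    """Run independent HMC chains from jittered copies of ``x0``.

    ``hess`` is the negative Hessian at ``x0`` used to seed the dense
    inverse-mass matrix; when omitted it is computed by finite
    differences. The result is bit-reproducible for a fixed seed and
    settings.
    """
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    if hess is None:
        hess = hessian(logpost_and_grad, x0)
    Sigma0, A0 = _chol_from_precision(hess)
    draws = []
    accept = np.empty(n_chains)
    steps = np.empty(n_chains)
    for c in range(n_chains):
        rng = np.random.default_rng(seeds[c])
        start = x0 + jitter * (A0 @ rng.standard_normal(len(x0)))
        d, a, e = _hmc_chain(
            logpost_and_grad, start, n_warmup, n_samples, rng, target_accept,
            max_leapfrog, Sigma0.copy(), A0.copy(),
        )
        draws.append(d)
        accept[c] = a
        steps[c] = e
    return HMCResult(draws=np.asarray(draws), accept_rate=accept, step_size=steps)
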