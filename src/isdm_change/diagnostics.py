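"""Convergence and goodness-of-fit diagnostics.

Split-chain potential scale reduction (Rhat), effective sample size,
discrimination metrics for the presence-absence data (AUC and Tjur's
R²), and randomized-quantile (PIT) residuals with a Kolmogorov–Smirnov
uniformity check for the presence-only counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def split_chains(draws: np.ndarray) -> np.ndarray:
    """Split each chain in half: (C, n) → (2C, n//2)."""
    draws = np.atleast_2d(np.asarray(draws, float))
    c, n = draws.shape
    h = n // 2
    return np.concatenate([draws[:, :h], draws[:, n - h:]], axis=0)


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` is (chains, iterations) with at least 2 chains and 4 draws
    per chain. Chains are split in half, so C chains contribute 2C
    sequences. Returns NaN when the within-chain variance is zero
    (degenerate chains — Rhat is undefined, reported as such).
    """
    draws = np.atleast_2d(np.asarray(draws, float))
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("rhat needs >= 2 chains with >= 4 draws each")
    sp = split_chains(draws)
    m, n = sp.shape
    means = sp.mean(axis=1)
    W = sp.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return np.nan
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def ess(draws: np.ndarray) -> float:
    """Effective sample size from split chains (Geyer initial monotone).

    Autocovariances are averaged over chains; paired autocorrelations
    are summed while the pair sums stay positive and non-increasing.
    """
    sp = split_chains(np.asarray(draws, float))
    m, n = sp.shape
    if n < 4:
        raise ValueError("ess needs at least 4 draws per half-chain")
    means = sp.mean(axis=1)
    W = sp.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if var_plus <= 0 or W <= 0:
        return np.nan

    acov = np.zeros((m, n))
    for c in range(m):
        x = sp[c] - sp[c].mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov[c] = ac
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0

    # Geyer: sum consecutive pairs while positive and monotone.
    tau = 0.0
    prev = np.inf
    t = 0
    while t + 1 < n:
        pair = rho[t] + rho[t + 1] if t > 0 else 1.0 + rho[1]
        if pair < 0:
            break
        pair = min(pair, prev)
        prev = pair
        tau += pair
        t += 2
    tau = max(2 * tau - 1.0, 1.0)  # convert pair sum to 1 + 2 sum rho
    return float(m * n / tau)


def evaluate_pa(y: np.ndarray, pi: np.ndarray) -> tuple[float, float]:
    """AUC and Tjur's R² of fitted presence probabilities.

    AUC is the probability that a random presence outranks a random
    absence (ties count one half); Tjur's R² is the mean fitted
    probability at presences minus the mean at absences.
    """
    y = np.asarray(y)
    pi = np.asarray(pi, float)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC/Tjur need both presences and absences")
    ranks = stats.rankdata(pi)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    tjur = pi[y == 1].mean() - pi[y == 0].mean()
    return float(auc), float(tjur)


@dataclass
class PITResult:
    """Randomized-quantile residuals and their uniformity check."""

    residuals: np.ndarray
    ks_statistic: float
    p_value: float


def pit_residuals(observed: np.ndarray, predictive: np.ndarray, seed: int = 0) -> PITResult:
    """Randomized PIT residuals of counts against predictive draws.

    ``predictive`` is (n_draws, n_obs) with at least 100 draws. Each
    residual is the randomized rank of the observation among its
    predictive draws, u = (#draws<obs + V·(#draws=obs + 1))/(n_draws+1)
    with V ~ Uniform(0,1) — exactly Uniform(0,1) when the observation is
    exchangeable with the draws. A Kolmogorov–Smirnov statistic against
    Uniform(0,1) summarises calibration.
    """
    predictive = np.asarray(predictive)
    observed = np.asarray(observed).ravel()
    if predictive.ndim != 2 or predictive.shape[0] < 100:
        raise ValueError("need at least 100 predictive draws per observation")
    if predictive.shape[1] != observed.size:
        raise ValueError("predictive draws and observations disagree in length")
    rng = np.random.default_rng(seed)
    m = predictive.shape[0]
    lt = (predictive < observed[None, :]).sum(axis=0)
    eq = (predictive == observed[None, :]).sum(axis=0)
    v = rng.uniform(size=observed.size)
    u = (lt + v * (eq + 1)) / (m + 1)
    ks = stats.kstest(u, "uniform")
    return PITResult(residuals=u, ks_statistic=float(ks.statistic), p_value=float(ks.pvalue))
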