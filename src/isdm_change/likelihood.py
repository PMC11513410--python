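"""Joint likelihood of the integrated model, with analytic gradients.

The latent state is an inhomogeneous Poisson point process whose log
intensity per km² in cell i and period t is

    log lambda_it = b0 + x_i·b + bD·D_i + B_i·g + 1[t=2]·(tau + B_i·g2)

Two observation processes see this state:

* presence-only counts  n_it ~ Poisson(lambda_it · A_i · p_i · rho_t)
  with retention (thinning) p_i = expit(a0 + a_access·access_i + c_j(i))
  and the fixed sampling-effort ratio rho = (1, rho2);
* presence-absence blobs y_b ~ Bernoulli(pi_b) with
  pi_b = (1 − exp(−lambda_b·A_b)) · (1 − exp(−q·E_b)),
  lambda_b the area-weighted mean cell intensity over the blob.

The sampler works on an unconstrained vector; the spatial fields are
non-centred (g = sigma_g · g~ with g~ standard normal) and sigma_g,
sigma_g2, q are log-transformed with the Jacobian included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, log_expit

__all__ = [
    "LatentParams",
    "ObservationParams",
    "ParamLayout",
    "log_intensity",
    "po_loglik",
    "pa_loglik",
    "JointModel",
]


@dataclass
class LatentParams:
    """Parameters of the latent intensity."""

    beta0: float
    betas: np.ndarray
    tau: float
    beta_dist: float
    g: np.ndarray
    g2: np.ndarray


@dataclass
class ObservationParams:
    """Parameters of the two observation processes.

    ``country_effects`` is the full sum-to-zero vector.
    """

    alpha0: float
    alpha_access: float
    country_effects: np.ndarray
    q: float

    def __post_init__(self):
        if self.q <= 0:
            raise ValueError("detection rate q must be positive")
        if len(self.country_effects) and abs(self.country_effects.sum()) > 1e-6:
            raise ValueError("country effects must sum to zero")


def log_intensity(params: LatentParams, X, D, B, period: int) -> np.ndarray:
    """Per-unit intensity lambda for one period (1 or 2)."""
    eta = params.beta0 + X @ params.betas + params.beta_dist * np.asarray(D) + B @ params.g
    if period == 2:
        eta = eta + params.tau + B @ params.g2
    with np.errstate(over="ignore"):
        lam = np.exp(eta)
    if not np.all(np.isfinite(lam)):
        bad = int(np.flatnonzero(~np.isfinite(lam))[0])
        raise FloatingPointError(f"non-finite intensity at unit {bad}")
    return lam


def po_loglik(n, lam, A, p, rho) -> float:
    """Poisson log likelihood of thinned presence-only counts.

    ``n`` and ``lam`` are (cells, periods); ``A`` and ``p`` per cell;
    ``rho`` per period. Cells with zero mean and positive count yield
    −inf (an impossible observation).
    """
    n = np.asarray(n, float)
    mu = np.asarray(lam) * np.asarray(A)[:, None] * np.asarray(p)[:, None] * np.asarray(rho)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n > 0, n * np.log(mu), 0.0)
    if np.any((mu == 0) & (n > 0)):
        return -np.inf
    return float(np.sum(term - mu - gammaln(n + 1)))


def pa_loglik(y, lam_b, A_b, E_b, q) -> float:
    """Bernoulli log likelihood of blob detections.

    Success probability factorises as presence x detection:
    pi = (1 − exp(−lam_b·A_b)) · (1 − exp(−q·E_b)).
    """
    if q <= 0:
        raise ValueError("q must be positive")
    y = np.asarray(y, float)
    u = np.asarray(lam_b) * np.asarray(A_b)
    pi = -np.expm1(-u) * -np.expm1(-q * np.asarray(E_b))
    with np.errstate(divide="ignore"):
        ll = np.where(y == 1, np.log(pi), np.log1p(-pi))
    if np.any((pi == 0) & (y == 1)):
        return -np.inf
    return float(ll.sum())


@dataclass
class ParamLayout:
    """Index map of the flat unconstrained parameter vector."""

    n_cov: int
    K: int
    n_countries: int

    def __post_init__(self):
        k, K, J = self.n_cov, self.K, self.n_countries
        i = 0
        self.i_beta0 = i; i += 1
        self.s_betas = slice(i, i + k); i += k
        self.i_tau = i; i += 1
        self.i_bdist = i; i += 1
        self.s_g = slice(i, i + K); i += K
        self.s_g2 = slice(i, i + K); i += K
        self.i_alpha0 = i; i += 1
        self.i_aaccess = i; i += 1
        self.s_cfree = slice(i, i + max(J - 1, 0)); i += max(J - 1, 0)
        self.i_lsg = i; i += 1
        self.i_lsg2 = i; i += 1
        self.i_lq = i; i += 1
        self.dim = i

    def names(self) -> list[str]:
        out = ["beta0"]
        out += [f"beta_{j}" for j in range(self.n_cov)]
        out += ["tau", "beta_dist"]
        out += [f"g_{j}" for j in range(self.K)]
        out += [f"g2_{j}" for j in range(self.K)]
        out += ["alpha0", "alpha_access"]
        out += [f"c_free_{j}" for j in range(max(self.n_countries - 1, 0))]
        out += ["log_sigma_g", "log_sigma_g2", "log_q"]
        return out


class JointModel:
    """The unnormalised log posterior and its gradient on the flat vector.

    Holds the aligned design arrays for one species and evaluates
    log p(theta | data) = PO likelihood + PA likelihood + priors, plus
    the exact gradient, for use by gradient-based MCMC and MAP search.

    Priors: Normal(0, prior_scale²) on beta0, betas, tau, beta_dist,
    alpha0, alpha_access; Normal(0, sigma_c²) on the sum-to-zero country
    effects; non-centred Normal(0, sigma²) fields with Half-Normal(1) on
    sigma_g and sigma_g2; Exponential(1) on q.
    """

    def __init__(
        self,
        X: np.ndarray,
        D: np.ndarray,
        B: np.ndarray,
        areas: np.ndarray,
        access: np.ndarray,
        country: np.ndarray,
        n_counts: np.ndarray,
        W: np.ndarray,
        blob_area: np.ndarray,
        blob_effort: np.ndarray,
        blob_period: np.ndarray,
        y: np.ndarray,
        rho2: float = 1.0,
        n_countries: int | None = None,
        prior_scale: float = 10.0,
        sigma_c: float = 10.0,
    ):
        self.X = np.asarray(X, float)
        self.D = np.asarray(D, float)
        self.B = np.asarray(B, float)
        self.logA = np.log(np.asarray(areas, float))
        self.access = np.asarray(access, float)
        self.country = np.asarray(country, int)
        self.n = np.asarray(n_counts, float)
        self.W = np.asarray(W, float)
        self.blob_area = np.asarray(blob_area, float)
        self.blob_effort = np.asarray(blob_effort, float)
        self.blob_period = np.asarray(blob_period, int)
        self.y = np.asarray(y, float)
        self.log_rho = np.array([0.0, np.log(rho2)])
        self.J = int(n_countries if n_countries is not None else (self.country.max() + 1 if len(self.country) else 1))
        self.prior_scale = prior_scale
        self.sigma_c = sigma_c
        self.layout = ParamLayout(self.X.shape[1], self.B.shape[1], self.J)
        # Sum-to-zero completion for country effects.
        self._t1 = self.blob_period == 1
        self._t2 = self.blob_period == 2

    # -- parameter handling -------------------------------------------------

    def unpack(self, theta: np.ndarray) -> tuple[LatentParams, ObservationParams, dict]:
        L = self.layout
        sg = float(np.exp(theta[L.i_lsg]))
        sg2 = float(np.exp(theta[L.i_lsg2]))
        cf = theta[L.s_cfree]
        c_full = np.append(cf, -cf.sum()) if self.J > 1 else np.zeros(1)
        lat = LatentParams(
            beta0=float(theta[L.i_beta0]),
            betas=theta[L.s_betas].copy(),
            tau=float(theta[L.i_tau]),
            beta_dist=float(theta[L.i_bdist]),
            g=sg * theta[L.s_g],
            g2=sg2 * theta[L.s_g2],
        )
        obs = ObservationParams(
            alpha0=float(theta[L.i_alpha0]),
            alpha_access=float(theta[L.i_aaccess]),
            country_effects=c_full,
            q=float(np.exp(theta[L.i_lq])),
        )
        return lat, obs, {"sigma_g": sg, "sigma_g2": sg2}

    # -- log posterior ------------------------------------------------------

    def logpost_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        with np.errstate(over="ignore", invalid="ignore"):
            return self._logpost_and_grad(theta)

    def _logpost_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        L = self.layout
        X, D, B = self.X, self.D, self.B
        b0 = theta[L.i_beta0]
        b = theta[L.s_betas]
        tau = theta[L.i_tau]
        bD = theta[L.i_bdist]
        gt = theta[L.s_g]
        g2t = theta[L.s_g2]
        a0 = theta[L.i_alpha0]
        aa = theta[L.i_aaccess]
        cf = theta[L.s_cfree]
        lsg, lsg2, lq = theta[L.i_lsg], theta[L.i_lsg2], theta[L.i_lq]
        sg, sg2, q = np.exp(lsg), np.exp(lsg2), np.exp(lq)
        g = sg * gt
        g2 = sg2 * g2t

        eta1 = b0 + X @ b + bD * D + B @ g
        eta2 = eta1 + tau + B @ g2
        eta = np.column_stack([eta1, eta2])
        if np.any(eta > 60):  # e^60·A would overflow the Poisson mean
            return -np.inf, np.zeros(L.dim)
        lam = np.exp(eta)

        # presence-only
        c_full = np.append(cf, -cf.sum()) if self.J > 1 else np.zeros(1)
        z = a0 + aa * self.access + c_full[self.country]
        p = expit(z)
        logmu = eta + (self.logA + log_expit(z))[:, None] + self.log_rho[None, :]
        mu = np.exp(logmu)
        ll = float(np.sum(self.n * logmu - mu - gammaln(self.n + 1)))
        G_po = self.n - mu  # d ll_po / d eta_it; also drives the thinning grad
        G = G_po.copy()

        # presence-absence
        if len(self.y):
            lam_b = np.where(self._t1, self.W @ lam[:, 0], self.W @ lam[:, 1])
            u = lam_b * self.blob_area
            P = -np.expm1(-u)
            Q = -np.expm1(-q * self.blob_effort)
            pi = np.clip(P * Q, 1e-12, 1 - 1e-12)
            ll += float(np.sum(self.y * np.log(pi) + (1 - self.y) * np.log1p(-pi)))
            dpi = self.y / pi - (1 - self.y) / (1 - pi)
            coef = dpi * np.exp(-u) * Q * self.blob_area  # d ll / d lam_b · A_b
            for t, mask in ((0, self._t1), (1, self._t2)):
                if mask.any():
                    G[:, t] += (self.W[mask].T @ coef[mask]) * lam[:, t]
            dlq = float(np.sum(dpi * P * np.exp(-q * self.blob_effort) * q * self.blob_effort))
        else:
            dlq = 0.0

        Gsum = G.sum(axis=1)
        grad = np.zeros(L.dim)
        grad[L.i_beta0] = Gsum.sum()
        grad[L.s_betas] = X.T @ Gsum
        grad[L.i_tau] = G[:, 1].sum()
        grad[L.i_bdist] = D @ Gsum
        BtG = B.T @ Gsum
        BtG2 = B.T @ G[:, 1]
        grad[L.s_g] = sg * BtG
        grad[L.s_g2] = sg2 * BtG2
        grad[L.i_lsg] = BtG @ g
        grad[L.i_lsg2] = BtG2 @ g2
        H = G_po.sum(axis=1) * (1 - p)  # d ll / d z_i (PO only)
        grad[L.i_alpha0] = H.sum()
        grad[L.i_aaccess] = self.access @ H
        if self.J > 1:
            by_country = np.bincount(self.country, weights=H, minlength=self.J)
            grad[L.s_cfree] = by_country[:-1] - by_country[-1]
        grad[L.i_lq] = dlq

        # priors
        s2 = self.prior_scale**2
        for idx in (L.i_beta0, L.i_tau, L.i_bdist, L.i_alpha0, L.i_aaccess):
            ll += -0.5 * theta[idx] ** 2 / s2
            grad[idx] += -theta[idx] / s2
        ll += -0.5 * float(b @ b) / s2
        grad[L.s_betas] += -b / s2
        if self.J > 1:
            sc2 = self.sigma_c**2
            ll += -0.5 * float(c_full @ c_full) / sc2
            dc = -c_full / sc2
            grad[L.s_cfree] += dc[:-1] - dc[-1]
        ll += -0.5 * float(gt @ gt) - 0.5 * float(g2t @ g2t)
        grad[L.s_g] += -gt
        grad[L.s_g2] += -g2t
        # Half-Normal(1) on sigma = e^l with log-Jacobian l.
        ll += -0.5 * sg**2 + lsg - 0.5 * sg2**2 + lsg2
        grad[L.i_lsg] += -(sg**2) + 1.0
        grad[L.i_lsg2] += -(sg2**2) + 1.0
        # Exponential(1) on q = e^l with log-Jacobian l.
        ll += -q + lq
        grad[L.i_lq] += -q + 1.0

        if not np.isfinite(ll):
            return -np.inf, np.zeros(L.dim)
        return ll, grad

    def logpost(self, theta: np.ndarray) -> float:
        return self.logpost_and_grad(theta)[0]

    def intensity_draws(self, thetas: np.ndarray) -> np.ndarray:
        """Per-cell intensity lambda (draws, cells, 2) for a draw matrix."""
        out = np.empty((len(thetas), len(self.D), 2))
        for s, th in enumerate(np.atleast_2d(thetas)):
            lat, _, _ = self.unpack(th)
            out[s, :, 0] = log_intensity(lat, self.X, self.D, self.B, 1)
            out[s, :, 1] = log_intensity(lat, self.X, self.D, self.B, 2)
        return out
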