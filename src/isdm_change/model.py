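"""The integrated species distribution model estimator.

``IntegratedSDM`` fits the joint presence-only + presence-absence model
by Hamiltonian Monte Carlo and exposes the posterior, convergence
diagnostics (split-Rhat, ESS), presence-absence discrimination (AUC,
Tjur R²) and presence-only calibration (randomized-quantile residuals).
It follows the scikit-learn estimator protocol: constructor parameters
only configure, ``fit`` learns, fitted attributes carry a trailing
underscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .basis import spline_basis
from .diagnostics import PITResult, ess, evaluate_pa, pit_residuals, rhat
from .likelihood import JointModel
from .mcmc import hessian, map_estimate, sample_hmc
from .preprocess import ISDMData

RHAT_LIMIT = 1.1


@dataclass
class ModelSpec:
    """Declarative model configuration (priors, basis, sampler settings)."""

    covariates: list[str] | None = None
    spline_df: int = 16
    prior_scale: float = 10.0
    sigma_c: float = 10.0
    dist_scale_km: float = 1000.0
    use_effort_ratio: bool = True
    chains: int = 4
    iterations: int = 2000  # per chain, half warmup
    target_accept: float = 0.85
    max_leapfrog: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.spline_df < 4:
            raise ValueError("spline_df must be at least 4")
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if min(self.prior_scale, self.sigma_c) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass
class ISDMPosterior:
    """Posterior draws plus diagnostics for one fitted species model.

    ``theta`` is (chains, draws, dim) on the sampling scale;
    ``parameters`` maps readable names to (chains, draws) arrays with
    sigma_g, sigma_g2 and q back-transformed to their natural scale.
    """

    theta: np.ndarray
    param_names: list[str]
    model: JointModel = dc_field(repr=False, default=None)
    rhat: pd.Series = None
    ess: pd.Series = None
    accept_rate: np.ndarray = None
    converged: bool = False
    status: str = "not converged"
    auc: float | None = None
    tjur_r2: float | None = None
    pit: PITResult | None = None

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    @property
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for j, name in enumerate(self.param_names):
            v = self.theta[:, :, j]
            if name.startswith("log_"):
                out[name[4:]] = np.exp(v)
            else:
                out[name] = v
        return out

    def flat(self) -> np.ndarray:
        """(chains*draws, dim) draw matrix."""
        return self.theta.reshape(-1, self.theta.shape[-1])

    def lambda_draws(self, thin_to: int | None = None, seed: int = 0) -> np.ndarray:
        """Per-cell intensity draws (S, cells, 2); optionally subsampled."""
        flat = self.flat()
        if thin_to is not None and thin_to < len(flat):
            idx = np.sort(np.random.default_rng(seed).choice(len(flat), thin_to, replace=False))
            flat = flat[idx]
        return self.model.intensity_draws(flat)

    def blob_probability_draws(self) -> np.ndarray:
        """Posterior draws of the blob detection probability pi_b."""
        m = self.model
        flat = self.flat()
        lam = m.intensity_draws(flat)
        lam_b = np.where(
            m.blob_period[None, :] == 1,
            lam[:, :, 0] @ m.W.T,
            lam[:, :, 1] @ m.W.T,
        )
        q = np.exp(flat[:, m.layout.i_lq])[:, None]
        return -np.expm1(-lam_b * m.blob_area[None, :]) * -np.expm1(-q * m.blob_effort[None, :])

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, v in self.parameters.items():
            flat = v.ravel()
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(flat),
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    "q2.5": np.quantile(flat, 0.025),
                    "q97.5": np.quantile(flat, 0.975),
                    "rhat": self.rhat.get(name, np.nan) if self.rhat is not None else np.nan,
                    "ess": self.ess.get(name, np.nan) if self.ess is not None else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_tidy(self) -> pd.DataFrame:
        """Tidy (chain, draw, parameter, value) frame of all draws."""
        C, n, _ = self.theta.shape
        frames = []
        for name, v in self.parameters.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(C), n),
                        "draw": np.tile(np.arange(n), C),
                        "parameter": name,
                        "value": v.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class IntegratedSDM(BaseEstimator):
    """Bayesian integrated SDM over gridded counts and survey blobs.

    The latent log intensity is linear in the screened covariates, the
    distance to the expert range, a low-rank spatial spline field, and a
    period effect with its own (shrunk) interaction field. Presence-only
    counts follow a thinned Poisson observation model with an
    accessibility/country thinning probability and a fixed period-2
    effort ratio; blob detections follow a presence x detection
    Bernoulli model. See :class:`~isdm_change.likelihood.JointModel` for
    the exact densities and priors.

    Parameters mirror :class:`ModelSpec`; ``random_state`` seeds the
    sampler, making fits bit-reproducible.
    """

    def __init__(
        self,
        covariates: list[str] | None = None,
        spline_df: int = 16,
        prior_scale: float = 10.0,
        sigma_c: float = 10.0,
        dist_scale_km: float = 1000.0,
        use_effort_ratio: bool = True,
        chains: int = 4,
        iterations: int = 2000,
        target_accept: float = 0.85,
        max_leapfrog: int = 64,
        pit_draws: int = 400,
        random_state: int = 0,
    ):
        self.covariates = covariates
        self.spline_df = spline_df
        self.prior_scale = prior_scale
        self.sigma_c = sigma_c
        self.dist_scale_km = dist_scale_km
        self.use_effort_ratio = use_effort_ratio
        self.chains = chains
        self.iterations = iterations
        self.target_accept = target_accept
        self.max_leapfrog = max_leapfrog
        self.pit_draws = pit_draws
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _build_model(self, data: ISDMData) -> JointModel:
        grid = data.grid
        names = self.covariates if self.covariates is not None else grid.covariate_names
        if not names:
            raise ValueError("no covariates selected; attach or pass covariate names")
        X = grid.covariate_matrix(list(names))
        if "dist_range" not in grid.cells.columns:
            raise ValueError("grid lacks 'dist_range'; compute distance_to_range first")
        if "access" not in grid.cells.columns or "country" not in grid.cells.columns:
            raise ValueError("grid lacks thinning fields 'access'/'country'")
        D = grid.cells["dist_range"].to_numpy(float) / self.dist_scale_km
        B = spline_basis(grid.centroids, self.spline_df)
        bt = data.blob_table
        return JointModel(
            X=X,
            D=D,
            B=B,
            areas=grid.areas,
            access=grid.cells["access"].to_numpy(float),
            country=grid.cells["country"].to_numpy(int),
            n_counts=data.po_counts,
            W=data.blob_weights,
            blob_area=bt["area_km2"].to_numpy(float),
            blob_effort=bt["effort_days"].to_numpy(float),
            blob_period=bt["period"].to_numpy(int),
            y=bt["y"].to_numpy(float),
            rho2=data.effort_ratio if self.use_effort_ratio else 1.0,
            n_countries=int(grid.cells["country"].max()) + 1,
            prior_scale=self.prior_scale,
            sigma_c=self.sigma_c,
        )

    def fit(self, data: ISDMData, y=None) -> "IntegratedSDM":
        """Sample the posterior for one species' data bundle.

        A non-converged fit (any split-Rhat >= 1.1) does not raise: the
        posterior is returned with ``converged_ = False`` and downstream
        stages are expected to exclude the species.
        """
        model = self._build_model(data)
        warmup = self.iterations // 2
        n_samples = self.iterations - warmup

        x0 = np.zeros(model.layout.dim)
        x0[model.layout.i_lsg] = -1.0
        x0[model.layout.i_lsg2] = -1.5
        x0[model.layout.i_lq] = -6.0
        x_map = map_estimate(model.logpost_and_grad, x0)
        hess = hessian(model.logpost_and_grad, x_map)

        res = sample_hmc(
            model.logpost_and_grad,
            x_map,
            n_chains=self.chains,
            n_warmup=warmup,
            n_samples=n_samples,
            seed=self.random_state,
            target_accept=self.target_accept,
            max_leapfrog=self.max_leapfrog,
            hess=hess,
        )

        names = model.layout.names()
        rhats = pd.Series({nm: rhat(res.draws[:, :, j]) for j, nm in enumerate(names)})
        esss = pd.Series({nm: ess(res.draws[:, :, j]) for j, nm in enumerate(names)})
        # natural-scale names for the report
        rhats.index = [nm[4:] if nm.startswith("log_") else nm for nm in rhats.index]
        esss.index = rhats.index
        converged = bool((rhats.dropna() < RHAT_LIMIT).all())

        post = ISDMPosterior(
            theta=res.draws,
            param_names=names,
            model=model,
            rhat=rhats,
            ess=esss,
            accept_rate=res.accept_rate,
            converged=converged,
            status="converged" if converged else "not converged",
        )

        yb = model.y
        if len(yb) and 0 < yb.sum() < len(yb):
            pi_med = np.median(post.blob_probability_draws(), axis=0)
            post.auc, post.tjur_r2 = evaluate_pa(yb, pi_med)
        post.pit = self._po_pit(post, model)

        self.model_ = model
        self.posterior_ = post
        self.rhat_ = rhats
        self.ess_ = esss
        self.converged_ = converged
        self.auc_ = post.auc
        self.tjur_r2_ = post.tjur_r2
        self.pit_ = post.pit
        self.data_ = data
        return self

    def _po_pit(self, post: ISDMPosterior, model: JointModel) -> PITResult:
        """Randomized-quantile residuals of the PO counts against the
        posterior predictive distribution."""
        flat = post.flat()
        m = self.pit_draws
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 101]))
        # resample with replacement when the chain is shorter than the
        # requested predictive sample
        idx = np.sort(rng.choice(len(flat), m, replace=len(flat) < m))
        lam = model.intensity_draws(flat[idx])
        rep = np.empty((m, model.n.size))
        from scipy.special import expit

        for s, theta in enumerate(flat[idx]):
            _, obs, _ = model.unpack(theta)
            p = expit(obs.alpha0 + obs.alpha_access * model.access + obs.country_effects[model.country])
            mu = lam[s] * np.exp(model.logA)[:, None] * p[:, None] * np.exp(model.log_rho)[None, :]
            rep[s] = rng.poisson(mu).ravel()
        return pit_residuals(model.n.ravel(), rep, seed=self.random_state + 7)

    # ------------------------------------------------------------------

    def predict_lambda(self, thin_to: int | None = None) -> np.ndarray:
        """Posterior intensity draws (S, cells, 2)."""
        check_is_fitted(self, "posterior_")
        return self.posterior_.lambda_draws(thin_to=thin_to, seed=self.random_state)

    def predict_occupancy(self, thin_to: int | None = None):
        """Posterior occupancy surface P = 1 − exp(−lambda·A)."""
        from .change import occupancy_probability

        check_is_fitted(self, "posterior_")
        lam = self.predict_lambda(thin_to=thin_to)
        return occupancy_probability(lam, self.data_.grid.areas)


def fit_isdm(data: ISDMData, spec: ModelSpec | None = None) -> ISDMPosterior:
    """Functional wrapper: fit the integrated model and return the posterior."""
    spec = spec or ModelSpec()
    est = IntegratedSDM(
        covariates=spec.covariates,
        spline_df=spec.spline_df,
        prior_scale=spec.prior_scale,
        sigma_c=spec.sigma_c,
        dist_scale_km=spec.dist_scale_km,
        use_effort_ratio=spec.use_effort_ratio,
        chains=spec.chains,
        iterations=spec.iterations,
        target_accept=spec.target_accept,
        max_leapfrog=spec.max_leapfrog,
        random_state=spec.seed,
    )
    est.fit(data)
    return est.posterior_
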