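"""Bayesian LASSO regression on marker dosages (Park & Casella sampler).

The model is

    ybar_i = mu + sum_j x_ij beta_j + eps_i,   eps_i ~ N(0, sigma2_eps / n_i)

with the double-exponential prior on marker effects expressed as the usual
scale mixture of normals: beta_j | tau2_j, sigma2 ~ N(0, tau2_j sigma2),
tau2_j ~ Exp(lambda^2 / 2), lambda^2 ~ Gamma(shape s, rate r), and a
scaled-inverse-chi-square prior on sigma2_eps with df = 4 and scale S = 1
(prior mean S/(df-2) = 0.5, i.e. half the unit variance of standardized
phenotypes).  Defaults s = 0.6 and r = 1e-4 put the induced prior mode of
lambda at sqrt((2s-1)/(2r)) ~ 31.6 and leave the prior flat over a wide
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._samplers import bl_gibbs
from .data import StandardizedPhenotypes

__all__ = ["BLHyperparams", "BayesianLasso", "BayesianLassoResults", "lambda_heuristic"]


@dataclass(frozen=True)
class BLHyperparams:
    """Prior settings and chain controls for the Bayesian LASSO."""

    df_residual: float = 4.0
    scale_residual: float = 1.0
    lambda_shape: float = 0.6
    lambda_rate: float = 1e-4
    n_iter: int = 30_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.df_residual <= 2:
            raise ValueError("df_residual must exceed 2")
        if self.lambda_shape <= 0 or self.lambda_rate <= 0:
            raise ValueError("lambda prior shape and rate must be positive")
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def lambda_prior_mode(self) -> float:
        """Mode of the prior induced on lambda by Gamma(s, r) on lambda^2.

        The density of lambda is proportional to lambda^(2s-1) exp(-r lambda^2),
        maximized at sqrt((2s-1)/(2r)) when s > 1/2.
        """
        if 2 * self.lambda_shape <= 1:
            return 0.0
        return float(np.sqrt((2 * self.lambda_shape - 1) / (2 * self.lambda_rate)))

    @property
    def residual_prior_mean(self) -> float:
        return self.scale_residual / (self.df_residual - 2)


def lambda_heuristic(h2: float, genotypes) -> float:
    """Prior-centering heuristic: sqrt(((1 - h2)/h2) * MSx).

    MSx is the average across lines of the sum of squared marker codes.
    Used only to sanity-check the prior location; lambda is sampled.
    """
    if not 0 < h2 < 1:
        raise ValueError("h2 must lie strictly between 0 and 1")
    X = genotypes.values if hasattr(genotypes, "values") else np.asarray(genotypes)
    msx = float(np.mean(np.sum(np.asarray(X, dtype=float) ** 2, axis=1)))
    return float(np.sqrt((1.0 - h2) / h2 * msx))


class BayesianLasso:
    """Model object: standardized phenotypes regressed on a covariate matrix.

    Parameters
    ----------
    endog : StandardizedPhenotypes or 1-D array
        Response.  When a plain array is passed, all replicate counts are 1.
    exog : 2-D array or CovariateMatrix
        Marker (or marker-product) covariates, one row per line.
    center : bool
        Center covariate columns before sampling (off by default; marker
        codes enter raw).
    """

    def __init__(self, endog, exog, center: bool = False):
        if isinstance(endog, StandardizedPhenotypes):
            self.y = np.asarray(endog.ybar, dtype=float)
            self.weights = np.asarray(endog.n_i, dtype=float)
            self.line_ids = list(endog.line_ids)
        else:
            self.y = np.asarray(endog, dtype=float)
            self.weights = np.ones_like(self.y)
            self.line_ids = None
        X = exog.values if hasattr(exog, "values") else np.asarray(exog)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError(
                f"exog must be 2-D with {self.y.size} rows, got {self.X.shape}"
            )
        if not np.all(np.isfinite(self.y)) or not np.all(np.isfinite(self.X)):
            raise ValueError("endog and exog must be finite")
        self.center = center
        self._offset = self.X.mean(axis=0) if center else np.zeros(self.X.shape[1])

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def fit(self, hyper: BLHyperparams | None = None, lambda_fixed: float | None = None,
            store_beta_chain: bool | None = None, **chain_kw) -> "BayesianLassoResults":
        """Run the Gibbs sampler and return posterior summaries.

        ``chain_kw`` may override n_iter / burn_in / thin / seed of ``hyper``.
        ``lambda_fixed`` pins the regularization parameter instead of
        sampling it.
        """
        hp = hyper or BLHyperparams()
        if chain_kw:
            hp = replace(hp, **chain_kw)
        if store_beta_chain is None:
            store_beta_chain = self.p <= 1000
        XT = np.ascontiguousarray((self.X - self._offset).T)
        out = bl_gibbs(
            self.y,
            XT,
            self.weights,
            float(hp.df_residual),
            float(hp.scale_residual),
            float(hp.lambda_shape),
            float(hp.lambda_rate),
            int(hp.n_iter),
            int(hp.burn_in),
            int(hp.thin),
            int(hp.seed) % (2**31 - 1),
            bool(store_beta_chain),
            -1.0 if lambda_fixed is None else float(lambda_fixed),
        )
        (mu, beta, beta_sd, sigma2, lam, c_mu, c_s2, c_lam, c_beta) = out
        if not (np.isfinite(mu) and np.all(np.isfinite(beta))):
            raise FloatingPointError("Bayesian LASSO chain produced non-finite draws")
        chains = {"mu": c_mu, "sigma2_eps": c_s2, "lambda": c_lam}
        if store_beta_chain:
            chains["beta"] = c_beta
        return BayesianLassoResults(
            model=self, mu=float(mu), beta=beta, beta_sd=beta_sd,
            sigma2_eps=float(sigma2), lambda_=float(lam), hyper=hp, chains=chains,
        )


@dataclass
class BayesianLassoResults:
    """Posterior summaries of a Bayesian LASSO fit."""

    model: BayesianLasso
    mu: float
    beta: np.ndarray
    beta_sd: np.ndarray
    sigma2_eps: float
    lambda_: float
    hyper: BLHyperparams
    chains: dict = field(default_factory=dict)

    @property
    def params(self) -> np.ndarray:
        return self.beta

    @property
    def n_samples(self) -> int:
        return self.chains["mu"].size

    def predict(self, exog) -> np.ndarray:
        """Posterior-mean prediction mu + X_new beta for new covariate rows."""
        X = exog.values if hasattr(exog, "values") else np.asarray(exog)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.p:
            raise ValueError(f"exog must have {self.model.p} columns, got {X.shape}")
        return self.mu + (X - self.model._offset) @ self.beta

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    def summary(self) -> str:
        hp = self.hyper
        top = np.argsort(-np.abs(self.beta))[:10]
        lines = [
            "Bayesian LASSO regression (Park-Casella Gibbs sampler)",
            f"  lines: {self.model.n}   covariates: {self.model.p}",
            f"  chain: {hp.n_iter} iter, burn-in {hp.burn_in}, thin {hp.thin}, "
            f"{self.n_samples} samples, seed {hp.seed}",
            f"  posterior mean mu        = {self.mu: .4f}",
            f"  posterior mean sigma2_e  = {self.sigma2_eps: .4f}",
            f"  posterior mean lambda    = {self.lambda_: .2f} "
            f"(prior mode {hp.lambda_prior_mode:.1f})",
            "  largest |beta| (posterior mean +/- SD):",
        ]
        for j in top:
            lines.append(f"    beta[{j:>5d}] = {self.beta[j]: .4f} +/- {self.beta_sd[j]:.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta_mean": self.beta, "beta_sd": self.beta_sd},
        )
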