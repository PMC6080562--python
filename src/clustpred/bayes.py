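"""Bayesian random-intercept logistic regression by Gibbs sampling.

Priors: normal N(0, 1000) on each fixed-effect coefficient and
inverse-gamma(0.001, 0.001) on the between-cluster variance (weakly
informative defaults).  The sampler uses Polya-Gamma data augmentation:
given PG(1, eta_ij) latent variables the joint conditional of all fixed and
random effects is Gaussian, and the conditional of sigma_u^2 given the
random effects is inverse-gamma(shape_0 + J/2, rate_0 + sum(u^2)/2) — exact
conjugacy throughout, no tuning parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._polyagamma import pg_draws
from .datagen import ClusteredDataset

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "BayesRandomInterceptLogit",
    "sample_sigma2_conditional",
    "potential_scale_reduction",
]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters: N(beta_mean, beta_variance) for coefficients,
    inverse-gamma(sigma2_shape, sigma2_rate) for the random-effect variance."""

    beta_mean: float = 0.0
    beta_variance: float = 1000.0
    sigma2_shape: float = 0.001
    sigma2_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.beta_variance <= 0 or self.sigma2_shape <= 0 or self.sigma2_rate <= 0:
            raise ValueError("prior scale parameters must be positive")


def sample_sigma2_conditional(
    u: np.ndarray, priors: PriorSpec, rng: np.random.Generator
) -> float:
    """One draw of sigma_u^2 | u ~ IG(shape_0 + J/2, rate_0 + sum(u^2)/2)."""
    shape = priors.sigma2_shape + u.size / 2.0
    rate = priors.sigma2_rate + 0.5 * float(u @ u)
    return rate / rng.gamma(shape)


def potential_scale_reduction(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Values near 1 indicate that
    between-chain variance is negligible relative to within-chain variance.
    """
    chains = np.asarray(chains, float)
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least two chains")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorDraws:
    """Saved MCMC draws of (beta0, beta1, sigma_u2) plus bookkeeping.

    ``df`` has one row per saved draw with columns chain, iteration, beta0,
    beta1, sigma_u2 (iteration = burn_in + thin * s for s = 1..n_save).
    """

    df: pd.DataFrame
    thin: int
    burn_in: int
    converged: Optional[bool] = None

    @property
    def n_draws(self) -> int:
        return len(self.df)

    @property
    def n_chains(self) -> int:
        return self.df["chain"].nunique()

    @property
    def beta0(self) -> np.ndarray:
        return self.df["beta0"].to_numpy()

    @property
    def beta1(self) -> np.ndarray:
        return self.df["beta1"].to_numpy()

    @property
    def sigma_u2(self) -> np.ndarray:
        return self.df["sigma_u2"].to_numpy()

    def rhat(self) -> dict[str, float]:
        """Potential scale reduction factor per parameter."""
        out = {}
        for par in ("beta0", "beta1", "sigma_u2"):
            wide = self.df.pivot_table(
                index="iteration", columns="chain", values=par, sort=True
            ).to_numpy().T
            out[par] = potential_scale_reduction(wide)
        return out

    def check_convergence(self, threshold: float = 1.1) -> dict:
        """Flag the draws with a pass iff every R-hat is below ``threshold``."""
        rhats = self.rhat()
        passed = all(v < threshold for v in rhats.values())
        self.converged = passed
        return {"rhat": rhats, "passed": passed, "threshold": threshold}

    def summary(self) -> pd.DataFrame:
        stats = self.df[["beta0", "beta1", "sigma_u2"]].agg(
            ["mean", "median", "std"]
        ).T
        stats["rhat"] = pd.Series(self.rhat())
        return stats

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str, thin: int = 1, burn_in: int = 0) -> "PosteriorDraws":
        return cls(pd.read_csv(path), thin=thin, burn_in=burn_in)


class BayesRandomInterceptLogit:
    """Gibbs sampler for the random-intercept logistic model.

    Parameters mirror :class:`clustpred.glmm.RandomInterceptLogit`; the
    model here is always the two-coefficient development model
    (intercept + predictor + cluster random intercepts).
    """

    def __init__(self, endog, exog, groups, priors: PriorSpec | None = None):
        self.endog = np.asarray(endog, float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
        self.group_labels = labels
        self.group_index = np.asarray(gidx, np.int64)
        self.n_groups = labels.size
        self.priors = priors or PriorSpec()

    @classmethod
    def from_dataset(
        cls, data: ClusteredDataset, priors: PriorSpec | None = None
    ) -> "BayesRandomInterceptLogit":
        X = np.column_stack([np.ones(data.n), data.x])
        return cls(data.y, X, data.df["cluster_id"].to_numpy(), priors)

    # -- sampling ---------------------------------------------------------

    def _run_chain(
        self,
        n_iter: int,
        rng: np.random.Generator,
        keep_mask: np.ndarray,
        fix_u_zero: bool,
        fixed_sigma2: Optional[float],
        init_beta: np.ndarray,
    ) -> np.ndarray:
        X, y, gidx, J = self.exog, self.endog, self.group_index, self.n_groups
        n, p = X.shape
        pr = self.priors
        kappa = y - 0.5
        Xt_kappa = X.T @ kappa
        Zt_kappa = np.bincount(gidx, weights=kappa, minlength=J)
        prior_prec_beta = 1.0 / pr.beta_variance
        prior_mean_term = pr.beta_mean * prior_prec_beta

        beta = init_beta.copy()
        u = np.zeros(J)
        sigma2 = fixed_sigma2 if fixed_sigma2 is not None else 1.0

        d = p if fix_u_zero else p + J
        rhs0 = np.concatenate([Xt_kappa + prior_mean_term, Zt_kappa])[:d]
        out = np.empty((int(keep_mask.sum()), 3))
        k_out = 0
        for it in range(n_iter):
            eta = X @ beta + u[gidx]
            omega = pg_draws(eta, rng.integers(2**31))

            Xw = X * omega[:, None]
            XtOX = Xw.T @ X
            P = np.empty((d, d))
            P[:p, :p] = XtOX + prior_prec_beta * np.eye(p)
            if not fix_u_zero:
                XtOZ = np.vstack(
                    [np.bincount(gidx, weights=Xw[:, c], minlength=J)
                     for c in range(p)]
                )
                Sw = np.bincount(gidx, weights=omega, minlength=J)
                P[:p, p:] = XtOZ
                P[p:, :p] = XtOZ.T
                P[p:, p:] = np.diag(Sw + 1.0 / sigma2)
            c, low = cho_factor(P, lower=True)
            mean = cho_solve((c, low), rhs0)
            z = rng.standard_normal(d)
            draw = mean + solve_triangular(c, z, lower=True, trans="T")
            beta = draw[:p]
            if not fix_u_zero:
                u = draw[p:]
                if fixed_sigma2 is None:
                    sigma2 = sample_sigma2_conditional(u, pr, rng)
            if keep_mask[it]:
                out[k_out] = beta[0], beta[1] if p > 1 else np.nan, sigma2
                k_out += 1
        return out

    def fit(
        self,
        chains: int = 2,
        thin: int = 10,
        n_save: int = 100,
        burn_in: int = 5000,
        seed: int = 0,
        fix_u_zero: bool = False,
        fixed_sigma2: Optional[float] = None,
        check: bool = True,
    ) -> PosteriorDraws:
        """Run the Gibbs sampler.

        Each chain runs ``burn_in + thin * n_save`` iterations and keeps the
        iterations ``burn_in + thin * s`` (s = 1..n_save), i.e. every
        ``thin``-th post-burn-in draw.  Defaults (2 chains, thin 10, 100
        saved per chain) yield 200 saved draws.  ``fix_u_zero`` freezes all
        random effects at zero (plain Bayesian logistic regression; used for
        validation), optionally with ``fixed_sigma2``.

        Initialisation is deterministic: beta at the plain-logistic ML
        estimates, u = 0, sigma_u^2 = 1.
        """
        if burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        import statsmodels.api as sm

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            init_beta = np.asarray(
                sm.Logit(self.endog, self.exog).fit(disp=0).params, float
            )

        n_iter = burn_in + thin * n_save
        keep_mask = np.zeros(n_iter, bool)
        # iterations are 1-based in the bookkeeping: keep burn_in + thin*s
        keep_iters = burn_in + thin * np.arange(1, n_save + 1)
        keep_mask[keep_iters - 1] = True

        frames = []
        for chain_id, ss in enumerate(np.random.SeedSequence(seed).spawn(chains)):
            rng = np.random.default_rng(ss)
            draws = self._run_chain(
                n_iter, rng, keep_mask, fix_u_zero, fixed_sigma2, init_beta
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chain": chain_id,
                        "iteration": keep_iters,
                        "beta0": draws[:, 0],
                        "beta1": draws[:, 1],
                        "sigma_u2": draws[:, 2],
                    }
                )
            )
        result = PosteriorDraws(
            pd.concat(frames, ignore_index=True), thin=thin, burn_in=burn_in
        )
        if check and chains >= 2 and not fix_u_zero:
            diag = result.check_convergence()
            if not diag["passed"]:
                warnings.warn(
                    f"MCMC convergence diagnostics failed: {diag['rhat']}",
                    RuntimeWarning,
                )
        return result
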