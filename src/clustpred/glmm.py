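"""Maximum-likelihood random-intercept logistic regression.

The marginal likelihood integrates the cluster-level random intercept out of
the Bernoulli-logit model with adaptive Gauss-Hermite quadrature: for each
cluster the integrand's mode and curvature are located by Newton iterations
and the Hermite rule is centred and scaled there.  Fixed effects may include
an expert-opinion category (dummy-coded) alongside the intercept and the
continuous predictor; the random intercept is always retained during
estimation.  Prediction for new clusters substitutes the random effect with
its mean zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit, roots_hermite

from .datagen import ClusteredDataset
from .expert import SCALES

__all__ = [
    "RandomInterceptLogit",
    "RandomInterceptLogitResults",
    "REFERENCE_CATEGORY",
    "quantile_cutpoints",
    "encode_expert_categories",
]

#: Reference category per scale: the lower half (m=2), second tertile (m=3)
#: or third quintile (m=5).
REFERENCE_CATEGORY = {2: 1, 3: 2, 5: 3}


def quantile_cutpoints(dev_u: Sequence[float], m: int) -> np.ndarray:
    """Empirical m-quantile cutpoints of the development clusters' random
    effects, used to place any cluster on the m-level categorical scale."""
    if m not in SCALES:
        raise ValueError(f"m must be one of {SCALES}")
    u = np.asarray(dev_u, float)
    if u.size == 0:
        raise ValueError("dev_u must be nonempty")
    return np.quantile(u, np.arange(1, m) / m)


def encode_expert_categories(
    u: Sequence[float], cutpoints: np.ndarray
) -> np.ndarray:
    """1-based category codes: bin of each random effect among the cutpoints.

    A value exactly on a cutpoint goes to the lower bin (deterministic
    tie-break).
    """
    return np.searchsorted(np.asarray(cutpoints), np.asarray(u, float),
                           side="left") + 1


def _dummy_columns(codes: np.ndarray, m: int) -> tuple[np.ndarray, list[int]]:
    """Dummy design for an m-level category, omitting the reference level.

    Returns the (n, m-1) matrix and the list of non-reference levels in
    column order.
    """
    ref = REFERENCE_CATEGORY[m]
    levels = [lev for lev in range(1, m + 1) if lev != ref]
    X = np.column_stack([(codes == lev).astype(float) for lev in levels])
    return X, levels


class RandomInterceptLogit:
    """ML estimation of logit(p_ij) = x_ij' beta + u_j, u_j ~ N(0, sigma_u^2).

    Parameters
    ----------
    endog : array-like of 0/1
        Binary outcomes.
    exog : array-like, shape (n, p)
        Fixed-effects design matrix including the intercept column.
    groups : array-like
        Cluster labels (any hashable values).
    exog_names : sequence of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, float)
        self.exog = np.atleast_2d(np.asarray(exog, float))
        labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
        self.group_labels = labels
        self.group_index = gidx
        self.n_groups = labels.size
        if self.n_groups < 2:
            raise ValueError("need at least two clusters")
        if self.endog.min() == self.endog.max():
            raise ValueError("outcome is constant; model not identifiable")
        p = self.exog.shape[1]
        self.exog_names = (
            list(exog_names) if exog_names is not None
            else [f"x{k}" for k in range(p)]
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataset(
        cls,
        data: ClusteredDataset,
        expert_codes: Optional[np.ndarray] = None,
        m: Optional[int] = None,
    ) -> "RandomInterceptLogit":
        """Build from a ClusteredDataset; optionally add an m-level expert
        category (one code per cluster, aligned with ``data.cluster_ids``)
        as dummy-coded fixed effects."""
        X = np.column_stack([np.ones(data.n), data.x])
        names = ["const", "x"]
        if expert_codes is not None:
            if m not in SCALES:
                raise ValueError(f"m must be one of {SCALES}")
            codes = np.asarray(expert_codes)
            if codes.size != data.n_clusters:
                raise ValueError("one expert code per cluster required")
            per_subject = codes[data.group_index]
            D, levels = _dummy_columns(per_subject, m)
            X = np.column_stack([X, D])
            names += [f"expert[{lev}]" for lev in levels]
        return cls(data.y, X, data.df["cluster_id"].to_numpy(), names)

    # -- likelihood -------------------------------------------------------

    def _posterior_modes(self, eta_fixed, sigma2, n_iter=25, tol=1e-10):
        """Per-cluster mode and curvature of the complete-data log-density
        in u (vectorised Newton; the integrand is log-concave)."""
        y, gidx, J = self.endog, self.group_index, self.n_groups
        u = np.zeros(J)
        inv_s2 = 1.0 / sigma2
        for _ in range(n_iter):
            p = expit(eta_fixed + u[gidx])
            g1 = np.bincount(gidx, weights=y - p, minlength=J) - u * inv_s2
            g2 = -(np.bincount(gidx, weights=p * (1 - p), minlength=J) + inv_s2)
            step = g1 / g2
            u -= step
            if np.max(np.abs(step)) < tol:
                break
        p = expit(eta_fixed + u[gidx])
        curv = np.bincount(gidx, weights=p * (1 - p), minlength=J) + inv_s2
        return u, curv

    def loglike(self, params: np.ndarray, n_quad: int = 15) -> float:
        """Marginal log-likelihood at params = (beta, sigma_u)."""
        beta, sigma = params[:-1], params[-1]
        sigma2 = max(sigma, 1e-8) ** 2
        y, gidx, J = self.endog, self.group_index, self.n_groups
        eta_fixed = self.exog @ beta

        u_hat, curv = self._posterior_modes(eta_fixed, sigma2)
        tau = 1.0 / np.sqrt(curv)  # adaptive scale per cluster

        nodes, weights = roots_hermite(n_quad)
        # f[k, j]: joint log-density at node k of cluster j
        f = np.empty((n_quad, J))
        sqrt2 = np.sqrt(2.0)
        for k, t in enumerate(nodes):
            u_k = u_hat + sqrt2 * tau * t
            eta = eta_fixed + u_k[gidx]
            # Bernoulli-logit log-likelihood per observation, summed by cluster
            ll_obs = y * eta + log_expit(-eta)
            f[k] = (
                np.bincount(gidx, weights=ll_obs, minlength=J)
                - 0.5 * u_k**2 / sigma2
                - 0.5 * np.log(2 * np.pi * sigma2)
            )
        # log sum_k w_k exp(f_k + t_k^2) + log(sqrt(2) tau), stabilised
        fmax = f.max(axis=0)
        s = np.einsum(
            "k,kj->j", weights, np.exp(f - fmax + nodes[:, None] ** 2)
        )
        return float(np.sum(fmax + np.log(s) + np.log(sqrt2 * tau)))

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        n_quad: int = 15,
        start_params: Optional[np.ndarray] = None,
        maxiter: int = 200,
    ) -> "RandomInterceptLogitResults":
        """Maximise the marginal likelihood (L-BFGS-B, sigma >= 1e-6)."""
        import statsmodels.api as sm

        p = self.exog.shape[1]
        if start_params is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta0 = sm.Logit(self.endog, self.exog).fit(disp=0).params
            start_params = np.append(beta0, 1.0)
        bounds = [(None, None)] * p + [(1e-6, None)]
        res = minimize(
            lambda th: -self.loglike(th, n_quad),
            start_params,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        params = res.x
        loglik = -res.fun
        cov = self._cov_params(params, n_quad)
        separation = bool(np.any(np.abs(params[:-1]) > 15))
        if separation:
            warnings.warn(
                "very large coefficient estimates; possible (quasi-)separation",
                RuntimeWarning,
            )
        return RandomInterceptLogitResults(
            model=self,
            params=params[:-1],
            sigma_u=params[-1],
            loglik=loglik,
            converged=bool(res.success),
            n_quadrature=n_quad,
            cov_params=cov,
            separation=separation,
        )

    def _cov_params(self, params, n_quad):
        """Inverse of the negative numerical Hessian at the optimum (Wald)."""
        k = params.size
        h = 1e-4 * np.maximum(np.abs(params), 1.0)
        H = np.empty((k, k))
        f0 = self.loglike(params, n_quad)

        def f(th):
            return self.loglike(th, n_quad)

        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(params + ei) - 2 * f0 + f(params - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(params + ei + ej)
                        - f(params + ei - ej)
                        - f(params - ei + ej)
                        + f(params - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            return np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return np.full((k, k), np.nan)


@dataclass
class RandomInterceptLogitResults:
    """ML fit of the random-intercept logistic model.

    ``params`` are the fixed-effect coefficients in ``model.exog_names``
    order; ``sigma_u`` is the random-intercept SD.  ``cov_params`` covers
    (beta..., sigma_u) from the numerical Hessian.
    """

    model: RandomInterceptLogit
    params: np.ndarray
    sigma_u: float
    loglik: float
    converged: bool
    n_quadrature: int
    cov_params: np.ndarray = field(repr=False, default=None)
    separation: bool = False

    @property
    def sigma_u2(self) -> float:
        return float(self.sigma_u**2)

    @property
    def beta0(self) -> float:
        return float(self.params[0])

    @property
    def beta1(self) -> float:
        return float(self.params[1])

    @property
    def category_coefs(self) -> dict:
        """Dummy coefficients for the expert category, keyed by level."""
        out = {}
        for name, val in zip(self.model.exog_names, self.params):
            if name.startswith("expert["):
                out[int(name[7:-1])] = float(val)
        return out

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (beta..., sigma_u)."""
        return np.sqrt(np.diag(self.cov_params))

    def conf_int_beta1(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        se = self.bse[1]
        z = norm.ppf(1 - alpha / 2)
        return self.beta1 - z * se, self.beta1 + z * se

    def predict(
        self,
        x: Sequence[float],
        expert_codes_per_subject: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        """Predicted risk for new-cluster subjects: the random effect is
        substituted with its mean zero, so risk = expit(beta0 + beta1 x
        [+ category coefficient])."""
        x = np.asarray(x, float)
        eta = self.beta0 + self.beta1 * x
        coefs = self.category_coefs
        if coefs:
            if expert_codes_per_subject is None:
                raise ValueError("model includes an expert category; codes required")
            codes = np.asarray(expert_codes_per_subject)
            m = len(coefs) + 1
            bad = ~np.isin(codes, np.arange(1, m + 1))
            if bad.any():
                raise ValueError(f"unknown category code(s): {np.unique(codes[bad])}")
            gamma = np.zeros(m + 1)
            for lev, val in coefs.items():
                gamma[lev] = val
            eta = eta + gamma[codes]
        elif expert_codes_per_subject is not None:
            raise ValueError("model has no expert category")
        return expit(eta)

    def predict_dataset(
        self, data: ClusteredDataset, expert_codes: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """Per-subject risks for a new dataset; ``expert_codes`` is one code
        per cluster aligned with ``data.cluster_ids``."""
        per_subject = None
        if expert_codes is not None:
            per_subject = np.asarray(expert_codes)[data.group_index]
        return self.predict(data.x, per_subject)

    def summary(self) -> pd.DataFrame:
        rows = list(zip(self.model.exog_names, self.params)) + [
            ("sigma_u", self.sigma_u)
        ]
        tbl = pd.DataFrame(rows, columns=["param", "estimate"]).set_index("param")
        tbl["std_err"] = self.bse
        tbl.attrs["loglik"] = self.loglik
        tbl.attrs["converged"] = self.converged
        return tbl
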