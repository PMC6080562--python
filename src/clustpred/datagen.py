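"""Simulation of clustered binary-outcome data.

The generating model is a random-intercept logistic regression: for subject
``i`` in cluster ``j``,

    logit(p_ij) = beta0 + beta1 * x_ij + u_j,      u_j ~ N(0, sigma_u^2),
    y_ij ~ Bernoulli(p_ij),                         x_ij ~ N(0, 1).

The between-cluster variance is parameterised either directly or through the
intraclass correlation coefficient (ICC) on the latent scale, where the
logistic error variance is fixed at pi^2/3.  The fixed intercept is solved so
that the marginal outcome prevalence matches a target value.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermite

__all__ = [
    "LOGISTIC_ERROR_VARIANCE",
    "SimulationConfig",
    "ClusteredDataset",
    "icc_to_variance",
    "variance_to_icc",
    "solve_intercept",
    "generate_dataset",
]

#: Variance of the standard logistic distribution: the fixed residual
#: variance on the latent scale used in the ICC for binary outcomes.
LOGISTIC_ERROR_VARIANCE = math.pi**2 / 3.0

_ROLES = ("development", "prediction")


def icc_to_variance(icc: float) -> float:
    """Between-cluster variance implied by a latent-scale ICC.

    Inverts ``ICC = sigma_u^2 / (sigma_u^2 + pi^2/3)``.

    Parameters
    ----------
    icc : float
        Intraclass correlation, strictly inside (0, 1).

    Returns
    -------
    float
        ``sigma_u^2 = ICC * (pi^2/3) / (1 - ICC)``.
    """
    if not 0.0 < icc < 1.0:
        raise ValueError(f"icc must lie strictly in (0, 1), got {icc!r}")
    return icc * LOGISTIC_ERROR_VARIANCE / (1.0 - icc)


def variance_to_icc(sigma_u2: float) -> float:
    """Latent-scale ICC implied by a between-cluster variance."""
    if not sigma_u2 > 0.0:
        raise ValueError(f"sigma_u2 must be positive, got {sigma_u2!r}")
    return sigma_u2 / (sigma_u2 + LOGISTIC_ERROR_VARIANCE)


# 64-node Gauss-Hermite rule: plenty for a 1-D normal expectation.
_GH_NODES, _GH_WEIGHTS = roots_hermite(64)


def marginal_prevalence(beta0: float, beta1: float, sigma_u2: float) -> float:
    """Marginal P(y=1) under the generating model.

    With x ~ N(0,1) and u ~ N(0, sigma_u^2) independent, the linear predictor
    minus the intercept collapses to Z ~ N(0, beta1^2 + sigma_u^2), so the
    prevalence is E[expit(beta0 + Z)], computed by Gauss-Hermite quadrature.
    """
    var = beta1**2 + sigma_u2
    if var == 0.0:
        return float(expit(beta0))
    z = math.sqrt(2.0 * var) * _GH_NODES
    return float(_GH_WEIGHTS @ expit(beta0 + z) / math.sqrt(math.pi))


def solve_intercept(
    beta1: float,
    sigma_u2: float,
    target_prevalence: float,
    tol: float = 1e-6,
) -> float:
    """Fixed intercept beta0 giving a target marginal prevalence.

    The prevalence is strictly increasing in beta0, so a bracketed root
    search on the quadrature-evaluated prevalence converges reliably.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must lie in (0, 1)")
    if sigma_u2 < 0.0:
        raise ValueError("sigma_u2 must be nonnegative")
    center = float(logit(target_prevalence))
    halfwidth = 6.0 * math.sqrt(beta1**2 + sigma_u2) + 1.0
    return float(
        brentq(
            lambda b0: marginal_prevalence(b0, beta1, sigma_u2) - target_prevalence,
            center - halfwidth,
            center + halfwidth,
            xtol=tol,
        )
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for one simulated scenario.

    Exactly one of ``icc`` and ``sigma_u2`` must be supplied; the other is
    derived from the latent-threshold identity.  Defaults reproduce the
    default study conditions: 50 clusters of 100 subjects, beta1 = 1.5,
    ICC = 0.20 (sigma_u^2 ~= 0.822) and 50% prevalence.
    """

    n_clusters: int = 50
    cluster_size: int = 100
    beta1: float = 1.5
    icc: Optional[float] = 0.20
    sigma_u2: Optional[float] = None
    target_prevalence: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cluster_size < 1:
            raise ValueError("n_clusters and cluster_size must be positive")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if (self.icc is None) == (self.sigma_u2 is None):
            raise ValueError("exactly one of icc and sigma_u2 must be given")
        if self.icc is not None:
            object.__setattr__(self, "sigma_u2", icc_to_variance(self.icc))
        elif self.sigma_u2 == 0.0:
            # degenerate no-clustering case: allowed in configs, ICC = 0
            object.__setattr__(self, "icc", 0.0)
        else:
            object.__setattr__(self, "icc", variance_to_icc(self.sigma_u2))
        if self.sigma_u2 > 0 and abs(variance_to_icc(self.sigma_u2) - self.icc) > 1e-10:
            raise ValueError("icc and sigma_u2 are inconsistent")

    @property
    def n_subjects(self) -> int:
        return self.n_clusters * self.cluster_size

    @property
    def beta0(self) -> float:
        """Intercept solved for the target prevalence."""
        return solve_intercept(self.beta1, self.sigma_u2, self.target_prevalence)

    def replace(self, **changes) -> "SimulationConfig":
        """New config with fields replaced (icc/sigma_u2 kept consistent)."""
        d = self.to_dict()
        if "icc" in changes and "sigma_u2" not in changes:
            d["sigma_u2"] = None
        if "sigma_u2" in changes and "icc" not in changes:
            d["icc"] = None
        d.update(changes)
        return SimulationConfig.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        # round-trip tolerance: files written by to_file carry both fields
        if d.get("icc") is not None and d.get("sigma_u2") is not None:
            s2, icc = d["sigma_u2"], d["icc"]
            consistent = (
                icc == 0.0 if s2 == 0.0
                else abs(variance_to_icc(s2) - icc) < 1e-8
            )
            if not consistent:
                raise ValueError("icc and sigma_u2 are inconsistent")
            d["icc" if icc == 0.0 else "sigma_u2"] = None
        return cls(**d)

    @classmethod
    def from_file(cls, path: str) -> "SimulationConfig":
        """Load from YAML or JSON; field names mirror the constructor."""
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            if path.endswith(".json"):
                json.dump(self.to_dict(), fh, indent=2)
            else:
                yaml.safe_dump(self.to_dict(), fh)


@dataclass
class ClusteredDataset:
    """Subject-level clustered binary-outcome data.

    ``df`` holds one row per subject with columns ``cluster_id`` (1-based),
    ``subject_id``, ``x``, ``y`` and, for simulated data where the truth is
    known, ``true_u`` (the cluster's latent random effect, repeated within
    cluster) and ``true_p`` (the latent risk).
    """

    df: pd.DataFrame

    REQUIRED = ("cluster_id", "subject_id", "x", "y")
    TRUTH = ("true_u", "true_p")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        y = self.df["y"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def cluster_ids(self) -> np.ndarray:
        """Distinct cluster ids in order of first appearance."""
        return self.df["cluster_id"].unique()

    @property
    def n_clusters(self) -> int:
        return self.df["cluster_id"].nunique()

    @property
    def has_truth(self) -> bool:
        return all(c in self.df.columns for c in self.TRUTH)

    @property
    def x(self) -> np.ndarray:
        return self.df["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(int)

    @property
    def group_index(self) -> np.ndarray:
        """0-based cluster index per subject, ordered by first appearance."""
        codes = pd.Categorical(
            self.df["cluster_id"], categories=self.cluster_ids
        ).codes
        return np.asarray(codes, dtype=np.int64)

    def true_u_by_cluster(self) -> np.ndarray:
        """One latent random effect per cluster (simulated data only)."""
        if "true_u" not in self.df.columns:
            raise ValueError("dataset carries no latent truth")
        return (
            self.df.groupby("cluster_id", sort=False)["true_u"].first().to_numpy(float)
        )

    @property
    def prevalence(self) -> float:
        return float(self.df["y"].mean())

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str) -> "ClusteredDataset":
        return cls(pd.read_csv(path))


def generate_dataset(
    config: SimulationConfig, role: str = "development"
) -> ClusteredDataset:
    """Simulate one clustered dataset under the generating model.

    ``role`` ("development" or "prediction") selects an independent named
    substream of the config's master seed, so the development and prediction
    datasets of one scenario are independent yet jointly reproducible, and
    regenerating one never perturbs the other.  Within a role, the predictor,
    random-effect and outcome draws use separate substreams.
    """
    if role not in _ROLES:
        raise ValueError(f"role must be one of {_ROLES}, got {role!r}")
    role_ss = np.random.SeedSequence(config.seed).spawn(len(_ROLES))[
        _ROLES.index(role)
    ]
    rng_x, rng_u, rng_y = (np.random.default_rng(s) for s in role_ss.spawn(3))

    J, nj = config.n_clusters, config.cluster_size
    beta0 = config.beta0
    x = rng_x.standard_normal(J * nj)
    u = rng_u.standard_normal(J) * math.sqrt(config.sigma_u2)
    gidx = np.repeat(np.arange(J), nj)
    p = expit(beta0 + config.beta1 * x + u[gidx])
    y = (rng_y.uniform(size=J * nj) < p).astype(int)

    df = pd.DataFrame(
        {
            "cluster_id": gidx + 1,
            "subject_id": np.tile(np.arange(1, nj + 1), J),
            "x": x,
            "y": y,
            "true_u": u[gidx],
            "true_p": p,
        }
    )
    return ClusteredDataset(df)
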