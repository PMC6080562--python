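"""Posterior-predictive risks for subjects in new clusters.

For every saved posterior draw k the new cluster's random effect is sampled
from N(0, sigma_u2^(k)) — over the whole distribution when no expert opinion
is available, or restricted to the expert's equal-probability region when it
is.  Sampling is by inverse CDF on the probability scale: a uniform U on
((r-1)/m, r/m) maps to u = sigma^(k) * Phi^-1(U), which honours the expert's
*positional* statement for every posterior draw of sigma (the probability
region is sigma-invariant) and is exact even in the 1/5-scale tails.  Each
cluster gets one random-effect draw per iteration, shared by all its
subjects; the per-subject point prediction is the median of the K risk
draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .bayes import PosteriorDraws
from .datagen import ClusteredDataset
from .expert import ExpertJudgment

__all__ = [
    "MODEL_LABELS",
    "PredictionResult",
    "predicted_risk",
    "summarize_point",
    "sample_cluster_effects",
    "predict_bayes_weakly",
    "predict_bayes_truncated",
]

#: Model labels used across outputs and results tables.
MODEL_LABELS = (
    "FREQ",
    "BAYES.WI",
    "BAYES.LI",
    "BAYES.MI",
    "BAYES.HI",
    "FREQ.2",
    "FREQ.3",
    "FREQ.5",
)


def predicted_risk(beta0, beta1, u, x):
    """Risk of the outcome: expit(beta0 + beta1*x + u), overflow-safe.

    Accepts scalars or broadcastable arrays.
    """
    return expit(
        np.asarray(beta0, float)
        + np.asarray(beta1, float) * np.asarray(x, float)
        + np.asarray(u, float)
    )


def summarize_point(risk_draws: np.ndarray, axis: int = -1) -> np.ndarray:
    """Median of the predicted-risk draws (midpoint convention for even K)."""
    draws = np.asarray(risk_draws, float)
    if draws.size == 0:
        raise ValueError("risk_draws must be nonempty")
    return np.median(draws, axis=axis)


@dataclass
class PredictionResult:
    """Per-subject posterior-predictive risks under one model.

    ``risk_draws`` has shape (n_subjects, K); ``u_draws`` has shape
    (n_clusters, K) aligned with ``cluster_ids`` — all subjects of one
    cluster share its random-effect draws.  ``risk_point`` is the per-subject
    median risk.  Frequentist predictions are represented with K = 1
    (a degenerate single "draw" with u = 0).
    """

    model: str
    cluster_ids: np.ndarray
    subject_cluster: np.ndarray
    x: np.ndarray
    risk_draws: np.ndarray
    u_draws: Optional[np.ndarray] = None

    @property
    def n_draws(self) -> int:
        return self.risk_draws.shape[1]

    @property
    def risk_point(self) -> np.ndarray:
        return summarize_point(self.risk_draws, axis=1)

    @property
    def linear_predictor_point(self) -> np.ndarray:
        """Logit of the point prediction (for observed-outcome calibration)."""
        p = np.clip(self.risk_point, 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))

    def to_frame(self, include_draws: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "model": self.model,
                "cluster_id": self.subject_cluster,
                "x": self.x,
                "risk_point": self.risk_point,
            }
        )
        if include_draws:
            draws = pd.DataFrame(
                self.risk_draws,
                columns=[f"risk_draw_{k}" for k in range(self.n_draws)],
            )
            df = pd.concat([df, draws], axis=1)
        return df

    def to_csv(self, path: str, include_draws: bool = False) -> None:
        self.to_frame(include_draws).to_csv(path, index=False)

    @classmethod
    def from_fixed_risk(
        cls, model: str, data: ClusteredDataset, risk: np.ndarray
    ) -> "PredictionResult":
        """Wrap deterministic (frequentist) risks as a single-draw result."""
        return cls(
            model=model,
            cluster_ids=np.asarray(data.cluster_ids),
            subject_cluster=data.df["cluster_id"].to_numpy(),
            x=data.x,
            risk_draws=np.asarray(risk, float)[:, None],
            u_draws=np.zeros((data.n_clusters, 1)),
        )


def sample_cluster_effects(
    sigma_draws: np.ndarray,
    regions: np.ndarray,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random-effect draws for C clusters under K posterior draws of sigma.

    ``regions[c]`` is the expert's region (1..m) for cluster c; m = 1 means
    no truncation (the whole distribution).  Returns shape (C, K):
    u[c, k] = sigma_draws[k] * Phi^-1((regions[c]-1)/m + U[c, k]/m).
    """
    sigma = np.asarray(sigma_draws, float)
    regions = np.asarray(regions, int)
    if np.any((regions < 1) | (regions > m)):
        raise ValueError(f"region indices must lie in 1..{m}")
    U = rng.uniform(size=(regions.size, sigma.size))
    prob = (regions[:, None] - 1.0) / m + U / m
    return sigma[None, :] * ndtri(prob)


def _predict_from_effects(
    draws: PosteriorDraws, new_data: ClusteredDataset, u_draws: np.ndarray, label: str
) -> PredictionResult:
    gidx = new_data.group_index
    risk = predicted_risk(
        draws.beta0[None, :],
        draws.beta1[None, :],
        u_draws[gidx],
        new_data.x[:, None],
    )
    return PredictionResult(
        model=label,
        cluster_ids=np.asarray(new_data.cluster_ids),
        subject_cluster=new_data.df["cluster_id"].to_numpy(),
        x=new_data.x,
        risk_draws=risk,
        u_draws=u_draws,
    )


def predict_bayes_weakly(
    draws: PosteriorDraws,
    new_data: ClusteredDataset,
    seed: int = 0,
    label: str = "BAYES.WI",
) -> PredictionResult:
    """Prediction with the random effect drawn from the whole N(0, sigma_u2^(k))
    distribution for each new cluster and iteration."""
    regions = np.ones(new_data.n_clusters, int)
    rng = np.random.default_rng(seed)
    u = sample_cluster_effects(np.sqrt(draws.sigma_u2), regions, 1, rng)
    return _predict_from_effects(draws, new_data, u, label)


def predict_bayes_truncated(
    draws: PosteriorDraws,
    new_data: ClusteredDataset,
    judgments: Sequence[ExpertJudgment],
    seed: int = 0,
    label: Optional[str] = None,
) -> PredictionResult:
    """Prediction with the random effect drawn from the expert's truncated
    region of N(0, sigma_u2^(k)), recomputed per posterior draw of sigma."""
    by_cluster = {j.cluster_id: j for j in judgments}
    ms = {j.m for j in judgments}
    if len(ms) != 1:
        raise ValueError("all judgments must share one scale m")
    m = ms.pop()
    regions = []
    for cid in new_data.cluster_ids:
        if cid not in by_cluster:
            raise ValueError(f"no expert judgment for new cluster {cid}")
        regions.append(by_cluster[cid].region)
    rng = np.random.default_rng(seed)
    u = sample_cluster_effects(np.sqrt(draws.sigma_u2), np.asarray(regions), m, rng)
    if label is None:
        label = {1: "BAYES.WI", 2: "BAYES.LI", 3: "BAYES.MI", 5: "BAYES.HI"}.get(
            m, f"BAYES.TRUNC{m}"
        )
    return _predict_from_effects(draws, new_data, u, label)
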