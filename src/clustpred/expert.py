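"""Cluster-level expert opinion as truncated regions of the random-effects
distribution.

An expert's judgment about a new cluster is encoded positionally: the
N(0, sigma_u^2) random-effects distribution is split into ``m`` regions of
equal probability mass (m = 2 halves, 3 tertiles or 5 quintiles) and the
expert names the region that contains the cluster's random effect.  An
*optimal* judgment names the region actually containing the true value; a
*discrepant* judgment names an adjacent region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.special import ndtri

__all__ = [
    "SCALES",
    "TruncationScheme",
    "ExpertJudgment",
    "region_bounds",
    "elicit_optimal",
    "elicit_discrepant",
    "assign_discrepant_clusters",
    "make_judgments",
]

#: Supported numbers of equal-probability regions (low / medium / high
#: informativeness).
SCALES = (2, 3, 5)


@dataclass(frozen=True)
class TruncationScheme:
    """Division of the random-effects distribution into ``m`` equal-mass
    regions; region ``r`` covers standard-normal probability ((r-1)/m, r/m)."""

    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be a positive integer")

    def bounds(self, r: int, sigma_u: float) -> Tuple[float, float]:
        return region_bounds(r, self.m, sigma_u)


@dataclass(frozen=True)
class ExpertJudgment:
    """One expert's regional judgment for one new cluster."""

    cluster_id: int
    m: int
    region: int
    discrepant: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.region <= self.m:
            raise ValueError(
                f"region {self.region} outside 1..{self.m} for cluster "
                f"{self.cluster_id}"
            )


def region_bounds(r: int, m: int, sigma_u: float) -> Tuple[float, float]:
    """Truncation interval of region ``r`` of ``m`` on the random-effect scale.

    Returns ``(sigma_u * Phi^-1((r-1)/m), sigma_u * Phi^-1(r/m))``; the first
    region is unbounded below and the last unbounded above.
    """
    if not 1 <= r <= m:
        raise ValueError(f"region {r} outside 1..{m}")
    if sigma_u <= 0:
        raise ValueError("sigma_u must be positive")
    lo = -math.inf if r == 1 else sigma_u * float(ndtri((r - 1) / m))
    hi = math.inf if r == m else sigma_u * float(ndtri(r / m))
    return lo, hi


def elicit_optimal(true_u: float, sigma_u_true: float, m: int):
    """Region index containing the true random effect.

    The smallest r whose upper bound exceeds true_u — equivalently
    ``ceil(m * Phi(true_u / sigma_u_true))``, but computed by comparing
    against the region boundaries directly so that values on a boundary are
    placed consistently with :func:`region_bounds`.  Accepts scalars or
    arrays.
    """
    if sigma_u_true <= 0:
        raise ValueError("sigma_u_true must be positive")
    boundaries = sigma_u_true * ndtri(np.arange(1, m) / m)
    r = np.searchsorted(boundaries, np.asarray(true_u, float), side="left") + 1
    return int(r) if np.isscalar(true_u) or r.ndim == 0 else r


def elicit_discrepant(optimal_region: int, m: int, rng: np.random.Generator) -> int:
    """Adjacent-region misjudgment.

    Edge regions have a single neighbour; interior regions go left or right
    with equal probability (seeded fair coin).
    """
    if m < 2:
        raise ValueError("discrepant opinion needs at least two regions")
    if not 1 <= optimal_region <= m:
        raise ValueError(f"region {optimal_region} outside 1..{m}")
    if optimal_region == 1:
        return 2
    if optimal_region == m:
        return m - 1
    return optimal_region + (1 if rng.uniform() < 0.5 else -1)


def assign_discrepant_clusters(
    cluster_ids: Sequence, pct: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random subset of round(pct * C) clusters to receive a
    discrepant judgment."""
    if not 0.0 <= pct <= 1.0:
        raise ValueError("pct must lie in [0, 1]")
    ids = np.asarray(cluster_ids)
    k = int(round(pct * ids.size))
    return rng.choice(ids, size=k, replace=False)


def make_judgments(
    cluster_ids: Sequence,
    true_u: Sequence[float],
    sigma_u_true: float,
    m: int,
    discrepant_ids: Sequence = (),
    rng: np.random.Generator | None = None,
) -> list[ExpertJudgment]:
    """Judgments for a set of new clusters: optimal everywhere except the
    clusters in ``discrepant_ids``, which get an adjacent region instead."""
    discrepant_set = set(np.asarray(discrepant_ids).tolist())
    if discrepant_set and rng is None:
        raise ValueError("rng is required when discrepant clusters are present")
    out = []
    for cid, u in zip(cluster_ids, true_u):
        r = elicit_optimal(float(u), sigma_u_true, m)
        if cid in discrepant_set:
            out.append(ExpertJudgment(cid, m, elicit_discrepant(r, m, rng), True))
        else:
            out.append(ExpertJudgment(cid, m, r))
    return out
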