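"""Predictive-performance metrics: Brier score, C-index, calibration.

Overall metrics pool all subjects; within-cluster metrics are computed per
cluster and summarised as mean and SD over clusters (clusters where a metric
is undefined — a single-class outcome or constant predictions — are excluded
and counted).  In simulation mode, calibration is the OLS slope of the true
latent risk on the predicted risk; in empirical mode it is the logistic
recalibration slope of the observed outcome on the predicted linear
predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricsReport",
    "brier_score",
    "c_index",
    "calibration_slope_true",
    "calibration_slope_observed",
    "within_cluster_metrics",
    "calibration_plot_data",
    "evaluate_predictions",
]


def brier_score(y, p_hat) -> float:
    """Mean squared difference between outcomes and predicted risks."""
    y = np.asarray(y, float)
    p = np.asarray(p_hat, float)
    if y.shape != p.shape:
        raise ValueError("y and p_hat must have equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("predicted risks must lie in [0, 1]")
    return float(np.mean((y - p) ** 2))


def c_index(y, score) -> float:
    """Concordance index (area under the ROC curve).

    Mann-Whitney convention: ties in the score receive 0.5 credit.  Raises
    on single-class input, where concordance is undefined.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("c_index undefined: outcome has a single class")
    return float(roc_auc_score(y, np.asarray(score, float)))


def calibration_slope_true(p_hat, p_true) -> float:
    """OLS slope of the true latent risk on the predicted risk (1 = perfect)."""
    p_hat = np.asarray(p_hat, float)
    p_true = np.asarray(p_true, float)
    if p_hat.shape != p_true.shape or p_hat.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.all(p_hat == p_hat[0]):
        raise ValueError("calibration slope undefined: constant predictions")
    return float(np.cov(p_hat, p_true, ddof=1)[0, 1] / p_hat.var(ddof=1))


def calibration_slope_observed(y, lp_hat) -> float:
    """Logistic recalibration slope of the observed outcome on the predicted
    linear predictor (intercept included)."""
    import statsmodels.api as sm

    y = np.asarray(y, float)
    lp = np.asarray(lp_hat, float)
    if np.unique(y).size < 2:
        raise ValueError("recalibration undefined: single-class outcome")
    if np.all(lp == lp[0]):
        raise ValueError("recalibration undefined: constant linear predictor")
    X = sm.add_constant(lp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0)
    if np.abs(res.params[1]) > 50:
        warnings.warn("possible separation in recalibration fit", RuntimeWarning)
    return float(res.params[1])


@dataclass
class MetricsReport:
    """Performance battery for one model on one prediction dataset."""

    model: str
    brier: float
    c_index_overall: float
    cal_slope_overall: float
    c_index_within_mean: float
    c_index_within_sd: float
    cal_slope_within_mean: float
    cal_slope_within_sd: float
    n_clusters_excluded: int = 0
    per_cluster: pd.DataFrame = field(default=None, repr=False)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Overall Brier score": self.brier,
                "Overall C-index/AUC": self.c_index_overall,
                "Overall calibration slope": self.cal_slope_overall,
                "Within cluster C-index/AUC mean": self.c_index_within_mean,
                "Within cluster C-index/AUC sd": self.c_index_within_sd,
                "Within cluster calibration slope mean": self.cal_slope_within_mean,
                "Within cluster calibration slope sd": self.cal_slope_within_sd,
            },
            name=self.model,
        )


def within_cluster_metrics(y, p_hat, p_true, cluster_ids):
    """Per-cluster C-index and true-risk calibration slope.

    Returns (table, summary) where the table has one row per cluster with
    NaN where a metric is undefined, and the summary dict carries the means,
    SDs (n-1 denominator) and the count of clusters excluded from at least
    one metric.
    """
    df = pd.DataFrame(
        {
            "cluster_id": np.asarray(cluster_ids),
            "y": np.asarray(y, float),
            "p_hat": np.asarray(p_hat, float),
            "p_true": None if p_true is None else np.asarray(p_true, float),
        }
    )
    rows = []
    for cid, grp in df.groupby("cluster_id", sort=False):
        try:
            ci = c_index(grp["y"], grp["p_hat"])
        except ValueError:
            ci = np.nan
        slope = np.nan
        if p_true is not None:
            try:
                slope = calibration_slope_true(grp["p_hat"], grp["p_true"])
            except ValueError:
                pass
        rows.append({"cluster_id": cid, "c_index": ci, "cal_slope": slope})
    table = pd.DataFrame(rows)
    excluded = int(table[["c_index", "cal_slope"]].isna().any(axis=1).sum())
    summary = {
        "c_index_mean": float(table["c_index"].mean()),
        "c_index_sd": float(table["c_index"].std(ddof=1)),
        "cal_slope_mean": float(table["cal_slope"].mean()),
        "cal_slope_sd": float(table["cal_slope"].std(ddof=1)),
        "n_clusters_excluded": excluded,
    }
    return table, summary


def calibration_plot_data(p_hat, p_true, cluster_ids) -> pd.DataFrame:
    """Long-format data behind a calibration plot: one row per subject with
    (cluster_id, p_hat, p_true).  Plotted against the identity line, each
    cluster's points trace one monotone curve."""
    return pd.DataFrame(
        {
            "cluster_id": np.asarray(cluster_ids),
            "p_hat": np.asarray(p_hat, float),
            "p_true": np.asarray(p_true, float),
        }
    )


def evaluate_predictions(pred, data, mode: str = "simulation") -> MetricsReport:
    """Full battery for one PredictionResult on a prediction dataset.

    ``mode`` "simulation" calibrates against the true latent risks (requires
    truth columns); "empirical" uses logistic recalibration on the observed
    outcomes.
    """
    y = data.y
    p_hat = pred.risk_point
    cids = data.df["cluster_id"].to_numpy()
    if mode == "simulation":
        if not data.has_truth:
            raise ValueError("simulation mode requires true latent risks")
        p_true = data.df["true_p"].to_numpy(float)
        slope = calibration_slope_true(p_hat, p_true)
    elif mode == "empirical":
        p_true = None
        slope = calibration_slope_observed(y, pred.linear_predictor_point)
    else:
        raise ValueError("mode must be 'simulation' or 'empirical'")
    table, within = within_cluster_metrics(y, p_hat, p_true, cids)
    return MetricsReport(
        model=pred.model,
        brier=brier_score(y, p_hat),
        c_index_overall=c_index(y, p_hat),
        cal_slope_overall=slope,
        c_index_within_mean=within["c_index_mean"],
        c_index_within_sd=within["c_index_sd"],
        cal_slope_within_mean=within["cal_slope_mean"],
        cal_slope_within_sd=within["cal_slope_sd"],
        n_clusters_excluded=within["n_clusters_excluded"],
        per_cluster=table,
    )
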