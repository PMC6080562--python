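"""Scenario orchestration: the eight-model comparison, the discrepant-opinion
grid, and the sensitivity suite.

One scenario generates a development dataset and an independent prediction
dataset from the same configuration, fits every requested model on the
development data, predicts for the new clusters, and evaluates against the
prediction data.  All models within a scenario consume the identical pair of
datasets, so performance differences are attributable to the models alone.
Bayesian model variants (BAYES.WI/LI/MI/HI and the discrepancy grid) share
one set of posterior draws — they differ only in how the new clusters'
random effects are sampled at prediction time.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import BayesRandomInterceptLogit, PosteriorDraws, PriorSpec
from .datagen import ClusteredDataset, SimulationConfig, generate_dataset
from .evaluation import MetricsReport, evaluate_predictions
from .expert import assign_discrepant_clusters, make_judgments
from .glmm import (
    RandomInterceptLogit,
    RandomInterceptLogitResults,
    encode_expert_categories,
    quantile_cutpoints,
)
from .prediction import (
    MODEL_LABELS,
    PredictionResult,
    predict_bayes_truncated,
    predict_bayes_weakly,
)

__all__ = [
    "MODEL_LABELS",
    "McmcSettings",
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioRun",
    "run_scenario",
    "run_discrepancy_suite",
    "sensitivity_configs",
    "run_sensitivity_suite",
    "format_table",
]

_SCALE_OF = {"BAYES.LI": 2, "BAYES.MI": 3, "BAYES.HI": 5}
_FREQ_K = {"FREQ.2": 2, "FREQ.3": 3, "FREQ.5": 5}

METRIC_ROWS = [
    "Overall Brier score",
    "Overall C-index/AUC",
    "Overall calibration slope",
    "Within cluster C-index/AUC mean",
    "Within cluster C-index/AUC sd",
    "Within cluster calibration slope mean",
    "Within cluster calibration slope sd",
]


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings for the Bayesian development fit."""

    chains: int = 2
    thin: int = 10
    n_save: int = 100
    burn_in: int = 5000


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario: a data recipe, a model list, an optional
    discrepant-opinion percentage, and sampler settings.  ``seed`` drives
    every scenario-level source of randomness (MCMC, prediction-time
    random-effect draws, discrepant-cluster assignment) via named
    substreams; the data themselves are keyed by ``config.seed``."""

    config: SimulationConfig = field(default_factory=SimulationConfig)
    models: Sequence[str] = MODEL_LABELS
    discrepancy_pct: float = 0.0
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_LABELS)
        if unknown:
            raise ValueError(f"unknown model labels: {sorted(unknown)}")
        if not 0.0 <= self.discrepancy_pct <= 1.0:
            raise ValueError("discrepancy_pct must lie in [0, 1]")
        if self.discrepancy_pct > 0 and not (
            set(self.models) & set(_SCALE_OF)
        ):
            raise ValueError(
                "discrepant opinion applies only to the truncated-prior models"
            )


@dataclass
class ScenarioResult:
    """Metrics table plus the per-model reports for one scenario run."""

    table: pd.DataFrame
    reports: Dict[str, MetricsReport]
    spec: ScenarioSpec

    def formatted(self) -> pd.DataFrame:
        return format_table(self.table)


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the numeric metric rows into the published table layout,
    with within-cluster rows shown as 'mean [sd]' at 3 decimals."""
    out = {}
    for col in table.columns:
        s = table[col]
        out[col] = {
            "Overall Brier score": f"{s['Overall Brier score']:.3f}",
            "Overall C-index/AUC": f"{s['Overall C-index/AUC']:.3f}",
            "Overall calibration slope": f"{s['Overall calibration slope']:.3f}",
            "Within cluster C-index/AUC": (
                f"{s['Within cluster C-index/AUC mean']:.3f} "
                f"[{s['Within cluster C-index/AUC sd']:.3f}]"
            ),
            "Within cluster calibration slope": (
                f"{s['Within cluster calibration slope mean']:.3f} "
                f"[{s['Within cluster calibration slope sd']:.3f}]"
            ),
        }
    return pd.DataFrame(out)


class ScenarioRun:
    """Lazy scenario engine: datasets, fits and posterior draws are computed
    once and reused across model variants and discrepancy percentages."""

    def __init__(self, spec: ScenarioSpec):
        self.spec = spec
        ss = np.random.SeedSequence(spec.seed).spawn(4)
        self._seed_mcmc = int(ss[0].generate_state(1)[0] % 2**31)
        self._ss_predict = ss[1]
        self._ss_assign = ss[2]
        self._ss_choice = ss[3]
        self._dev: Optional[ClusteredDataset] = None
        self._pred: Optional[ClusteredDataset] = None
        self._freq_fits: Dict[str, RandomInterceptLogitResults] = {}
        self._posterior: Optional[PosteriorDraws] = None
        self._predict_seeds: Dict[str, int] = {}

    # -- cached stages ----------------------------------------------------

    @property
    def dev_data(self) -> ClusteredDataset:
        if self._dev is None:
            self._dev = generate_dataset(self.spec.config, "development")
        return self._dev

    @property
    def pred_data(self) -> ClusteredDataset:
        if self._pred is None:
            self._pred = generate_dataset(self.spec.config, "prediction")
        return self._pred

    @property
    def posterior(self) -> PosteriorDraws:
        if self._posterior is None:
            model = BayesRandomInterceptLogit.from_dataset(
                self.dev_data, PriorSpec()
            )
            m = self.spec.mcmc
            self._posterior = model.fit(
                chains=m.chains,
                thin=m.thin,
                n_save=m.n_save,
                burn_in=m.burn_in,
                seed=self._seed_mcmc,
            )
        return self._posterior

    def freq_fit(self, label: str = "FREQ") -> RandomInterceptLogitResults:
        if label not in self._freq_fits:
            if label == "FREQ":
                model = RandomInterceptLogit.from_dataset(self.dev_data)
            else:
                m = _FREQ_K[label]
                codes = self._dev_codes(m)
                model = RandomInterceptLogit.from_dataset(
                    self.dev_data, expert_codes=codes, m=m
                )
            self._freq_fits[label] = model.fit()
        return self._freq_fits[label]

    # -- expert encodings -------------------------------------------------

    def _cutpoints(self, m: int) -> np.ndarray:
        return quantile_cutpoints(self.dev_data.true_u_by_cluster(), m)

    def _dev_codes(self, m: int) -> np.ndarray:
        return encode_expert_categories(
            self.dev_data.true_u_by_cluster(), self._cutpoints(m)
        )

    def _new_codes(self, m: int) -> np.ndarray:
        return encode_expert_categories(
            self.pred_data.true_u_by_cluster(), self._cutpoints(m)
        )

    def discrepant_ids(self, pct: float) -> np.ndarray:
        """Clusters assigned discrepant opinion at this percentage; one draw
        per percentage, shared across the three scales."""
        if pct == 0.0:
            return np.array([], dtype=self.pred_data.cluster_ids.dtype)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=self._ss_assign.entropy,
                spawn_key=self._ss_assign.spawn_key + (int(round(pct * 1000)),),
            )
        )
        return assign_discrepant_clusters(self.pred_data.cluster_ids, pct, rng)

    def judgments(self, m: int, pct: float):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=self._ss_choice.entropy,
                spawn_key=self._ss_choice.spawn_key
                + (m, int(round(pct * 1000))),
            )
        )
        return make_judgments(
            self.pred_data.cluster_ids,
            self.pred_data.true_u_by_cluster(),
            np.sqrt(self.spec.config.sigma_u2),
            m,
            discrepant_ids=self.discrepant_ids(pct),
            rng=rng,
        )

    def _predict_seed(self, key: str) -> int:
        # stable in the key, independent of model execution order
        if key not in self._predict_seeds:
            ss = np.random.SeedSequence(
                entropy=self._ss_predict.entropy,
                spawn_key=self._ss_predict.spawn_key
                + (zlib.crc32(key.encode()),),
            )
            self._predict_seeds[key] = int(ss.generate_state(1)[0] % 2**31)
        return self._predict_seeds[key]

    # -- model execution --------------------------------------------------

    def predict_model(self, label: str, pct: float = 0.0) -> PredictionResult:
        if label == "FREQ":
            risk = self.freq_fit("FREQ").predict_dataset(self.pred_data)
            return PredictionResult.from_fixed_risk(label, self.pred_data, risk)
        if label in _FREQ_K:
            m = _FREQ_K[label]
            risk = self.freq_fit(label).predict_dataset(
                self.pred_data, expert_codes=self._new_codes(m)
            )
            return PredictionResult.from_fixed_risk(label, self.pred_data, risk)
        if label == "BAYES.WI":
            return predict_bayes_weakly(
                self.posterior, self.pred_data, seed=self._predict_seed("WI")
            )
        if label in _SCALE_OF:
            m = _SCALE_OF[label]
            return predict_bayes_truncated(
                self.posterior,
                self.pred_data,
                self.judgments(m, pct),
                seed=self._predict_seed(f"{label}:{pct}"),
                label=label,
            )
        raise ValueError(f"unknown model label {label!r}")

    def evaluate_model(self, label: str, pct: float = 0.0) -> MetricsReport:
        return evaluate_predictions(self.predict_model(label, pct), self.pred_data)

    def execute(self) -> ScenarioResult:
        pct = self.spec.discrepancy_pct
        reports = {}
        for label in self.spec.models:
            use_pct = pct if label in _SCALE_OF else 0.0
            reports[label] = self.evaluate_model(label, use_pct)
        table = pd.DataFrame(
            {lab: rep.to_series() for lab, rep in reports.items()}
        ).reindex(METRIC_ROWS)
        return ScenarioResult(table=table, reports=reports, spec=self.spec)


def run_scenario(spec: ScenarioSpec) -> ScenarioResult:
    """Generate the data pair, fit, predict and evaluate every model in the
    spec; returns the metrics table (rows = metrics, columns = models)."""
    return ScenarioRun(spec).execute()


def run_discrepancy_suite(
    spec: ScenarioSpec, pcts: Sequence[float] = (0.10, 0.30, 0.50)
) -> pd.DataFrame:
    """Truncated-prior models under increasing shares of discrepant opinion.

    Per percentage, the discrepant clusters are drawn once and reused across
    the three scales.  Columns are FREQ and BAYES.WI references plus
    (model, pct) combinations, mirroring the published layout.
    """
    run = ScenarioRun(spec)
    cols = {}
    for ref in ("FREQ", "BAYES.WI"):
        if ref in spec.models:
            cols[ref] = run.evaluate_model(ref).to_series()
    for label in ("BAYES.LI", "BAYES.MI", "BAYES.HI"):
        if label not in spec.models:
            continue
        for pct in pcts:
            cols[f"{label} ({pct:.0%})"] = run.evaluate_model(label, pct).to_series()
    return pd.DataFrame(cols).reindex(METRIC_ROWS)


def sensitivity_configs(
    default: Optional[SimulationConfig] = None,
) -> Dict[str, SimulationConfig]:
    """The eight one-feature-at-a-time sensitivity scenarios: ICC 0.05 and
    0.50, prevalence 10% and 25%, 20 clusters, 20 subjects per cluster, and
    predictor strength 0.5 and 3.0."""
    base = default or SimulationConfig()
    return {
        "icc_0.05": base.replace(icc=0.05),
        "icc_0.50": base.replace(icc=0.50),
        "prevalence_0.10": base.replace(target_prevalence=0.10),
        "prevalence_0.25": base.replace(target_prevalence=0.25),
        "clusters_20": base.replace(n_clusters=20),
        "cluster_size_20": base.replace(cluster_size=20),
        "beta1_0.5": base.replace(beta1=0.5),
        "beta1_3.0": base.replace(beta1=3.0),
    }


def run_sensitivity_suite(spec: ScenarioSpec) -> Dict[str, ScenarioResult]:
    """Run every sensitivity scenario with the spec's models and settings."""
    out = {}
    for name, cfg in sensitivity_configs(spec.config).items():
        out[name] = run_scenario(replace(spec, config=cfg))
    return out
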