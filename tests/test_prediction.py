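import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, truncnorm

from clustpred import (
    ExpertJudgment,
    PosteriorDraws,
    SimulationConfig,
    generate_dataset,
    predict_bayes_truncated,
    predict_bayes_weakly,
    predicted_risk,
    summarize_point,
)
from clustpred.expert import region_bounds
from clustpred.prediction import sample_cluster_effects

# Worked posterior-prediction examples: five posterior draws applied to two
# new-cluster subjects (x = 1.1 and x = -0.46), risks printed at 2 d.p.
WORKED_EXAMPLES = [
    # (beta0, beta1, u_c, x, risk)
    (-1.35, 1.07, 0.50, 1.1, 0.58),
    (-1.35, 1.07, 0.50, -0.46, 0.21),
    (-1.24, 1.08, -1.89, 1.1, 0.13),
    (-1.24, 1.08, -1.89, -0.46, 0.03),
    (-1.36, 1.18, -0.06, 1.1, 0.47),
    (-1.36, 1.18, -0.06, -0.46, 0.12),
    (-1.31, 1.05, -0.64, 1.1, 0.31),
    (-1.31, 1.05, -0.64, -0.46, 0.08),
    (-0.94, 0.98, 0.26, 1.1, 0.60),
    (-0.94, 0.98, 0.26, -0.46, 0.24),
]


@pytest.mark.parametrize("beta0, beta1, u, x, expected", WORKED_EXAMPLES)
def test_predicted_risk_worked_examples(beta0, beta1, u, x, expected):
    assert round(float(predicted_risk(beta0, beta1, u, x)), 2) == expected


def test_predicted_risk_overflow_safe():
    assert predicted_risk(0, 0, 0, 5.0) == 0.5
    assert float(predicted_risk(800.0, 0, 0, 0)) == 1.0
    assert float(predicted_risk(-800.0, 0, 0, 0)) == 0.0


class TestSummarizePoint:
    def test_constant(self):
        assert summarize_point(np.full(7, 0.3)) == pytest.approx(0.3)

    def test_even_count_midpoint(self):
        assert summarize_point(np.array([0.1, 0.2, 0.3, 0.4])) == pytest.approx(0.25)

    def test_matches_sorting_oracle(self, rng):
        draws = rng.uniform(size=200)
        s = np.sort(draws)
        assert summarize_point(draws) == pytest.approx((s[99] + s[100]) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_point(np.array([]))


def _synthetic_draws(K=200, sigma2=1.0, beta0=-1.0, beta1=1.2, seed=0):
    rng = np.random.default_rng(seed)
    return PosteriorDraws(
        pd.DataFrame(
            {
                "chain": np.repeat([0, 1], K // 2),
                "iteration": np.tile(10 * np.arange(1, K // 2 + 1), 2),
                "beta0": beta0 + 0.05 * rng.standard_normal(K),
                "beta1": beta1 + 0.05 * rng.standard_normal(K),
                "sigma_u2": sigma2 * np.exp(0.1 * rng.standard_normal(K)),
            }
        ),
        thin=10,
        burn_in=1000,
    )


@pytest.fixture(scope="module")
def new_data():
    cfg = SimulationConfig(n_clusters=10, cluster_size=25, seed=51)
    return generate_dataset(cfg, "prediction")


class TestBayesPrediction:
    def test_single_region_reproduces_weakly_informative(self, new_data):
        draws = _synthetic_draws()
        judgments = [
            ExpertJudgment(cid, m=1, region=1) for cid in new_data.cluster_ids
        ]
        a = predict_bayes_weakly(draws, new_data, seed=21)
        b = predict_bayes_truncated(draws, new_data, judgments, seed=21)
        np.testing.assert_array_equal(a.risk_draws, b.risk_draws)
        np.testing.assert_array_equal(a.u_draws, b.u_draws)

    def test_weakly_effect_draws_are_centered(self, rng):
        u = sample_cluster_effects(np.ones(10_000), np.array([1]), 1, rng)
        assert abs(u.mean()) < 0.03

    def test_lower_half_mean_is_half_normal(self, rng):
        # E[u | u < 0, sigma=1] = -sqrt(2/pi)
        u = sample_cluster_effects(np.ones(100_000), np.array([1]), 2, rng)
        assert u.mean() == pytest.approx(-math.sqrt(2 / math.pi), abs=0.01)

    def test_truncated_draws_match_analytic_distribution(self, rng):
        sigma = 0.9066
        r, m = 2, 5
        u = sample_cluster_effects(
            np.full(100_000, sigma), np.array([r]), m, rng
        ).ravel()
        lo, hi = region_bounds(r, m, sigma)
        dist = truncnorm(lo / sigma, hi / sigma, scale=sigma)
        assert kstest(u, dist.cdf).pvalue > 0.01

    def test_draws_respect_region_bounds(self, new_data):
        draws = _synthetic_draws(sigma2=0.82)
        judgments = [
            ExpertJudgment(cid, m=5, region=1 + (i % 5))
            for i, cid in enumerate(new_data.cluster_ids)
        ]
        pred = predict_bayes_truncated(draws, new_data, judgments, seed=8)
        sigma_k = np.sqrt(draws.sigma_u2)
        for c, j in enumerate(judgments):
            for k in range(draws.n_draws):
                lo, hi = region_bounds(j.region, j.m, sigma_k[k])
                assert lo < pred.u_draws[c, k] < hi

    def test_regions_stochastically_ordered(self, rng):
        means = [
            sample_cluster_effects(
                np.full(20_000, 0.9), np.array([r]), 5, rng
            ).mean()
            for r in range(1, 6)
        ]
        assert np.all(np.diff(means) > 0)

    def test_within_cluster_ranking_follows_predictor(self, new_data):
        draws = _synthetic_draws()
        assert np.all(draws.beta1 > 0)
        pred = predict_bayes_weakly(draws, new_data, seed=4)
        df = pred.to_frame()
        for _, grp in df.groupby("cluster_id"):
            order_x = np.argsort(grp["x"].to_numpy())
            order_p = np.argsort(grp["risk_point"].to_numpy())
            np.testing.assert_array_equal(order_x, order_p)

    def test_cluster_shares_one_effect_draw(self, new_data):
        draws = _synthetic_draws(K=50)
        pred = predict_bayes_weakly(draws, new_data, seed=13)
        gidx = new_data.group_index
        # invert the risk to recover u per subject/draw and compare rows
        logit_risk = np.log(pred.risk_draws / (1 - pred.risk_draws))
        u_sub = logit_risk - (
            draws.beta0[None, :] + draws.beta1[None, :] * new_data.x[:, None]
        )
        np.testing.assert_allclose(u_sub, pred.u_draws[gidx], atol=1e-8)

    def test_missing_judgment_rejected(self, new_data):
        draws = _synthetic_draws(K=10)
        judgments = [ExpertJudgment(new_data.cluster_ids[0], m=2, region=1)]
        with pytest.raises(ValueError, match="no expert judgment"):
            predict_bayes_truncated(draws, new_data, judgments, seed=0)

    def test_mixed_scales_rejected(self, new_data):
        draws = _synthetic_draws(K=10)
        judgments = [
            ExpertJudgment(cid, m=2 if i else 3, region=1)
            for i, cid in enumerate(new_data.cluster_ids)
        ]
        with pytest.raises(ValueError, match="share one scale"):
            predict_bayes_truncated(draws, new_data, judgments, seed=0)

    def test_prediction_frame_export(self, new_data, tmp_path):
        draws = _synthetic_draws(K=20)
        pred = predict_bayes_weakly(draws, new_data, seed=2)
        df = pred.to_frame(include_draws=True)
        assert len(df) == new_data.n
        assert df["model"].eq("BAYES.WI").all()
        assert sum(c.startswith("risk_draw_") for c in df.columns) == 20
        path = tmp_path / "pred.csv"
        pred.to_csv(str(path))
        assert len(pd.read_csv(path)) == new_data.n
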