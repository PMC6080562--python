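import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from clustpred import (
    ClusteredDataset,
    RandomInterceptLogit,
    SimulationConfig,
    encode_expert_categories,
    generate_dataset,
    quantile_cutpoints,
)
from clustpred.glmm import REFERENCE_CATEGORY, RandomInterceptLogitResults


@pytest.fixture(scope="module")
def independent_data():
    """Data generated with zero between-cluster variance, on a replicate
    where the variance estimate reaches the zero boundary (that happens for
    roughly half of replicates; only there does the mixed fit collapse to
    the plain logistic fit)."""
    cfg = SimulationConfig(
        n_clusters=20, cluster_size=100, icc=None, sigma_u2=0.0, seed=30
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="module")
def independent_fit(independent_data):
    return RandomInterceptLogit.from_dataset(independent_data).fit()


class TestFit:
    def test_no_clustering_matches_plain_logistic(
        self, independent_data, independent_fit
    ):
        X = sm.add_constant(independent_data.x)
        plain = sm.Logit(independent_data.y, X).fit(disp=0)
        assert independent_fit.beta0 == pytest.approx(plain.params[0], abs=1e-4)
        assert independent_fit.beta1 == pytest.approx(plain.params[1], abs=1e-4)
        assert independent_fit.sigma_u2 < 0.01

    def test_beta1_recovery_default_scenario(self, ml_fit_default):
        assert ml_fit_default.converged
        se = ml_fit_default.bse[1]
        assert abs(ml_fit_default.beta1 - 1.5) < 3 * se

    def test_cluster_duplication_leaves_estimates_unchanged(self, small_data):
        fit1 = RandomInterceptLogit.from_dataset(small_data).fit()
        dup = small_data.df.copy()
        dup["cluster_id"] = dup["cluster_id"] + small_data.n_clusters
        doubled = ClusteredDataset(
            pd.concat([small_data.df, dup], ignore_index=True)
        )
        fit2 = RandomInterceptLogit.from_dataset(doubled).fit()
        # duplicating whole clusters squares the likelihood: same argmax
        np.testing.assert_allclose(fit2.params, fit1.params, atol=5e-4)
        assert fit2.sigma_u == pytest.approx(fit1.sigma_u, abs=5e-4)
        assert fit2.loglik == pytest.approx(2 * fit1.loglik, rel=1e-5)

    def test_marginal_loglik_dominates_independence_fit(self, small_data):
        fit = RandomInterceptLogit.from_dataset(small_data).fit()
        model = RandomInterceptLogit.from_dataset(small_data)
        X = sm.add_constant(small_data.x)
        plain = sm.Logit(small_data.y, X).fit(disp=0)
        at_zero = model.loglike(np.append(plain.params, 1e-6))
        assert fit.loglik >= at_zero - 1e-6

    def test_quadrature_node_stability(self, dev_data):
        model = RandomInterceptLogit.from_dataset(dev_data)
        f7 = model.fit(n_quad=7)
        f25 = model.fit(n_quad=25)
        assert abs(f7.beta1 - f25.beta1) < 1e-3

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            RandomInterceptLogit(
                np.ones(10), np.ones((10, 1)), np.repeat([1, 2], 5)
            )

    def test_agrees_with_lme4_reference(self, small_data, tmp_path):
        """Independent oracle: the same model fitted by lme4's glmer with
        15-node adaptive quadrature."""
        csv = tmp_path / "data.csv"
        small_data.to_csv(str(csv))
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            f <- glmer(y ~ x + (1 | cluster_id), data = d,
                       family = binomial, nAGQ = 15)
            cat(fixef(f), sqrt(unlist(VarCorr(f))), logLik(f), sep = "\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        b0, b1, sigma, ll = map(float, out.stdout.strip().split("\n"))
        fit = RandomInterceptLogit.from_dataset(small_data).fit()
        assert fit.beta0 == pytest.approx(b0, abs=5e-3)
        assert fit.beta1 == pytest.approx(b1, abs=5e-3)
        assert fit.sigma_u == pytest.approx(sigma, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-2)


class TestExpertCategories:
    def test_reference_categories(self):
        # lower half, second tertile, third quintile
        assert REFERENCE_CATEGORY == {2: 1, 3: 2, 5: 3}

    def test_maximal_effect_in_highest_bin(self, rng):
        u = rng.standard_normal(50)
        for m in (2, 3, 5):
            cut = quantile_cutpoints(u, m)
            codes = encode_expert_categories(u, cut)
            assert codes[np.argmax(u)] == m

    def test_even_quintile_occupancy(self, rng):
        u = rng.standard_normal(50)
        codes = encode_expert_categories(u, quantile_cutpoints(u, 5))
        assert np.bincount(codes, minlength=6)[1:].tolist() == [10] * 5

    def test_tie_on_cutpoint_goes_to_lower_bin(self):
        u = np.arange(10.0)
        cut = np.array([u[4]])  # a cutpoint equal to an observed value
        codes = encode_expert_categories(u, cut)
        assert codes[4] == 1 and codes[5] == 2

    def test_fit_includes_m_minus_one_dummies(self, small_data):
        u = small_data.true_u_by_cluster()
        codes = encode_expert_categories(u, quantile_cutpoints(u, 3))
        fit = RandomInterceptLogit.from_dataset(
            small_data, expert_codes=codes, m=3
        ).fit()
        assert len(fit.category_coefs) == 2
        assert REFERENCE_CATEGORY[3] not in fit.category_coefs


class TestPredict:
    @pytest.fixture(scope="class")
    def null_results(self, small_data):
        model = RandomInterceptLogit.from_dataset(small_data)
        return RandomInterceptLogitResults(
            model=model,
            params=np.array([0.0, 0.0]),
            sigma_u=1.0,
            loglik=0.0,
            converged=True,
            n_quadrature=15,
            cov_params=np.eye(3),
        )

    def test_null_model_predicts_half(self, null_results):
        np.testing.assert_allclose(
            null_results.predict([-2.0, 0.0, 3.0]), 0.5
        )

    def test_zeroed_random_effect_value(self, small_data):
        model = RandomInterceptLogit.from_dataset(small_data)
        res = RandomInterceptLogitResults(
            model=model, params=np.array([-1.35, 1.07]), sigma_u=1.0,
            loglik=0.0, converged=True, n_quadrature=15, cov_params=np.eye(3),
        )
        # no random-effect contribution: expit(-1.35 + 1.07 * 1.1) = 0.4569;
        # with the posterior-sample random effect 0.50 added this subject's
        # risk would instead be 0.58, so zeroing the effect is visible here
        assert res.predict([1.1])[0] == pytest.approx(0.4569, abs=5e-4)

    def test_monotone_in_x(self, ml_fit_default):
        x = np.linspace(-3, 3, 50)
        risks = ml_fit_default.predict(x)
        assert ml_fit_default.beta1 > 0
        assert np.all(np.diff(risks) > 0)

    def test_unknown_category_code_rejected(self, small_data):
        u = small_data.true_u_by_cluster()
        codes = encode_expert_categories(u, quantile_cutpoints(u, 2))
        fit = RandomInterceptLogit.from_dataset(
            small_data, expert_codes=codes, m=2
        ).fit()
        with pytest.raises(ValueError, match="unknown category"):
            fit.predict([0.0], np.array([7]))
        with pytest.raises(ValueError, match="codes required"):
            fit.predict([0.0])
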