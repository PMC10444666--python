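"""LR tests, information criteria, random-effect prediction."""



import numpy as np
import pytest
from scipy.special import logsumexp

import mptml
from mptml import (
    ParameterSet,
    PersonData,
    QuadratureSpec,
    fit,
    information_criteria,
    joint_logdensity,
    lr_test,
    predict_random_effects,
)
from mptml.links import link_inverse


def _fake_fit(loglik, n_labels, n_obs=100):
    """Minimal FitResult stand-in for arithmetic-level LR/IC checks."""
    from mptml.estimation import FitResult
    from mptml.integration import ModeSet

    pset = ParameterSet(["p"], np.ones(1, bool), mu=np.zeros(1), Sigma=np.eye(1))
    from mptml.likelihood import ParameterMap

    return FitResult(
        params=pset,
        flat_estimates=np.zeros(n_labels),
        labels=[f"t{i}" for i in range(n_labels)],
        std_errors=np.ones(n_labels),
        cov_params=np.eye(n_labels),
        loglik=loglik,
        per_person_loglik=np.zeros(1),
        n_obs=n_obs,
        modes=ModeSet(np.zeros((1, 1)), np.ones((1, 1, 1))),
        converged=True,
        messages=[],
        spec=QuadratureSpec(),
        link="probit",
        n_iter=1,
        pmap=ParameterMap(pset),
    )


class TestLrTest:
    def test_statistic_arithmetic(self):
        res = lr_test(_fake_fit(-105.0, 3), _fake_fit(-100.0, 5))
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 2

    def test_df19_critical_value(self):
        res = lr_test(_fake_fit(-105.0, 1), _fake_fit(-100.0, 20))
        assert res.df == 19
        assert res.crit_05 == pytest.approx(30.14, abs=0.01)
        assert round(res.crit_05, 1) == 30.1

    def test_zero_statistic_p_one(self):
        res = lr_test(_fake_fit(-100.0, 3), _fake_fit(-100.0, 5))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_equal_df_rejected(self):
        with pytest.raises(ValueError):
            lr_test(_fake_fit(-105.0, 4), _fake_fit(-100.0, 4))

    def test_restricted_above_unrestricted_warns(self):
        with pytest.warns(UserWarning, match="optimizer"):
            lr_test(_fake_fit(-90.0, 3), _fake_fit(-100.0, 5))

    def test_nested_pair_clustering_restriction(self, small_pair_dataset):
        # u = a holds only approximately in the population (0.25 vs 0.15),
        # but both fits must satisfy ll_r <= ll_u
        pop, data, _ = small_pair_dataset
        full = fit(pop.model, data, spec=QuadratureSpec("aghq", nodes_per_dim=2),
                   config={"compute_se": False})
        restricted_model = mptml.apply_restrictions(
            pop.model, [mptml.parse_restriction("u=a")]
        )
        red_data = [
            PersonData.from_frequencies(restricted_model, p.frequencies)
            for p in data
        ]
        red = fit(restricted_model, red_data,
                  spec=QuadratureSpec("aghq", nodes_per_dim=2),
                  config={"compute_se": False})
        res = lr_test(red, full)
        assert res.statistic >= 0.0
        assert res.df == (4 + 10) - (3 + 6)

    def test_lr_calibration_under_true_restriction(self, two_tree_model):
        # fixed-effects nested pair: unrestricted p != q vs restricted p = q,
        # data generated under the restriction; E[LR] ~ df = 1
        rng = np.random.default_rng(17)
        restricted_model = mptml.apply_restrictions(
            two_tree_model, [mptml.parse_restriction("p=q")]
        )
        stats = []
        for _ in range(25):
            counts = rng.multinomial(30, [0.4, 0.6], size=2)
            freqs = np.array([counts[0, 0], counts[0, 1], counts[1, 0], counts[1, 1]])
            d_u = [PersonData.from_frequencies(two_tree_model, freqs)]
            d_r = [PersonData.from_frequencies(restricted_model, freqs)]
            f_u = fit(two_tree_model, d_u, spec=QuadratureSpec("laplace"),
                      config={"random": [], "compute_se": False})
            f_r = fit(restricted_model, d_r, spec=QuadratureSpec("laplace"),
                      config={"random": [], "compute_se": False})
            stats.append(lr_test(f_r, f_u).statistic)
        mean = np.mean(stats)
        # mean of chi2(1) is 1; MC half-width ~ 2*sqrt(2/25) ~ 0.57
        assert 0.3 < mean < 1.9


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        aic, _, df = information_criteria(_fake_fit(-100.0, 5))
        assert aic == pytest.approx(210.0)
        assert df == 5

    def test_pair_clustering_df(self, small_pair_dataset):
        pop, data, _ = small_pair_dataset
        res = fit(pop.model, data, spec=QuadratureSpec("laplace"),
                  config={"compute_se": False})
        _, _, df = information_criteria(res)
        assert df == 4 + 0 + 0 + 10  # R means + covariance parameters

    def test_bic_uses_total_response_count(self, small_pair_dataset):
        pop, data, _ = small_pair_dataset
        res = fit(pop.model, data, spec=QuadratureSpec("laplace"),
                  config={"compute_se": False})
        aic, bic, df = information_criteria(res)
        n = sum(p.n_responses for p in data)
        assert bic == pytest.approx(-2 * res.loglik + np.log(n) * df)

    def test_one_extra_weight_raises_aic_penalty_by_two(self):
        a1, _, _ = information_criteria(_fake_fit(-100.0, 5))
        a2, _, _ = information_criteria(_fake_fit(-100.0, 6))
        assert a2 - a1 == pytest.approx(2.0)


class TestRandomEffectPrediction:
    def test_zero_counts_returns_prior_mean(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([-0.4]),
                            Sigma=np.array([[0.7]]))
        data = [PersonData.from_frequencies(bernoulli_model, [0, 0]),
                PersonData.from_frequencies(bernoulli_model, [12, 8])]
        res = fit(bernoulli_model, data,
                  spec=QuadratureSpec("aghq", nodes_per_dim=9),
                  start=pset, config={"compute_se": False, "maxiter": 0,
                                      "restarts": 0, "polish_max": 0})
        for estimator in ("mode", "empirical_bayes"):
            b = predict_random_effects(fitted=res, estimator=estimator)
            assert b[0, 0] == pytest.approx(res.params.mu[0], abs=1e-6)

    def test_empirical_bayes_matches_trapezoid_oracle(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([-0.2]),
                            Sigma=np.array([[0.5]]))
        person = PersonData.from_frequencies(bernoulli_model, [14, 26])
        res = fit(bernoulli_model, [person],
                  spec=QuadratureSpec("aghq", nodes_per_dim=15),
                  start=pset, config={"compute_se": False, "maxiter": 0,
                                      "restarts": 0, "polish_max": 0})
        eb = predict_random_effects(fitted=res, estimator="empirical_bayes")[0, 0]
        grid = np.linspace(-6, 6, 20001)
        lj = np.array([
            joint_logdensity(bernoulli_model, res.params, [b], person) for b in grid
        ])
        w = np.exp(lj - logsumexp(lj))
        oracle = float((grid * w).sum())
        assert eb == pytest.approx(oracle, abs=1e-3)

    def test_shrinkage_towards_population_mean(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([-0.3]),
                            Sigma=np.array([[0.4]]))
        rng = np.random.default_rng(31)
        data, ml = [], []
        for _ in range(15):
            b = rng.normal(-0.3, np.sqrt(0.4))
            k = int(rng.binomial(20, link_inverse("probit", b)))
            k = min(max(k, 1), 19)  # keep the per-person ML estimate finite
            data.append(PersonData.from_frequencies(bernoulli_model, [k, 20 - k]))
            ml.append(mptml.link_forward("probit", k / 20))
        res = fit(bernoulli_model, data,
                  spec=QuadratureSpec("aghq", nodes_per_dim=11),
                  start=pset, config={"compute_se": False, "maxiter": 0,
                                      "restarts": 0, "polish_max": 0})
        eb = predict_random_effects(fitted=res, estimator="empirical_bayes")[:, 0]
        mu = res.params.mu[0]
        assert np.all(np.abs(eb - mu) <= np.abs(np.array(ml) - mu) + 1e-9)
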