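"""Conditional likelihood, joint density, analytic scores, parameter map."""

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import multivariate_normal

import mptml
from mptml import (
    ParameterMap,
    ParameterSet,
    PersonData,
    conditional_loglik,
    joint_logdensity,
    person_theta,
    score_components,
)
from mptml.simulate import DEFAULT_SIGMA


@pytest.fixture(scope="module")
def pair_pset(pair_model):
    return ParameterSet(
        parameter_names=pair_model.parameter_names,
        random_mask=np.ones(4, dtype=bool),
        mu=np.array([0.1, -0.2, -0.5, -1.0]),
        Sigma=DEFAULT_SIGMA,
    )


@pytest.fixture(scope="module")
def pair_person(pair_model):
    return PersonData.from_frequencies(pair_model, [2, 0, 1, 7, 1, 4])


class TestPersonTheta:
    def test_all_random_probit_at_zero(self, pair_model):
        pset = ParameterSet(pair_model.parameter_names, np.ones(4, bool),
                            mu=np.zeros(4), Sigma=np.eye(4))
        theta = person_theta(pset, np.zeros(4), np.zeros(0), "probit")
        np.testing.assert_allclose(theta, 0.5)

    def test_fixed_parameter_with_covariate(self):
        pset = ParameterSet(
            parameter_names=["p"],
            random_mask=np.zeros(1, bool),
            mu=np.zeros(0),
            Sigma=np.zeros((0, 0)),
            beta=np.array([0.0]),
            gamma=np.array([[1.0]]),
            covariate_names=["x"],
        )
        theta = person_theta(pset, np.zeros(0), np.array([2.0]), "logit")
        assert theta[0] == pytest.approx(1.0 / (1.0 + np.exp(-2.0)), abs=1e-9)

    def test_zeroed_weight_row_blocks_covariate(self, pair_model):
        Gamma = np.array([[0.7], [0.0], [0.0], [0.0]])
        pset = ParameterSet(
            pair_model.parameter_names, np.ones(4, bool),
            mu=np.zeros(4), Sigma=np.eye(4), Gamma=Gamma,
            covariate_names=["x"],
        )
        # theta depends on b only; covariates act through the mean of b
        b = np.array([0.3, -0.3, 0.1, 0.0])
        t1 = person_theta(pset, b, np.array([0.0]))
        t2 = person_theta(pset, b, np.array([5.0]))
        np.testing.assert_allclose(t1, t2)


class TestConditionalLoglik:
    def test_matches_direct_product_multinomial(
        self, pair_model, pair_pset, pair_person
    ):
        from scipy.special import ndtri

        b = ndtri([0.5, 0.4, 0.25, 0.15])  # theta = (.5, .4, .25, .15)
        got = conditional_loglik(pair_model, pair_pset, b, pair_person)
        # independent oracle: hand-written branch formulas + multinomial coefficients
        c, r, u, a = 0.5, 0.4, 0.25, 0.15
        probs = [c * r, (1 - c) * u**2, 2 * (1 - c) * u * (1 - u),
                 c * (1 - r) + (1 - c) * (1 - u) ** 2, a, 1 - a]
        n = pair_person.frequencies
        expected = (
            gammaln(11) - gammaln(n[:4] + 1.0).sum()
            + sum(n[j] * np.log(probs[j]) for j in range(4))
            + gammaln(6) - gammaln(n[4:] + 1.0).sum()
            + sum(n[4 + j] * np.log(probs[4 + j]) for j in range(2))
        )
        assert got == pytest.approx(float(expected), abs=1e-10)

    def test_certain_outcome_gives_zero(self):
        model = mptml.parse_eqn("t yes p\nt no (1-p)\ns hit q\ns miss (1-q)")
        fixed = mptml.apply_restrictions(model, [mptml.parse_restriction("q=1")])
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.zeros(1), Sigma=np.eye(1))
        person = PersonData.from_frequencies(fixed, [0, 0, 9, 0])
        assert conditional_loglik(fixed, pset, np.zeros(1), person) == pytest.approx(0.0)

    def test_doubling_counts_doubles_noncoefficient_part(
        self, pair_model, pair_pset, pair_person
    ):
        b = np.array([0.2, -0.1, -0.6, -0.9])
        model = pair_model
        coef = lambda p: float(  # noqa: E731
            gammaln(p.totals + 1.0).sum() - gammaln(p.frequencies + 1.0).sum()
        )
        p2 = PersonData.from_frequencies(model, 2 * pair_person.frequencies)
        l1 = conditional_loglik(model, pair_pset, b, pair_person) - coef(pair_person)
        l2 = conditional_loglik(model, pair_pset, b, p2) - coef(p2)
        assert l2 == pytest.approx(2 * l1, rel=1e-12)


class TestJointDensity:
    def test_decomposition(self, pair_model, pair_pset, pair_person):
        b = np.array([0.5, 0.1, -0.3, -1.2])
        joint = joint_logdensity(pair_model, pair_pset, b, pair_person)
        cond = conditional_loglik(pair_model, pair_pset, b, pair_person)
        gauss = multivariate_normal(pair_pset.mu, pair_pset.Sigma).logpdf(b)
        assert joint == pytest.approx(cond + gauss, abs=1e-10)

    def test_standard_normal_at_mean(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([-0.4]),
                            Sigma=np.array([[1.0]]))
        person = PersonData.from_frequencies(bernoulli_model, [3, 5])
        joint = joint_logdensity(bernoulli_model, pset, pset.mu, person)
        cond = conditional_loglik(bernoulli_model, pset, pset.mu, person)
        assert joint - cond == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_pure_gaussian_decreases_away_from_mean(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([0.2]),
                            Sigma=np.array([[0.5]]))
        empty = PersonData.from_frequencies(bernoulli_model, [0, 0])
        vals = [
            joint_logdensity(bernoulli_model, pset, np.array([0.2 + d]), empty)
            for d in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _random_structures(pair_model, two_tree_model):
    """Model/parameter configurations exercising fixed, random, covariates."""
    yield (
        pair_model,
        ParameterSet(pair_model.parameter_names, np.ones(4, bool),
                     mu=np.array([0.3, -0.2, -0.7, -1.1]), Sigma=DEFAULT_SIGMA),
        [2, 0, 1, 7, 1, 4],
        np.zeros(0),
    )
    yield (
        pair_model,
        ParameterSet(
            pair_model.parameter_names,
            np.array([True, True, False, False]),
            mu=np.array([0.1, -0.4]),
            Sigma=np.array([[0.4, 0.1], [0.1, 0.3]]),
            beta=np.array([-0.6, -1.0]),
            gamma=np.array([[0.2], [0.0]]),
            Gamma=np.array([[0.5], [-0.3]]),
            gamma_free=np.array([[True], [False]]),
            covariate_names=["age"],
        ),
        [5, 1, 3, 11, 2, 3],
        np.array([0.8]),
    )
    yield (
        two_tree_model,
        ParameterSet(two_tree_model.parameter_names, np.ones(2, bool),
                     mu=np.array([0.5, -0.5]),
                     Sigma=np.array([[0.7, -0.2], [-0.2, 0.5]])),
        [9, 6, 2, 13],
        np.zeros(0),
    )


class TestScores:
    def test_mu_derivative_zero_at_mean(self, bernoulli_model):
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([0.3]),
                            Sigma=np.array([[1.0]]))
        empty = PersonData.from_frequencies(bernoulli_model, [0, 0])
        pmap = ParameterMap(pset)
        g, _ = score_components(bernoulli_model, pset, pset.mu, empty, pmap=pmap)
        assert g[pmap.sl_mu][0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_variance_diagonal_derivative(self, bernoulli_model):
        # at b = mu with Sigma = 1 the log-chol diagonal score is -1
        # (the -1/2 derivative w.r.t. sigma, through d sigma /
        #  d log-chol = 2 at unit variance)
        pset = ParameterSet(["p"], np.ones(1, bool), mu=np.array([0.3]),
                            Sigma=np.array([[1.0]]))
        empty = PersonData.from_frequencies(bernoulli_model, [0, 0])
        pmap = ParameterMap(pset)
        g, _ = score_components(bernoulli_model, pset, pset.mu, empty, pmap=pmap)
        assert g[pmap.sl_chol][0] == pytest.approx(-1.0, abs=1e-12)

    def test_scores_match_finite_differences(self, pair_model, two_tree_model):
        rng = np.random.default_rng(11)
        h = 1e-6
        for model, pset, freqs, X in _random_structures(pair_model, two_tree_model):
            person = PersonData.from_frequencies(model, freqs, X)
            pmap = ParameterMap(pset)
            x = pmap.flatten(pset)
            for _ in range(6):
                b = pset.mu_t(X) + 0.5 * rng.standard_normal(pset.R)
                g_free, g_b = score_components(model, pset, b, person, pmap=pmap)
                for j in range(pmap.n_free):
                    e = np.zeros_like(x)
                    e[j] = h
                    fd = (
                        joint_logdensity(model, pmap.unflatten(x + e), b, person)
                        - joint_logdensity(model, pmap.unflatten(x - e), b, person)
                    ) / (2 * h)
                    assert g_free[j] == pytest.approx(fd, abs=2e-5, rel=1e-5)
                for j in range(pset.R):
                    e = np.zeros(pset.R)
                    e[j] = h
                    fd = (
                        joint_logdensity(model, pset, b + e, person)
                        - joint_logdensity(model, pset, b - e, person)
                    ) / (2 * h)
                    assert g_b[j] == pytest.approx(fd, abs=2e-5, rel=1e-5)


class TestParameterMap:
    def test_flatten_unflatten_roundtrip(self, pair_model):
        pset = ParameterSet(pair_model.parameter_names, np.ones(4, bool),
                            mu=np.array([0.4, -0.1, 0.0, -1.3]), Sigma=DEFAULT_SIGMA)
        pmap = ParameterMap(pset)
        x = pmap.flatten(pset)
        back = pmap.unflatten(x)
        np.testing.assert_allclose(back.mu, pset.mu, atol=1e-12)
        np.testing.assert_allclose(back.Sigma, pset.Sigma, atol=1e-12)
        np.testing.assert_allclose(pmap.flatten(back), x, atol=1e-12)

    def test_any_vector_yields_positive_definite_sigma(self, pair_model):
        pset = ParameterSet(pair_model.parameter_names, np.ones(4, bool),
                            mu=np.zeros(4), Sigma=np.eye(4))
        pmap = ParameterMap(pset)
        rng = np.random.default_rng(5)
        for _ in range(25):
            vec = rng.uniform(-3, 3, size=pmap.n_free)
            Sigma = pmap.unflatten(vec).Sigma
            assert np.all(np.linalg.eigvalsh(Sigma) > 0)

    def test_labels_cover_all_blocks(self, pair_model):
        pset = ParameterSet(
            pair_model.parameter_names,
            np.array([True, True, False, False]),
            mu=np.zeros(2), Sigma=np.eye(2),
            beta=np.zeros(2), covariate_names=["x"],
        )
        pmap = ParameterMap(pset)
        assert any(lab.startswith("mu[") for lab in pmap.labels)
        assert any(lab.startswith("beta[") for lab in pmap.labels)
        assert any(lab.startswith("Gamma[") for lab in pmap.labels)
        assert any(lab.startswith("gamma[") for lab in pmap.labels)
        assert sum(lab.startswith("lchol[") for lab in pmap.labels) == 3
        assert pmap.n_free == len(pmap.labels)
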