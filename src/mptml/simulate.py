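"""Synthetic-data generation from the latent-trait MPT population model.

Person parameters are drawn on the link scale from a multivariate normal,
mapped to probabilities, and category counts are drawn from the resulting
product multinomial.  The default population is the pair-clustering free
recall model: storage (c) and retrieval (r) of word-pair clusters, recall of
non-clustered pair members (u), and recall of singletons (a), with
probability-scale means (0.50, 0.40, 0.25, 0.15) and a link-scale covariance
whose non-zero terms correspond to correlations of 0.30, 0.20 and 0.10.
About 80% of each person's responses fall in the word-pair system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import cholesky

from .likelihood import ParameterSet, PersonData, person_theta
from .links import link_forward
from .tree import MptModel, parse_eqn

__all__ = [
    "PAIR_CLUSTERING_EQN",
    "pair_clustering_model",
    "PopulationSpec",
    "default_population",
    "simulate_dataset",
]

#: the pair-clustering free-recall model (word pairs + singletons)
PAIR_CLUSTERING_EQN = """\
pairs C11 c*r
pairs C12 (1-c)*u*u
pairs C13 (1-c)*u*(1-u)
pairs C13 (1-c)*(1-u)*u
pairs C14 c*(1-r)
pairs C14 (1-c)*(1-u)*(1-u)
singletons C21 a
singletons C22 (1-a)
"""

#: link-scale covariance of (c, r, u, a) used by the default population
DEFAULT_SIGMA = np.array(
    [
        [0.50, 0.08, 0.04, 0.00],
        [0.08, 0.35, 0.03, 0.00],
        [0.04, 0.03, 0.20, 0.07],
        [0.00, 0.00, 0.07, 0.20],
    ]
)

#: probability-scale means of (c, r, u, a) in the default population
DEFAULT_MU_PROB = np.array([0.50, 0.40, 0.25, 0.15])


def pair_clustering_model() -> MptModel:
    """The 4-parameter, 2-tree pair-clustering model."""
    return parse_eqn(PAIR_CLUSTERING_EQN)


@dataclass
class PopulationSpec:
    """A simulation population: model, latent-trait distribution, design."""

    model: MptModel
    mu_prob: np.ndarray  # (R,) probability-scale means of the random parameters
    Sigma: np.ndarray  # (R, R) link-scale covariance
    T: int = 75
    counts_per_system: tuple = (20, 5)
    link: str = "probit"
    random_mask: np.ndarray | None = None  # default: all parameters random
    beta: np.ndarray | None = None  # link-scale intercepts of fixed parameters
    gamma: np.ndarray | None = None
    Gamma: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)
    covariate_sampler: Callable | None = None  # f(rng, T) -> (T, p)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_mask is None:
            self.random_mask = np.ones(self.model.n_parameters, dtype=bool)
        self.random_mask = np.asarray(self.random_mask, dtype=bool)
        self.mu_prob = np.atleast_1d(np.asarray(self.mu_prob, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if np.any(self.mu_prob <= 0.0) or np.any(self.mu_prob >= 1.0):
            raise ValueError("mu_prob entries must lie strictly in (0, 1)")
        if self.T < 1 or any(c < 0 for c in self.counts_per_system):
            raise ValueError("T must be >= 1 and counts non-negative")
        if len(self.counts_per_system) != self.model.n_systems:
            raise ValueError("counts_per_system must give one total per tree")
        cholesky(self.Sigma, lower=True)  # PD check

    def parameter_set(self) -> ParameterSet:
        """The population as a :class:`ParameterSet` (the simulation truth)."""
        p = len(self.covariate_names)
        R = int(self.random_mask.sum())
        return ParameterSet(
            parameter_names=list(self.model.parameter_names),
            random_mask=self.random_mask,
            mu=link_forward(self.link, self.mu_prob),
            Sigma=self.Sigma,
            beta=self.beta if self.beta is not None else np.zeros(
                self.model.n_parameters - R
            ),
            gamma=self.gamma,
            Gamma=self.Gamma,
            covariate_names=list(self.covariate_names),
        )


def default_population(
    T: int = 75, counts_per_system: tuple = (20, 5), link: str = "probit",
    seed: int = 0,
) -> PopulationSpec:
    """The pair-clustering simulation population (the N=25 design cell by
    default: 20 pair responses and 5 singleton responses per person)."""
    return PopulationSpec(
        model=pair_clustering_model(),
        mu_prob=DEFAULT_MU_PROB.copy(),
        Sigma=DEFAULT_SIGMA.copy(),
        T=T,
        counts_per_system=tuple(counts_per_system),
        link=link,
        seed=seed,
    )


def simulate_dataset(spec: PopulationSpec):
    """Draw a dataset from the population.

    Per person: draw link-scale random effects b_t ~ MVN(mu + Gamma X_t,
    Sigma), map to probabilities, and draw each system's counts from a
    multinomial with the requested totals.  Fully reproducible from
    ``spec.seed``.

    Returns ``(data, truth)`` where ``data`` is a list of
    :class:`PersonData` and ``truth`` records the generating parameters and
    the drawn random effects.
    """
    rng = np.random.default_rng(spec.seed)
    pset = spec.parameter_set()
    model = spec.model
    R, T = pset.R, spec.T

    if spec.covariate_sampler is not None:
        X = np.asarray(spec.covariate_sampler(rng, T), dtype=float)
        X = X.reshape(T, -1)
    else:
        X = np.zeros((T, len(spec.covariate_names)))

    L = cholesky(pset.Sigma, lower=True) if R else np.zeros((0, 0))
    z = rng.standard_normal((T, R))
    b_all = np.empty((T, R))
    data: list[PersonData] = []
    cps = model.categories_per_system
    offsets = np.concatenate([[0], np.cumsum(cps)])
    for t in range(T):
        mu_t = pset.mu_t(X[t])
        b_t = mu_t + L @ z[t]
        b_all[t] = b_t
        theta = person_theta(pset, b_t, X[t], spec.link)
        probs = model.category_probabilities(theta)
        freqs = np.zeros(model.n_categories_total, dtype=np.int64)
        for k in range(model.n_systems):
            pk = probs[offsets[k]: offsets[k + 1]]
            pk = pk / pk.sum()
            freqs[offsets[k]: offsets[k + 1]] = rng.multinomial(
                spec.counts_per_system[k], pk
            )
        data.append(PersonData.from_frequencies(model, freqs, X[t]))

    truth = {
        "mu_prob": spec.mu_prob.copy(),
        "mu_link": pset.mu.copy(),
        "Sigma": pset.Sigma.copy(),
        "beta": pset.beta.copy(),
        "gamma": pset.gamma.copy(),
        "Gamma": pset.Gamma.copy(),
        "random_mask": pset.random_mask.copy(),
        "link": spec.link,
        "seed": spec.seed,
        "b": b_all,
        "X": X,
    }
    return data, truth
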