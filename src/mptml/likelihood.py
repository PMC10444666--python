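"""Conditional likelihood, joint log-density and analytic scores.

The hierarchical model: for person ``t`` the link-scale values of the R
*random* process parameters are ``b_t ~ MVN(mu + Gamma X_t, Sigma)``; the
remaining S-R *fixed* parameters sit at ``beta_s + gamma_s X_t`` for every
person.  Given ``b_t`` the category counts follow the product-multinomial MPT
likelihood.  This module evaluates

* ``conditional_loglik`` -- log f(n_t | b_t)  (multinomial coefficients included),
* ``joint_logdensity``   -- log f(n_t | b_t) + log MVN(b_t | mu_t, Sigma),
* ``score_components``   -- exact gradients of the joint log-density with
  respect to every free model parameter and with respect to ``b_t``.

Sigma is carried through unconstrained optimization as a log-Cholesky factor
(log on the diagonal), which keeps it positive definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import gammaln

from .links import link_derivative, link_inverse
from .tree import MptModel

__all__ = [
    "ParameterSet",
    "PersonData",
    "ParameterMap",
    "LikelihoodEngine",
    "person_theta",
    "conditional_loglik",
    "joint_logdensity",
    "score_components",
]

_LOG_2PI = np.log(2.0 * np.pi)
_TINY = 1e-300
#: bound on log-Cholesky diagonal entries during unconstrained optimization
_LCHOL_DIAG_BOUND = 12.0


def _safe_cholesky(Sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating edge-of-domain numerical PSD-ness."""
    scale = max(1.0, float(np.max(np.diag(Sigma), initial=1.0)))
    for eps in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return cholesky(Sigma + eps * scale * np.eye(Sigma.shape[0]),
                            lower=True)
        except np.linalg.LinAlgError:
            continue
    raise ValueError("Sigma must be positive definite")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class ParameterSet:
    """All estimable quantities of the hierarchical model.

    ``random_mask`` marks which of the S process parameters carry a person
    random effect; for identification their intercepts are fixed at zero, so
    ``beta``/``gamma`` have one row per *fixed* parameter only.  Structural
    zeros in the covariate weights are encoded by ``gamma_free``/``Gamma_free``
    (False entries are pinned at zero and never estimated).
    """

    parameter_names: list[str]
    random_mask: np.ndarray  # bool (S,)
    mu: np.ndarray  # (R,)
    Sigma: np.ndarray  # (R, R)
    beta: np.ndarray | None = None  # (S-R,)
    gamma: np.ndarray | None = None  # (S-R, p)
    Gamma: np.ndarray | None = None  # (R, p)
    gamma_free: np.ndarray | None = None  # bool (S-R, p)
    Gamma_free: np.ndarray | None = None  # bool (R, p)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.random_mask = np.asarray(self.random_mask, dtype=bool)
        S, R, p = self.S, self.R, self.n_covariates
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        if self.mu.shape != (R,):
            raise ValueError(f"mu must have length R={R}")
        if self.Sigma.shape != (R, R):
            raise ValueError(f"Sigma must be {R}x{R}")
        if R and not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        self._chol = _safe_cholesky(self.Sigma) if R else np.zeros((0, 0))
        if self.beta is None:
            self.beta = np.zeros(S - R)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.shape != (S - R,):
            raise ValueError(f"beta must have length S-R={S - R}")
        for name, rows in (("gamma", S - R), ("Gamma", R)):
            mat = getattr(self, name)
            if mat is None:
                mat = np.zeros((rows, p))
            mat = np.asarray(mat, dtype=float).reshape(rows, p)
            setattr(self, name, mat)
            free = getattr(self, name + "_free")
            if free is None:
                free = np.ones((rows, p), dtype=bool)
            free = np.asarray(free, dtype=bool).reshape(rows, p)
            setattr(self, name + "_free", free)
            if np.any(mat[~free] != 0.0):
                raise ValueError(f"structurally zero entries of {name} must be 0")

    @property
    def chol(self) -> np.ndarray:
        """Cached lower Cholesky factor of Sigma."""
        return self._chol

    @property
    def S(self) -> int:
        return len(self.parameter_names)

    @property
    def R(self) -> int:
        return int(self.random_mask.sum())

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    @property
    def random_indices(self) -> np.ndarray:
        return np.flatnonzero(self.random_mask)

    @property
    def fixed_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.random_mask)

    @property
    def random_names(self) -> list[str]:
        return [self.parameter_names[i] for i in self.random_indices]

    @property
    def fixed_names(self) -> list[str]:
        return [self.parameter_names[i] for i in self.fixed_indices]

    def mu_t(self, X: np.ndarray) -> np.ndarray:
        """Person-specific random-effect mean ``mu + Gamma X``."""
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return self.mu.copy()
        return self.mu + self.Gamma @ X


@dataclass
class PersonData:
    """One participant: flat category counts, per-system totals, covariates."""

    frequencies: np.ndarray  # (n_categories_total,) int, model category order
    totals: np.ndarray  # (K,)
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        if np.any(self.frequencies < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_frequencies(
        cls, model: MptModel, frequencies, covariates=()
    ) -> "PersonData":
        freqs = np.asarray(frequencies, dtype=np.int64)
        if freqs.shape != (model.n_categories_total,):
            raise ValueError(
                f"expected {model.n_categories_total} category counts, "
                f"got {freqs.shape}"
            )
        totals = np.bincount(
            model.system_of_category, weights=freqs, minlength=model.n_systems
        ).astype(np.int64)
        return cls(freqs, totals, np.asarray(covariates, dtype=float))

    @property
    def n_responses(self) -> int:
        return int(self.totals.sum())


class ParameterMap:
    """Ordered flattening of the free entries of a :class:`ParameterSet`.

    Order: mu, beta, free Gamma entries (row-major), free gamma entries,
    then the log-Cholesky factor of Sigma (lower triangle, row-major, log on
    the diagonal).  ``flatten`` / ``unflatten`` are exact inverses and the
    unflattened Sigma is positive definite for any real vector.
    """

    def __init__(self, template: ParameterSet):
        self.template = template
        R, p = template.R, template.n_covariates
        labels: list[str] = [f"mu[{n}]" for n in template.random_names]
        labels += [f"beta[{n}]" for n in template.fixed_names]
        self._Gamma_idx = [
            (r, c) for r in range(R) for c in range(p) if template.Gamma_free[r, c]
        ]
        labels += [
            f"Gamma[{template.random_names[r]},{template.covariate_names[c]}]"
            for r, c in self._Gamma_idx
        ]
        self._gamma_idx = [
            (r, c)
            for r in range(template.S - R)
            for c in range(p)
            if template.gamma_free[r, c]
        ]
        labels += [
            f"gamma[{template.fixed_names[r]},{template.covariate_names[c]}]"
            for r, c in self._gamma_idx
        ]
        self.chol_pairs = [(i, j) for i in range(R) for j in range(i + 1)]
        rn = template.random_names
        labels += [f"lchol[{rn[i]},{rn[j]}]" for i, j in self.chol_pairs]

        self.labels = labels
        self.n_free = len(labels)
        n_mu, n_beta = R, template.S - R
        nG, ng = len(self._Gamma_idx), len(self._gamma_idx)
        ofs = np.cumsum([0, n_mu, n_beta, nG, ng, len(self.chol_pairs)])
        self.sl_mu = slice(ofs[0], ofs[1])
        self.sl_beta = slice(ofs[1], ofs[2])
        self.sl_Gamma = slice(ofs[2], ofs[3])
        self.sl_gamma = slice(ofs[3], ofs[4])
        self.sl_chol = slice(ofs[4], ofs[5])

    # -- conversions --------------------------------------------------------
    def flatten(self, pset: ParameterSet) -> np.ndarray:
        R = pset.R
        out = np.empty(self.n_free)
        out[self.sl_mu] = pset.mu
        out[self.sl_beta] = pset.beta
        out[self.sl_Gamma] = [pset.Gamma[r, c] for r, c in self._Gamma_idx]
        out[self.sl_gamma] = [pset.gamma[r, c] for r, c in self._gamma_idx]
        if R:
            L = pset.chol
            vals = []
            for i, j in self.chol_pairs:
                vals.append(np.log(L[i, i]) if i == j else L[i, j])
            out[self.sl_chol] = vals
        return out

    def chol_from_vector(self, vec: np.ndarray) -> np.ndarray:
        R = self.template.R
        L = np.zeros((R, R))
        for val, (i, j) in zip(vec[self.sl_chol], self.chol_pairs):
            if i == j:
                # clip so line-search excursions cannot overflow Sigma
                L[i, j] = np.exp(np.clip(val, -_LCHOL_DIAG_BOUND, _LCHOL_DIAG_BOUND))
            else:
                L[i, j] = np.clip(val, -1e6, 1e6)
        return L

    def unflatten(self, vec: np.ndarray) -> ParameterSet:
        t = self.template
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise ValueError(f"expected vector of length {self.n_free}")
        Gamma = np.zeros_like(t.Gamma)
        for val, (r, c) in zip(vec[self.sl_Gamma], self._Gamma_idx):
            Gamma[r, c] = val
        gamma = np.zeros_like(t.gamma)
        for val, (r, c) in zip(vec[self.sl_gamma], self._gamma_idx):
            gamma[r, c] = val
        L = self.chol_from_vector(vec)
        Sigma = L @ L.T if t.R else np.zeros((0, 0))
        return ParameterSet(
            parameter_names=list(t.parameter_names),
            random_mask=t.random_mask.copy(),
            mu=vec[self.sl_mu].copy(),
            Sigma=Sigma,
            beta=vec[self.sl_beta].copy(),
            gamma=gamma,
            Gamma=Gamma,
            gamma_free=t.gamma_free.copy(),
            Gamma_free=t.Gamma_free.copy(),
            covariate_names=list(t.covariate_names),
        )

    # -- delta method for Sigma entries -------------------------------------
    def sigma_entry_labels(self) -> list[str]:
        rn = self.template.random_names
        return [f"Sigma[{rn[i]},{rn[j]}]" for i, j in self.chol_pairs]

    def sigma_entries(self, pset: ParameterSet) -> np.ndarray:
        return np.array([pset.Sigma[i, j] for i, j in self.chol_pairs])

    def sigma_jacobian(self, vec: np.ndarray) -> np.ndarray:
        """d(natural-scale Sigma entries)/d(free vector); zero outside the
        log-Cholesky block."""
        L = self.chol_from_vector(vec)
        n_entries = len(self.chol_pairs)
        J = np.zeros((n_entries, self.n_free))
        base = self.sl_chol.start
        for col, (a, bcol) in enumerate(self.chol_pairs):
            E = np.zeros_like(L)
            E[a, bcol] = L[a, a] if a == bcol else 1.0
            dS = E @ L.T + L @ E.T
            for row, (i, j) in enumerate(self.chol_pairs):
                J[row, base + col] = dS[i, j]
        return J


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------
class LikelihoodEngine:
    """Vectorized product-multinomial likelihood over batches of theta."""

    def __init__(self, model: MptModel, link: str = "probit"):
        self.model = model
        self.link = link
        self.A = model.a_exponents.astype(float)  # (nb, S)
        self.B = model.b_exponents.astype(float)
        with np.errstate(divide="ignore"):
            self.log_const = np.log(model.branch_constants)
        self.cat_idx = model.branch_category_index
        ncat, nb = model.n_categories_total, model.n_branches
        M = np.zeros((ncat, nb))
        M[self.cat_idx, np.arange(nb)] = 1.0
        self.M = M

    def log_multinomial_coef(self, counts: np.ndarray) -> np.ndarray:
        """Log multinomial coefficients, summed over systems; counts (T, ncat)."""
        counts = np.atleast_2d(counts)
        sys_of_cat = self.model.system_of_category
        totals = np.stack(
            [counts[:, sys_of_cat == k].sum(axis=1) for k in range(self.model.n_systems)],
            axis=1,
        )
        return gammaln(totals + 1.0).sum(axis=1) - gammaln(counts + 1.0).sum(axis=1)

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        """Category probabilities for a (..., S) batch of theta."""
        with np.errstate(divide="ignore"):
            logPB = (
                np.log(theta) @ self.A.T
                + np.log1p(-theta) @ self.B.T
                + self.log_const
            )
        return np.exp(logPB) @ self.M.T

    def cond_loglik(self, theta: np.ndarray, counts: np.ndarray) -> np.ndarray:
        """log f(n | theta) without coefficients; theta (T, Q, S), counts (T, ncat)."""
        Pcat = self.category_probs(theta)
        logp = np.log(np.clip(Pcat, _TINY, None))
        return np.einsum("...qc,...c->...q", logp, counts.astype(float))

    def cond_loglik_and_dtheta(self, theta, counts):
        """Conditional log-likelihood and its gradient in theta."""
        with np.errstate(divide="ignore"):
            logPB = (
                np.log(theta) @ self.A.T
                + np.log1p(-theta) @ self.B.T
                + self.log_const
            )
        PB = np.exp(logPB)
        Pcat = PB @ self.M.T
        Pcat_safe = np.clip(Pcat, _TINY, None)
        cf = counts.astype(float)
        cll = np.einsum("...qc,...c->...q", np.log(Pcat_safe), cf)
        w = cf[..., None, :] / Pcat_safe  # (T, Q, ncat)
        wb = PB * w[..., self.cat_idx]  # (T, Q, nb)
        dth = (wb @ self.A) / theta - (wb @ self.B) / (1.0 - theta)
        return cll, dth


# ---------------------------------------------------------------------------
# batched joint density + scores (used by all integration back ends)
# ---------------------------------------------------------------------------
def _eta_batch(pset: ParameterSet, B: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Latent-scale values eta (T, Q, S) from random draws B (T, Q, R)."""
    T, Q = B.shape[0], B.shape[1]
    eta = np.empty((T, Q, pset.S))
    eta[..., pset.random_indices] = B
    if pset.S - pset.R:
        fixed_eta = pset.beta + (X @ pset.gamma.T if X.size else 0.0)  # (T, S-R) or (S-R,)
        fixed_eta = np.broadcast_to(np.atleast_2d(fixed_eta), (T, pset.S - pset.R))
        eta[..., pset.fixed_indices] = fixed_eta[:, None, :]
    return eta


def joint_logdensity_batch(
    engine: LikelihoodEngine,
    pset: ParameterSet,
    B: np.ndarray,  # (T, Q, R)
    counts: np.ndarray,  # (T, ncat)
    logcoef: np.ndarray,  # (T,)
    X: np.ndarray,  # (T, p)
    pmap: ParameterMap | None = None,
):
    """Joint log-density l(b) = log f(n|b) + log MVN(b) for a node batch.

    Returns ``(l, grad_b)`` or ``(l, grad_b, grad_free)`` when ``pmap`` is
    given; shapes (T, Q), (T, Q, R), (T, Q, n_free).
    """
    R = pset.R
    T, Q = B.shape[0], B.shape[1]
    eta = _eta_batch(pset, B, X)
    theta = link_inverse(engine.link, eta)
    cll, dth = engine.cond_loglik_and_dtheta(theta, counts)
    deta = dth * link_derivative(engine.link, eta)  # (T, Q, S)

    if R:
        L = pset.chol
        Linv = solve_triangular(L, np.eye(R), lower=True)
        Sinv = Linv.T @ Linv
        logdet = 2.0 * np.log(np.diag(L)).sum()
        mu_t = pset.mu + (X @ pset.Gamma.T if X.size else 0.0)
        mu_t = np.broadcast_to(np.atleast_2d(mu_t), (T, R))
        diff = B - mu_t[:, None, :]
        v = diff @ Sinv  # (T, Q, R)
        quad = np.einsum("tqr,tqr->tq", diff, v)
        lg = -0.5 * (R * _LOG_2PI + logdet + quad)
        grad_b = deta[..., pset.random_indices] - v
    else:
        lg = np.zeros((T, Q))
        v = np.zeros((T, Q, 0))
        grad_b = np.zeros((T, Q, 0))

    l = cll + logcoef[:, None] + lg
    if pmap is None:
        return l, grad_b

    g = np.zeros((T, Q, pmap.n_free))
    g[..., pmap.sl_mu] = v
    if pset.S - R:
        g[..., pmap.sl_beta] = deta[..., pset.fixed_indices]
    for col, (r, c) in enumerate(pmap._Gamma_idx):
        g[..., pmap.sl_Gamma.start + col] = v[..., r] * X[:, c][:, None]
    deta_fixed = deta[..., pset.fixed_indices]
    for col, (r, c) in enumerate(pmap._gamma_idx):
        g[..., pmap.sl_gamma.start + col] = deta_fixed[..., r] * X[:, c][:, None]
    if R:
        u = v @ L  # (T, Q, R); u_j = (L^T v)_j
        C = Sinv @ L
        for col, (i, j) in enumerate(pmap.chol_pairs):
            gij = v[..., i] * u[..., j] - C[i, j]
            if i == j:
                gij = gij * L[i, i]
            g[..., pmap.sl_chol.start + col] = gij
    return l, grad_b, g


# ---------------------------------------------------------------------------
# scalar (single person / single b) public operations
# ---------------------------------------------------------------------------
def person_theta(
    pset: ParameterSet, b: np.ndarray, X: np.ndarray, link: str = "probit"
) -> np.ndarray:
    """Probability-scale process parameters of one person.

    Random parameters take ``link_inverse(b_s)``; fixed parameters take
    ``link_inverse(beta_s + gamma_s X)``.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    X = np.asarray(X, dtype=float)
    if b.shape != (pset.R,):
        raise ValueError(f"b must have length R={pset.R}")
    if X.size != pset.n_covariates:
        raise ValueError(f"X must have length p={pset.n_covariates}")
    eta = _eta_batch(pset, b[None, None, :], X[None, :])
    return link_inverse(link, eta[0, 0])


def _as_batch(model, pset, b, person):
    counts = person.frequencies[None, :]
    if counts.shape[1] != model.n_categories_total:
        raise ValueError("person frequencies inconsistent with model categories")
    B = np.atleast_1d(np.asarray(b, dtype=float))[None, None, :]
    if B.shape[2] != pset.R:
        raise ValueError(f"b must have length R={pset.R}")
    X = person.covariates[None, :]
    return B, counts, X


def conditional_loglik(
    model: MptModel, pset: ParameterSet, b, person: PersonData, link: str = "probit"
) -> float:
    """log f(n_t | b_t): product-multinomial mass with coefficients."""
    engine = LikelihoodEngine(model, link)
    B, counts, X = _as_batch(model, pset, b, person)
    eta = _eta_batch(pset, B, X)
    theta = link_inverse(link, eta)
    cll = engine.cond_loglik(theta, counts)
    return float(cll[0, 0] + engine.log_multinomial_coef(counts)[0])


def joint_logdensity(
    model: MptModel, pset: ParameterSet, b, person: PersonData, link: str = "probit"
) -> float:
    """Conditional log-likelihood plus the MVN log-density of ``b``."""
    engine = LikelihoodEngine(model, link)
    B, counts, X = _as_batch(model, pset, b, person)
    logcoef = engine.log_multinomial_coef(counts)
    l, _ = joint_logdensity_batch(engine, pset, B, counts, logcoef, X)
    return float(l[0, 0])


def score_components(
    model: MptModel,
    pset: ParameterSet,
    b,
    person: PersonData,
    link: str = "probit",
    pmap: ParameterMap | None = None,
):
    """Exact gradients of the joint log-density.

    Returns ``(grad_free, grad_b)`` where ``grad_free`` follows the ordering
    of ``pmap`` (a fresh :class:`ParameterMap` of ``pset`` by default).
    """
    if pmap is None:
        pmap = ParameterMap(pset)
    engine = LikelihoodEngine(model, link)
    B, counts, X = _as_batch(model, pset, b, person)
    logcoef = engine.log_multinomial_coef(counts)
    _, grad_b, grad_free = joint_logdensity_batch(
        engine, pset, B, counts, logcoef, X, pmap=pmap
    )
    return grad_free[0, 0], grad_b[0, 0]
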