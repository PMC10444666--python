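"""Approximation of the per-person marginal likelihood integral.

Each person's marginal likelihood integrates the joint density of counts and
random effects over the R-dimensional random-effect space.  Three back ends
are provided, all centered on the per-person posterior mode ``b_hat_t`` and
curvature ``Omega_hat_t`` (the inverse negative Hessian of the joint
log-density at the mode):

* **Laplace** -- Gaussian approximation at the mode; exact when the integrand
  is Gaussian and identical to AGHQ with a single node.
* **AGHQ** -- tensor-product Gauss-Hermite rule with M nodes per dimension,
  affinely transformed per person by the mode and the Cholesky factor of the
  curvature.
* **QMC** -- deterministic Halton points mapped through the normal quantile,
  scaled the same way, with an importance-weight correction so the estimator
  is consistent for the target integral.

All accumulation happens in log space via log-sum-exp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky
from scipy.special import logsumexp, ndtri

from .likelihood import (
    LikelihoodEngine,
    ParameterMap,
    ParameterSet,
    PersonData,
    joint_logdensity_batch,
)
from .tree import MptModel

__all__ = [
    "ModeSet",
    "QuadratureSpec",
    "MarginalEvaluator",
    "find_modes",
    "halton_points",
    "marginal_loglik_laplace",
    "marginal_loglik_aghq",
    "marginal_loglik_qmc",
]

_LOG_2PI = np.log(2.0 * np.pi)
_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
           53, 59, 61, 67, 71, 73, 79, 83, 89, 97)
#: refuse tensor-product rules beyond this many nodes per person
NODE_BUDGET = 1_000_000


@dataclass
class QuadratureSpec:
    """Which integral approximation to use and at what resolution."""

    method: str = "aghq"
    nodes_per_dim: int = 4
    n_points: int = 1000
    seed: int | None = None  # reserved; Halton is deterministic

    def __post_init__(self) -> None:
        if self.method not in ("laplace", "aghq", "qmc"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.nodes_per_dim < 1 or self.n_points < 1:
            raise ValueError("node counts must be >= 1")


@dataclass
class ModeSet:
    """Per-person posterior modes and mode curvatures."""

    modes: np.ndarray  # (T, R)
    curvatures: np.ndarray  # (T, R, R) -- Omega_hat, inverse negative Hessians
    grad_norms: np.ndarray = field(default_factory=lambda: np.zeros(0))
    converged: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        T = self.modes.shape[0]
        if self.grad_norms.size == 0:
            self.grad_norms = np.zeros(T)
        if self.converged.size == 0:
            self.converged = np.ones(T, dtype=bool)


def halton_points(dim: int, n: int) -> np.ndarray:
    """First ``n`` points of the ``dim``-dimensional Halton sequence.

    Uses the r-th prime as the base for dimension r and skips the zero point
    (indices 1..n), so every coordinate lies strictly inside (0, 1).
    """
    if dim > len(_PRIMES):
        raise ValueError(f"Halton sequence supports at most {len(_PRIMES)} dimensions")
    if dim < 1 or n < 1:
        raise ValueError("dim and n must be >= 1")
    out = np.empty((n, dim))
    idx = np.arange(1, n + 1, dtype=np.int64)
    for d in range(dim):
        base = _PRIMES[d]
        res = np.zeros(n)
        f = 1.0 / base
        i = idx.copy()
        while np.any(i > 0):
            res += f * (i % base)
            i //= base
            f /= base
        out[:, d] = res
    return out


class MarginalEvaluator:
    """Caches the per-dataset arrays and evaluates marginal log-likelihoods.

    The heart of estimation: given current parameters and per-person modes it
    produces total and per-person marginal log-likelihoods, the analytic
    marginal gradient (quadrature-weighted average of joint-density scores at
    the same nodes), and posterior summaries of the random effects.
    """

    def __init__(self, model: MptModel, data: list[PersonData], link: str = "probit"):
        if not data:
            raise ValueError("data must be nonempty")
        self.model = model
        self.link = link
        self.engine = LikelihoodEngine(model, link)
        self.counts = np.stack([p.frequencies for p in data])
        if self.counts.shape[1] != model.n_categories_total:
            raise ValueError("data category layout inconsistent with model")
        p = data[0].covariates.size
        self.X = np.stack([p_.covariates for p_ in data]).reshape(len(data), p)
        self.logcoef = self.engine.log_multinomial_coef(self.counts)
        self.T = len(data)

    # -- joint density over a node batch ------------------------------------
    def joint(self, pset: ParameterSet, B: np.ndarray, pmap: ParameterMap | None = None):
        return joint_logdensity_batch(
            self.engine, pset, B, self.counts, self.logcoef, self.X, pmap=pmap
        )

    # -- per-person mode finding (batched damped Newton) ---------------------
    def find_modes(
        self,
        pset: ParameterSet,
        warm_start: ModeSet | None = None,
        gtol: float = 1e-8,
        max_iter: int = 100,
        fd_step: float = 1e-5,
    ) -> ModeSet:
        R = pset.R
        T = self.T
        if R == 0:
            return ModeSet(np.zeros((T, 0)), np.zeros((T, 0, 0)))

        mu_t = pset.mu + (self.X @ pset.Gamma.T if self.X.size else 0.0)
        mu_t = np.broadcast_to(np.atleast_2d(mu_t), (T, R)).copy()
        b = warm_start.modes.copy() if warm_start is not None else mu_t.copy()

        def value_grad(bcur):
            l, g = self.joint(pset, bcur[:, None, :])
            return l[:, 0], g[:, 0, :]

        def fd_hessian(bcur):
            H = np.empty((T, R, R))
            for r in range(R):
                e = np.zeros(R)
                e[r] = fd_step
                _, gp = value_grad(bcur + e)
                _, gm = value_grad(bcur - e)
                H[:, :, r] = (gp - gm) / (2.0 * fd_step)
            return 0.5 * (H + np.swapaxes(H, 1, 2))

        l, g = value_grad(b)
        for _ in range(max_iter):
            gnorm = np.abs(g).max(axis=1)
            active = gnorm > gtol
            if not active.any():
                break
            H = fd_hessian(b)
            step = np.zeros_like(b)
            for t in np.flatnonzero(active):
                # modified Newton: clip the spectrum so the step is an
                # ascent direction even where the joint density is not concave
                w, V = np.linalg.eigh(-H[t])
                w = np.maximum(w, 1e-4)
                step[t] = V @ ((V.T @ g[t]) / w)
            # backtracking line search, vectorized over persons
            alpha = np.where(active, 1.0, 0.0)
            improved = ~active
            for _bt in range(30):
                trial = b + alpha[:, None] * step
                l_new, g_new = value_grad(trial)
                ok = active & ~improved & (l_new >= l - 1e-12)
                b[ok] = trial[ok]
                l[ok] = l_new[ok]
                g[ok] = g_new[ok]
                improved |= ok
                if improved.all():
                    break
                alpha = np.where(improved, alpha, alpha * 0.5)
            if not improved.any():
                break  # no person can make progress
            l, g = value_grad(b)

        gnorm = np.abs(g).max(axis=1) if R else np.zeros(T)
        H = fd_hessian(b)
        curvatures = np.empty((T, R, R))
        converged = gnorm <= max(gtol, 1e-6)
        for t in range(T):
            Hn = -H[t]
            try:
                cholesky(Hn, lower=True)
                curvatures[t] = np.linalg.inv(Hn)
            except np.linalg.LinAlgError:
                curvatures[t] = pset.Sigma  # fallback; person flagged
                converged[t] = False
        return ModeSet(b, curvatures, gnorm, converged)

    # -- node construction ---------------------------------------------------
    def _nodes(self, pset: ParameterSet, modes: ModeSet, spec: QuadratureSpec):
        """Node batch B (T, Q, R) and log-weights (T, Q) such that the
        per-person marginal log-likelihood is logsumexp_q(l + logw)."""
        R = pset.R
        T = self.T
        if R == 0:
            return np.zeros((T, 1, 0)), np.zeros((T, 1))

        Ls = np.linalg.cholesky(modes.curvatures)  # (T, R, R)
        logdetL = np.log(np.diagonal(Ls, axis1=1, axis2=2)).sum(axis=1)

        if spec.method == "laplace":
            B = modes.modes[:, None, :]
            logw = (0.5 * R * _LOG_2PI + logdetL)[:, None]
            return B, logw

        if spec.method == "aghq":
            M = spec.nodes_per_dim
            if M**R > NODE_BUDGET:
                raise ValueError(
                    f"AGHQ tensor rule needs {M}^{R} nodes per person, above the "
                    f"budget of {NODE_BUDGET}; use the QMC back end instead"
                )
            x, w = np.polynomial.hermite.hermgauss(M)
            grids = np.meshgrid(*([x] * R), indexing="ij")
            z = np.stack([gr.ravel() for gr in grids], axis=1)  # (Q, R)
            lw = np.stack(
                [grl.ravel() for grl in np.meshgrid(*([np.log(w)] * R), indexing="ij")],
                axis=1,
            ).sum(axis=1)
            logw_q = lw + (z**2).sum(axis=1) + 0.5 * R * np.log(2.0)
            B = modes.modes[:, None, :] + np.sqrt(2.0) * np.einsum(
                "qr,tsr->tqs", z, Ls
            )
            logw = logw_q[None, :] + logdetL[:, None]
            return B, logw

        # qmc: Halton points through the normal quantile, importance-weighted
        M = spec.n_points
        z = ndtri(halton_points(R, M))  # (M, R)
        B = modes.modes[:, None, :] + np.einsum("qr,tsr->tqs", z, Ls)
        # log proposal density N(b_hat, Omega_hat) at the transformed points
        logq = -0.5 * (R * _LOG_2PI + (z**2).sum(axis=1))[None, :] - logdetL[:, None]
        logw = -np.log(M) - logq
        return B, logw

    # -- marginal log-likelihood, gradient, posterior summaries -------------
    def marginal(
        self,
        pset: ParameterSet,
        modes: ModeSet,
        spec: QuadratureSpec,
        pmap: ParameterMap | None = None,
        posterior_mean: bool = False,
    ):
        """Evaluate the approximate marginal log-likelihood.

        Returns a dict with keys ``total``, ``per_person`` and, on request,
        ``grad`` (analytic marginal gradient in ParameterMap order) and
        ``posterior_mean`` (per-person quadrature-weighted mean of b).
        """
        B, logw = self._nodes(pset, modes, spec)
        if pmap is not None:
            l, _, g = self.joint(pset, B, pmap=pmap)
        else:
            l, _ = self.joint(pset, B)
        terms = l + logw
        per_person = logsumexp(terms, axis=1)
        out = {"total": float(per_person.sum()), "per_person": per_person}
        if pmap is not None or posterior_mean:
            omega = np.exp(terms - per_person[:, None])  # normalized weights
        if pmap is not None:
            out["grad"] = np.einsum("tq,tqk->k", omega, g)
            out["grad_per_person"] = np.einsum("tq,tqk->tk", omega, g)
        if posterior_mean:
            out["posterior_mean"] = np.einsum("tq,tqr->tr", omega, B)
        return out


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------
def find_modes(
    model: MptModel,
    params: ParameterSet,
    data: list[PersonData],
    link: str = "probit",
    warm_start: ModeSet | None = None,
    **kwargs,
) -> ModeSet:
    """Per-person maximization of the joint log-density in ``b``."""
    return MarginalEvaluator(model, data, link).find_modes(
        params, warm_start=warm_start, **kwargs
    )


def _marginal(model, params, data, link, modes, spec):
    ev = MarginalEvaluator(model, data, link)
    if modes is None:
        modes = ev.find_modes(params)
    res = ev.marginal(params, modes, spec)
    return res["total"], res["per_person"]


def marginal_loglik_laplace(model, params, data, link="probit", modes=None):
    """Laplace-approximated marginal log-likelihood (total, per person)."""
    return _marginal(model, params, data, link, modes, QuadratureSpec("laplace"))


def marginal_loglik_aghq(model, params, data, link="probit", modes=None, nodes_per_dim=4):
    """Adaptive Gauss-Hermite marginal log-likelihood (total, per person)."""
    return _marginal(
        model, params, data, link, modes,
        QuadratureSpec("aghq", nodes_per_dim=nodes_per_dim),
    )


def marginal_loglik_qmc(model, params, data, link="probit", modes=None, n_points=1000):
    """Quasi Monte Carlo (Halton) marginal log-likelihood (total, per person)."""
    return _marginal(
        model, params, data, link, modes, QuadratureSpec("qmc", n_points=n_points)
    )
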