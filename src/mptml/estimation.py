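"""Marginal maximum-likelihood estimation.

The marginal log-likelihood (random effects integrated out) is maximized by
a quasi-Newton (BFGS) pass over all free parameters in which the per-person
posterior modes and curvatures are profiled out: every objective evaluation
refreshes them (warm-started from the previous evaluation), so the
mode-update and parameter-update steps of the classical alternating scheme
interleave at every iteration.  The analytic marginal gradient is the
quadrature-weighted average of the joint-density scores at the refreshed
nodes.

Standard errors come from the observed information, either by central finite
differences of the analytic marginal gradient (default) or from the
quadrature-approximated exact second-derivative expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import minimize

from .integration import MarginalEvaluator, ModeSet, QuadratureSpec
from .likelihood import (
    LikelihoodEngine,
    ParameterMap,
    ParameterSet,
    PersonData,
)
from .links import link_derivative, link_inverse
from .tree import MptModel

__all__ = ["FitResult", "fit", "standard_errors", "aggregate_fixed_effects_fit"]


@dataclass
class FitResult:
    """Everything a fit produces: estimates, uncertainty, diagnostics."""

    params: ParameterSet
    flat_estimates: np.ndarray
    labels: list[str]
    std_errors: np.ndarray | None
    cov_params: np.ndarray | None
    loglik: float
    per_person_loglik: np.ndarray
    n_obs: int
    modes: ModeSet
    converged: bool
    messages: list[str]
    spec: QuadratureSpec
    link: str
    n_iter: int
    pmap: ParameterMap
    model: MptModel = field(repr=False, default=None)
    data: list = field(repr=False, default=None)

    @property
    def n_persons(self) -> int:
        return len(self.per_person_loglik)

    def sigma_estimates(self):
        """Natural-scale Sigma entries (lower triangle) with delta-method SEs.

        Returns (labels, estimates, std_errors); std_errors is None when the
        covariance of the estimates is undefined.
        """
        labels = self.pmap.sigma_entry_labels()
        est = self.pmap.sigma_entries(self.params)
        if self.cov_params is None:
            return labels, est, None
        J = self.pmap.sigma_jacobian(self.flat_estimates)
        cov = J @ self.cov_params @ J.T
        var = np.diag(cov)
        se = np.sqrt(np.where(var > 0, var, np.nan))
        return labels, est, se


def aggregate_fixed_effects_fit(
    model: MptModel, data: list[PersonData], link: str = "probit"
) -> np.ndarray:
    """Link-scale ML estimates from counts aggregated across persons.

    Cheap and stable; used as starting values for the hierarchical fit.
    Returns an (S,) vector of link-scale parameter values.
    """
    engine = LikelihoodEngine(model, link)
    counts = np.stack([p.frequencies for p in data]).sum(axis=0)[None, :]

    def negll_grad(eta):
        th = link_inverse(link, eta)[None, None, :]
        cll, dth = engine.cond_loglik_and_dtheta(th, counts)
        deta = dth[0, 0] * link_derivative(link, eta)
        return -float(cll[0, 0]), -deta

    x0 = np.zeros(model.n_parameters)
    opt = minimize(negll_grad, x0, jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    # guard against boundary drift on the link scale
    return np.clip(opt.x, -5.0, 5.0)


def _default_start(
    model: MptModel,
    data: list[PersonData],
    link: str,
    random_mask: np.ndarray,
    covariate_names: list[str],
    sigma_init: float = 0.3,
) -> ParameterSet:
    eta = aggregate_fixed_effects_fit(model, data, link)
    R = int(random_mask.sum())
    p = len(covariate_names)
    return ParameterSet(
        parameter_names=list(model.parameter_names),
        random_mask=random_mask,
        mu=eta[random_mask],
        Sigma=sigma_init * np.eye(R),
        beta=eta[~random_mask],
        gamma=np.zeros((model.n_parameters - R, p)),
        Gamma=np.zeros((R, p)),
        covariate_names=list(covariate_names),
    )


def fit(
    model: MptModel,
    data: list[PersonData],
    spec: QuadratureSpec | None = None,
    link: str = "probit",
    start: ParameterSet | None = None,
    config: dict[str, Any] | None = None,
) -> FitResult:
    """Maximize the marginal log-likelihood over all free parameters.

    ``start`` fixes the model structure (random/fixed split, covariate zero
    patterns); without it, all parameters are treated as random (or per
    ``config['random']``, a list of parameter names).  Deterministic given
    its inputs.
    """
    cfg = {
        "maxiter": 500,
        "gtol": 1e-6,
        "restarts": 2,
        "polish_max": 25,
        "polish_gtol": 1e-6,
        "se_method": "grad_fd",
        "compute_se": True,
        "sigma_init": 0.3,
    }
    cfg.update(config or {})
    spec = spec or QuadratureSpec()
    if not data:
        raise ValueError("data must be nonempty")

    if start is None:
        random_cfg = cfg.get("random")
        if random_cfg is None:
            random_mask = np.ones(model.n_parameters, dtype=bool)
        else:
            random_mask = np.array(
                [name in random_cfg for name in model.parameter_names]
            )
        covariate_names = cfg.get("covariate_names")
        if covariate_names is None:
            p = data[0].covariates.size
            covariate_names = [f"X{i + 1}" for i in range(p)]
        start = _default_start(
            model, data, link, random_mask, list(covariate_names), cfg["sigma_init"]
        )

    ev = MarginalEvaluator(model, data, link)
    pmap = ParameterMap(start)
    x = pmap.flatten(start)
    messages: list[str] = []

    # the per-person modes are profiled out: every objective evaluation
    # refreshes them (warm-started from the previous evaluation), so the
    # mode-update and parameter-update steps alternate at every iteration
    state = {"modes": ev.find_modes(start)}

    def negll_grad(xv):
        ps = pmap.unflatten(xv)
        state["modes"] = ev.find_modes(ps, warm_start=state["modes"])
        res = ev.marginal(ps, state["modes"], spec, pmap=pmap)
        return -res["total"], -res["grad"]

    n_iter = 0
    for attempt in range(1 + cfg["restarts"]):
        opt = minimize(
            negll_grad,
            x,
            jac=True,
            method="BFGS",
            options={"maxiter": cfg["maxiter"], "gtol": cfg["gtol"]},
        )
        x = opt.x
        n_iter += opt.nit
        scaled = np.abs(opt.jac).max() / max(1.0, abs(opt.fun))
        if opt.success or scaled <= 1e-4 or opt.nit == 0:
            break

    # polish: short classical two-step alternation rounds.  With the modes
    # held fixed the quadrature objective and the marginal gradient are
    # exactly consistent, so a few BFGS steps make sharp local progress; each
    # round is accepted only if the profiled (modes-refreshed) log-likelihood
    # improves, which keeps the alternation from exploiting stale modes.
    best_ll = -negll_grad(x)[0]
    for _polish in range(cfg["polish_max"]):
        modes_now = state["modes"]

        def negll_grad_fixed(xv):
            ps = pmap.unflatten(xv)
            res = ev.marginal(ps, modes_now, spec, pmap=pmap)
            return -res["total"], -res["grad"]

        fval, fgrad = negll_grad_fixed(x)
        if np.abs(fgrad).max() / max(1.0, abs(fval)) <= cfg["polish_gtol"]:
            break
        opt = minimize(
            negll_grad_fixed, x, jac=True, method="BFGS",
            options={"maxiter": 5, "gtol": cfg["gtol"]},
        )
        ll_cand = -negll_grad(opt.x)[0]  # refreshes modes at the candidate
        if not np.isfinite(ll_cand) or ll_cand <= best_ll + 1e-10:
            state["modes"] = ev.find_modes(
                pmap.unflatten(x), warm_start=state["modes"]
            )
            break
        x = opt.x
        best_ll = ll_cand
        n_iter += opt.nit

    pset = pmap.unflatten(x)
    modes = ev.find_modes(pset, warm_start=state["modes"])
    res = ev.marginal(pset, modes, spec, pmap=pmap)
    ll = res["total"]
    grad_norm = float(np.abs(res["grad"]).max())
    scaled_gnorm = grad_norm / max(1.0, abs(ll))
    if scaled_gnorm > 1e-4:
        messages.append(f"scaled marginal gradient norm {scaled_gnorm:.2e} > 1e-4")
    if not modes.converged.all():
        messages.append(
            f"{int((~modes.converged).sum())} person mode(s) did not reach "
            "the inner tolerance"
        )

    n_obs = int(sum(p.n_responses for p in data))
    result = FitResult(
        params=pset,
        flat_estimates=x,
        labels=list(pmap.labels),
        std_errors=None,
        cov_params=None,
        loglik=float(ll),
        per_person_loglik=res["per_person"],
        n_obs=n_obs,
        modes=modes,
        converged=False,
        messages=messages,
        spec=spec,
        link=link,
        n_iter=n_iter,
        pmap=pmap,
        model=model,
        data=data,
    )

    se_ok = True
    if cfg["compute_se"]:
        se, cov = standard_errors(result, method=cfg["se_method"])
        result.std_errors, result.cov_params = se, cov
        se_ok = se is not None and bool(np.all(np.isfinite(se)) and np.all(se > 0))
        if not se_ok:
            messages.append("standard errors undefined (information not positive definite)")

    # convergence means an admissible solution: finite estimates, a
    # positive-definite Sigma (guaranteed by the log-Cholesky map), and every
    # standard error defined and positive.  A large final gradient norm is
    # reported as a diagnostic; boundary solutions typically also yield a
    # non-invertible information matrix and fail the SE criterion.
    result.converged = bool(np.all(np.isfinite(x)) and se_ok)
    return result


def standard_errors(fitted: FitResult, method: str = "grad_fd"):
    """Observed-information standard errors and estimate covariance.

    ``grad_fd`` central-differences the analytic marginal gradient (modes
    refreshed, warm-started, at each perturbed parameter vector); ``exact``
    evaluates the second-derivative expressions with quadrature-approximated
    inner integrals at the final nodes.  Returns ``(se, cov)``; both are
    ``None`` when the information matrix is not positive definite.
    """
    if method not in ("grad_fd", "exact"):
        raise ValueError(f"unknown SE method {method!r}")
    ev = MarginalEvaluator(fitted.model, fitted.data, fitted.link)
    pmap, spec = fitted.pmap, fitted.spec
    x = fitted.flat_estimates
    n = pmap.n_free

    if method == "grad_fd":
        # quadrature held fixed at the final modes: the resulting matrix is
        # the observed information of the approximated log-likelihood, the
        # same object the exact second-derivative expressions estimate
        def grad_at(xv):
            ps = pmap.unflatten(xv)
            return ev.marginal(ps, fitted.modes, spec, pmap=pmap)["grad"]

        H = np.empty((n, n))
        for j in range(n):
            h = 1e-5 * max(1.0, abs(x[j]))
            e = np.zeros(n)
            e[j] = h
            H[:, j] = (grad_at(x + e) - grad_at(x - e)) / (2.0 * h)
        info = -0.5 * (H + H.T)
    else:
        modes = fitted.modes
        pset = pmap.unflatten(x)
        B, logw = ev._nodes(pset, modes, spec)
        l, _, s = ev.joint(pset, B, pmap=pmap)
        terms = l + logw
        from scipy.special import logsumexp

        per = logsumexp(terms, axis=1)
        omega = np.exp(terms - per[:, None])  # (T, Q)
        score_t = np.einsum("tq,tqk->tk", omega, s)
        E_ssT = np.einsum("tq,tqk,tqm->tkm", omega, s, s)
        E_H = np.empty((ev.T, n, n))
        for j in range(n):
            h = 1e-5 * max(1.0, abs(x[j]))
            e = np.zeros(n)
            e[j] = h
            _, _, sp = ev.joint(pmap.unflatten(x + e), B, pmap=pmap)
            _, _, sm = ev.joint(pmap.unflatten(x - e), B, pmap=pmap)
            E_H[:, :, j] = np.einsum("tq,tqk->tk", omega, (sp - sm) / (2.0 * h))
        E_H = 0.5 * (E_H + np.swapaxes(E_H, 1, 2))
        hess_t = E_H + E_ssT - np.einsum("tk,tm->tkm", score_t, score_t)
        info = -hess_t.sum(axis=0)

    if not np.all(np.isfinite(info)):
        return None, None
    eigvals = np.linalg.eigvalsh(info)
    # a practically singular information matrix (non-identified direction)
    # yields undefined standard errors
    if eigvals[0] <= 1e-8 * max(eigvals[-1], 1e-300):
        return None, None
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    return se, cov
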