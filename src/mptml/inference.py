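"""Likelihood-ratio tests, information criteria and random-effect prediction."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .estimation import FitResult
from .integration import MarginalEvaluator, QuadratureSpec

__all__ = ["LrResult", "lr_test", "information_criteria", "predict_random_effects"]


@dataclass
class LrResult:
    """A likelihood-ratio comparison of two nested fits."""

    statistic: float
    df: int
    p_value: float
    crit_05: float

    def __str__(self) -> str:
        return (
            f"LR = {self.statistic:.2f}, df = {self.df}, "
            f"p = {self.p_value:.3g} (chi2 crit at .05: {self.crit_05:.2f})"
        )


def lr_test(restricted: FitResult, unrestricted: FitResult) -> LrResult:
    """LR = -2 (ll_restricted - ll_unrestricted) against a central chi-square.

    Nestedness is the caller's responsibility; the degrees of freedom are the
    difference in free-parameter counts.
    """
    df = len(unrestricted.labels) - len(restricted.labels)
    if df < 1:
        raise ValueError("models have identical free-parameter counts")
    stat = -2.0 * (restricted.loglik - unrestricted.loglik)
    if stat < -1e-6:
        warnings.warn(
            "restricted model has higher log-likelihood than the unrestricted "
            "one; an optimizer failure is likely",
            stacklevel=2,
        )
    stat = max(stat, 0.0)
    return LrResult(
        statistic=stat,
        df=df,
        p_value=float(chi2.sf(stat, df)),
        crit_05=float(chi2.ppf(0.95, df)),
    )


def information_criteria(fitted: FitResult) -> tuple[float, float, int]:
    """(AIC, BIC, df); BIC uses the total number of recorded responses.

    df counts the random means (R), fixed intercepts (S-R), free covariate
    weights, and the R(R+1)/2 covariance parameters.
    """
    df = len(fitted.labels)
    aic = -2.0 * fitted.loglik + 2.0 * df
    bic = -2.0 * fitted.loglik + np.log(fitted.n_obs) * df
    return float(aic), float(bic), df


def predict_random_effects(
    model=None,
    data=None,
    fitted: FitResult = None,
    estimator: str = "empirical_bayes",
    spec: QuadratureSpec | None = None,
) -> np.ndarray:
    """Per-person random-effect estimates, (T, R).

    ``mode`` returns the posterior modes already computed during estimation;
    ``empirical_bayes`` the per-person posterior mean, approximated with the
    fitted quadrature back end (shrunken towards the population mean).
    """
    if fitted is None:
        raise ValueError("a FitResult is required")
    model = model if model is not None else fitted.model
    data = data if data is not None else fitted.data
    spec = spec or fitted.spec
    if estimator == "mode":
        return fitted.modes.modes.copy()
    if estimator != "empirical_bayes":
        raise ValueError(f"unknown estimator {estimator!r}")
    ev = MarginalEvaluator(model, data, fitted.link)
    res = ev.marginal(fitted.params, fitted.modes, spec, posterior_mean=True)
    return res["posterior_mean"]
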