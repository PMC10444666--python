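"""Model / Results facade for hierarchical MPT estimation.

`LatentTraitMPT` is built from an MPT tree structure plus per-participant
frequency data and holds the modelling choices (which process parameters are
random, which covariates enter, the link).  Its :meth:`fit` returns a
:class:`LatentTraitMPTResults` carrying estimates, standard errors,
information criteria and random-effect predictions, with a ``summary()``
table in the style of statsmodels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import FitResult, fit as _fit
from .inference import information_criteria, lr_test, predict_random_effects
from .integration import QuadratureSpec
from .io import frame_to_persons
from .likelihood import ParameterSet, PersonData
from .links import link_inverse
from .tree import MptModel, Restriction, apply_restrictions, parse_eqn

__all__ = ["LatentTraitMPT", "LatentTraitMPTResults"]


class LatentTraitMPT:
    """Hierarchical MPT model with multivariate-normal random effects.

    Parameters
    ----------
    model : MptModel or str
        Tree structure, or EQN text to parse.
    data : list of PersonData or pandas.DataFrame
        Per-participant category frequencies (+ covariate columns for a
        DataFrame, named in ``covariates``).
    random : "all" or list of parameter names
        Which process parameters vary across participants (default: all).
    covariates : list of column names entering the mean structure.
    link : "probit" (default) or "logit".
    restrictions : list of Restriction, applied to the tree first.
    """

    def __init__(
        self,
        model: MptModel | str,
        data,
        random="all",
        covariates: list[str] | None = None,
        link: str = "probit",
        restrictions: list[Restriction] | None = None,
        center_covariates: bool = True,
    ):
        if isinstance(model, str):
            model = parse_eqn(model)
        if restrictions:
            model = apply_restrictions(model, restrictions)
        self.model = model
        self.link = link
        self.covariate_names = list(covariates or [])
        if isinstance(data, pd.DataFrame):
            data = frame_to_persons(
                data, model, self.covariate_names, center_covariates
            )
        self.data: list[PersonData] = list(data)
        if random == "all":
            self.random_mask = np.ones(model.n_parameters, dtype=bool)
        else:
            unknown = set(random) - set(model.parameter_names)
            if unknown:
                raise KeyError(f"unknown random parameters: {sorted(unknown)}")
            self.random_mask = np.array(
                [p in random for p in model.parameter_names]
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model, **kwargs) -> "LatentTraitMPT":
        return cls(model, df, **kwargs)

    def fit(
        self,
        method: str = "aghq",
        nodes: int = 4,
        qmc_points: int = 1000,
        start: ParameterSet | None = None,
        se_method: str = "grad_fd",
        **config,
    ) -> "LatentTraitMPTResults":
        spec = QuadratureSpec(method, nodes_per_dim=nodes, n_points=qmc_points)
        cfg = {
            "random": [
                p for p, r in zip(self.model.parameter_names, self.random_mask) if r
            ],
            "covariate_names": self.covariate_names,
            "se_method": se_method,
        }
        cfg.update(config)
        res = _fit(self.model, self.data, spec=spec, link=self.link,
                   start=start, config=cfg)
        return LatentTraitMPTResults(self, res)


class LatentTraitMPTResults:
    """Results wrapper: labelled estimates, uncertainty, diagnostics."""

    def __init__(self, model: LatentTraitMPT, fitres: FitResult):
        self.model = model
        self._fit = fitres

    # -- statsmodels-flavoured surface --------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.flat_estimates, index=self._fit.labels)

    @property
    def bse(self) -> pd.Series:
        se = self._fit.std_errors
        if se is None:
            se = np.full(len(self._fit.labels), np.nan)
        return pd.Series(se, index=self._fit.labels)

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def aic(self) -> float:
        return information_criteria(self._fit)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self._fit)[1]

    @property
    def df_model(self) -> int:
        return information_criteria(self._fit)[2]

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def nobs(self) -> int:
        return self._fit.n_obs

    def cov_params(self) -> pd.DataFrame | None:
        if self._fit.cov_params is None:
            return None
        return pd.DataFrame(
            self._fit.cov_params, index=self._fit.labels, columns=self._fit.labels
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    # -- model-specific extras ----------------------------------------------
    @property
    def mean_probabilities(self) -> pd.Series:
        """Probability-scale values of the random-parameter means."""
        pm = self._fit.pmap
        mu = self._fit.flat_estimates[pm.sl_mu]
        return pd.Series(
            link_inverse(self._fit.link, mu), index=self._fit.params.random_names
        )

    def sigma(self) -> pd.DataFrame:
        """Natural-scale Sigma entries with delta-method standard errors."""
        labels, est, se = self._fit.sigma_estimates()
        return pd.DataFrame(
            {"estimate": est, "se": se if se is not None else np.nan}, index=labels
        )

    def predict_random_effects(self, estimator: str = "empirical_bayes") -> pd.DataFrame:
        b = predict_random_effects(fitted=self._fit, estimator=estimator)
        return pd.DataFrame(b, columns=self._fit.params.random_names)

    def lr_test(self, unrestricted: "LatentTraitMPTResults"):
        """Treat self as the restricted model of a nested pair."""
        return lr_test(self._fit, unrestricted._fit)

    def summary(self) -> str:
        f = self._fit
        aic, bic, df = information_criteria(f)
        lines = [
            "Latent-trait MPT marginal ML fit",
            "=" * 64,
            f"link: {f.link}   method: {f.spec.method}"
            + (f" ({f.spec.nodes_per_dim} nodes/dim)" if f.spec.method == "aghq" else "")
            + (f" ({f.spec.n_points} Halton points)" if f.spec.method == "qmc" else ""),
            f"persons: {f.n_persons}   responses: {f.n_obs}   "
            f"converged: {f.converged}",
            f"loglik: {f.loglik:.3f}   AIC: {aic:.1f}   BIC: {bic:.1f}   df: {df}",
            "-" * 64,
            f"{'parameter':<24}{'estimate':>10}{'std err':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        se = f.std_errors
        for i, lab in enumerate(f.labels):
            est = f.flat_estimates[i]
            if se is not None and np.isfinite(se[i]):
                lines.append(
                    f"{lab:<24}{est:>10.4f}{se[i]:>10.4f}"
                    f"{est - 1.96 * se[i]:>10.4f}{est + 1.96 * se[i]:>10.4f}"
                )
            else:
                lines.append(f"{lab:<24}{est:>10.4f}{'--':>10}{'--':>10}{'--':>10}")
        sig_labels, sig_est, sig_se = f.sigma_estimates()
        if sig_labels:
            lines.append("-" * 64)
            lines.append("Sigma (natural scale, delta-method SEs):")
            for i, lab in enumerate(sig_labels):
                s = f"{sig_se[i]:.4f}" if sig_se is not None else "--"
                lines.append(f"{lab:<24}{sig_est[i]:>10.4f}{s:>10}")
        if f.messages:
            lines.append("-" * 64)
            lines.extend(f"note: {m}" for m in f.messages)
        return "\n".join(lines)
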