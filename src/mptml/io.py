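"""Reading frequency tables and serializing fit results.

The canonical data format is a delimited table with one row per participant
and one integer column per (tree, category) pair named ``tree.category``,
plus optional covariate columns.  Covariates are mean-centered by default so
that the population means describe a participant with average covariate
values.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .estimation import FitResult
from .inference import information_criteria
from .likelihood import ParameterSet, PersonData
from .tree import MptModel

__all__ = [
    "read_frequencies",
    "frame_to_persons",
    "persons_to_frame",
    "write_frequencies",
    "write_fit",
    "read_fit",
    "parameterset_from_dict",
]


def frame_to_persons(
    df: pd.DataFrame,
    model: MptModel,
    covariate_names: list[str] | None = None,
    center_covariates: bool = True,
) -> list[PersonData]:
    """Convert a frequency DataFrame into per-person records.

    Category columns are matched by name against the model's
    ``tree.category`` labels; if none match, the first ``n_categories``
    non-covariate columns are used positionally with a warning.
    """
    covariate_names = list(covariate_names or [])
    labels = model.category_labels
    if all(lbl in df.columns for lbl in labels):
        cat = df[labels]
    else:
        candidates = [
            c for c in df.columns
            if c not in covariate_names and c.lower() not in ("id", "participant")
        ]
        if len(candidates) < len(labels):
            missing = [lbl for lbl in labels if lbl not in df.columns]
            raise ValueError(f"missing category columns: {missing}")
        warnings.warn(
            "category columns matched by position, not by name", stacklevel=2
        )
        cat = df[candidates[: len(labels)]]

    values = cat.to_numpy()
    if np.any(pd.isna(values)):
        raise ValueError("NA counts are not allowed")
    fvalues = values.astype(float)
    if np.any(fvalues != np.round(fvalues)):
        raise ValueError("counts must be integers")
    counts = fvalues.astype(np.int64)
    bad = np.argwhere(counts < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"negative count at row {df.index[r]}, column {cat.columns[c]!r}"
        )

    if covariate_names:
        missing = [c for c in covariate_names if c not in df.columns]
        if missing:
            raise ValueError(f"missing covariate columns: {missing}")
        X = df[covariate_names].to_numpy(dtype=float)
        if center_covariates:
            X = X - X.mean(axis=0)
    else:
        X = np.zeros((len(df), 0))

    return [
        PersonData.from_frequencies(model, counts[t], X[t]) for t in range(len(df))
    ]


def read_frequencies(
    path,
    model: MptModel,
    covariate_names: list[str] | None = None,
    center_covariates: bool = True,
) -> list[PersonData]:
    """Read a delimited frequency table (with header) into person records."""
    df = pd.read_csv(path, sep=None, engine="python")
    return frame_to_persons(df, model, covariate_names, center_covariates)


def persons_to_frame(
    data: list[PersonData], model: MptModel, covariate_names: list[str] | None = None
) -> pd.DataFrame:
    """Inverse of :func:`frame_to_persons` (covariates as stored, uncentered)."""
    covariate_names = list(covariate_names or [])
    cols = {"id": np.arange(1, len(data) + 1)}
    counts = np.stack([p.frequencies for p in data])
    for j, lbl in enumerate(model.category_labels):
        cols[lbl] = counts[:, j]
    for j, name in enumerate(covariate_names):
        cols[name] = np.array([p.covariates[j] for p in data])
    return pd.DataFrame(cols)


def write_frequencies(path, data, model, covariate_names=None) -> None:
    persons_to_frame(data, model, covariate_names).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------
def _pset_to_dict(pset: ParameterSet) -> dict:
    return {
        "parameter_names": list(pset.parameter_names),
        "random_mask": pset.random_mask.tolist(),
        "mu": pset.mu.tolist(),
        "Sigma": pset.Sigma.tolist(),
        "beta": pset.beta.tolist(),
        "gamma": pset.gamma.tolist(),
        "Gamma": pset.Gamma.tolist(),
        "gamma_free": pset.gamma_free.tolist(),
        "Gamma_free": pset.Gamma_free.tolist(),
        "covariate_names": list(pset.covariate_names),
    }


def parameterset_from_dict(d: dict) -> ParameterSet:
    return ParameterSet(
        parameter_names=list(d["parameter_names"]),
        random_mask=np.array(d["random_mask"], dtype=bool),
        mu=np.array(d["mu"], dtype=float),
        Sigma=np.array(d["Sigma"], dtype=float),
        beta=np.array(d["beta"], dtype=float),
        gamma=np.array(d["gamma"], dtype=float),
        Gamma=np.array(d["Gamma"], dtype=float),
        gamma_free=np.array(d["gamma_free"], dtype=bool),
        Gamma_free=np.array(d["Gamma_free"], dtype=bool),
        covariate_names=list(d["covariate_names"]),
    )


def write_fit(path, fitted: FitResult) -> None:
    """Serialize a fit to JSON (estimates, SEs, CIs, criteria, diagnostics)."""
    aic, bic, df = information_criteria(fitted)
    se = fitted.std_errors
    ci = None
    if se is not None and np.all(np.isfinite(se)):
        ci = np.stack(
            [fitted.flat_estimates - 1.96 * se, fitted.flat_estimates + 1.96 * se],
            axis=1,
        ).tolist()
    sig_labels, sig_est, sig_se = fitted.sigma_estimates()
    payload = {
        "version": _version,
        "labels": fitted.labels,
        "flat_estimates": fitted.flat_estimates.tolist(),
        "std_errors": None if se is None else se.tolist(),
        "wald_ci_95": ci,
        "cov_params": None
        if fitted.cov_params is None
        else fitted.cov_params.tolist(),
        "loglik": fitted.loglik,
        "aic": aic,
        "bic": bic,
        "df": df,
        "n_obs": fitted.n_obs,
        "n_persons": fitted.n_persons,
        "converged": fitted.converged,
        "messages": fitted.messages,
        "sigma_labels": sig_labels,
        "sigma_estimates": sig_est.tolist(),
        "sigma_std_errors": None if sig_se is None else sig_se.tolist(),
        "settings": {
            "link": fitted.link,
            "method": fitted.spec.method,
            "nodes_per_dim": fitted.spec.nodes_per_dim,
            "n_points": fitted.spec.n_points,
            "seed": fitted.spec.seed,
            "n_iter": fitted.n_iter,
        },
        "parameter_set": _pset_to_dict(fitted.params),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit(path) -> dict:
    """Read back a serialized fit as a dict (arrays restored to numpy)."""
    d = json.loads(Path(path).read_text())
    for key in ("flat_estimates", "std_errors", "sigma_estimates",
                "sigma_std_errors", "cov_params", "wald_ci_95"):
        if d.get(key) is not None:
            d[key] = np.array(d[key], dtype=float)
    return d
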