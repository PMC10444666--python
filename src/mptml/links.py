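"""Link functions mapping latent person parameters to probabilities.

Random and fixed process parameters live on an unbounded latent scale and are
mapped into (0, 1) through a logit or probit link.  Probit is the default,
following the latent-trait tradition for hierarchical MPT models.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, ndtr, ndtri

__all__ = ["LINKS", "link_inverse", "link_derivative", "link_forward"]

LINKS = ("logit", "probit")

#: clamp keeping the conditional log-likelihood finite for extreme draws
_CLAMP = 1e-12

_SQRT_2PI = np.sqrt(2.0 * np.pi)


def _check(kind: str, eta) -> np.ndarray:
    if kind not in LINKS:
        raise ValueError(f"unknown link {kind!r}; choose from {LINKS}")
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return eta


def link_inverse(kind: str, eta):
    """Map the latent scale to a probability strictly inside (0, 1)."""
    eta = _check(kind, eta)
    p = expit(eta) if kind == "logit" else ndtr(eta)
    return np.clip(p, _CLAMP, 1.0 - _CLAMP)


def link_derivative(kind: str, eta):
    """d theta / d eta of :func:`link_inverse`; strictly positive."""
    eta = _check(kind, eta)
    if kind == "logit":
        p = expit(eta)
        return p * (1.0 - p)
    return np.exp(-0.5 * eta**2) / _SQRT_2PI


def link_forward(kind: str, p):
    """The forward transform (log-odds or normal quantile)."""
    if kind not in LINKS:
        raise ValueError(f"unknown link {kind!r}; choose from {LINKS}")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    if kind == "logit":
        return np.log(p) - np.log1p(-p)
    return ndtri(p)
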