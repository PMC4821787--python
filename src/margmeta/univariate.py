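"""Univariate DerSimonian-Laird random-effects (and fixed-effect) pooling.

These marginal fits are the backbone of the marginal method of moments: each
outcome is pooled exactly as in a conventional univariate meta-analysis, so
joint inference built on top never alters the familiar marginal results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ValidationError

__all__ = ["UnivariateFit", "q_statistic", "dl_tau2", "pool", "Z95"]

#: Normal 95% quantile used for all confidence intervals.
Z95 = 1.96


@dataclass(frozen=True)
class UnivariateFit:
    """Pooled estimate for one outcome.

    ``weights`` are the per-study weights over the reporting set, in dataset
    row order: ``1/s_i^2`` for the fixed-effect model, ``1/(s_i^2 + tau2)``
    for the random-effects model.  ``se = (sum of weights)^(-1/2)``.
    """

    beta: float
    se: float
    tau2: float
    Q: float
    weights: np.ndarray
    model: str

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


def _check(y: np.ndarray, s2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if y.size == 0:
        raise ValidationError("no studies supplied")
    if y.shape != s2.shape:
        raise ValidationError(f"length mismatch: {y.shape} vs {s2.shape}")
    if np.any(s2 <= 0):
        raise ValidationError("within-study variances must be strictly positive")
    return y, s2


def q_statistic(y, s2) -> float:
    """Cochran's heterogeneity statistic Q = sum (y_i - ybar_w)^2 / s_i^2.

    ``ybar_w`` is the inverse-variance weighted mean; Q is 0 for one study.
    """
    y, s2 = _check(y, s2)
    w = 1.0 / s2
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def dl_tau2(y, s2, m_obs: int | None = None) -> float:
    """DerSimonian-Laird moment estimate of the between-study variance.

    ``tau2 = max(0, (Q - (m-1)) / (sum 1/s^2 - sum 1/s^4 / sum 1/s^2))``,
    truncated at zero; defined as 0 for a single study (the moment equation
    is degenerate there).

    ``m_obs`` overrides the study count in the ``m - 1`` expectation term:
    when the input contains MCAR pseudo-observations with very large
    variances, those rows contribute (essentially) nothing to Q or to the
    denominator, but must not inflate the degrees of freedom.
    """
    y, s2 = _check(y, s2)
    m = y.size if m_obs is None else int(m_obs)
    if m < 2:
        return 0.0
    q = q_statistic(y, s2)
    w = 1.0 / s2
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - (m - 1)) / denom))


def pool(
    y,
    s2,
    model: str = "random",
    m_obs: int | None = None,
    tau2: float | None = None,
) -> UnivariateFit:
    """Inverse-variance weighted pooling of one outcome.

    With ``model="random"`` the weights are ``1/(s_i^2 + tau2)`` with the
    DerSimonian-Laird tau2; with ``model="fixed"`` they are ``1/s_i^2``.
    ``m_obs`` is forwarded to :func:`dl_tau2`.  Passing ``tau2`` plugs in an
    externally estimated between-study variance (e.g. REML) in place of the
    DerSimonian-Laird default.
    """
    y, s2 = _check(y, s2)
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    q = q_statistic(y, s2)
    if model == "fixed":
        tau2 = 0.0
    elif tau2 is None:
        tau2 = dl_tau2(y, s2, m_obs=m_obs)
    elif tau2 < 0:
        raise ValidationError(f"tau2 must be non-negative, got {tau2}")
    w = 1.0 / (s2 + tau2)
    beta = float(np.sum(w * y) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return UnivariateFit(beta=beta, se=se, tau2=tau2, Q=q, weights=w, model=model)
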