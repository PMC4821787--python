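"""The marginal method of moments (MMoM) for bivariate meta-analysis.

Two conventional univariate random-effects fits are augmented with a moment
estimate of the covariance between the two pooled estimates,

    cov(b1, b2) = sum_{i in R12} (w_i1/w_1+)(w_i2/w_2+)(y_i1 - b1)(y_i2 - b2),

summed over the studies reporting both outcomes.  This needs no within-study
correlations, allows no borrowing of strength, and leaves the marginal
results exactly equal to the univariate ones, while enabling valid joint
inference and delta-method inference for functions f(beta1, beta2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .data import BivariateDataset, ValidationError
from .univariate import UnivariateFit, Z95, pool

__all__ = [
    "JointFit",
    "FunctionInference",
    "mmom_cov",
    "mmom_fit",
    "truncate_psd",
    "linear_combo",
    "delta_method",
]


@dataclass(frozen=True)
class JointFit:
    """Pooled effects for both outcomes with a joint covariance matrix.

    ``sigma`` is the covariance used for joint and function-of-effects
    inference (positive semi-definite after any eigenvalue truncation,
    indicated by ``truncated``).  For the marginal method of moments the
    untruncated marginal fits are kept in ``marginals``: truncation exists
    only to make joint inference valid and never alters the univariate
    results reported per outcome.
    """

    beta: np.ndarray
    sigma: np.ndarray
    method: str
    truncated: bool
    marginals: tuple[UnivariateFit, UnivariateFit] | None = None

    @property
    def correlation(self) -> float:
        d = np.sqrt(self.sigma[0, 0] * self.sigma[1, 1])
        return float(self.sigma[0, 1] / d) if d > 0 else 0.0


@dataclass(frozen=True)
class FunctionInference:
    """Point estimate, standard error and 95% CI for a function of effects."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    function_spec: object = None


def truncate_psd(mat, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Clamp negative eigenvalues of a symmetric matrix to zero.

    Returns the (possibly reconstructed) matrix and a flag saying whether
    truncation was applied.  The input must be symmetric to a relative
    tolerance ``tol``; matrices that are already positive semi-definite are
    returned unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    scale = max(1.0, float(np.abs(mat).max()))
    if np.abs(mat - mat.T).max() > tol * scale:
        raise ValidationError("matrix is not symmetric")
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= -1e-12 * max(1.0, float(np.abs(vals).max())):
        return mat, False
    clipped = np.clip(vals, 0.0, None)
    out = (vecs * clipped) @ vecs.T
    return (out + out.T) / 2.0, True


def mmom_cov(ds: BivariateDataset, fit1: UnivariateFit, fit2: UnivariateFit) -> float:
    """Moment estimate of the covariance between the two pooled estimates.

    Uses the same weights as the marginal fits; the per-study covariance
    cov(Y_i1, Y_i2) is replaced by the cross product of residuals about the
    pooled estimates.  An empty overlap set gives covariance 0 (disjoint
    reporting sets make the pooled estimates independent).
    """
    if not ds.R12:
        return 0.0
    w1_of = dict(zip(ds.R1, fit1.weights))
    w2_of = dict(zip(ds.R2, fit2.weights))
    w1_sum = float(np.sum(fit1.weights))
    w2_sum = float(np.sum(fit2.weights))
    total = 0.0
    for i in ds.R12:
        r = ds.records[i]
        total += (
            (w1_of[i] / w1_sum)
            * (w2_of[i] / w2_sum)
            * (r.y1 - fit1.beta)
            * (r.y2 - fit2.beta)
        )
    return float(total)


def mmom_fit(ds: BivariateDataset, model: str = "random") -> JointFit:
    """Fit the marginal method of moments to a bivariate dataset.

    The two pooled estimates and their standard errors are exactly those of
    the per-outcome univariate fits; only the off-diagonal of the joint
    covariance is new.  If the assembled 2x2 matrix is indefinite its
    negative eigenvalue is truncated to zero for joint inference.
    """
    for outcome in (1, 2):
        if not ds.reporting_set(outcome):
            raise ValidationError(f"no study reports outcome {outcome}")
    fit1 = pool(*ds.outcome_arrays(1), model=model, m_obs=ds.observed_count(1))
    fit2 = pool(*ds.outcome_arrays(2), model=model, m_obs=ds.observed_count(2))
    cov = mmom_cov(ds, fit1, fit2)
    sigma = np.array([[fit1.se**2, cov], [cov, fit2.se**2]])
    sigma, truncated = truncate_psd(sigma)
    return JointFit(
        beta=np.array([fit1.beta, fit2.beta]),
        sigma=sigma,
        method="mmom",
        truncated=truncated,
        marginals=(fit1, fit2),
    )


def linear_combo(fit: JointFit, coeffs: Sequence[float]) -> FunctionInference:
    """Inference for c1*beta1 + c2*beta2 using the joint covariance."""
    c = np.asarray(coeffs, dtype=float)
    if c.shape != (2,):
        raise ValidationError(f"need exactly 2 coefficients, got shape {c.shape}")
    if np.all(c == 0):
        raise ValidationError("coefficient vector must be nonzero")
    est = float(c @ fit.beta)
    var = float(c @ fit.sigma @ c)
    se = float(np.sqrt(max(var, 0.0)))
    return FunctionInference(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        function_spec=tuple(c),
    )


def delta_method(
    fit: JointFit,
    f: Callable[[float, float], float],
    grad: Callable[[float, float], Sequence[float]] | None = None,
) -> FunctionInference:
    """Approximate inference for a differentiable f(beta1, beta2).

    The gradient is taken analytically when supplied, otherwise by central
    differences with step ``1e-6 * (1 + |beta_j|)`` per coordinate.
    """
    b1, b2 = float(fit.beta[0]), float(fit.beta[1])
    est = float(f(b1, b2))
    if not np.isfinite(est):
        raise ValidationError(f"f is not finite at the pooled estimates ({b1}, {b2})")
    if grad is not None:
        g = np.asarray(grad(b1, b2), dtype=float)
    else:
        g = np.empty(2)
        for j, bj in enumerate((b1, b2)):
            h = 1e-6 * (1.0 + abs(bj))
            args_hi = (b1 + h, b2) if j == 0 else (b1, b2 + h)
            args_lo = (b1 - h, b2) if j == 0 else (b1, b2 - h)
            g[j] = (f(*args_hi) - f(*args_lo)) / (2 * h)
    if not np.all(np.isfinite(g)):
        raise ValidationError(f"gradient of f is not finite at ({b1}, {b2})")
    var = float(g @ fit.sigma @ g)
    se = float(np.sqrt(max(var, 0.0)))
    return FunctionInference(
        estimate=est, se=se, ci_low=est - Z95 * se, ci_high=est + Z95 * se,
        function_spec=f,
    )
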