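"""Meta-regression extension of the marginal method of moments.

Each outcome gets a weighted-least-squares regression on study-level
covariates with a DerSimonian-Laird-type moment estimator of the residual
between-study variance; the cross-outcome covariance of the two coefficient
vectors is built from products of per-study residuals over the studies
reporting both outcomes.  With an intercept-only design the procedure
reduces to the plain marginal method of moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BivariateDataset, ValidationError
from .mmom import truncate_psd
from .univariate import Z95

__all__ = ["MetaRegFit", "metareg_tau2", "metareg_fit"]


@dataclass(frozen=True)
class MetaRegFit:
    """Per-outcome regression coefficients with a joint block covariance.

    ``beta1``/``beta2`` are the random-effects GLS coefficient vectors,
    ``beta_fix1``/``beta_fix2`` their fixed-effect (tau2 = 0) counterparts
    used in the residual products, and ``sigma`` the (p1+p2) x (p1+p2)
    covariance of the stacked coefficients (PSD after any truncation).
    """

    beta1: np.ndarray
    beta2: np.ndarray
    sigma: np.ndarray
    tau2_1: float
    tau2_2: float
    beta_fix1: np.ndarray
    beta_fix2: np.ndarray
    truncated: bool

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate([self.beta1, self.beta2])

    def contrast(self, coeffs) -> tuple[float, float, tuple[float, float]]:
        """Estimate, SE and 95% CI for a linear contrast of stacked coefficients."""
        c = np.asarray(coeffs, dtype=float)
        est = float(c @ self.stacked)
        se = float(np.sqrt(max(c @ self.sigma @ c, 0.0)))
        return est, se, (est - Z95 * se, est + Z95 * se)


def metareg_tau2(y, s2, X, m_obs: int | None = None) -> float:
    """Moment estimate of the residual between-study variance in meta-regression.

    Q is the weighted residual sum of squares about the fixed-effect WLS fit;
    equating it to its expectation gives

        tau2 = max(0, (Q - (m - p)) /
                   (tr L^-1 - tr[(X'L^-1 X)^-1 X'L^-2 X])),  L = diag(s^2).
    """
    y = np.asarray(y, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValidationError(f"design has {X.shape[0]} rows for {y.size} studies")
    m, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValidationError("design matrix is rank deficient")
    if m_obs is not None:
        # MCAR pseudo-rows enter the sums with vanishing weight but must not
        # inflate the m - p expectation term
        m = int(m_obs)
    if m <= p:
        raise ValidationError(f"need more studies ({m}) than coefficients ({p})")
    w = 1.0 / s2
    xtw = X.T * w
    A = xtw @ X
    beta_fix = np.linalg.solve(A, xtw @ y)
    resid = y - X @ beta_fix
    q = float(np.sum(w * resid**2))
    denom = float(np.sum(w) - np.trace(np.linalg.solve(A, (X.T * w**2) @ X)))
    return max(0.0, (q - (m - p)) / denom)


def _design(ds: BivariateDataset, outcome: int, intercept: bool) -> np.ndarray:
    idx = ds.reporting_set(outcome)
    rows = []
    for i in idx:
        r = ds.records[i]
        x = r.x1 if outcome == 1 else r.x2
        rows.append([] if x is None else list(x))
    p = max(len(r) for r in rows)
    if any(len(r) != p for r in rows):
        raise ValidationError(f"outcome {outcome}: covariate vectors have unequal length")
    X = np.array(rows, dtype=float).reshape(len(rows), p)
    if intercept:
        X = np.column_stack([np.ones(len(rows)), X])
    if X.shape[1] == 0:
        raise ValidationError(f"outcome {outcome}: empty design (no covariates, no intercept)")
    return X


def metareg_fit(
    ds: BivariateDataset,
    intercept: bool = True,
    cov_residuals: str = "fixed",
) -> MetaRegFit:
    """Bivariate meta-regression by the marginal method of moments.

    Per outcome: fixed-effect WLS coefficients, moment tau2, then GLS with
    weights 1/(s^2 + tau2).  The cross-outcome coefficient covariance runs
    the per-study residual products of the overlap studies through both GLS
    projection matrices.  ``cov_residuals`` selects the residuals used in
    those products: ``"fixed"`` (fixed-effect coefficients, the default) or
    ``"random"`` (random-effects coefficients, which reproduces the
    intercept-only method exactly).
    """
    if cov_residuals not in ("fixed", "random"):
        raise ValueError(f"cov_residuals must be 'fixed' or 'random', got {cov_residuals!r}")
    per = {}
    for outcome in (1, 2):
        idx = ds.reporting_set(outcome)
        if not idx:
            raise ValidationError(f"no study reports outcome {outcome}")
        y, s2 = ds.outcome_arrays(outcome)
        X = _design(ds, outcome, intercept)
        tau2 = metareg_tau2(y, s2, X, m_obs=ds.observed_count(outcome))
        w_fix = 1.0 / s2
        beta_fix = np.linalg.solve((X.T * w_fix) @ X, (X.T * w_fix) @ y)
        w = 1.0 / (s2 + tau2)
        A = (X.T * w) @ X
        beta = np.linalg.solve(A, (X.T * w) @ y)
        per[outcome] = dict(idx=idx, y=y, X=X, w=w, A=A, beta=beta,
                            beta_fix=beta_fix, tau2=tau2)

    p1, p2 = per[1]["X"].shape[1], per[2]["X"].shape[1]
    cov11 = np.linalg.inv(per[1]["A"])
    cov22 = np.linalg.inv(per[2]["A"])

    # off-diagonal block: A1^-1 X1' W1 D W2 X2 A2^-1 with D the diagonal of
    # per-study residual products over the overlap set
    cross = np.zeros((p1, p2))
    if ds.R12:
        pos1 = {i: k for k, i in enumerate(per[1]["idx"])}
        pos2 = {i: k for k, i in enumerate(per[2]["idx"])}
        ref1 = per[1]["beta_fix"] if cov_residuals == "fixed" else per[1]["beta"]
        ref2 = per[2]["beta_fix"] if cov_residuals == "fixed" else per[2]["beta"]
        for i in ds.R12:
            k1, k2 = pos1[i], pos2[i]
            x1 = per[1]["X"][k1]
            x2 = per[2]["X"][k2]
            d = (per[1]["y"][k1] - x1 @ ref1) * (per[2]["y"][k2] - x2 @ ref2)
            cross += np.outer(per[1]["w"][k1] * x1, per[2]["w"][k2] * x2) * d
        cross = cov11 @ cross @ cov22

    sigma = np.block([[cov11, cross], [cross.T, cov22]])
    sigma, truncated = truncate_psd(sigma)
    return MetaRegFit(
        beta1=per[1]["beta"],
        beta2=per[2]["beta"],
        sigma=sigma,
        tau2_1=per[1]["tau2"],
        tau2_2=per[2]["tau2"],
        beta_fix1=per[1]["beta_fix"],
        beta_fix2=per[2]["beta_fix"],
        truncated=truncated,
    )
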