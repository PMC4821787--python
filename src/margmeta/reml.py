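"""Restricted maximum likelihood (REML) estimation of the between-study
covariance for the bivariate random-effects model, followed by BLUE pooling.

The restricted log-likelihood for Omega is

    -1/2 [ log| sum_i V_i^-1 | + sum_i log|V_i|
           + sum_i (y_i - b)' V_i^-1 (y_i - b) ],   V_i = Omega + Delta_i,

with b the GLS estimate at the current Omega.  Studies reporting a single
outcome enter through their observed (scalar) marginal, which is the exact
missing-completely-at-random likelihood contribution and coincides with the
large-variance augmentation convention in the limit.  Omega is parameterized
through its Cholesky factor with log-transformed diagonal, so every iterate
is positive semi-definite and no constraints are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data import BivariateDataset, ValidationError
from .jackson import blue_pool, jackson_fit
from .mmom import JointFit
from .univariate import dl_tau2

__all__ = ["RemlResult", "restricted_loglik", "reml_fit"]

_BIG = 1e10


@dataclass(frozen=True)
class RemlResult:
    """REML estimate of Omega plus the joint fit computed at that Omega."""

    omega: np.ndarray
    joint: JointFit
    converged: bool
    n_iter: int
    loglik: float


class _Arrays:
    """Dataset unpacked into flat arrays for fast likelihood evaluation."""

    def __init__(self, ds: BivariateDataset):
        ds.require_rho_w()
        comp, only1, only2 = [], [], []
        for r in ds:
            if r.complete:
                comp.append((r.y1, r.y2, r.s1, r.s2, r.rho_w))
            elif r.has_outcome1:
                only1.append((r.y1, r.s1**2))
            elif r.has_outcome2:
                only2.append((r.y2, r.s2**2))
        if comp:
            c = np.array(comp)
            self.cy = c[:, :2]
            s1, s2, rho = c[:, 2], c[:, 3], c[:, 4]
            self.d11, self.d22 = s1**2, s2**2
            self.d12 = s1 * s2 * rho
        else:
            self.cy = np.empty((0, 2))
            self.d11 = self.d22 = self.d12 = np.empty(0)
        a1 = np.array(only1) if only1 else np.empty((0, 2))
        a2 = np.array(only2) if only2 else np.empty((0, 2))
        self.y1o, self.v1o = a1[:, 0], a1[:, 1]
        self.y2o, self.v2o = a2[:, 0], a2[:, 1]
        self.m1 = len(self.cy) + len(self.y1o)
        self.m2 = len(self.cy) + len(self.y2o)


def _neg_rll(o11: float, o12: float, o22: float, arr: _Arrays) -> float:
    """Negative restricted log-likelihood at a given Omega (entries)."""
    v11 = o11 + arr.d11
    v22 = o22 + arr.d22
    v12 = o12 + arr.d12
    det = v11 * v22 - v12 * v12
    if not (np.isfinite(o11) and np.isfinite(o12) and np.isfinite(o22)):
        return _BIG
    if det.size and (not np.all(np.isfinite(det)) or det.min() <= 0):
        return _BIG
    i11 = v22 / det
    i22 = v11 / det
    i12 = -v12 / det

    u1 = o11 + arr.v1o
    u2 = o22 + arr.v2o
    if (u1.size and u1.min() <= 0) or (u2.size and u2.min() <= 0):
        return _BIG

    W11 = i11.sum() + (1.0 / u1).sum()
    W22 = i22.sum() + (1.0 / u2).sum()
    W12 = i12.sum()
    detW = W11 * W22 - W12 * W12
    if detW <= 0:
        return _BIG
    U1 = (i11 * arr.cy[:, 0] + i12 * arr.cy[:, 1]).sum() + (arr.y1o / u1).sum()
    U2 = (i12 * arr.cy[:, 0] + i22 * arr.cy[:, 1]).sum() + (arr.y2o / u2).sum()
    b1 = (W22 * U1 - W12 * U2) / detW
    b2 = (W11 * U2 - W12 * U1) / detW

    r1 = arr.cy[:, 0] - b1
    r2 = arr.cy[:, 1] - b2
    quad = (i11 * r1 * r1 + 2 * i12 * r1 * r2 + i22 * r2 * r2).sum()
    quad += ((arr.y1o - b1) ** 2 / u1).sum() + ((arr.y2o - b2) ** 2 / u2).sum()
    logdets = np.log(det).sum() + np.log(u1).sum() + np.log(u2).sum()
    val = 0.5 * (math.log(detW) + logdets + quad)
    return val if np.isfinite(val) else _BIG


def restricted_loglik(omega, ds: BivariateDataset) -> float:
    """Restricted log-likelihood of Omega for the given dataset.

    The fixed effects are profiled out by GLS at this Omega; the value is
    finite for any Omega making every Omega + Delta_i positive definite.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (2, 2):
        raise ValidationError(f"omega must be 2x2, got {omega.shape}")
    val = -_neg_rll(float(omega[0, 0]), float(omega[0, 1]), float(omega[1, 1]), _Arrays(ds))
    if val <= -_BIG / 2:
        raise ValidationError(
            f"restricted likelihood not finite at omega={omega.tolist()}"
        )
    return val


def _theta_to_entries(theta: np.ndarray, diagonal: bool) -> tuple[float, float, float]:
    # clip the log-scale entries: exp(+-60) is far beyond any plausible tau
    d = np.exp(np.clip(theta[:2], -60.0, 60.0))
    if diagonal:
        return d[0] * d[0], 0.0, d[1] * d[1]
    l21 = float(np.clip(theta[2], -1e12, 1e12))
    return d[0] * d[0], d[0] * l21, l21 * l21 + d[1] * d[1]


def _omega_to_theta(omega: np.ndarray, diagonal: bool) -> np.ndarray:
    floor = 1e-6
    o11 = max(float(omega[0, 0]), floor)
    o22 = max(float(omega[1, 1]), floor)
    if diagonal:
        return np.array([0.5 * math.log(o11), 0.5 * math.log(o22)])
    l11 = math.sqrt(o11)
    l21 = float(omega[0, 1]) / l11
    rest = o22 - l21 * l21
    l22 = math.sqrt(max(rest, floor * o22, floor**2))
    return np.array([math.log(l11), math.log(l22), l21])


def reml_fit(
    ds: BivariateDataset,
    start=None,
    max_iter: int = 500,
    tol: float = 1e-8,
    diagonal: bool = False,
) -> RemlResult:
    """Maximize the restricted likelihood over positive semi-definite Omega.

    Starts from the DerSimonian-Laird diagonal (zero covariance) and from the
    moment-equation estimate when available; quasi-Newton iterations with
    numeric gradients.  With ``diagonal=True`` the between-study covariance
    is constrained to zero.  Non-convergence is reported, never raised: the
    best iterate is returned with ``converged=False``.
    """
    y1, s21 = ds.outcome_arrays(1)
    y2, s22 = ds.outcome_arrays(2)
    if y1.size < 2 or y2.size < 2:
        raise ValidationError("REML needs at least 2 studies per outcome")
    arr = _Arrays(ds)

    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.asarray(start, dtype=float))
    t1 = max(dl_tau2(y1, s21), 1e-4)
    t2 = max(dl_tau2(y2, s22), 1e-4)
    starts.append(np.diag([t1, t2]))
    try:
        _, om = jackson_fit(ds)
        if not np.allclose(om.omega, np.diag([t1, t2])):
            starts.append(om.omega + 1e-6 * np.eye(2))
    except ValidationError:
        pass

    best = None
    for om0 in starts:
        theta0 = _omega_to_theta(om0, diagonal)
        with np.errstate(over="ignore", invalid="ignore"):
            res = minimize(
                lambda th: _neg_rll(*_theta_to_entries(th, diagonal), arr),
                theta0,
                method="L-BFGS-B",
                options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-7},
            )
        if best is None or res.fun < best.fun:
            best = res
    o11, o12, o22 = _theta_to_entries(best.x, diagonal)
    omega = np.array([[o11, o12], [o12, o22]])
    joint = blue_pool(ds, omega)
    joint = JointFit(beta=joint.beta, sigma=joint.sigma, method="reml", truncated=False)
    return RemlResult(
        omega=omega,
        joint=joint,
        converged=bool(best.success),
        n_iter=int(best.nit),
        loglik=-float(best.fun),
    )
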