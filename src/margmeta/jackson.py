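"""Jackson's multivariate method of moments for the bivariate random-effects
model (BRMA).

A multivariate heterogeneity statistic (Q1, Q12, Q2) is equated to its
expectation to estimate the between-study covariance matrix Omega; pooling is
then the BLUE / generalized-least-squares estimator with weights
(Omega + Delta_i)^-1, where Delta_i is the within-study covariance built from
the reported standard errors and the within-study correlation rho_w.  Unlike
the marginal method of moments, this comparator requires rho_w for every
study reporting both outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import BivariateDataset, ValidationError
from .mmom import JointFit, truncate_psd
from .univariate import dl_tau2

__all__ = ["QVector", "OmegaEstimate", "q_vector", "solve_omega", "blue_pool", "jackson_fit"]


@dataclass(frozen=True)
class QVector:
    """Components of the multivariate heterogeneity statistic.

    ``ybar1``/``ybar2`` are the 1/s^2-weighted means over each outcome's
    reporting set; the starred means weight by 1/(s_i1 s_i2) over the studies
    reporting both outcomes.  ``Q12`` (and the starred means) are 0/NaN when
    no study reports both outcomes, signalled by ``r12_empty``.
    """

    Q1: float
    Q12: float
    Q2: float
    ybar1: float
    ybar2: float
    ybar1_star: float
    ybar2_star: float
    r12_empty: bool = False


@dataclass(frozen=True)
class OmegaEstimate:
    """Moment estimate of the between-study covariance matrix.

    ``tau1_2``/``tau2_2`` are the (zero-truncated) between-study variances —
    identical to the univariate DerSimonian-Laird estimates; ``cov_B`` solves
    Q12 = a + b * cov_B.  ``omega`` is the assembled matrix after eigenvalue
    truncation; ``truncated`` records whether the raw moment solution had a
    negative eigenvalue (including any negative raw tau^2).
    """

    tau1_2: float
    tau2_2: float
    cov_B: float
    omega: np.ndarray
    truncated: bool
    a_coef: float
    b_coef: float
    r12_empty: bool = False


def q_vector(ds: BivariateDataset) -> QVector:
    """Multivariate Q statistic of the bivariate dataset."""
    y1, s2_1 = ds.outcome_arrays(1)
    y2, s2_2 = ds.outcome_arrays(2)
    if y1.size == 0 or y2.size == 0:
        raise ValidationError("each outcome needs at least one reporting study")
    w1 = 1.0 / s2_1
    w2 = 1.0 / s2_2
    ybar1 = float(np.sum(w1 * y1) / np.sum(w1))
    ybar2 = float(np.sum(w2 * y2) / np.sum(w2))
    q1 = float(np.sum(w1 * (y1 - ybar1) ** 2))
    q2 = float(np.sum(w2 * (y2 - ybar2) ** 2))

    if not ds.R12:
        return QVector(q1, 0.0, q2, ybar1, ybar2, np.nan, np.nan, r12_empty=True)

    b1 = np.array([ds.records[i].y1 for i in ds.R12])
    b2 = np.array([ds.records[i].y2 for i in ds.R12])
    p1 = np.array([ds.records[i].s1 for i in ds.R12])
    p2 = np.array([ds.records[i].s2 for i in ds.R12])
    ws = 1.0 / (p1 * p2)
    ybar1_star = float(np.sum(ws * b1) / np.sum(ws))
    ybar2_star = float(np.sum(ws * b2) / np.sum(ws))
    q12 = float(np.sum(ws * (b1 - ybar1_star) * (b2 - ybar2_star)))
    return QVector(q1, q12, q2, ybar1, ybar2, ybar1_star, ybar2_star)


def solve_omega(qv: QVector, ds: BivariateDataset) -> OmegaEstimate:
    """Solve the moment equations for the between-study covariance matrix.

    The diagonal equations reproduce the univariate DerSimonian-Laird tau^2
    per outcome; the off-diagonal equation Q12 = a + b*cov_B uses the
    within-study correlations of the overlap studies.  The assembled matrix
    is made positive semi-definite by clamping negative eigenvalues (which,
    for a 2x2 matrix, also truncates negative variances to zero and the
    implied correlation into [-1, 1]).
    """
    tau1 = dl_tau2(*ds.outcome_arrays(1), m_obs=ds.observed_count(1))
    tau2 = dl_tau2(*ds.outcome_arrays(2), m_obs=ds.observed_count(2))

    # raw (untruncated) diagonal solutions, to detect truncation honestly
    def _raw_tau(y, s2, m):
        if m < 2:
            return 0.0
        w = 1.0 / s2
        q = float(np.sum(w * (y - np.sum(w * y) / np.sum(w)) ** 2))
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        return (q - (m - 1)) / denom

    raw1 = _raw_tau(*ds.outcome_arrays(1), ds.observed_count(1))
    raw2 = _raw_tau(*ds.outcome_arrays(2), ds.observed_count(2))

    if qv.r12_empty or len(ds.R12) < 2:
        # no overlap, or a single overlapping study (then Q12 = 0 = a + 0*cov_B
        # identically): the covariance is unidentified and set to 0
        omega = np.diag([tau1, tau2])
        truncated = min(raw1, raw2) < 0
        return OmegaEstimate(tau1, tau2, 0.0, omega, truncated, np.nan, np.nan, r12_empty=True)

    ds.require_rho_w()
    rho = np.array([ds.records[i].rho_w for i in ds.R12])
    p1 = np.array([ds.records[i].s1 for i in ds.R12])
    p2 = np.array([ds.records[i].s2 for i in ds.R12])
    inv12 = 1.0 / (p1 * p2)
    a = float(np.sum(rho) - np.sum(rho * inv12) / np.sum(inv12))
    b = float(np.sum(inv12) - np.sum(inv12**2) / np.sum(inv12))
    if b == 0.0:
        raise ValidationError(
            "between-study covariance is unidentified (b = 0 in the moment equation)"
        )
    cov_b = (qv.Q12 - a) / b

    raw = np.array([[raw1, cov_b], [cov_b, raw2]])
    raw_min_eig = float(np.linalg.eigvalsh((raw + raw.T) / 2.0).min())
    omega, eig_truncated = truncate_psd(np.array([[tau1, cov_b], [cov_b, tau2]]))
    truncated = eig_truncated or raw_min_eig < 0
    return OmegaEstimate(tau1, tau2, cov_b, omega, truncated, a, b)


def _delta(record) -> np.ndarray:
    s1, s2, rho = record.s1, record.s2, record.rho_w
    return np.array([[s1**2, s1 * s2 * rho], [s1 * s2 * rho, s2**2]])


def blue_pool(ds: BivariateDataset, omega) -> JointFit:
    """BLUE pooling of both outcomes given a between-study covariance matrix.

    beta = (sum V_i^-1)^-1 sum V_i^-1 y_i with V_i = Omega + Delta_i; its
    covariance is (sum V_i^-1)^-1.  Studies reporting a single outcome
    contribute their scalar marginal weight 1/(Omega_jj + s_ij^2) — the exact
    limit of the large-variance augmentation convention for missing outcomes.
    Studies reporting neither outcome contribute nothing.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (2, 2):
        raise ValidationError(f"omega must be 2x2, got shape {omega.shape}")
    ds.require_rho_w()
    W = np.zeros((2, 2))
    u = np.zeros(2)
    any_study = False
    for r in ds:
        if r.complete:
            v = omega + _delta(r)
            det = v[0, 0] * v[1, 1] - v[0, 1] ** 2
            if det <= 0:
                raise ValidationError(
                    f"study {r.study_id!r}: Omega + Delta_i is singular"
                )
            vinv = np.array([[v[1, 1], -v[0, 1]], [-v[0, 1], v[0, 0]]]) / det
            W += vinv
            u += vinv @ np.array([r.y1, r.y2])
            any_study = True
        elif r.has_outcome1:
            w = 1.0 / (omega[0, 0] + r.s1**2)
            W[0, 0] += w
            u[0] += w * r.y1
            any_study = True
        elif r.has_outcome2:
            w = 1.0 / (omega[1, 1] + r.s2**2)
            W[1, 1] += w
            u[1] += w * r.y2
            any_study = True
    if not any_study or W[0, 0] == 0 or W[1, 1] == 0:
        raise ValidationError("each outcome needs at least one reporting study")
    cond = np.linalg.cond(W)
    if cond >= 1e12:
        warnings.warn(
            f"pooling weight matrix is ill-conditioned (cond={cond:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = np.linalg.solve(W, u)
    detW = W[0, 0] * W[1, 1] - W[0, 1] ** 2
    sigma = np.array([[W[1, 1], -W[0, 1]], [-W[0, 1], W[0, 0]]]) / detW
    return JointFit(beta=beta, sigma=sigma, method="jackson", truncated=False)


def jackson_fit(ds: BivariateDataset) -> tuple[JointFit, OmegaEstimate]:
    """Estimate Omega by the moment equations, then BLUE-pool with it."""
    est = solve_omega(q_vector(ds), ds)
    joint = blue_pool(ds, est.omega)
    joint = JointFit(
        beta=joint.beta, sigma=joint.sigma, method="jackson",
        truncated=est.truncated,
    )
    return joint, est
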