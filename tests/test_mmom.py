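"""The marginal method of moments: covariance estimate, joint fit,
eigenvalue truncation and function-of-effects inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from margmeta import (
    ValidationError,
    delta_method,
    linear_combo,
    mmom_cov,
    mmom_fit,
    pool,
    truncate_psd,
)
from margmeta.simulate import SimConfig, generate_dataset
from conftest import make_complete


class TestCov:
    def test_disjoint_reporting_sets_give_zero(self, disjoint_ds):
        fit = mmom_fit(disjoint_ds)
        assert fit.sigma[0, 1] == 0.0
        assert fit.sigma[1, 0] == 0.0

    def test_symmetric_hand_case(self):
        # y1 = y2 = (1, -1), unit s: tau2 = 1 per outcome, all weights equal
        # (w_i/w_+ = 1/2), residuals (1,-1) for both -> cov = 1/4 + 1/4 = 1/2
        ds = make_complete([1, -1], [1, 1], [1, -1], [1, 1])
        f1 = pool(*ds.outcome_arrays(1))
        f2 = pool(*ds.outcome_arrays(2))
        assert f1.tau2 == pytest.approx(1.0)
        assert mmom_cov(ds, f1, f2) == pytest.approx(0.5)

    def test_matches_loop_oracle(self):
        cfg = SimConfig(m=10, tau2=0.5)
        ds = generate_dataset(cfg, 0.6, 0.5, np.random.default_rng(5))
        f1 = pool(*ds.outcome_arrays(1))
        f2 = pool(*ds.outcome_arrays(2))
        w1 = {i: w for i, w in zip(ds.R1, f1.weights)}
        w2 = {i: w for i, w in zip(ds.R2, f2.weights)}
        expected = sum(
            (w1[i] / sum(w1.values()))
            * (w2[i] / sum(w2.values()))
            * (ds.records[i].y1 - f1.beta)
            * (ds.records[i].y2 - f2.beta)
            for i in ds.R12
        )
        assert mmom_cov(ds, f1, f2) == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_marginals_identical_to_univariate(self, small_complete_ds):
        ds = small_complete_ds
        joint = mmom_fit(ds)
        f1 = pool(*ds.outcome_arrays(1))
        f2 = pool(*ds.outcome_arrays(2))
        # bit-for-bit: the joint fit must never perturb the univariate results
        assert joint.beta[0] == f1.beta and joint.beta[1] == f2.beta
        assert joint.marginals[0].se == f1.se and joint.marginals[1].se == f2.se
        if not joint.truncated:
            assert joint.sigma[0, 0] == f1.se**2
            assert joint.sigma[1, 1] == f2.se**2

    def test_missing_outcome_errors_name_outcome(self):
        from margmeta import BivariateDataset, StudyRecord

        ds = BivariateDataset((StudyRecord("a", y1=0.1, s1=0.2),))
        with pytest.raises(ValidationError, match="outcome 2"):
            mmom_fit(ds)

    def test_estimated_covariance_tracks_monte_carlo_covariance(self):
        # across replicates the mean estimated off-diagonal must agree with
        # the empirical covariance of the pooled estimates
        cfg = SimConfig(m=25, tau2=0.5)
        rng = np.random.default_rng(314)
        b1, b2, covs = [], [], []
        for _ in range(500):
            ds = generate_dataset(cfg, 0.5, 0.5, rng)
            f = mmom_fit(ds)
            b1.append(f.beta[0])
            b2.append(f.beta[1])
            covs.append(mmom_cov(ds, *f.marginals))
        z = (np.array(b1) - np.mean(b1)) * (np.array(b2) - np.mean(b2))
        mc_cov = z.sum() / (len(z) - 1)
        mc_se = np.std(z, ddof=1) / np.sqrt(len(z))
        assert abs(np.mean(covs) - mc_cov) < 3 * mc_se


class TestTruncatePsd:
    def test_psd_input_unchanged(self):
        out, flag = truncate_psd(np.eye(2))
        assert not flag and np.array_equal(out, np.eye(2))

    def test_analytic_two_by_two(self):
        # eigenvalues 3 and -1 with eigenvectors (1, +-1)/sqrt(2)
        out, flag = truncate_psd(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert flag
        assert np.allclose(out, [[1.5, 1.5], [1.5, 1.5]])

    def test_matches_eigen_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(2, 2))
        mat = (a + a.T) / 2 - 1.2 * np.eye(2)  # push an eigenvalue negative
        vals, vecs = np.linalg.eigh(mat)
        if vals.min() >= 0:  # pragma: no cover - seed chosen to avoid this
            pytest.skip("seed produced PSD matrix")
        expected = (vecs * np.clip(vals, 0, None)) @ vecs.T
        out, flag = truncate_psd(mat)
        assert flag
        assert np.allclose(out, expected, atol=1e-12)
        assert np.linalg.eigvalsh(out).min() >= -1e-12

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            truncate_psd(np.array([[1.0, 0.5], [0.0, 1.0]]))


@given(
    offdiag=st.floats(-3, 3, allow_nan=False),
    d1=st.floats(0.01, 2, allow_nan=False),
    d2=st.floats(0.01, 2, allow_nan=False),
)
@settings(max_examples=80, deadline=None, derandomize=True)
def test_truncation_always_yields_psd_with_bounded_correlation(offdiag, d1, d2):
    out, _ = truncate_psd(np.array([[d1, offdiag], [offdiag, d2]]))
    assert np.linalg.eigvalsh(out).min() >= -1e-10
    denom = np.sqrt(out[0, 0] * out[1, 1])
    if denom > 0:
        assert abs(out[0, 1]) <= denom * (1 + 1e-10)


class TestFunctions:
    @pytest.fixture
    def fit(self, small_complete_ds):
        return mmom_fit(small_complete_ds)

    def test_projection_recovers_marginal(self, fit):
        inf = linear_combo(fit, (1.0, 0.0))
        assert inf.estimate == fit.beta[0]
        assert inf.se == pytest.approx(np.sqrt(fit.sigma[0, 0]))

    def test_difference_hand_algebra(self):
        from margmeta.mmom import JointFit

        jf = JointFit(
            beta=np.array([0.0, 2.0]),
            sigma=np.array([[1.0, 0.5], [0.5, 1.0]]),
            method="mmom",
            truncated=False,
        )
        inf = linear_combo(jf, (1.0, -1.0))
        assert inf.estimate == pytest.approx(-2.0)
        assert inf.se == pytest.approx(1.0)

    def test_zero_coefficients_rejected(self, fit):
        with pytest.raises(ValidationError):
            linear_combo(fit, (0.0, 0.0))

    def test_delta_method_agrees_with_linear_combo_for_linear_f(self, fit):
        lin = linear_combo(fit, (0.5, 0.5))
        dm = delta_method(fit, lambda b1, b2: 0.5 * b1 + 0.5 * b2)
        assert dm.estimate == pytest.approx(lin.estimate, rel=1e-12)
        assert dm.se == pytest.approx(lin.se, rel=1e-8)

    def test_ratio_hand_gradient(self):
        from margmeta.mmom import JointFit

        jf = JointFit(
            beta=np.array([1.0, 2.0]), sigma=np.eye(2), method="mmom", truncated=False
        )
        inf = delta_method(jf, lambda b1, b2: b1 / b2)
        assert inf.estimate == pytest.approx(0.5)
        assert inf.se == pytest.approx(np.sqrt(0.3125), rel=1e-6)

    def test_analytic_and_numeric_gradients_agree(self, fit):
        f = lambda b1, b2: np.exp(b1 - b2)
        g = lambda b1, b2: (np.exp(b1 - b2), -np.exp(b1 - b2))
        num = delta_method(fit, f)
        ana = delta_method(fit, f, grad=g)
        assert num.se == pytest.approx(ana.se, rel=1e-6)

    def test_nonfinite_function_rejected(self, fit):
        with pytest.raises(ValidationError):
            delta_method(fit, lambda b1, b2: np.inf)


def test_coverage_of_difference_interval():
    """95% CI for delta = beta1 - beta2 keeps near-nominal coverage under
    uncorrelated outcomes (coverage at extreme correlations, where the
    covariance must be estimated from few cross products, is tracked by the
    grid summaries instead)."""
    for m, floor in ((10, 0.85), (25, 0.88)):
        cfg = SimConfig(m=m, tau2=0.5)
        rng = np.random.default_rng(99)
        hits = 0
        n = 500
        for _ in range(n):
            ds = generate_dataset(cfg, 0.0, 0.0, rng)
            inf = linear_combo(mmom_fit(ds), (1.0, -1.0))
            hits += inf.ci_low <= -2.0 <= inf.ci_high
        assert hits / n >= floor
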