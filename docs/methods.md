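# Methods

## Model

Study *i* reports estimates (Y_i1, Y_i2) of its true effects (θ_i1, θ_i2)
for up to two outcomes. The bivariate random-effects model (BRMA) is the
two-level normal hierarchy

    (Y_i1, Y_i2) ~ N2((θ_i1, θ_i2), Δ_i),   Δ_i = [[s_i1², s_i1 s_i2 ρ_wi],
                                                   [s_i1 s_i2 ρ_wi, s_i2²]]
    (θ_i1, θ_i2) ~ N2((β_1, β_2), Ω),       Ω   = [[τ_1², τ_1 τ_2 ρ_B],
                                                   [τ_1 τ_2 ρ_B, τ_2²]]

with the within-study standard errors s_ij treated as fixed and known.
Marginally, Y_i ~ N2(β, Δ_i + Ω). The within-study correlation ρ_wi is
induced by shared subjects and is rarely reported; the between-study
correlation ρ_B describes how the true effects co-vary across studies.

## Estimators

**Marginal method of moments (MMoM)** — the package's core. Each outcome is
pooled by the ordinary DerSimonian–Laird univariate random-effects analysis
over its reporting set R_j: weights w_ij = (s_ij² + τ̃_j²)⁻¹ with the
non-iterative moment estimate τ̃_j² (zero-truncated). The covariance between
the two pooled estimates is then estimated by replacing each study's
cov(Y_i1, Y_i2) with the cross product of its residuals about the pooled
effects, summed over the overlap set R₁₂ with the pooling weights (zero when
R₁₂ is empty — disjoint analyses really are independent). The resulting 2×2
matrix Σ̃* has the exact squared univariate standard errors on its diagonal;
if it is indefinite, its negative eigenvalue is clamped to zero
(`truncate_psd`) for joint inference, while the reported marginal standard
errors always remain the untruncated univariate ones — truncation exists
only to make joint statements valid, never to change the marginal results.
Linear functions c'β use se = √(c'Σ̃*c); nonlinear functions use the delta
method with analytic or central-difference gradients (step 1e-6·(1+|β̃_j|)).
No within-study correlations are needed, and no borrowing of strength is
attempted: the marginal estimates are exactly the univariate ones.

**Jackson's multivariate method of moments** (comparator; needs ρ_wi).
The multivariate heterogeneity statistic (Q₁, Q₁₂, Q₂) is equated to its
expectation. The diagonal equations reproduce the univariate
DerSimonian–Laird τ̃_j² exactly; the off-diagonal equation
Q₁₂ = a + b·cov_B is solved for the between-study covariance, where a and b
are the weighted-sum coefficients built from the overlap studies'
s_i1 s_i2 and ρ_wi. Negative τ̃_j² are clamped before assembly and the
assembled Ω̂ is made PSD by eigenvalue truncation; the `truncated` flag
records whether the raw moment solution (untruncated variances included) had
a negative eigenvalue. Pooling is then the BLUE / GLS estimator
β̂ = (Σ V_i⁻¹)⁻¹ Σ V_i⁻¹ Y_i with V_i = Ω̂ + Δ_i and covariance (Σ V_i⁻¹)⁻¹.

**REML** (comparator; needs ρ_wi). Ω is estimated by maximizing the
restricted log-likelihood (fixed effects profiled out by GLS), and pooling
proceeds as above at Ω̂. Ω is parameterized through its Cholesky factor with
log-transformed diagonal, so every iterate is PSD without constraints and
boundary correlations ±1 are reachable in the limit. Optimization is
L-BFGS-B with numeric gradients, ftol 1e-8, at most 500 iterations, started
from the DerSimonian–Laird diagonal and from Jackson's Ω̂ when computable;
the best optimum is kept and non-convergence is reported (best iterate
returned), never raised. The implementation was cross-checked against R's
`metafor::rma.mv` (REML, unstructured Ω): coefficients, variance components,
a boundary correlation of 1, and the coefficient covariance all agree to
printed precision on a 12-study fixture.

**Meta-regression extension.** Per outcome, fixed-effect weighted least
squares gives β̂_fix and the residual Q statistic; equating Q to its
expectation gives a moment τ̂_j² (the `m − p_j` term uses the reporting-set
size), and random-effects GLS with Λ* = diag(s² + τ̂²) gives the
coefficients. The cross-outcome coefficient covariance propagates per-study
residual products of the overlap studies through both GLS projections.
The residuals in those products use the fixed-effect coefficients by
default, as the printed formulation of the extension specifies; with
`cov_residuals="random"` they use the random-effects coefficients, which
makes the intercept-only case reduce *exactly* (covariance included) to the
plain MMoM. The two variants answer the same question and differ only in
this residual choice, which the source formulation leaves unreconciled.

## Missing outcomes (MCAR)

All estimators assume missing outcomes are missing completely at random.
Two equivalent routes are provided. The direct route restricts every sum to
the relevant reporting set; partially reported studies enter the BLUE/REML
computations through their observed (scalar) marginal blocks, which is the
exact MCAR likelihood contribution. The augmentation route
(`augment_mcar`) fills each missing outcome with estimate 0, standard error
√(large_variance) (default 10⁶) and ρ_w = 0, after which the complete-data
formulas apply; the filled-in cells receive vanishing weight, so the two
routes agree to O(1/large_variance) — about 1e-6 relative at the default.
One bookkeeping subtlety: a pseudo-observation must not inflate the
degrees-of-freedom term (m_Yj − 1) in the moment equations, because it
contributes essentially nothing to Q_j; `augment_mcar` therefore flags
filled-in cells and the moment estimators count only genuine observations.
Without this correction the augmented τ̃² would be biased low by a constant
that does not shrink as the variance grows.

## Simulation study

`margmeta.simulate` draws data from the two-stage hierarchy above with
defaults matching the benchmark design: β = (0, 2); τ₁² = τ₂² = 0.5
(0.1 and 0.25 as lighter-heterogeneity variants); ρ_B over
{−0.8, −0.6, −0.4, 0, 0.4, 0.6, 0.8}; ρ_w over {−0.8, −0.5, 0, 0.5, 0.8};
m = 10 or 25 studies; optionally 30% MCAR deletion per outcome
(independently; a study may lose both outcomes and then contributes
nothing). Within-study variances are the square of an N(0.25, 0.50) draw,
where 0.50 is the *variance* — this reading gives the design's median
within-study variance of ≈ 0.26 (the standard-deviation reading gives
≈ 0.15) — and one draw is shared by both outcomes of a study
(`shared_s2=True`). The shared draw makes the two outcomes' precisions
equal within each study, which is what reproduces the published efficiency
behaviour of the moment estimators relative to REML; fully independent
per-outcome draws are available via `shared_s2=False` and make the
marginal approach look relatively worse, because the two outcomes' pooling
weights then disagree and the difference estimator loses efficiency.

Per (ρ_B, ρ_w) cell and method the driver records: bias of
δ̂ = β̃₁ − β̃₂ with its Monte-Carlo standard error, coverage of the nominal
95% interval, relative efficiency versus REML, truncation frequency and
REML non-convergence frequency. Relative efficiency is

    RE = 100 × Var_MC(δ̂_REML) / Var_MC(δ̂_method),

the ratio of empirical variances across replicates ("the square of the
standard error of the estimator" read as the Monte-Carlo standard
deviation). The alternative reading — ratio of mean squared model-based
standard errors — is available as `re_method="model_se"`, but is not the
default: model-based standard errors of the marginal method are noticeably
conservative in high-correlation cells, and that reading drives RE far below
any published range. Replicates in which a method fails outright are
excluded from that method's aggregates and counted. Per-cell random streams
are spawned deterministically from the master seed and the cell index, so
any sub-grid is reproducible in isolation.

Default replication is 200 per cell (a reduced-cost setting for routine
runs); the test suite uses the full 1000 for the headline m = 10 complete
grid and 400 for the other grids, and `scripts/acceptance.py` uses 800 for
the efficiency grid and 1000 for the truncation grid — sizes chosen so the
grid-minimum statistics are stable while a full run stays in the minutes
range on one CPU.

## What the generator does and does not emulate

It emulates: two-stage normal sampling with exact within- and between-study
correlation structure, fixed known within-study variances with a realistic
right-skewed distribution, MCAR missingness, and equal per-study precision
across outcomes. It does not emulate: non-normal effect distributions,
estimated (noisy) s_ij, correlation between s_ij and effect size
(small-study effects), outcome-reporting bias (missingness would then not
be MCAR), or more than two outcomes. Passing tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to their violation.

## Numerical choices and edge cases

- Normal 95% quantile 1.96 everywhere; no small-sample (Knapp–Hartung)
  adjustment.
- τ̃² and the meta-regression τ̂² are zero-truncated; a single study gives
  Q = 0 and τ̃² = 0 by convention (the moment equation is degenerate).
- `truncate_psd` treats eigenvalues above −1e-12 (relative) as
  non-negative, so exactly-PSD inputs are returned unchanged and not
  flagged; asymmetry beyond 1e-8 relative is an error.
- 2×2 systems are solved analytically; the BLUE weight matrix warns when
  its condition number reaches 1e12.
- Weights in the MMoM covariance are the pooling weights (fixed- or
  random-effects per the fitted model); they are not re-estimated on the
  overlap subset, and the residuals use the all-studies pooled estimates,
  exactly as the estimator is defined.
- An overlap of a single study estimates the covariance from one cross
  product; no small-sample correction is applied.
- With an empty overlap set Jackson's off-diagonal moment equation is
  vacuous; the between-study covariance is set to 0 and flagged
  (`r12_empty`).

## Known limitations

- Bivariate only; the data structures do not preclude more outcomes, but
  nothing beyond two is implemented or tested.
- The MMoM covariance estimate is noisy when few studies report both
  outcomes: in high-|correlation| cells at m = 10–25 the implied
  correlation regularly exceeds ±1 (truncation rates of 10–35% per cell in
  our grids), and coverage of the difference interval there runs a few
  points below the ~90% seen at moderate correlations.
- REML results depend mildly on optimizer settings near boundary Ω̂; exact
  third-party agreement is checked at fixture scale, and simulation-scale
  agreement is distributional only.
- MCAR is assumed, never tested; informative missingness biases every
  estimator here.
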