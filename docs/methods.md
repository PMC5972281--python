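# Methods

## The model and the study design

`cfasim` studies how reliably a unifactorial measurement model can be
recovered from sample data by confirmatory factor analysis (CFA). The
population follows the common factor model

    x = Lambda xi + delta,          Sigma = Lambda Phi Lambda' + Theta,

with one common factor (k = 1), factor variance Phi = 1 fixed for
identification, equal loadings lambda on all p indicators, and unique
variances theta_i = 1 - lambda^2 so each indicator has unit variance. Under
this design the implied covariance matrix equals the implied correlation
matrix: every off-diagonal element is lambda^2.

The simulation grid crosses loading magnitude lambda in {0.2, 0.3, 0.4},
indicators per factor p in {4, 5, 6, 7, 15}, and sample size N in
{200, 300, 400, 500} — 60 conditions, 1,000 replications each by default.
These magnitudes deliberately cover the weak range where applied scales are
often built (a common applied rule is not to interpret loadings below 0.3),
which is exactly where improper solutions and misleading fit indices appear.

## Data generation

Each replication draws xi ~ N(0, 1) and delta_i ~ N(0, theta_i)
independently and forms the N x p matrix row-wise; sample moments use the
n - 1 covariance denominator, and the correlation matrix is derived from the
covariance matrix of the same raw data. Seeding is hierarchical
(`numpy.random.SeedSequence` with entropy pool = master seed, condition
labels, replicate index), so any single replication (its CASE id) is
regenerable in isolation and study outputs are byte-identical across reruns
regardless of execution order.

What the generator emulates: multivariate-normal, unit-variance, equal-
loading indicator sets. What it does not emulate: non-normal or categorical
indicators (a threshold discretizer is provided but not exercised by the
study pipeline), unequal loadings, multi-factor structures, or missing
data. Passing tests therefore speak to CFA behaviour under ideal
distributional conditions; real scales violate several of these at once.

## Estimation

`OneFactorCFA.fit` minimizes a discrepancy function F(S; Sigma*) over the
2p free parameters (p loadings, p unique variances):

* **ML** (fitted to S): F_ML = ln|Sigma*| + tr(S Sigma*^-1) - ln|S| - p,
  the normal-theory likelihood discrepancy whose (n - 1) F_min is the usual
  chi-square statistic.
* **ULS** (fitted to R): F_ULS = d'd, the sum of squared non-redundant
  moment residuals. The diagonal is included in the objective; its
  residuals vanish identically at the optimum, so on correlation input this
  coincides with fitting the off-diagonals under a fixed unit diagonal.

Numerical choices:

* Optimizer: L-BFGS-B with the analytic gradient
  (dF_ML/dSigma = Sigma^-1 (Sigma - S) Sigma^-1 mapped onto the
  parameters), iteration cap 250 (matching the classical convergence-
  criterion setting), internal tolerances well below the reported
  convergence rule.
* Convergence is declared when the gradient infinity-norm is below 1e-6;
  anything else is classified `nonconvergent` — a result, not an error. In
  weak-loading conditions the likelihood frequently has no interior optimum
  (one theta_i drifts to -infinity while F creeps downward); these runs hit
  the iteration cap and are classified nonconvergent, mirroring classical
  SEM software behaviour.
* Start values: first principal axis, lambda0 = v1 sqrt(a1),
  theta0 = s_ii - lambda0_i^2 floored at 0.05 s_ii to keep the starting
  Sigma* positive definite.
* Unique variances are unconstrained so Heywood cases (theta_i < 0 at a
  converged optimum) occur and are detected; theta = 0 exactly counts as
  proper. When an iterate leaves the positive-definite region a smooth
  eigenvalue penalty pushes it back.
* Reflection invariance (lambda and -lambda are equivalent) is resolved by
  forcing a nonnegative loading sum.
* p = 3 leaves df = 0 and the model interpolates the moment matrix exactly;
  the fitter returns the algebraic triad solution
  lambda_1 = sqrt(s12 s13 / s23) (and permutations) directly, which also
  covers moment matrices that are not positive definite and hence
  unreachable by likelihood iteration.

Standard errors (ML only) come from the inverse observed information of the
discrepancy, Cov = 2/(n - 1) H^-1 with H the numerically differentiated
Hessian of F_ML at the optimum, and are reported in the unstandardized
metric; t statistics are lambda_i / SE_i. Standardized loadings divide by
the observed indicator standard deviation, making ML-on-S solutions
directly comparable with ULS-on-R solutions.

## Fit indices

chi-square = (n - 1) F_min with df = p(p+1)/2 - 2p; p-value from the
chi-square upper tail. The independence baseline (diagonal Sigma*) has ML
discrepancy -ln|R|, so its chi-square is -(n - 1) ln|R| with
df = p(p-1)/2.

* RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))) (Steiger-Lind).
* CFI is computed as the **raw noncentrality ratio**
  1 - (chi2 - df)/(chi2_b - df_b), clipped to [0, 1]. This differs from
  Bentler's max-truncated form (also available via `form="bentler"`)
  exactly when the sample baseline noncentrality estimate is negative —
  common when population correlations are as low as 0.04 — where the raw
  ratio clips to 0. The raw ratio is what classical SEM output evidently
  prints: it reproduces both the mean and the large SD of the CFI column in
  the reference summary table at lambda = 0.2, where the truncated form
  gives ~0.95 instead of ~0.70. ULS chi-squares use the same (n - 1) F
  transformation but are flagged non-comparable in the index metadata.

## Evaluation

Parameter recovery is scored by the coefficient of congruence (Tucker's
phi) between estimated and population loading vectors, with the usual
0.85 (fair) / 0.95 (good) reading. Summaries pool sub-conditions into the
3 x 6 layout (lambda rows; columns: p in {4-6}, {7}, {15} crossed with
N in {200-300}, {400-500}), computed over proper solutions only. The
per-replication "average loading" is the mean of the p standardized
estimates; the table's min-max row shows the extremes of those replication
averages (not of individual loadings). SDs use n - 1. Congruence ranks use
mean ranks for ties, rank 1 = highest congruence, and the ranking-vs-
p-value table carries the Spearman correlation.

## Diagnostics

Positive definiteness is checked by eigendecomposition (all eigenvalues
above 1e-10). Outlier screening computes squared Mahalanobis distances
(x_i - xbar)' S^-1 (x_i - xbar) directly — equivalent to, but cleaner than,
the leverage obtained by regressing a random criterion on the indicators —
and flags cases beyond the upper-alpha chi-square(p) quantile
(alpha = 0.05 default, per-case, unadjusted for multiplicity). The
chi-square reference is asymptotic; at the study's N the null flag rate
calibrates to alpha within about a percentage point. Refitting after
removal recomputes moments, refits, and rescores congruence.

## Known limitations and observed deviations

* The original study ran on PRELIS/LISREL; its random number generator is
  not reproducible, so reproduction is distributional, not bit-wise.
* In the weakest cell (lambda = 0.2, 4-6 indicators, N = 200-300) roughly
  15% of our proper ML solutions are "dominant indicator" optima: one large
  loading, the rest near zero, excellent fit. Multi-start checks confirm
  these are genuine global minima of the ML discrepancy. LISREL's iterative
  path evidently settles elsewhere in these nearly flat likelihoods, which
  shifts two statistics of that one cell relative to the printed table:
  mean congruence (ours ~0.76 vs 0.84) and mean CFI (ours ~0.73 vs 0.70,
  the distorted solutions' perfect fit pulling the mean up). Proper-
  solution rates, loading means, RMSEA, and every statistic of the
  stronger cells reproduce within Monte Carlo tolerance.
* ULS standard errors are not provided (the classical unstandardized-SE
  recipe is ML-specific); ULS fit indices are transformations of the same
  (n - 1) F statistic and are not on the likelihood-ratio scale.

## Problem sizes used by the test suite

The acceptance checks run the five pooled cells that back the reported
quantities at the study's full 1,000 replications per sub-condition
(22,000 fits, about two minutes with the analytic-gradient fitter); unit
and property tests use small seeded samples, large-n law-of-large-numbers
checks up to n = 200,000, and 60-150-replication Monte Carlo checks for
rate and SE assertions.
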