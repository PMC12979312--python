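# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `sparsesem`, in the spirit of the methods documentation of
packages like statsmodels or msprime.

## Data convention

All estimators consume *standardized* data: each column mean-centered and
scaled by the **population** standard deviation (denominator N), so that
every column has squared norm exactly N and ‖Y‖²_F = N·J. The population
(rather than N−1) convention is a deliberate choice: the factor-score
columns carry the constraint Σ_i η²_iq = N, and only with matching scaling
do the identities used throughout hold exactly — loss N·J at **P** = 0, PEV
bounded by rank-Q PCA, and (for the orthogonal variant) nonzero loadings
equal to item–score Pearson correlations to machine precision. Missing
values are rejected rather than imputed; any imputation is the user's
responsibility upstream.

## Stage 1: the two sparse factor analyzers

Both estimators minimize the least-squares misfit ‖Y − ηPᵀ‖²_F of the
approximate factor model. The residuals are only assumed weakly correlated;
no residual covariance is estimated (it cannot be, as a full-rank object,
when J ≥ N).

**LASSO variant.** The penalized objective ‖Y − ηPᵀ‖²_F + λ·Σ|p_jq| is
minimized by alternating optimization:

- *Scores.* Column-wise block updates: for factor q, with partial residual
  R_q = Y − Σ_{t≠q} η_t p_tᵀ, the constrained minimizer is
  η_q = √N·R_q p_q / ‖R_q p_q‖ (Lagrange multiplier for the norm
  constraint). Each column update is the exact minimizer of its subproblem,
  so the loss cannot increase. A column whose loadings are entirely zero has
  an undefined update; inside the fitting loop it is left unchanged (its
  loadings being zero, the loss is unaffected), while the public
  `update_scores` raises by default.
- *Loadings.* Cyclic coordinate descent with the closed form
  p_jq ← S(η_qᵀ r_j^{(−q)}, λ/2) / (η_qᵀη_q), where S is soft-thresholding
  and r_j^{(−q)} the partial residual of variable j. The divisor is the
  actual Gram diagonal (equal to N up to rounding) so each step is an exact
  conditional minimizer. Loadings for a given factor are independent across
  variables and are updated as a vector. Cycles repeat until the largest
  coordinate change falls below `inner_tol` (default 1e-8). Zeros produced
  by the threshold are exact zeros; no post-hoc rounding is ever applied.

**Cardinality variant.** For orthogonal factors (ηᵀη = N·I) the problem
with a hard cap Card(P) ≤ C is solved by alternating three closed forms:
dense loadings P = YᵀH/N (item–score correlations), top-C hard thresholding
(exact because, given orthogonal scores, the loss is separable over loading
entries), and the orthogonal Procrustes score update η = √N·UVᵀ from the
thin SVD of YP. Although the cardinality constraint is non-convex — so no
global guarantee exists — each half step is an exact conditional minimizer
and the implementation additionally guards by tracking the best iterate and
stopping on any (numerical) loss increase. Ties at the C-th largest
magnitude are broken deterministically toward the entry earlier in
column-major (factor, then variable) order.

**Multistart protocol.** Both fits draw `n_starts` random score matrices
(i.i.d. normal columns rescaled to norm √N; projected to the orthogonality
constraint via the polar factor for the cardinality variant) plus one
deterministic start from the top-Q left singular vectors of Y, and keep the
run with the lowest final loss (ties within 1e-9 keep the earliest start,
for reproducibility). The deterministic SVD start also makes the λ = 0 and
C = J·Q limits coincide with the truncated-SVD solution, a property the test
suite asserts. The default `n_starts=100` mirrors the simulation-study
protocol; selection paths use far fewer because each candidate inherits a
warm start (below).

**Convergence.** A run stops when the relative loss decrease falls below
`tol` (default 1e-8) or after `max_iter` (default 1000) iterations, in which
case the fit is returned with `converged_ = False` and a warning. The
cardinality variant finishes each run with one extra loading half-step so
the returned (η, P) pair is exactly self-consistent (nonzero loadings equal
item–score correlations within 1e-8); the step cannot increase the loss.

## Model selection

The Index of Sparseness IS = PEV_PCA × PEV_model × PS multiplies the
variance proportion of rank-Q PCA (a constant per dataset), the model's
explained-variance proportion, and the proportion of zero loadings. The
candidate maximizing IS is selected; ties within 1e-12 go to the sparser
candidate, since the index exists to penalize complexity.

- Cardinality grid: all integers in [3Q, J·Q] by default (at least three
  loadings per factor, the simulation-study convention); the floor is
  configurable down to Q.
- λ grid: `n_points` log-spaced values between 0.1·N and λ_max. λ_max — the
  smallest penalty leaving one nonzero loading per factor — has no closed
  form under the norm-constrained alternating scheme, so it is bracketed by
  bisection over refits to 1% relative width (upper bracket returned). The
  0.1·N floor is a convention kept configurable.
- The grid is traversed from sparse to dense, each candidate warm-started
  from the previous solution in addition to fresh random starts and the SVD
  start; a backward (dense-to-sparse) refinement sweep then re-fits each
  candidate from its denser neighbour's solution and keeps the better fit —
  the sparsest candidate has no warm start on the forward pass, and without
  the sweep an early local optimum can propagate along the path. Candidate fits use a relaxed tolerance (1e-6 relative, 500
  iterations): the slow tail of alternating least squares below that level
  can cost hundreds of iterations per candidate while IS ranks candidates on
  PEV differences orders of magnitude larger. Refit the chosen level at full
  tolerance when exact loadings matter.
- `lambda_for_cardinality` bisects the penalty until a fit attains a target
  nonzero count (used for oracle-sparsity LASSO runs); the count is not
  perfectly monotone in λ under non-convex alternating fits, so after
  `max_steps` the closest-count penalty is returned with a warning.
- The number of factors Q is treated as a user input. Horn's parallel
  analysis (column-permutation null, configurable quantile) is provided as a
  convenience but is not part of the selection loop.

An intrinsic property of the product form worth knowing: an extra nonzero
loading is selected only when its squared item–score correlation exceeds
roughly PEV_model/(Q·PS). Moderate secondary loadings (e.g. cross-loadings
of 0.5 on standardized items) fall below this bar for small Q and J, so IS
deliberately prefers the primary-only pattern there; this is the index
trading fit for parsimony, not an optimization failure (the selection traces
show the fitted PEV kink at the true cardinality).

## Stage 2

The structural model is single-equation OLS of an outcome on the factor
scores, optional pre-encoded numeric covariates, and optional
factor-by-covariate product terms, solved via QR with classical standard
errors and t-based p-values (degrees of freedom N − #terms). The design must
be full rank — a rank-deficient design raises an error naming the dependent
terms — and N must exceed the number of terms; Stage 2 is intentionally not
regularized. No Stage-1 uncertainty (model selection, loading estimation,
factor-score measurement error) is propagated into Stage-2 standard errors;
a parametric bootstrap around both stages would be the natural extension and
is out of scope here.

## Synthetic-data generator

The generator emulates a block-sparse population model. For a design cell
(N, Q, K, cross, reliability, r, VAFz):

- Loadings: item block k loads √0.6 on factor ⌈k/K⌉; when cross-loadings
  are on, the first item of each block additionally loads 0.5 on the next
  factor, cyclically, so every factor receives exactly one cross-loading
  (the placement is a package choice; `build_population` is written so a
  different placement map can be substituted). True nonzero count:
  J + Q·1{cross > 0}.
- Factor scores: multivariate normal, unit variances, common correlation r,
  sampled through the Cholesky factor for bitwise reproducibility.
- Item residual variances solve reliability = explained/(explained + σ²_j)
  with explained = p_jᵀΦp_j, so the per-item population reliability matches
  the design level exactly (asserted analytically over the whole grid in the
  tests).
- Outcome: z = 0.1·Σ_q η_q + e with Var(e) solving the target VAFz, using
  Var(0.1·1ᵀη) = 0.01·(Q + Q(Q−1)r).
- Both indicators and outcome are standardized with their *sample* moments
  before return — estimators consume standardized data, and finite-sample
  deviation of sample communalities from the population levels is intended
  sampling noise (Monte-Carlo tests confirm convergence at N = 10⁵). The
  outcome's removed scale is recorded so structural estimates can be mapped
  back to the raw-outcome units where the generating weight 0.1 lives.

Design grids: the low-dimensional regime crosses N ∈ {50, 100, 500},
Q ∈ {3, 5}, K ∈ {3, 5}, cross ∈ {0, 0.5}, reliability ∈ {0.3, 0.8},
r ∈ {0, 0.3}, VAFz ∈ {0.5, 0.9} — 192 cells, 9600 datasets at 50
replicates; the high-dimensional regime fixes N = 50, Q = 5 and crosses
K ∈ {15, 30, 100} with the remaining levels — 48 cells, 2400 datasets.
Per-dataset seeds derive deterministically from
(base seed, cell index, replicate) via a seed sequence, so any single
dataset can be regenerated in isolation.

What the generator does *not* emulate: non-normal or ordinal items,
missingness, heteroscedastic residuals, residual correlations, or
loading heterogeneity. Passing recovery tests on these data therefore
demonstrate algorithmic correctness under the stated population model, not
robustness to those real-data features.

## Evaluation

Estimated solutions are identified only up to column permutation and sign.
Alignment enumerates all Q! permutations (feasible for Q ≤ 8); for each
permutation the optimal sign per factor is read directly off the sign of
Tucker's congruence, which is equivalent to enumerating all 2^Q sign
patterns. The aggregate maximized is the *mean* per-factor congruence (the
aggregate is a package choice; sum and mean coincide, and min is not used).
Zero estimated columns contribute congruence 0; ties prefer the
lexicographically smallest permutation and positive signs. The zero/nonzero
recovery rate PL counts exactly stored zeros — no epsilon thresholding,
since both estimators produce exact zeros. Bias/RMSE of structural
coefficients, entrywise loading standard deviations across replicates
(ddof = 1, with a congruence check that inputs share an alignment), and the
number of multistarts agreeing with the best loss (relative tolerance 1e-6)
complete the metric set.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the study at desk scale, as the
package's own choice of demonstration size: the selection-accuracy
computation uses the 32 N=500 cells at VAFz = 0.9 with 5 replicates each and
2 fresh random starts per warm-started candidate (verified to reproduce the
same selections as 5 starts on probe cells); the structural-bias properties
use 50–100 replicates of single cells; randomized algorithmic guarantees use
1,000 small fixtures. The full 12,000-dataset factorial with 100-start fits
is reachable through the same `run_study` entry point.

## Known limitations

- The cardinality variant assumes orthogonal factors; with correlated
  factors it remains a good *pattern* finder but biases Stage-2 coefficients
  (the package's own simulations reproduce this directionally), so the
  recommended exploratory workflow is: find the sparsity pattern with the
  cardinality fit, then estimate scores and paths with the LASSO fit at the
  matched sparsity level.
- IS-based selection systematically prefers dropping moderate secondary
  loadings for small Q·J (see the selection section); with oracle knowledge
  of the nonzero count, both estimators recover such patterns.
- Alignment is exhaustive and limited to Q ≤ 8.
- No inference accounts for two-stage uncertainty.
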