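# Methods

## Model

Six-point Likert responses (categories 0–5) are decomposed by a fixed
decision tree into five binary pseudo-items per rating item: agreement
(Y1), nonmoderate vs. moderate choice given disagreement (Y2) or agreement
(Y3), and extreme vs. nonextreme choice given a nonmoderate response (Y4,
Y5). Categories 0/5 are extreme, 1/4 nonextreme, 2/3 moderate. Nodes not
on the branch of the observed category are *structurally missing* and
contribute factor 1 to the likelihood; this is kept distinct from
person-level missingness, which is treated as missing at random. The
branch table is data, not code: alternate trees (4/5/7-point scales) can
be registered, but only the six-category tree ships with validated tests.

Each pseudo-item follows a logistic law in the latent vector
x = (traits…, eta_nm, eta_e). The trait enters the within-(dis)agreement
nodes with loadings a_nm (nodes 2/3) and a_e (nodes 4/5) and a
branch-dependent sign — negative on the disagree side, positive on the
agree side — which is structural and never stored as a parameter. Two
variants are supported:

* **constant-loading (Rasch-style)**: a_nm, a_e shared across items, the
  agreement-node trait loading and both response-style loadings fixed at
  1, latent covariance Sigma fully free;
* **item-specific**: free loadings a_1i, a_nm,i, a_e,i per item, trait
  variances fixed at 1 (style variances free).

Response-style loadings stay fixed at 1 in both variants: response styles
are defined as content-independent, so free style loadings would
reintroduce item dependence without substantive meaning. The loadings
a_nm, a_e are expected positive but not constrained; a negative estimate
triggers a warning, not an error, since positivity is a modeling
assumption rather than an optimizer bound.

## Estimation

Marginal ML with the latent vector integrated on a tensor Gauss–Hermite
grid placed in standardized space: z carries the grid of a standard
normal and x = Lz with L the Cholesky factor of Sigma. Because the grid
lives in z-space, Sigma is an ordinary smooth parameter of the
quadrature-approximated likelihood; EM is then *exactly* monotone (the
M-step maximizes the expected complete-data log-likelihood over
intercepts, loadings, and L jointly with L-BFGS and analytic gradients).
The same fixed grid is shared between fitting, per-person
log-likelihoods, and score computation, so the per-person values sum
exactly to the fitted log-likelihood and the scores sum to (numerically)
zero at the optimum.

Defaults: 11 quadrature points per dimension for up to three latent
dimensions, 7 for four; convergence when the largest absolute change of
any structural parameter (including Sigma entries) falls below .001;
latent means fixed at 0. Non-convergence yields a flagged result plus a
warning. A pseudo-item observed with only one outcome is a hard error
naming the item and node, because its intercept would diverge.

A stochastic-approximation alternative (`method="sa"`) imputes the latent
vectors by Metropolis–Hastings and applies Robbins–Monro averaged
complete-data M-steps — an MHRM-style estimator retained for parity with
high-dimensional practice. It is not the test baseline: the deterministic
EM makes every downstream number reproducible bit-for-bit, and the
invariance machinery only requires *a* consistent ML estimate.

## Score-based tests

The tested parameter vector Psi comprises the item loadings and
intercepts; Sigma is estimated but not tested (heterogeneity questions in
this setting concern the structural item parameters). Per-person scores
are posterior-weighted complete-data gradients (Fisher's identity),
N × p at the MLE.

Conventions pinned by this implementation, where the literature leaves a
choice open:

* **OPG covariance**: uncentered cross-product (1/N) Σ s_v s_v'. At the
  MLE the mean score vanishes, so centering is asymptotically irrelevant;
  the uncentered form matches the cross-product-of-gradients definition.
* **Subset decorrelation**: tests of a parameter subset decorrelate with
  the subset block of the OPG matrix (select-then-decorrelate). The
  alternative — decorrelate the full process, then select columns — is
  available as `decorrelate="full"` but non-default.
* **Bridge endpoint**: the subset scores are mean-centered before
  cumulation. At an exact MLE this is a no-op; at the default convergence
  threshold of .001 it removes the residual drift, so B_N = 0 holds to
  machine precision and the bridge functionals are well defined.
* **Ties**: persons with equal covariate values form one block, and all
  statistics are evaluated at block boundaries only, making the arbitrary
  within-block order irrelevant.
* **Inverse square root**: symmetric eigendecomposition with an
  eigenvalue floor of 1e-10 times the largest eigenvalue; a sub-floor
  eigenvalue raises a rank-deficiency error (advising a smaller subset)
  instead of silent regularization.

Statistics: DM, CvM, and maxLM for metric covariates; WDMo and maxLMo
evaluated at the m−1 category boundaries for ordinal covariates; LMuo for
unordered categories. CvM is implemented in its standard form
N⁻¹ Σ_v Σ_j B_vj² and maxLM as the trimmed maximum of the weighted sum of
squares (trim t ∈ [0.1, 0.9], the field-standard choice). LMuo scales
each category increment by the inverse category proportion, which yields
the chi-square((m−1)k) null its analytic p-value assumes; the unscaled
sum is available for sensitivity checks. CvM and maxLM grow unwieldy for
large parameter vectors and are excluded from the replication harness;
they remain available for small subsets.

p-values: DM analytically via the Kolmogorov distribution of the
Brownian-bridge supremum, raised to the k-th power for k independent
decorrelated components; WDMo via the joint normal law of the weighted
bridge at the boundaries (correlation sqrt(t_l(1−t_l')/(t_l'(1−t_l)));
LMuo via the chi-square survival function; maxLM, CvM, and maxLMo by
Monte-Carlo over simulated bridge paths (default 10,000 paths on a
1,000-point grid, seed recorded in the result). The analytic p-values are
asymptotic; on a finite grid of N evaluation points the simulated supremum
sits slightly below its continuous limit, which makes the analytic DM
p-value mildly conservative in small samples.

Tests for a_nm and a_e are run separately with no multiplicity
correction, mirroring how the two response processes are interrogated in
practice; a Bonferroni flag exists but is off by default.

## Partitioning

After a significant test, candidate cuts are the boundaries between
distinct covariate values leaving at least `min_size` (default 300)
persons per side; each candidate is evaluated by two independent full
refits — all item parameters and, by default, Sigma free per side — and
the cut maximizing the summed log-likelihood is selected. Recursion
retests, by default, only the subsets that triggered the parent split.
For unordered covariates with up to six categories all binary partitions
are searched exhaustively; beyond that a greedy frequency-ordered chain
is used (an extension beyond the validated design).

Two accelerations are available for the profile search and used by the
scaled experiments: `profile="fixed_sigma"` holds Sigma at the pooled
estimate in the side fits (the side fits also warm-start from the pooled
item parameters), and `max_candidates` thins the candidate set to
quantile-spaced cuts. On fixtures the fixed-Sigma profile selects the
same cut as the exact profile while cutting the search cost severalfold;
both options are off by default so the direct call reproduces the exact
algorithm.

## Synthetic-data generator

The generator emulates the validation design: two traits (each loading on
half the items) and two response styles drawn from N(0, Sigma) with the
fixed covariance printed in the README (trait and style correlations .5,
style variances 1.0 and 2.25); intercepts uniform per node family
(U(−1,1) agreement, U(−1,.5) nonmoderate, U(−2.5,−1.5) extremity — so
extreme categories are rare, which is why tests of a_e carry less
information than tests of a_nm); covariates categorical (balanced),
metric (U(20,80), focal group ≤ 40, i.e. one third of the sample), or
ordinal (five categories, uniform or skewed .1/.1/.35/.35/.1, focal group
≤ 3). Heterogeneity is an additive shift of ±.2 or ±.5 applied, by
default, to both a_nm and a_e in the focal group (single-parameter shifts
are configurable, since the tests are run per parameter). Item parameters
derive from a length-keyed seed and therefore stay fixed across all cells
with the same test length; replicate streams are spawned hierarchically
(cell seed → replicate → persons/covariate/responses) so any single
replicate can be regenerated in isolation.

What the generator does *not* emulate: real response data feature item
content effects, local dependence, non-normal latent distributions, and
nonuniform missingness. Passing tests therefore demonstrate the
correctness and calibration of the machinery under the model, not
robustness to model violations.

## Problem sizes of the scaled experiments

The routine suite and the acceptance script use scaled-down experiment
cells chosen as the package's own defaults for iteration speed: 6 rating
items; N = 500 (null cells), N = 1000–2000 (power and cutpoint cells);
100–150 replications for rejection rates, 10–16 for cutpoint cells;
5 quadrature points per dimension for the 4-dimensional simulation fits
(doubling the grid moves the fitted log-likelihood by well under 1e-3 per
person, and parameter recovery is unbiased to Monte-Carlo resolution);
cutpoint searches with the fixed-Sigma profile and 10 quantile-spaced
candidates. Monte-Carlo claims are asserted with 95% binomial or normal
bands at the stated replication counts.

## Known limitations

* Analytic p-values are asymptotic in N; for small samples the DM test is
  mildly conservative and LMuo relies on the chi-square approximation of
  group-mean contrasts.
* The quadrature model at coarse grids is a slightly different (but
  internally consistent) likelihood than the exact integral; all scores
  and information estimates are computed under the same grid, so test
  calibration is unaffected, but point estimates can shift at the third
  decimal between grids.
* Multi-covariate split selection with covariate-wise corrections is out
  of scope: each call partitions along a single covariate, and looping
  over covariates with a multiplicity correction is left to the user.
* Person-level scoring (EAP/MAP estimates of individual latent values) is
  not provided; only structural-parameter inference is in scope.
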