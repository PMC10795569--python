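# Methods

## The scientific question

Extreme response style (ERS) — the tendency to pick the endpoints of a
Likert scale regardless of item content — distorts group comparisons on the
substantive trait a questionnaire is meant to measure.  Two widely used IRT
corrections conceptualize ERS differently, and `ersirt` implements both,
plus the no-correction control, to quantify how much the *choice of
correction model* changes conclusions about a focal group's latent mean and
variance when the two groups differ in average ERS.

## Models

All models address four-category items answered by persons with a bivariate
latent trait `theta = (theta1, theta2)`: `theta1` substantive, `theta2` ERS.

**MNRM.** Category probabilities are a softmax over linear predictors

    P(Y_i = k | theta)  ∝  exp( sum_v a_iv * s_kv * theta_v + c_ik ),

with a fixed integer scoring matrix `s`: column 1 is the ordinal scoring
(0, 1, 2, 3) and column 2 flags the extreme categories (1, 0, 0, 1).
Intercepts convert to thresholds by `tau_g = (c_g - c_{g+1}) / a_1`; the
first intercept is fixed at 0 (probabilities are invariant to intercept
location, and this convention makes the conversion round-trip exact).
Removing the ERS column yields the GPCM, the "ignore response style"
control.

**IRTree.** The observed category is decomposed into three binary
pseudo-items: node 1 = agreement (category 3/4 vs. 1/2), node 2 = extremity
of disagreement, node 3 = extremity of agreement; the node not on the taken
branch is structurally missing and is marginalized, never imputed.  Each
node is a 2-PL with linear predictor `sum_v alpha_imv * theta_v + d_im`,
under the identifying constraints: no ERS slope on node 1
(`alpha_i12 = 0`), a substantive slope shared by nodes 2 and 3
(`alpha_i21 = alpha_i31`), and mirrored ERS slopes
(`alpha_i22 = -alpha_i32`).  A `TreeItem` therefore stores five free
parameters plus the structural zero.

The families differ observably: under the tree, the agreement probability
P(Y in {3,4}) never depends on ERS; under the MNRM, the *conditional*
extreme-agreement probability P(4 | Y in {1,4}) never depends on ERS
(the shared ERS score of categories 1 and 4 cancels from the odds).  Each
model lacks the other's invariance, and `study.curves_report` renders both
numerically.  These two invariances are also the package's sharpest unit
tests, asserted to 1e-10 over an ERS grid.

## Synthetic data: the study conditions

The generator emulates a two-group (e.g. cross-cultural) comparison:

* reference group: `theta ~ N(0, I)`; focal group: `theta1 ~ N(0,1)`,
  `theta2 ~ N(delta, 1)`, independent, with `delta` in {-1, 0, +1};
* 10 or 20 items, all slopes 1.5 on both dimensions;
* base thresholds `[-1, 0, 1]` (symmetric) or `[0, 1, 2]` (asymmetric,
  i.e. a left-skewed test), shifted per item by constants equally spaced in
  `[-0.5, 0.5]`;
* generating family MNRM, IRTree, or GPCM (control: every person's ERS
  contribution nulled).

`n_per_group` defaults to 1000: bias is an expectation and is stable in `n`;
the sample size only sets the Monte-Carlo error of a replication.

**Tree-generating truth.** Tree item parameters are not free inputs.  They
are calibrated by simulating a large MNRM sample with *both* groups at the
reference distribution (item parameters are population quantities and must
not depend on any focal ERS shift — one calibration per (n_items,
thresholds) pair serves all shift conditions) and fitting the constrained
tree by marginal ML with the latent distribution pinned at the exact
generating N(0, I).  The fit is warm-started from a per-item least-squares
match of the tree's category-probability curves to the MNRM's on a 5x5
trait grid, then run to convergence.  The default calibration size is
500,000 per group; the shipped tests and the acceptance script use
20,000-50,000 per group, which reproduces the derived parameters to about
two decimals — far below the size of the downstream bias effects.

What the generator does **not** emulate: correlated traits at generation,
non-normal trait distributions, slope heterogeneity across items, group
differences in the substantive mean, response styles other than ERS, and
K != 4 trees.  Passing tests therefore demonstrate correctness of the
models and estimators under these idealized conditions, not robustness of
the corrections on arbitrary real data.

## Estimation

All three families are fit by multigroup marginal maximum likelihood.  The
reference group's latent means are fixed at 0 and its covariance at the
identity; the focal group's mean vector and covariance are free, and item
parameters are constrained equal across groups.  The focal covariance is
parameterized by its Cholesky factor with a positive-bounded diagonal, so
every proposal is positive-definite by construction.

**Quadrature.** The latent traits are integrated out on an equally spaced
grid of 31 points per dimension over [-5.25, 5.25] in standard-normal
units, with normalized normal weights, mapped through each group's current
mean and covariance (`theta = mu_g + L_g z`); 61 points are used for the
1-D GPCM.  An equally spaced rule is deliberately preferred to
Gauss-Hermite: with 10-20 informative items, per-person posteriors have SD
near 0.3, narrower than the central spacing of a tensor Gauss-Hermite rule
of any affordable order.  In a convergence study of the true-parameter
log-likelihood (10 items, n = 2000) the equally spaced rule converged to
within 0.05 log-likelihood units by spacing 0.35, while 41-point
Gauss-Hermite was still off by more than one unit — enough to bias the
focal variance estimate by ~0.1.  Node counts are configurable everywhere
(`quad_points`).

**Optimization.** A single L-BFGS-B run over all free parameters with
analytic gradients assembled from posterior-expected category counts at the
quadrature nodes (gradients verified against central finite differences to
1e-9 relative error).  Substantive and node-1 slopes are bounded to
[0.05, 10]; ERS-dimension slopes are sign-free in [-10, 10], and the
reflection indeterminacy of the ERS axis is resolved after convergence by
flipping the axis so the mean ERS slope is positive (the focal ERS mean and
trait covariance flip with it; the likelihood is exactly invariant).
Stopping: relative objective change below 3e-9 or projected gradient below
1e-6 per person (a 30-pair L-BFGS memory handles the flat ERS-slope ridge
that arises when the data carry no response style; focal estimates were
verified to change by < 0.003 against a 1e-10 tolerance), with an
evaluation budget of 600; hitting the budget marks the fit non-converged
(flagged, never an exception).  Non-convergent
replications are excluded from bias means and counted in every table.
Starting values are unit slopes, intercepts from pooled observed category
logits, and the focal group at the reference values.

Items with an unobserved category are dropped with a warning before
fitting (their boundary intercepts are not estimable).  Missing responses
are marginalized via a unit likelihood factor.  Log-space throughout;
the likelihood never returns NaN on valid input.

**Model comparison.** `fit_indices` implements AIC, BIC, sample-size
adjusted BIC (`p * ln((N+2)/24)`) and Hannan-Quinn; `select_model` ranks
fits of the same data per index and compares raw log-likelihoods only
between equal-parameter-count fits.  Parameter counts: GPCM `4J + 2`,
MNRM `5J + 5`, IRTree `6J + 5` (J items; focal mean and covariance
included).

**Person scoring.** `eap_scores` returns posterior means and SDs of the
traits per person under the fitted model, each person's prior being their
group's fitted latent distribution, on the same adapted grid.

## The bias study

`study.run_condition` draws fresh persons and responses per replication
from dedicated RNG substreams of a root seed (so generated data do not
depend on the estimator list, and a rerun is bit-identical) and fits every
requested estimator to the identical dataset.  Outcomes per cell: mean over
converged replications of the focal substantive-mean estimate (true 0) and
of the variance estimate minus 1 (true 1), each with its Monte-Carlo SE.
Cells whose bias exceeds both 0.05 and three Monte-Carlo SEs are flagged
(the rendering equivalent of bold entries); the 0.05/3-SE rule is this
package's choice, since "substantial" is not otherwise defined.

Presets: `smoke` (5 reps, n=200, control+MNRM generators only), `desk`
(100 reps, n=1000), `full` (500 reps, n=1000 — the reference replication
count; bias is stable in n, which only sets per-replication noise).
`run_study` checkpoints per-cell results to CSV and resumes from them, and
writes a manifest (config, root seed, per-cell spawn keys, convergence
counts, package versions) sufficient to re-create every table.

Expected qualitative pattern, reproduced by the acceptance tests: variance
bias appears whenever the groups differ in mean ERS and the fitted family
is not the generating one; mean bias additionally requires asymmetric
thresholds.  Fitting the tree to MNRM data *undercorrects* (bias shrinks,
same sign as no correction); fitting the MNRM to tree data *overcorrects*
(bias shrinks and flips sign).  Flipping the ERS shift flips all signs.

## Problem sizes in the shipped checks

The packaged tests and `scripts/acceptance.py` run the study at reduced
scale — 5-8 replications per cell in the tests, 30 in the acceptance
script, versus 500 in the full design — with tolerances that carry an
explicit `3 * mc_se` Monte-Carlo allowance (a printed bias is itself a
simulation estimate).  These sizes are the package's chosen working scale;
`--preset full` reproduces the complete design.

## Known limitations

* Standard errors of the group parameters (observed-information) are not
  implemented; confidence statements about a single fit need them.
* Only the three-node tree for K = 4 is supported; `ScoringMatrix` and
  `MnrmItem` handle general K, `TreeItem` does not.
* The reference group's trait covariance is fixed to the identity rather
  than freely estimated; with data generated under independence this is
  exact, but it is one parameter fewer than some software defaults.
* Local optima are handled only by bounded parameters and neutral starts;
  pathological data could in principle converge to a reflected or boundary
  solution, which the convergence flag and slope signs would reveal.
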