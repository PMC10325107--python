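# Methods

This note documents the statistical models implemented in `birdcrop`,
the defaults and numerical choices, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Effect sizes

Each experimental comparison supplies group means, standard deviations
and sample sizes. Cohen's d standardizes the mean difference by the
pooled within-group SD (``(n-1)``-weighted sums of squares over
``n_t + n_c - 2``); its sampling variance is
``(n_c + n_t)/(n_c n_t) + d²/(2(n_c + n_t))``. Hedges' correction
``J = 1 - 3/(4 df - 1)`` with ``df = n_t + n_c - 2`` removes the
small-sample upward bias; ``g = J d``, ``v_g = J² v_d``. Records with a
zero SD are rejected rather than imputed — with a zero pooled SD the
variance is undefined even when the means are equal, so no effect (not
even 0) is emitted; the reader reports such rows for manual repair.
Convertible statistics are supported for studies that do not report raw
summaries: a two-sample t statistic (``d = t √(1/n_t + 1/n_c)``) or
means with standard errors (``SD = SE √n``).

Outcomes arrive on two scales: production gains (5 kg vs 10 kg) and crop
losses (50% loss vs 30% loss). Loss-scale effects are multiplied by −1
after computation, so a positive g uniformly means a favourable outcome
(birds increase production; a mitigation measure reduces loss). The flip
is an involution and leaves v_g untouched.

## Multilevel random-effects model

For effects g_i with known sampling variances v_i nested in studies,

    g_i = x_i'β + u_{study(i)} + w_i + e_i,
    u ~ N(0, τ²_study), w ~ N(0, τ²_within), e_i ~ N(0, v_i).

The marginal covariance is block diagonal over studies:
``diag(v_i + τ²_within) + τ²_study·11'`` per block, so solves and
determinants use a Sherman–Morrison rank-one update per study (O(k) per
criterion evaluation). Variance components are estimated by REML —
L-BFGS-B over (τ²_study, τ²_within) with non-negativity bounds, several
starting points, and a 1e-8 criterion tolerance; the criterion includes
the ``+½ log|X'X|`` constant so log-likelihoods are directly comparable
with the usual REML likelihood. Coefficients are GLS at the optimum,
i.e. each effect is weighted by the inverse of its sampling-plus-
between-study variance; intervals are normal Wald (z), not
Knapp–Hartung, matching the defaults of the standard meta-analytic
toolchain. When every study has a single comparison the within-study
component is unidentified and dropped automatically; a "none" structure
(single-level random-effects model ignoring study grouping) is available
and is what the publication-bias procedures use.

QE (residual heterogeneity) uses fixed-effects weights 1/v_i at the
fixed-effect projection, df = k − p, chi-square upper tail. QM is the
Wald chi-square on all non-intercept coefficients of the multilevel fit.
Subgroup estimates come from a single indicator-coded fit without
intercept, one pooled estimate per level; levels are ordered
lexicographically unless a caller-supplied order is given, and empty
requested levels are omitted with a warning. Missing moderator values
trigger listwise deletion for that model with a logged count.

The implementation is cross-checked in the test suite against
`metafor::rma.mv` (coefficients, standard errors, variance components
and REML log-likelihood agree to ≤1e-5) and against a brute-force dense
grid search over (τ²_study, τ²_within).

## Publication bias

* **Fail-safe N** (Rosenthal): ``N = max(0, ⌊(ΣZ_i)²/z²_α − k⌋)`` with
  Z_i = g_i/se_i and one-sided α = 0.05; "robust" when N > 5k + 10.
* **Rank correlation** (Begg/Kendall): tau-b between the variance-
  standardized, fixed-effect-centred effects and their sampling
  variances. Variance ranks stand in for sample size — monotone in n and
  always available; ranking by n itself is exposed as an option. The
  p-value is exact for k ≤ 10 (inversion-count distribution when there
  are no ties, full vectorized permutation enumeration for tied inputs
  up to k = 8) and otherwise uses the tie-corrected normal
  approximation.
* **Egger-type regression**: a single-level random-effects
  meta-regression of g on its standard error; the reported p tests the
  se coefficient. Per the standard toolchain's convention, this and
  trim-and-fill collapse the multilevel structure.
* **Trim-and-fill** (Duval–Tweedie, L0): iteratively estimate the number
  k0 of suppressed studies from the signed ranks of absolute deviations
  about the trimmed-set centre, trim the k0 most extreme effects from
  the surviving side, re-centre, repeat to convergence (≤50 iterations);
  then impute mirror images of the k0 extremes and refit. ``side`` is
  the side presumed missing; ``auto`` picks it by the sign of the rank
  correlation (falling back to funnel skewness when all variances are
  equal). Absolute deviations are quantized at 1e-8 relative tolerance
  before ranking so exactly mirrored pairs tie despite roundoff.

A caveat documented by simulation in the test suite: on noisy symmetric
funnels with a handful of suppressed studies, the iterative L0 estimator
recovers fewer than the true k0 on average (it matches `metafor`'s
`trimfill` decision-for-decision, which behaves identically). The
recovery acceptance check therefore uses an idealized funnel — mirrored
pairs at ±1.96 se with geometrically spaced se — on which the estimator
lands within ±1 of the truth in every replicate while still returning
k0 = 0 on the symmetric input.

## Conditional inference tree

The response is the direction of each effect (g > 0; an exact zero
counts as non-positive). At each node every covariate is tested for
independence from the response: 2×2 tables use the exact conditional
(Fisher) distribution; larger categorical tables use a Monte-Carlo
permutation distribution of the Pearson chi-square statistic (9,999
permutations, add-one p estimate); numeric covariates use a maximally
selected standardized two-sample statistic over cutpoints, with the same
permutation scheme applied to the maximum. P-values are Bonferroni-
adjusted across covariates; the smallest-p covariate splits the node iff
its adjusted p < α (default 0.05). Splits are binary: exhaustive search
over two-set level partitions (categorical) or cutpoints (numeric)
maximizing the collapsed 2×2 chi-square, subject to a minimum child size
of 7 and a minimum node size of 20 to attempt a split. Covariates may
recur deeper in the tree. The Monte-Carlo seed is a parameter (default
20230706) so trees are reproducible.

## Survey models

Each survey is one observation: n respondents, a proportion giving the
focal answer, and survey-level covariates (income class, bird group,
stakeholder, climate). Proportions are converted to success counts by
rounding proportion × n (a discrepancy above 0.25 respondents triggers a
validation warning — it means the proportion cannot correspond to an
integer count at the reported precision). The model is a logit binomial
GLMM with a Gaussian survey-level random intercept, which absorbs
extra-binomial between-survey heterogeneity. With one observation per
cluster the marginal likelihood is a one-dimensional integral per
survey; it is evaluated by a Laplace approximation at the conditional
mode (inner Newton iterations to 1e-10) and maximized by L-BFGS-B over
(β, log σ). Standard errors come from the numeric Hessian. The
implementation matches `lme4::glmer` on the same data to ~0.02 on
coefficients and the random-intercept SD.

Model selection is all-subsets over the candidate terms (the four
survey-level variables as main effects, no interactions; exhaustive
enumeration capped at 12 terms). AICc uses n = number of surveys and
p = fixed coefficients + 1 variance parameter. Models with ΔAICc < 2 are
averaged with renormalized Akaike weights; the default is full (zero-
substituted) averaging, with conditional averaging as an option.
Averaged standard errors use the Burnham–Anderson unconditional form
``Σ w_m √(se²_m + (β_m − β̄)²)`` and the reported p-values are normal
approximations flagged as approximate. Negative-attitude outcomes are
out of scope (they mirror the positive-attitude models); the supported
outcomes are positive attitude and perceived service/disservice.

The decade-count trend test is a two-sided Spearman correlation of
counts against period index, exact by permutation enumeration for ≤ 9
periods and t-approximate beyond.

## Prioritization grids

Grids are 2-D non-negative arrays with a nodata mask and cell-centre
registration (row 0 = north); co-analysed layers must agree exactly in
shape, origin and cell size — nothing is resampled silently. The benefit
index is the cellwise woody share of total crop production; cells with
zero total production become *missing*, not zero, so oceans and no-crop
land cannot compress the terciles. The conservation index is the product
of min-max standardized threatened-species richness and total richness
(a constant layer standardizes to all zeros with a warning, keeping
products defined). Tercile cuts are the 1/3 and 2/3 linear-interpolation
quantiles of non-missing cells; boundary ties go to the lower class.
The bivariate code is 3·(conservation tercile − 1) + benefit tercile;
class 9 is the priority mask. Because classification is rank-based, the
mask is invariant under strictly monotone transformations of either
input. I/O uses the ESRI ASCII grid format.

## Synthetic-data generators

`simulate_effects` draws a true standardized effect per comparison
(grand mean + study effect + within-study effect + categorical moderator
shifts), then draws group sizes (uniform on a configured range,
defaults 4–30 per arm, matching heterogeneous field-trial replication),
log-normal group SDs (scale 0.3 around 1, varying v_g realistically),
and emits *raw* sample means and SDs (normal means, chi-square-scaled
SDs) whose population standardized difference equals the true effect —
so the effect-size stage is exercised end to end, including loss-scale
polarity. Default corpus shape: 40 studies × 1–6 comparisons, mirroring
a ~160-comparison exclosure corpus. The optional censoring rule
suppresses a comparison with probability
``strength · Φ(z_0.05 − z) · (1 − e^{−se/0.25})`` — one-sided-significant
results are always published, imprecise null results mostly are not —
which produces funnel asymmetry detectable by the bias suite.

`simulate_surveys` draws covariates uniformly, adds a Gaussian random
intercept and configured logit-scale coefficients, and draws binomial
successes. `simulate_grids` builds log-normal (hence positive,
spatially autocorrelated) smoothed fields, derives woody production as
total × a logistic share field so woody ≤ total holds everywhere, and
can plant a jointly-high "hot corner" whose recovery by the priority
mask is a construction oracle. All generators are pure functions of
(config, seed).

What the generators do *not* emulate: real-world covariate correlation
structure (moderators are drawn independently), non-normal outcome
distributions, informative missingness beyond the funnel-censoring rule,
actual geographic layouts, or reporting heterogeneity across studies.
Passing tests therefore demonstrate correctness of the estimators under
the stated models, not robustness to every feature of field data.

## Problem sizes and defaults

Simulation-based checks use 500 replicates at k = 100 for bias/coverage
of the pooled estimate, 500 null replicates for the Egger type-I error,
200 replicates for trim-and-fill recovery and GLMM recovery, and 100
replicates for the tree's null-refusal rate; the acceptance script runs
reduced replicate counts (100–200) chosen to keep a full from-scratch
run under a minute while leaving Monte-Carlo error well inside the
asserted bands.

## Limitations

* No robust (sandwich) variance estimation, permutation CIs, or
  correlated-effects multivariate meta-analysis.
* The Egger test and trim-and-fill ignore the multilevel structure by
  design (matching the standard toolchain's convention); with many
  comparisons per study their p-values are anti-conservative.
* The tree does not handle missing covariate values or surrogate
  splits; rows must be complete for the covariates used.
* Bivariate terciles are computed over each layer's own non-missing
  cells; when the two layers have different masks their terciles are
  based on slightly different supports.
* The reproduction harness (`birdcrop reproduce`, and the corresponding
  acceptance test) needs the original supplementary datasets, which are
  not redistributable with the package.
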