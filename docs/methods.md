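# Methods

## Model

Cox proportional hazards: h_i(t) = h0(t) exp(x_i' beta), with inference by
the partial log-likelihood

    l(beta) = sum_i delta_i [ x_i' beta − log sum_{j in R_i} exp(x_j' beta) ],

where R_i = {j : t_j >= t_i} is the risk set at the i-th follow-up time and
delta_i indicates an observed death. Tied event times use the Breslow
convention (tied events share one risk set), matching the reference
penalized-regression ecosystem. The fitted objective is

    f(beta) = −l(beta)/n + lambda [ alpha ||q∘beta||_1 + (1−alpha) ||q∘beta||_2² ],

i.e. the penalty factors sit **inside** the norms (the ridge term carries
q²) and the ridge part carries no 1/2 — the formula is implemented exactly
as published for the correlation-weighted penalty, which differs from the
glmnet convention (factors linear, ridge halved). With q ≡ 1 this is the
plain elastic net. The mean (1/n) likelihood scaling makes lambda
comparable across cohort sizes.

### Correlation-dissimilarity weights

Per gene j, sigma_j^T and sigma_j^N are the j-th columns of the Pearson
correlation matrices of the tumor and normal groups. The dissimilarity is
the angle d_j = arccos(cos_sim(sigma_j^T, sigma_j^N)) in [0, pi];
normalization w_j = d_j / max_k d_k puts max(w) = 1 exactly; penalty
factors are q_j = 1 / max(w_j, eps).

Numerical/interface choices:

* the cosine argument is clamped to [−1, 1] before arccos;
* the self-correlation entry (always 1) is **included** in each profile by
  default — the literal "column of the correlation matrix" — which also
  bounds both norms below by 1; `include_diagonal=False` excludes it;
* floor eps = 1e-3 on w before inversion: the inverse is undefined at
  w = 0 (a gene with identical correlation structure in both tissues) and
  downstream solvers need finite factors, so q is capped at 1000;
* before entering the solver, q is rescaled to sum to the feature count
  (`rescale_q=True`), mirroring the reference ecosystem's penalty-factor
  convention so lambda scales match between weighted and unweighted fits;
  `penalty_value` itself never rescales.

### Solver

Proximal Newton with a diagonal approximation of the partial-likelihood
Hessian in the linear predictor: each outer iteration builds working
weights/responses, and a cyclic coordinate descent with soft thresholding
solves the penalized weighted least-squares subproblem over an active set
(vectorized KKT screening pulls in violators; the sequential inner loop is
numba-compiled). Details:

* per-coordinate update: beta_j <- S(u_j, lambda alpha q_j) /
  (sum_i w_i x_ij²/n + 2 lambda (1−alpha) q_j²);
* features standardized internally by default (population sd), coefficients
  returned on the original scale; note the standardized and raw penalized
  problems have different optima — oracle comparisons in the tests use
  `standardize=False`;
* convergence: max |coefficient change| < 1e-7 across an outer iteration
  (inner tolerance 10x tighter), at most 100 outer iterations; a
  non-converged fit is returned with `converged=False`;
* a step-halving safeguard keeps the penalized objective non-increasing
  (the quadratic model can overshoot);
* a KKT certificate (max stationarity violation of the true gradient) is
  reported on every fit;
* lambda path: log-spaced from lambda_max = max_j |grad_j(0)|/(alpha q_j)
  (the smallest lambda with an all-zero solution) down to a fixed ratio;
  for alpha = 0 lambda_max is undefined and 100x the near-lasso
  (alpha = 1e-3) scale is used.

### Cross-validation

k-fold (default 10), folds stratified on event status by a seeded shuffle
(one reshuffle is attempted if a training fold has no events). The
criterion is the Verweij–Van Houwelingen partial-likelihood deviance,
−2 [l_full(beta_−k) − l_train(beta_−k)], which avoids forming risk sets in
small test folds. Selection rule "min" by default ("1se" by flag; under
pure noise the min rule occasionally follows small deviance dips and keeps
a few noise genes — the 1-SE rule stays at the empty model).

## Evaluation protocol

Per run: censoring-stratified 70% subsample -> CV for lambda -> refit on
the **whole** cohort at that lambda -> median split of the fitted relative
risks exp(x_i' beta) (ties to the low-risk group; all-equal risks are a
flagged degenerate run) -> two-group log-rank p. This is deliberately the
published scheme, kept for fidelity: because the split is fitted and
evaluated on the same data, the p-values are optimistically biased (on
pure-noise data the mean non-degenerate p is ~0.007, not 0.5), and every
summary carries that caveat. Selection frequencies over runs are unbiased
by this choice. Stability threshold "at least 50%" is inclusive; degenerate
runs are excluded from mean-p/mean-size summaries but counted; exact-zero
(underflowed) p-values are flagged rather than printed as 0.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines
behind this module's interface and verified against hand product-limit and
hypergeometric arithmetic in the tests.

## Differential expression

logFC is the difference of group means on the log2(x+1) scale, with an
explicit reference group (`group1="tumor"` or `"early"`), so "up" always
means upregulated in tumor / early stage and swapping roles negates every
value. The per-gene test is Welch's t by default; count-model tests
(quasi-likelihood F-tests on raw counts) belong to a different model family
and are out of scope — the pluggable interface accepts any per-gene test.
Zero-variance-in-both-groups genes get p = 1 (equal means) or p = 0
(unequal), logged. BH adjustment is statsmodels' step-up implementation
behind `benjamini_hochberg`, verified against exhaustive enumeration.

## Pre-ranked GSEA

The enrichment score is the signed extremum of the weighted
Kolmogorov–Smirnov running sum over a ranked list (hit increment
|score|^w / total over hits with w = 1 by default, w = 0 giving the classic
KS statistic; miss decrement 1/(N − |S|)). Only gene-label permutation
nulls are available — the module never sees sample-level data, matching
pre-ranked usage on logFC or beta rankings. Significance follows the
standard GSEA convention: the observed ES is compared with same-sign null
scores and normalized by the same-sign count with a plus-one correction,
p = (1 + #{|ES_null| >= |ES|, same sign}) / (1 + #same-sign), which keeps p
uniform under the null (dividing by the total permutation count instead
would be anti-conservative by ~1/P(sign)). NES = ES / mean(|ES_null| of the
same sign). An all-zero hit-weight set falls back to unweighted increments.

## Synthetic cohorts

The generator draws log2-scale expression from a Gaussian block-factor
model: genes in a block share one latent factor, giving exact population
correlation rho within blocks; differential-correlation genes are assigned
to a *different* block in the tumor group (equal marginal variances, purely
correlational effect); DE genes get a mean shift in tumor; values are
clipped at zero to stay on a log2(x+1)-like scale. Survival for tumor
samples is exponential with rate baseline_rate * exp(x' beta_true) (inverse
transform; expression gene-centered so the baseline rate is the
typical-patient rate), under independent exponential censoring whose rate
solves mean_i c/(c + r_i) = target via Brent's method. Stage labels I–IV
are quartiles of the true linear predictor — a convenience making
early-vs-advanced DE non-null, not a biological claim.

Defaults (the stated testing world, chosen once): p = 200 genes,
300 tumor + 300 normal samples, four 25-gene blocks at rho = 0.6, ten
differential-correlation genes, six DE genes (|shift| 1.5–2 log2 units), a
5-gene survival signal with |beta| 0.6–0.8 on unit-variance covariates,
baseline rate 1/1500 per day (median survival ≈ 3 years, plausible for a
kidney-cancer cohort) and censoring target 0.67. What the generator does
**not** emulate: count-level noise (negative-binomial overdispersion,
library-size effects), mean–variance coupling, isoform structure and
clinical covariates — so a green recovery test establishes that the
pipeline identifies correlation-structured prognostic signal under
Gaussian noise at realistic censoring, not that it tolerates RNA-seq
count artifacts.

## Runtime scaling

The repeated-protocol defaults descend the CV lambda path only to 5% of
lambda_max over 40 points with a 1e-4 CV fit tolerance (the final
full-data fit stays at 1e-7): lambda selection needs the deviance curve
around its minimum, and skipping the near-unpenalized dense tail cuts the
cost ~20x with identical selections on the stated world. General-purpose
`cv_lambda` defaults remain deeper (ratio 0.01, 50 points).

## Known limitations

* Breslow ties only (no Efron); no time-varying covariates, stratified
  baselines, left truncation or clinical-covariate adjustment.
* The protocol's log-rank p-values are in-sample optimistic by design (see
  above); treat them as a relative ranking of configurations, not as
  calibrated significance.
* The min-rule CV can retain a few noise genes in weak-signal settings;
  use the 1-SE rule for conservative selection.
* GSEA supports gene-label permutation only; phenotype permutation would
  require sample-level expression.
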