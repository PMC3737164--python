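# Methods

## Model

`animalgmrf` fits Bayesian *animal models*: generalized linear mixed models
in which an observed trait is decomposed into fixed effects and an additive
genetic effect (breeding value) whose covariance across individuals is
dictated by the pedigree. For record *r* of individual *i*,

    eta_r = beta_0 + z_r' beta + u_i (+ ind_i),

with

* `beta ~ N(0, sigma_beta^2 I)` — intercept, factor levels (sex, cohort,
  locality, ...) and linear covariates, with a large fixed prior variance
  (default `sigma_beta^2 = 2.2e4`);
* `u | A, sigma_u^2 ~ N(0, sigma_u^2 A)` — breeding values, where `A` is the
  additive relationship matrix; its inverse is sparse and is assembled
  directly from the pedigree by the Henderson/Quaas rules with inbreeding
  (`F`) accounted for through the Mendelian-sampling fractions `d_i`;
* `ind_i ~ N(0, sigma_ind^2)` — optional i.i.d. individual effects for
  repeated Gaussian measurements;
* an observation model: Gaussian (identity link, residual variance
  `sigma_e^2`), binomial (logit link), Poisson (log link, known exposure
  `E_i`), or zero-inflated Poisson
  `P(y) = p 1[y=0] + (1-p) Poisson(y; E_i e^eta)`.

For non-Gaussian families the unstructured residual is confounded with the
link and is omitted from the linear predictor; the package rejects model
specifications that request it.

The latent field `x = (beta, u, ind)` is a Gaussian Markov random field with
block-diagonal prior precision `Q(theta)`; variance components carry
inverse-gamma priors (default `InvGamma(0.5, 0.5)` for `sigma_u^2` and
`sigma_e^2`, `InvGamma(1, 0.001)` for `sigma_ind^2`) and the ZIP mixing
probability a `N(0, 1)` prior on the logit scale (the source analyses do not
pin this choice; it is configurable). Identifiability of factor levels and
of the breeding values against the intercept is restored by exact
sum-to-zero constraints `Bx = 0`.

## Inference

Inference is deterministic, in the style of integrated nested Laplace
approximation:

1. **Gaussian approximation at fixed hyperparameters.** The conditional
   posterior `pi(x | theta, y)` is approximated by a Gaussian found by
   Newton–Raphson with step halving (max 50 iterations, max-abs projected
   gradient < 1e-8). Constraints are imposed by conditioning by kriging:
   solve unconstrained, then correct
   `x <- x - Q*^{-1} B'(B Q*^{-1} B')^{-1}(Bx - e)`, with the matching
   covariance correction. For the Gaussian family the approximation is exact
   and converges in one step. Inside Newton steps, non-concave likelihood
   curvature (ZIP at y = 0) is clamped to keep the working precision
   positive definite; the *final* precision at the mode uses the true
   curvature whenever it remains positive definite. This distinction
   matters: clamping in the reported precision induced a small but
   systematic, p-dependent bias in the ZIP hyperparameter posterior that the
   dense-quadrature oracle tests detect.
2. **Hyperparameter posterior.** `pi(theta | y)` is evaluated up to a
   constant by the Laplace ratio
   `pi(y|x*) pi(x*|theta) pi(theta) / pi_G(x*|theta, y)` on the internal
   scale (log variances, logit p). Under constraints, both the prior and the
   approximation enter as densities conditioned on `Bx = e`; their quadratic
   terms cancel exactly, leaving normalizer ratios
   (`|B Q^{-1} B'|` terms) that the implementation computes analytically for
   the block-diagonal prior. The mode is found by Nelder–Mead; an
   axis-aligned grid with step `delta` (default 0.5) standard deviations
   (from the numerical Hessian) extends along each axis until the
   log-density drops by `drop_threshold` (default 2.5) below the mode.
   Weights are normalized exponentials of the log density. With at most
   three internal hyperparameter dimensions here, a full tensor grid (pruned
   by the quadratic drop predictor) is affordable.

   For non-Gaussian families the plain Laplace ratio systematically
   underestimates variance components when each record carries little
   information — the analogue of the PQL small-cluster bias, worst for
   binomial data with 1–2 trials, where an exact factorized oracle shows
   the uncorrected posterior mean of `sigma_u^2` off by ~40%. The package
   therefore adds a per-record correction: writing the posterior as the
   Gaussian approximation times `exp(sum_r r_r(eta_r))`, with `r_r` each
   record's log-likelihood residual beyond its quadratic expansion at the
   mode, the missing factor is approximated as `prod_r E[exp r_r]` under
   `eta_r ~ N(eta*_r, Var(eta_r))`, each factor by 31-point Gauss–Hermite
   quadrature. Cross-record dependence of the residuals is neglected; the
   correction vanishes identically for the Gaussian family. On the
   factorized oracle this tracks the exact evidence profile to ~0.04
   log-units over a 16-fold range of `sigma_u^2`, and it moves the n = 2
   binomial heritability ladder from ~3–6 posterior SDs below truth to
   within ~1 SD. It can be disabled (`record_correction=False`) to obtain
   the plain Laplace ratio.
3. **Marginals.** Hyperparameter marginals collapse the grid onto one axis,
   interpolate the log-density, and transform to the variance (or
   probability) scale with the exact Jacobian. Latent marginals and linear
   combinations of breeding values (cohort means, cohort differences) are
   weight-mixtures of the per-theta Gaussians; no simplified-Laplace
   refinement is applied. The oracle suite quantifies the consequences: for
   the Gaussian family results are exact up to grid discretization; for
   binomial/Poisson/ZIP the mixture tracks dense quadrature to total
   variation ~1e-3 at the information levels exercised, degrading as
   per-individual information falls. For *binary* traits (one trial per
   individual) the Gaussian approximation can be badly wrong; the package
   emits a warning recommending a simulation check rather than pretending
   otherwise.
4. **DIC.** The deviance information criterion is
   `DIC = E[D] + p_D`. The posterior mean deviance integrates, per grid
   point, the second-order expansion of D around the conditional mode
   (`D(theta, x*) + sum_r curvature_r Var(eta_r)`, with a plug-in fallback
   behind a flag). The effective number of parameters is
   `p_D = (dim - k) - tr{Q(theta^m) Q*(theta^m)^{-1}}` at the componentwise
   posterior *median* `theta^m`, where `dim` is the latent-field size and
   `k` the number of active constraints (each exact constraint removes one
   effective dimension). The posterior-mean variant of `theta^m` (as used by
   some MCMC packages) is available by computing DIC at a caller-supplied
   theta.

## Heritability

* Gaussian: `h^2 = sigma_u^2 / (sigma_u^2 + sigma_e^2)`, evaluated at every
  retained point of the joint hyperparameter grid and accumulated into a
  kernel-free histogram with exact weighted summaries. Whether
  `sigma_ind^2` joins the denominator in repeated-measures fits is exposed
  as an option (default: it does not).
* Binomial (liability scale): `h^2 = sigma_u^2 / (sigma_u^2 + pi^2/3)` — an
  exact change of variables of the `sigma_u^2` marginal, `pi^2/3` being the
  variance of a standard logistic variable.
* Poisson/ZIP (log scale): `h^2 = sigma_u^2 / (sigma_u^2 + 1/lambda*)` with
  the plug-in mean intensity `lambda* = sum(y_i) / sum(E_i)` computed from
  the data.

Non-Gaussian heritabilities live on the latent (liability / log-intensity)
scale and are *not* proportions of explained phenotypic variance; every such
report carries that caveat.

## Synthetic data

The simulator emulates the structure of a wild-passerine quantitative
genetics study:

* multi-generation pedigrees (discrete generations, random monogamous
  pairing, Poisson offspring counts, optional unrelated immigrants). Study
  scale defaults: ~1,200–1,700 individuals over 7 generations, with mean
  sibship sizes of 3–4 typical of multi-brooded passerines; sibship size
  controls how much pedigree information the data carry about `sigma_u^2`,
  and small-sibship pedigrees visibly weaken recovery;
* breeding values by sequential Mendelian sampling with inbreeding-aware
  `d_i`, so the joint law is exactly `N(0, sigma_u^2 A)` (verified against
  the tabular relationship matrix by a 10^5-replicate covariance test);
* trait laws per family, including per-individual binomial trial counts
  uniform on {1..9} and Poisson/ZIP exposures, and *missing-structure
  imposition*: a morphological-trait profile observes ~29% of pedigree
  members (1025/3574), a reproductive-trait profile ~33% (1182/3574), or an
  explicit observed-mask/fraction.

Synthetic missing masks are drawn independently of family structure; a real
study's missingness correlates with survival and locality, so simulation
calibrations transfer only approximately to real masks. Gaussian synthetic
designs keep `sigma_u^2 + sigma_e^2 = 1` so that the generating value is
also the heritability. ZIP designs default to small per-season intensities
(the regime of reproductive count traits); with large counts a plain
Poisson model can absorb inflated zeros into extreme breeding values, and
DIC selection between Poisson and ZIP is then unreliable — the model-choice
test operates in the small-intensity regime for that reason.

All randomness descends from one master seed; replicate `r` uses
`default_rng([seed, r])`, so studies are reproducible replicate by
replicate.

## DIC-based testing of genetic effects

The presence of additive genetic variance is posed as model choice between
`H0: eta = beta_0 + z'beta` and `H1: eta = beta_0 + z'beta + u`, with
statistic `dDIC = DIC(H0) - DIC(H1)` and rejection rule `dDIC > 10`. Because
the null distribution of dDIC is not chi-square-like, the package estimates
it by simulation: S datasets are drawn under H0 with the study's pedigree,
priors and missing structure; both models are fitted to each; the rejection
proportion at the limit estimates the type-I error, and the empirical
quantile gives the limit for a desired level. Power at a given `sigma_u^2`
repeats this under H1. Every rejection proportion is reported with a
binomial 95% CI (at S = 100 that is roughly ±0.08, which bounds how finely
such studies can be compared). Failed replicates are excluded from the
denominator and reported; a study aborts if more than 10% fail.

## Numerical choices

* Sparse symmetric factorizations use SuperLU in symmetric mode
  (`MMD_AT_PLUS_A` ordering, no diagonal pivoting); log-determinants come
  from `|diag(U)|`. This handles the 100k-individual replicated-pedigree
  demonstration in seconds per factorization.
* Marginal variances and the `p_D` trace use multi-right-hand-side solves
  against the factor (selected inversion would be an optimization, not a
  correctness change); the trace is guarded to latent dimensions <= 8000.
* `|eta|` is capped at 35 before exponentiation (log-link means), with a
  warning; no realistic fit approaches the cap.
* Grid defaults `delta = 0.5`, `drop_threshold = 2.5` suit point estimates;
  interval-based conclusions (CI coverage studies) use `drop_threshold = 5`
  so that the 95% tails are actually integrated. Both are run-configurable.
* Ties in stepwise DIC selection break toward the smaller model.

## Known limitations

* Exact sum-to-zero constraints change the model, not just its
  parameterization: conditioning `u ~ N(0, sigma_u^2 A)` on `1'u = 0`
  perturbs the prior along the direction `A1`. Only when `A1 ∝ 1`
  (exchangeable founders) is that direction absorbed by a diffuse intercept,
  making fitted predictors invariant; on structured pedigrees constrained
  and unconstrained fits differ slightly — by design, since the constraint
  is part of the model.
* Binary-trait fits are unreliable (see above); the warning is the
  mitigation.
* Latent marginals use Gaussian mixtures without skewness correction.
* Single-trait models only; maternal/litter effects, genetic groups,
  genomic relationship matrices and multivariate models are out of scope.
* The systematic upward error of the `sigma_u^2` posterior mean for small
  generating values (< 0.1, with `InvGamma(0.5, 0.5)` priors) is a prior
  sensitivity of the model itself; it is reproduced, documented, and not
  "corrected".
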