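# Methods

## Distribution families

**SHASH.** We use the direct sinh-arcsinh form
`Y = mu + sigma * sinh((asinh(Z) + nu) / tau)` with `Z ~ N(0,1)`, giving the
closed-form CDF `F(y) = Phi( sinh( tau * asinh((y - mu)/sigma) - nu ) )` and
quantile `Q(c) = mu + sigma * sinh((asinh(Phi^{-1}(c)) + nu)/tau)`. This
variant was chosen because exact inverse mapping is required by the
quantile-mapping step, and because it reduces *exactly* to `Normal(mu,
sigma)` at `nu = 0, tau = 1` (the parameterisation constant k of the
SHASH-to-Normal identity is 1 under this form). `nu` shifts mass to the
right as it increases (the median is `mu + sigma*sinh(nu/tau)`); `tau < 1`
thickens both tails, `tau > 1` thins them. Several sinh-arcsinh variants
circulate (differing in how nu and tau enter); results are invariant to the
choice up to reparameterisation, but fitted shape coefficients are
interpretable only within the form documented here.

**Generalised gamma.** The three-parameter (mu, sigma, nu) form standard in
distributional regression: `z = (y/mu)^nu`, `theta = 1/(sigma^2 nu^2)`,
`theta*z ~ Gamma(theta, 1)`, support `y > 0`, `mu > 0`. CDF and quantile go
through the regularised incomplete gamma function and its inverse. The
family degenerates as `nu -> 0`; below `|nu| < 1e-5` we evaluate its
log-normal limit `log y ~ N(log mu, sigma)` instead, which is the analytic
limit and keeps likelihood surfaces continuous. `mu` keeps the identity
link, with positivity enforced by rejecting update steps that would make
any fitted `mu` non-positive.

**Links.** Identity on mu and nu, log on sigma and tau. CDF values are
never clipped on the harmonisation path: a centile that saturates to 0.0 or
1.0 in floating point must reach the QC stage untouched so the open-interval
rule can fire. Clipping (to [1e-15, 1-1e-15]) would be admissible inside
likelihood computations only; in practice the step-halving line search makes
it unnecessary there too.

## Model structure

Location and log-scale predictors contain an intercept, a sex fixed effect
(0/1 indicator, reference level = lexicographically smaller observed label),
a P-spline smooth of age, and a cohort random intercept. The two shape
predictors contain an intercept and, depending on the specification, a
cohort random intercept. A subject-level random intercept in mu is
supported behind a configuration flag (default off): pooled multi-cohort
analyses are treated as effectively cross-sectional here, with within-subject
dependence handled upstream.

**P-spline.** Cubic B-splines on 20 interior knots, uniformly spaced over
the observed age range and uniformly *extended* beyond it (Eilers–Marx
convention), with a second-order difference penalty. The uniform extension
matters: it makes the penalty null space correspond exactly to functions
linear in age, which the infinite-penalty limit test exercises. The basis is
column-centred over the training sample so the smooth carries no constant
and cannot trade off against the intercept. For prediction outside the
training age range the smooth is continued linearly from the boundary value
and boundary derivative, and such rows are flagged.

**Random intercepts.** Ridge-penalised coefficients with penalty `1/s_b^2`,
the prior variance `s_b^2` re-estimated each cycle by the EM update
`s_b^2 = (b'b + tr C_bb)/q` where `C_bb` is the posterior covariance block.
Because the intercept is unpenalised and the smooth basis centred, the
stationarity conditions force the fitted offsets to sum to (numerically)
zero, matching their zero-mean formulation; small cohorts are shrunk toward
zero relative to their raw mean offsets.

## Estimation

RS-type backfitting: the outer loop cycles over the distributional
parameters (mu, sigma, nu, tau); each parameter is updated by one penalised
weighted least-squares step on a working response built from per-observation
first and second derivatives of the log-likelihood with respect to that
parameter's linear predictor. Derivatives are central differences with a
relative step of 1e-4 — accurate to ~1e-8 on these smooth likelihoods and
uniform across families, which keeps every family on the identical code
path. Where the observed curvature is not negative the squared gradient is
substituted (a standard quasi-Fisher fallback). Observations whose perturbed
likelihood leaves the parameter domain get negligible weight for that
update.

Each proposed update is accepted only if it does not decrease the penalised
log-likelihood (step-halving up to 2^-30, otherwise the previous
coefficients are kept). Smoothing parameters and random-effect variances are
updated by the EM rules during the first 20 cycles and then frozen; after
the freeze, the penalised log-likelihood is monotone non-decreasing by
construction (the monotonicity test asserts this with 1e-6 slack).
Responses are standardised internally (affine for SHASH/Normal, pure
scaling for the positive-support GG — whose sigma is dimensionless and
scale-invariant); all reported coefficients, offsets and predictions are
transformed back to the natural scale.

**Starting values.** mu from an ordinary least-squares fit of its design;
log sigma from the log residual SD; nu = 0 and log tau = 0 — the Normal
limit of SHASH (for GG, nu starts at 1, the gamma sub-family).

**Convergence rule.** A fit converges iff the absolute change in global
deviance is below 1e-3 for two consecutive outer cycles within 200
iterations, all coefficients are finite, and no full Newton step in the
final two cycles violated the shape-predictor bounds (|eta_nu| <= 8,
|log tau| <= 4, |log sigma| <= 12 on the standardised scale). The bound
clause is what operationalises "failure": when a shape parameter is
unidentifiable the unconstrained step diverges, the fit stalls at the
boundary, and the specification is genuinely unusable — declaring it
non-converged hands the feature to the next fallback stage. Non-convergence
is a returned flag, never an exception; only data errors (non-positive
responses for GG, constant response, degenerate design, cohorts below 10
rows) raise.

**Fallback hierarchy.** (1) SHASH with cohort intercepts on nu and tau;
(2) nu only; (3) tau only; (4) intercept-only shapes; (5) generalised gamma;
(6) Normal. The GG stage is fitted with an intercept-only shape parameter:
by the time it is reached the shape random intercepts have already failed
twice, so the conservative specification maximises the chance of a usable
fit. Whether the nu-only or tau-only reduction should come first is a
convention; the order above is fixed and recorded per feature in the
attempt log.

## Harmonisation and QC

Centiles use the full cohort-specific parameters (all random effects
included); harmonised parameters set every cohort random effect to zero on
its link scale (subtraction on the log scale before exponentiation for
sigma and tau); quantile mapping evaluates the family quantile at the
original centile under the harmonised parameters. Parameters without a
fitted cohort effect pass through unchanged, so a model with all offsets
zero reproduces the input to within round-off (the identity test uses
relative tolerance 1e-8).

QC applies three rules in order, and a record failing an earlier rule is
not evaluated by later ones: (1) centile outside the *open* interval (0,1),
by exact floating-point comparison with no epsilon widening — widening would
silently discard valid extremes; (2) negative (for features declared
non-negative, the default) or non-finite harmonised value; (3) non-finite
z-score, which voids only the z. Rows whose input was already missing are
carried through with an `excluded_input` marker distinct from the five QC
flags: they are upstream exclusions, not harmonisation losses, and the
retention metric (valid before, missing after) reconciles exactly with the
flag counts.

## Validation metrics

* **Cohort R² increment** — gain in OLS R² when cohort indicators are added
  to a baseline of centred-age polynomial (degree 3, raw powers — centring
  controls conditioning without changing the fit) plus sex. Nested OLS, so
  non-negative by construction.
* **Mean pairwise KS** — exact two-sample Kolmogorov–Smirnov statistic on
  age/sex-residualised values for every unique cohort pair, averaged. The
  default residualisation fits one pooled degree-3 + sex model across
  cohorts, so residuals remove biology while leaving cohort structure for
  the KS to see; per-cohort residualisation is available as an option.
  Only the statistic is reported, as a magnitude, not a test.
* **Moment differences** — |log SD ratio| (scale-invariant across units),
  |delta skewness|, |delta excess kurtosis| between cohort pairs.
* **Age preservation** — Spearman rank correlation (average ranks for
  ties), robust to non-Gaussian marginals and monotone transforms, with
  Benjamini–Hochberg FDR across features.
* **Sex preservation** — Cohen's d with the pooled SD (sign: reference
  minus other, reference = smaller label), two-sided Welch t-tests,
  BH-FDR across features.
* **Retention** — per-feature and overall counts/rates of records valid
  before harmonisation but missing after.

## Synthetic data

The generator draws cohorts with distinct but chain-overlapping age windows
(as in real lifespan consortia, where the youngest and oldest studies never
overlap directly but each consecutive pair does), uniform ages within
window, sex coded 1/2, and SHASH responses built from per-feature truth:
intercepts, a named nonlinear age trajectory (linear decline, inverted-U,
exponential increase), sex effects, and zero-sum cohort offsets on any
subset of the four link-scale parameters. The same latent uniform draws
generate a "no-batch" twin table with all offsets zeroed — the
counterfactual batch-free measurement used as generating truth by the
preservation and offset-removal checks. A separate helper produces a
zero-bounded, strongly right-skewed, leptokurtic feature with an
exponential mean-age trajectory (exp of a linear-in-age mean plus SHASH
noise on the log scale), the stress case for non-Gaussian harmonisation.

The standard benchmark is 4 cohorts x 2000 observations x 20 features with
offsets of SD 0.5 (feature-SD units) on the location, SD 0.2 on the
log-scale, and SD 0.15 on the skewness of alternate features. These sizes
keep a full fit-harmonise-validate cycle around twenty seconds on one CPU
while leaving Monte-Carlo error well below the decision thresholds.

What the generator does *not* emulate: within-cohort scanner or site
structure, longitudinal within-subject correlation, cross-feature
covariance, and non-random cohort selection. Passing tests therefore
demonstrate correctness of the estimation and mapping machinery under the
model's own assumptions, not robustness to the full messiness of real
multi-site data.

## Known limitations

* Per-feature fitting ignores covariance between features; multivariate
  relationships are not directly controlled.
* No transfer step: prediction and harmonisation require the cohort to have
  been present at fit time.
* The fallback order and the convergence bounds are conventions; other
  reasonable choices would assign borderline features to different
  families.
* The numeric-derivative backfitting trades a little speed for family
  uniformity; very large cohorts (millions of rows) would warrant analytic
  derivatives.
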