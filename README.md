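# gamharm

Hierarchical GAMLSS harmonisation and normative modelling for pooled
multi-cohort continuous features — in particular bounded, skewed,
heavy-tailed measurements such as regional brain volumes, cortical
thickness, or white-matter-hypointensity volume pooled across studies with
different recruitment windows, scanners and protocols.

## The problem

When several cohorts are pooled, systematic between-cohort ("batch")
differences contaminate every distributional property of a feature: not just
its mean and variance, but also its skewness and tail weight.
Location–scale corrections under Gaussian assumptions (the ComBat family)
cannot represent those higher-order offsets and can produce invalid
(negative) values for zero-bounded features. `gamharm` instead models the
full conditional distribution of each feature and removes cohort effects by
quantile mapping, so harmonised values stay on the native measurement scale,
preserve within-cohort ranks at fixed covariates, and respect the support of
the feature.

## The model

Each feature *y<sub>ij</sub>* (subject *i*, cohort *j*) is fitted with a
generalised additive model for location, scale and shape (GAMLSS) under the
four-parameter sinh-arcsinh distribution (SHASH),

    y_ij ~ SHASH(mu_ij, sigma_ij, nu_ij, tau_ij)

with one linear predictor per distributional parameter:

    mu_ij        = beta_0  + b_j^(mu)    + pb(age_i) + beta_1  * sex_i
    log sigma_ij = gamma_0 + b_j^(sigma) + pb(age_i) + gamma_1 * sex_i
    nu_ij        = delta_0 + b_j^(nu)
    log tau_ij   = eps_0   + b_j^(tau)

where `pb(.)` is a penalised B-spline (P-spline) smooth of age and the
`b_j^(theta)` are cohort random intercepts estimated under a zero-mean
normal prior. If the full SHASH specification fails to converge, simpler
parameterisations are attempted in a fixed order (cohort intercepts on both
shape parameters, on the skewness only, on the tail weight only, neither),
then a three-parameter generalised gamma, then the Normal as terminal
fallback.

Harmonisation proceeds in three steps:

1. **centile** — `c_ij = F(y_ij | mu_ij, sigma_ij, nu_ij, tau_ij)`, the CDF
   of the observation under its own cohort's fitted distribution;
2. **cohort-effect removal** — every random intercept is set to zero on its
   link scale, `theta~_i = g^{-1}( g(theta_ij) - b_j^(theta) )`;
3. **quantile mapping** — `y~_i = Q(c_ij | mu~_i, sigma~_i, nu~_i, tau~_i)`
   returns the observation to the native scale under the cohort-free
   parameters.

The same centile yields the normative deviation score `z_ij =
Phi^{-1}(c_ij)`; under a correctly specified model on reference data these
z-scores are standard normal. A post-processing QC pass sets to missing any
harmonised value arising from a centile outside the open interval (0, 1),
any negative or non-finite back-transform, and any non-finite z-score.

## Worked example

```python
from gamharm import synthetic_data as sd, harmonise as hz, validate as vd

cfg = sd.benchmark_config(seed=7, n_cohorts=3, n_per_cohort=800, n_features=3)
table, truth = sd.generate(cfg)                   # long table + no-batch twin
feats = [f.name for f in cfg.features]
long_out, models, qc = hz.harmonise_table(table, feats, non_negative=False)
post = vd.harmonised_wide(long_out)
report = vd.validation_report(table, post, feats)
print(report.table[["feature", "state", "cohort_r2_increment",
                    "mean_pairwise_ks"]].round(4).to_string(index=False))
```

prints

```
feature state  cohort_r2_increment  mean_pairwise_ks
    f01   pre               0.0133            0.0988
    f02   pre               0.0024            0.1083
    f03   pre               0.0154            0.1225
    f01  post               0.0000            0.0246
    f02  post               0.0001            0.0396
    f03  post               0.0001            0.0308
```

The `cohort_r2_increment` column is the gain in OLS R² when cohort
indicators are added to a degree-3-age + sex baseline — the share of
variance attributable to cohort membership. The injected cohort offsets put
it at 0.2–1.5 % before harmonisation; afterwards it is essentially zero
(medians 0.0133 pre vs 0.00006 post in this run). `mean_pairwise_ks`, the
mean two-sample Kolmogorov–Smirnov statistic between cohorts on
age/sex-residualised values, drops about threefold, while age and sex
associations are preserved (all three features fitted as SHASH, every
record retained).

The same pipeline is available from the shell:

```sh
gamharm run-all --config demo.yaml --seed 7 --out results/
gamharm simulate|fit|harmonise|validate --help
```

Every run writes a provenance record (config hash, seed, versions,
per-feature family used, convergence, QC counts) and is byte-identical
given the same config and seed.

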