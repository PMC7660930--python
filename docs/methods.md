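# Methods

## Model

For one gene in one tissue, let `Y` be the covariate-adjusted expression
vector over `n` individuals and `X` the `n x p` dosage matrix of cis-SNPs
(±1 Mb beyond the TSS/TES, MAF ≥ 0.01, strand-ambiguous SNPs removed,
missing dosages mean-imputed, columns centered).  The imputation model is
a bi-level spike-and-slab regression:

    Y = X beta + eps,                 eps ~ N(0, sigma2 I)
    beta_k | gamma_k = 1 ~ N(0, sigma_beta2 * sigma2)
    beta_k | gamma_k = 0 ~ delta_0
    gamma_k ~ Bernoulli(pi_k)

What distinguishes it from a plain spike-and-slab (the `vb` comparator) is
that the prior inclusion probability of each SNP is a logistic function of
its epigenetic annotations:

    logit(pi_k) = omega_0 + A_k . omega,      omega ~ N(0, eta^{-1} I)

`A_k` holds continuous, non-negative tissue annotation values (fold
enrichments over background for histone-mark/DNase signal, methylation
fractions) after significance masking: entries whose underlying signal has
p ≥ 1e-2 are set to exactly 0.  An explicit intercept column is always
prepended to `A`, and `omega` is refit per gene.

Hyper-priors: `sigma2 ~ IG(a, b)`, `sigma_beta2 ~ IG(c, d)`,
`eta ~ Gamma(a0, b0)`; defaults `a=b=c=d=0.01`, `a0=b0=1` (weakly
informative — with these values the grid weights below are dominated by
the data term).

## Inference

The posterior is approximated by coordinate-ascent variational Bayes under
the fully factorized family `q(beta, gamma) = prod_k q(beta_k, gamma_k)`
with a Gaussian `q(omega)`.  The per-SNP updates are the standard
conjugate spike-and-slab ones (residualized against all other SNPs via
sufficient statistics `X'X`, `X'Y`):

    s2_k   = sigma2 / (x_k'x_k + 1/sigma_beta2)
    mu_k   = s2_k x_k' r_{-k} / sigma2
    logit(alpha_k) = A_k E[omega] + log(s2_k/(sigma_beta2 sigma2))/2
                     + mu_k^2 / (2 s2_k)

The logistic prior term is non-conjugate; it is handled with the
Jaakkola–Jordan quadratic bound with one local parameter `xi_k` per SNP,
which makes the `omega` update a closed-form Gaussian:

    Cov(omega)^{-1} = eta I + 2 A' diag(lambda(xi)) A
    E[omega]        = Cov(omega) A' (alpha - 1/2)
    xi_k^2          = A_k (Cov + E E') A_k',    lambda(xi) = tanh(xi/2)/(4 xi)

Every update is an exact coordinate maximization of the bounded ELBO, so
the ELBO trace is monotone non-decreasing (asserted to 1e-8 in the test
suite).  Bound-based handling of the logistic term was chosen over
sampling or Laplace precisely because it preserves this monotonicity,
which is the main correctness certificate of the fit.

Hyperparameters `theta = (sigma2, sigma_beta2, eta)` are not updated
inside the variational loop; each fit runs at a fixed grid point and the
per-SNP posterior probability of selection averages over the grid,

    PPS(k) = sum_theta w_theta alpha_k(theta),
    w_theta ∝ exp(ELBO(theta)) p(theta),

with `p(theta)` the IG/IG/Gamma hyper-prior density.  The model weights
used for prediction are the grid-averaged posterior-mean effects
`beta_hat_k = sum_theta w_theta alpha_k mu_k`, matching the prediction
rule `Yhat = X_c beta_hat`.  The default auto-grid is
`sigma_beta2 in {0.001, 0.01, 0.1, 1}` crossed with `eta in {1, 10}`;
`sigma2` is profiled — re-optimized each outer iteration at its
coordinate-wise ELBO maximum

    sigma2 = (E||Y - X beta||^2 + sum_k alpha_k (s2_k + mu_k^2)/sigma_beta2)
             / (n + sum_k alpha_k),

which is itself a coordinate-ascent step and keeps the trace monotone.
Explicit grids hold `sigma2` fixed (needed when comparing against
fixed-hyperparameter oracles).

Numerical choices: initialization `alpha = 0.1` (intercept logit
`log(1/9)`), `mu = 0`, `omega = 0` apart from the intercept, `xi = 1`;
cyclic update order over SNPs in genomic order, then the `omega` block,
then the profiled `sigma2`; convergence at |ΔELBO| < 1e-4 (default),
max 500 iterations; non-convergence is flagged on the returned state and
a run fails only if no grid point converges.  All updates are
deterministic, so fits are reproducible without seeding; seeds appear in
the interfaces for fold splitting, the elastic-net comparator, and the
data generator.

Comparators: `vb` is the identical machinery with an intercept-only
annotation design (with all-zero annotation columns the two are the same
computation, which the suite asserts to 1e-6); `elnt` is elastic net with
mixing parameter 0.5 and CV-chosen penalty (scikit-learn `ElasticNetCV`);
`vb.annot` / `elnt.annot` first drop SNPs with no positive value on any
annotation track, then fit the base learner.

## Model evaluation and the FDR gate

Imputation quality is 5-fold cross-validation: folds of near-equal size,
models refit on each training complement, out-of-fold predictions pooled,
and R² the squared Pearson correlation between observed and pooled
predicted expression.  Gene models enter association testing only when
significant at Benjamini–Hochberg FDR < 0.05 within a tissue.

The model p-value (one-sided, for positive correlation between observed
and out-of-fold predictions) comes in two flavours.  The analytic Pearson
test on the pooled vector is the field convention and the default, but it
is not exactly calibrated: under the null the pooled CV correlation is
slightly negatively biased and over-dispersed relative to the Pearson
null, because out-of-fold predictions in one fold are functions of the
responses of the other folds.  This is a property of pooled
cross-validated correlations in general — it reproduces with ordinary
least squares in place of the Bayesian fit — not of this model.  The
`permutation` flavour refits the entire cross-validation on permuted
responses and ranks the observed pooled correlation among the permuted
ones; it is a Monte Carlo exact test, calibrated by construction, at
`n_permutations` times the cost.  The calibration tests in the suite use
the permutation flavour; the analytic default is appropriate as a fast,
slightly conservative screening gate.

## Association test

Given fitted weights `beta_hat`, harmonized GWAS z-scores `z` and a
reference dosage panel, the gene-trait statistic is

    z_gene = sum_k beta_hat_k lambda_k z_k,
    lambda_k = sd(x_k) / sd(X_c beta_hat)   (reference panel, ddof = 1),

the weighted sum of SNP-level GWAS z-scores with weights proportional to
each SNP's share of the imputed-expression standard deviation; the
p-value is two-sided normal.  `sd(X_c beta_hat)` is computed as the
empirical SD of the model's prediction on the reference panel, equivalent
to `sqrt(beta_hat' Sigma_ref beta_hat)` with the empirical covariance
(asserted to 1e-10 in the suite).  Harmonization matches SNPs by id with
a chrom:pos fallback, keeps z when the GWAS allele pair equals the
model's (ref, alt), flips its sign when swapped, and drops
strand-ambiguous or mismatched SNPs together with their weights.
Significance is Bonferroni across all gene-tissue pairs tested in a run
(BH optional); aggregation of significant genes into cytogenetic bands
takes a user-supplied band map.

The suite validates the statistic against an individual-level oracle:
with the GWAS cohort itself as the reference panel, `z_gene` agrees with
the t-statistic from regressing the trait directly on imputed expression
to within 0.1 (the residual gap is the O(r^2) difference between
correlation t-statistics and their linear approximation), and under a
null trait it is standard normal with nominal type-I error.

## Synthetic data

The generator emulates the statistical structure the model assumes, with
every quantity exported as ground truth.  Defaults describe one realistic
cis region and are the conditions under which the package's guarantees
are stated: n_train = 500, p = 200 SNPs in a 2 Mb window, MAF ~
U(0.05, 0.5), adjacent-SNP LD via a latent Gaussian AR(1) copula with
rho = 0.3 (each haplotype drawn from its own copula), one annotation
track that is zero for 80% of SNPs (emulating significance masking) and
Exponential(1) otherwise, prior logit intercept −2 with slope +2
(baseline inclusion ≈ 0.12), relative slab variance sigma_beta2 = 0.03
with sigma2 = 1 giving realized cis heritability around 0.3, GWAS cohort
n_gwas = 5000 with a mediated trait `T = kappa X_c beta + noise` scaled
to unit variance (kappa = 0.1), and an independent reference panel of
n_ref = 500.  GWAS z-scores are actual marginal-regression t-statistics
on the simulated cohort, not analytic approximations, so the
individual-level association oracle is meaningful.

What the generator does not emulate — and hence what passing tests do not
establish about real data: recombination-map LD beyond AR(1), population
structure, trans effects, annotation measurement error correlated with
LD, non-Gaussian expression noise, and covariate confounding (expression
is assumed pre-adjusted everywhere).

## Problem sizes used in the shipped checks

The acceptance script and system-level tests run at desk scale, chosen as
the smallest sizes at which the asymptotic statements are clean: exact
enumeration at p = 8 (256 configurations, 20 instances), ELBO
monotonicity over 100 random instances, annotation benefit over 50
replicates at n = 500, p = 200, the association oracle over 100
replicates at n_gwas = 2000, null calibration of the gene test over 2000
gene-replicates (200 fitted genes × 10 independent null GWAS draws), and
CV null calibration over 200 pure-noise replicates with 99 permutations
each.

## Known limitations

* Mean-field VB underestimates posterior dependence between SNPs in tight
  LD; the PPS of a causal SNP can be split across its proxies.  The
  enumeration checks bound this at modest LD (rho = 0.3) only.
* `omega` is refit per gene from at most a few hundred SNPs, so its
  per-gene estimate is noisy; only its grid-averaged value is reported.
  A shared-omega (per-tissue) mode is a natural extension and is not
  built.
* The analytic CV p-value is approximate (see above); exact calibration
  costs a permutation factor.
* The association test ignores LD between the gene's SNPs beyond what the
  reference-panel SD scaling captures; joint/conditional gene tests are
  out of scope.
* PLINK output stores hard calls only; fractional (imputed) dosages are
  rounded on write.  VCF output carries exact dosages in the DS field.
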