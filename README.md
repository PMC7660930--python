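# tgen

Transcriptome-wide association analysis with epigenetically informed
expression imputation.

## The problem

TWAS methods test whether a trait associates with the genetically
regulated component of a gene's expression: per gene, a sparse model
`Y = X beta + eps` is trained on an expression cohort (X = cis-SNP
dosages), and the fitted SNP weights are then combined with GWAS summary
statistics to obtain a gene-level association z-score.  Standard weight
learners (elastic net, plain spike-and-slab) treat all cis-SNPs
exchangeably, although SNPs sitting in active regulatory chromatin —
marked by H3K4me1/H3K4me3/H3K9ac, DNase hypersensitivity, or DNA
methylation — are far more likely to be true eQTLs.

`tgen` makes the prior SNP-selection probability a function of those
annotations.  Each SNP's effect follows a spike-and-slab prior

    beta_k ~ pi_k N(0, sigma_beta2 sigma2) + (1 - pi_k) delta_0,
    logit(pi_k) = omega_0 + A_k . omega,

where `A_k` is the SNP's row of continuous epigenetic annotation values
and `omega` is learned per gene.  The model is fitted by coordinate-ascent
variational Bayes (Jaakkola–Jordan bound for the logistic term) over a
hyperparameter grid; per-SNP posterior selection probabilities (PPS) and
effect estimates are grid-weighted averages.  The downstream gene-trait
test needs only GWAS summary statistics and a reference genotype panel:

    z_gene = beta_hat' Lambda z_GWAS,
    Lambda = diag( sd(x_k) / sd(X beta_hat) ).

See `docs/methods.md` for the full model, updates, and design choices.
The package ships the comparator weight learners (`vb`, `vb.annot`,
`elnt`, `elnt.annot`), 5-fold cross-validation with an FDR gate on gene
models, harmonization of GWAS alleles, and a synthetic-data generator
producing linked genotype / annotation / expression / GWAS datasets with
exported ground truth, so the entire pipeline is testable offline.

Intended users: statistical geneticists building expression imputation
models from an expression cohort plus epigenetic tracks, and anyone
running gene-level association scans from GWAS summary statistics.

## Worked example

```python
from tgen import (SimConfig, simulate_dataset, fit_grid, fit_vb_baseline,
                  cross_validate, run_twas)
from sklearn.metrics import roc_auc_score

cfg = SimConfig(seed=42, kappa=0.15)       # one cis region + mediated trait
ds = simulate_dataset(cfg)

fit, model = fit_grid(ds.panel.dosages, ds.expression.values,
                      ds.annotations, snps=ds.panel.snps, gene_id="gene_sim")
vb = fit_vb_baseline(ds.panel.dosages, ds.expression.values,
                     snps=ds.panel.snps)
report = cross_validate(ds.panel.dosages, ds.expression.values,
                        ds.annotations, method_tag="tgen", seed=42)
table, failures = run_twas([model], ds.gwas, ds.reference)
```

Output (printing the quantities above):

```
simulated gene: 200 cis-SNPs, n=500, 42 true eQTLs, h2=0.30
annotation coefficients (intercept, slope): (-0.77, +0.76)
eQTL-recovery AUC: tgen=0.810 vb=0.712
5-fold CV: R2=0.193, p=2.74e-25
TWAS: z=6.36, p=2.06e-10, n_snps=200
```

The generator planted 42 eQTLs whose prior probability rises with an
annotation track (true slope +2); the fitted slope is positive, and
ranking SNPs by PPS recovers the true eQTLs better than the
annotation-blind `vb` baseline (AUC 0.81 vs 0.71).  Cross-validated
imputation R² is 0.19 against a realized cis heritability of 0.30, and
the summary-statistics test detects the mediated gene-trait effect
(z = 6.4) using only per-SNP GWAS z-scores and the reference panel.

## Command line

```bash
tgen simulate  --config run.yaml --seed 11     # write a synthetic study
tgen train     --config run.yaml --method tgen # fit + CV + FDR gate
tgen evaluate  --config run.yaml               # CV only
tgen associate --config run.yaml               # summary-statistics TWAS
```

Inputs are VCF or PLINK1 genotypes, a genes × samples expression TSV, a
BED-like annotation TSV (chrom, start, end, track, value, pvalue), and a
GWAS summary TSV (SNP, A1, A2, Z, N).  Model stores are documented TSV
pairs; every run writes a manifest with the config hash and seed.

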