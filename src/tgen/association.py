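"""Summary-statistics gene-trait association test.

Given a fitted expression imputation model (SNP weights beta_hat), GWAS
summary z-scores, and a reference genotype panel, the gene-level statistic
for the effect of imputed expression Yhat = X beta_hat on the trait is

    z_gene = beta_hat' Lambda Zhat_X

where Zhat_X is the harmonized vector of per-SNP GWAS z-scores and Lambda
is diagonal with entries sd(x_k) / sd(Yhat), both standard deviations taken
on the reference panel.  The statistic is the weighted sum of GWAS z-scores
with weights proportional to each SNP's share of the imputed-expression
variance; under the null of no mediated effect it is asymptotically
standard normal, and the two-sided p-value is 2 Phi(-|z|).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AlignedModelGwas,
    AssociationResult,
    GenotypePanel,
    GwasSummary,
    ImputationModel,
    is_ambiguous,
)
from .vb import predict_expression

__all__ = [
    "harmonize",
    "build_lambda",
    "gene_zscore",
    "bonferroni_threshold",
    "run_twas",
    "aggregate_loci",
]


class HarmonizationError(ValueError):
    """No model SNP could be matched to the GWAS."""


def harmonize(model: ImputationModel, gwas: GwasSummary) -> AlignedModelGwas:
    """Align GWAS z-scores to the model's allele coding.

    SNPs are matched by id (falling back to chrom:pos); a GWAS record with
    (A1, A2) equal to the model's (ref, alt) keeps its z, the swapped order
    flips the sign, and strand-ambiguous (A/T, C/G) or allele-mismatched
    or absent SNPs are dropped with a reason.  Dropped SNPs are excluded
    from the downstream test (their beta entries are removed with them).
    """
    by_pos = {v: k for k, v in gwas.positions.items()}
    snp_ids: list[str] = []
    kept_idx: list[int] = []
    z: list[float] = []
    dropped: list[tuple[str, str]] = []
    for k, snp in enumerate(model.snps):
        rec_id = snp.snp_id
        if rec_id not in gwas.records:
            rec_id = by_pos.get((snp.chrom, snp.pos))
        if rec_id is None or rec_id not in gwas.records:
            dropped.append((snp.snp_id, "not_in_gwas"))
            continue
        a1, a2, zval = gwas.records[rec_id]
        if is_ambiguous(a1, a2):
            dropped.append((snp.snp_id, "ambiguous"))
            continue
        if (a1, a2) == (snp.allele_ref, snp.allele_alt):
            z.append(zval)
        elif (a1, a2) == (snp.allele_alt, snp.allele_ref):
            z.append(-zval)
        else:
            dropped.append((snp.snp_id, "allele_mismatch"))
            continue
        snp_ids.append(snp.snp_id)
        kept_idx.append(k)
    if not snp_ids:
        raise HarmonizationError(
            f"{model.gene_id}: no model SNP matched the GWAS "
            f"({len(dropped)} dropped: "
            f"{sorted(set(r for _, r in dropped))})"
        )
    return AlignedModelGwas(
        snp_ids=snp_ids, z=np.array(z), dropped=dropped,
        kept_idx=np.array(kept_idx),
    )


def build_lambda(
    model: ImputationModel,
    reference: GenotypePanel,
    aligned: AlignedModelGwas | None = None,
) -> AlignedModelGwas:
    """Fill in the reference-panel scalings of the aligned statistics.

    snp_sd is the per-SNP dosage standard deviation on the reference
    panel; pred_sd the standard deviation of the model's imputed
    expression there (ddof=1 throughout); lambda_diag their elementwise
    ratio.  A model whose prediction has zero variance on the reference
    (e.g. all-zero weights) is degenerate and rejected.
    """
    if aligned is None:
        aligned = AlignedModelGwas(
            snp_ids=model.snp_ids,
            z=np.zeros(len(model.snps)),
            kept_idx=np.arange(len(model.snps)),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = predict_expression(model, reference)
    pred_sd = float(np.std(pred, ddof=1))
    if pred_sd == 0:
        raise ValueError(f"{model.gene_id}: degenerate model (pred_sd = 0)")
    ref_pos = {sid: j for j, sid in enumerate(reference.snp_ids)}
    snp_sd = np.empty(len(aligned.snp_ids))
    for i, sid in enumerate(aligned.snp_ids):
        j = ref_pos.get(sid)
        if j is None:
            raise ValueError(f"{model.gene_id}: SNP {sid} absent from reference")
        snp_sd[i] = np.std(reference.dosages[:, j], ddof=1)
    if np.any(snp_sd == 0):
        bad = [s for s, sd in zip(aligned.snp_ids, snp_sd) if sd == 0]
        raise ValueError(f"{model.gene_id}: monomorphic reference SNPs {bad[:5]}")
    aligned.snp_sd = snp_sd
    aligned.pred_sd = pred_sd
    aligned.lambda_diag = snp_sd / pred_sd
    return aligned


def gene_zscore(
    aligned: AlignedModelGwas,
    beta_hat: np.ndarray,
    gene_id: str = "gene",
    tissue: str = "tissue",
    alpha_threshold: float | None = None,
) -> AssociationResult:
    """The gene-level statistic z = sum_k beta_k lambda_k z_k."""
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    if aligned.lambda_diag is None:
        raise ValueError("aligned statistics lack lambda (run build_lambda)")
    if len(beta_hat) != len(aligned.z):
        raise ValueError(
            f"beta length {len(beta_hat)} != aligned SNP count {len(aligned.z)}"
        )
    z = float(np.sum(beta_hat * aligned.lambda_diag * aligned.z))
    if not np.isfinite(z):
        raise ValueError(f"{gene_id}: non-finite gene z-score")
    pvalue = float(2.0 * stats.norm.sf(abs(z)))
    return AssociationResult(
        gene_id=gene_id,
        tissue=tissue,
        z=z,
        pvalue=pvalue,
        n_snps_used=len(aligned.z),
        significant=(alpha_threshold is not None and pvalue < alpha_threshold),
    )


def bonferroni_threshold(n_gene_tissue_pairs: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / (number of tested gene-tissue pairs)."""
    if n_gene_tissue_pairs < 1:
        raise ValueError("need at least one gene-tissue pair")
    return alpha / n_gene_tissue_pairs


def run_twas(
    models: list[ImputationModel],
    gwas: GwasSummary,
    reference: GenotypePanel,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Test every gene-tissue model against one trait.

    Returns a results table (gene, tissue, z, pvalue, n_snps, significant)
    and a list of per-gene failures (gene, tissue, reason); individual
    failures do not abort the run.  Significance is Bonferroni over the
    pairs actually tested (BH available via ``correction='fdr_bh'``).
    """
    if not models:
        raise ValueError("no models supplied")
    results: list[AssociationResult] = []
    failures: list[tuple[str, str, str]] = []
    for model in models:
        try:
            aligned = harmonize(model, gwas)
            aligned = build_lambda(model, reference, aligned)
            beta = model.beta_hat[aligned.kept_idx]
            results.append(
                gene_zscore(aligned, beta, gene_id=model.gene_id, tissue=model.tissue)
            )
        except (ValueError, HarmonizationError) as exc:
            failures.append((model.gene_id, model.tissue, str(exc)))
    if not results:
        raise RuntimeError(
            f"association failed for all {len(models)} models; "
            f"first failure: {failures[0] if failures else 'none'}"
        )
    pvals = np.array([r.pvalue for r in results])
    if correction == "bonferroni":
        thr = bonferroni_threshold(len(results), alpha)
        significant = pvals < thr
    elif correction == "fdr_bh":
        from statsmodels.stats.multitest import multipletests

        significant = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown correction '{correction}'")
    table = pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "tissue": [r.tissue for r in results],
            "z": [r.z for r in results],
            "pvalue": pvals,
            "n_snps": [r.n_snps_used for r in results],
            "significant": significant,
        }
    )
    return table, failures


def aggregate_loci(
    results: pd.DataFrame,
    band_map: pd.DataFrame,
    gene_info: dict[str, tuple[str, int]],
) -> pd.DataFrame:
    """Group significant genes into user-supplied cytogenetic bands.

    ``band_map`` has columns chrom/start/end/band (1-based inclusive);
    ``gene_info`` maps gene_id -> (chrom, tss).  Returns one row per band
    containing at least one significant gene, with the gene count.
    """
    required = {"chrom", "start", "end", "band"}
    if not required.issubset(band_map.columns):
        raise ValueError(f"band map must have columns {sorted(required)}")
    rows = []
    sig = results[results["significant"]]
    for gene in sig["gene"].unique():
        if gene not in gene_info:
            continue
        chrom, tss = gene_info[gene]
        hit = band_map[
            (band_map["chrom"].astype(str) == str(chrom))
            & (band_map["start"] <= tss)
            & (band_map["end"] >= tss)
        ]
        for band in hit["band"]:
            rows.append({"band": band, "gene": gene})
    if not rows:
        return pd.DataFrame(columns=["band", "n_genes", "genes"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("band")["gene"]
        .agg(n_genes="nunique", genes=lambda g: ",".join(sorted(set(g))))
        .reset_index()
    )
    return out
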