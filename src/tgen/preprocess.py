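"""SNP QC, cis-window extraction, and annotation significance masking."""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .types import AnnotationMatrix, GeneInfo, GenotypePanel

__all__ = ["qc_filter", "cis_snps", "mask_annotations", "annotate_snps"]


class EmptyPanelError(ValueError):
    """Raised when QC or windowing removes every SNP and none can remain."""


def qc_filter(panel: GenotypePanel, maf_min: float = 0.01) -> GenotypePanel:
    """Remove low-MAF, strand-ambiguous, and monomorphic SNPs; impute missing.

    SNPs with minor allele frequency below ``maf_min`` are dropped, as are
    strand-ambiguous (A/T, C/G) SNPs regardless of frequency and SNPs whose
    dosage column is constant.  Remaining missing dosages are mean-imputed
    per SNP.  Sample order is unchanged; the operation is idempotent.
    """
    if panel.n_snps == 0:
        raise EmptyPanelError("qc_filter: input panel has no SNPs")

    dos = panel.dosages.copy()
    keep = np.ones(panel.n_snps, dtype=bool)
    for j, snp in enumerate(panel.snps):
        if snp.maf < maf_min or snp.ambiguous:
            keep[j] = False
            continue
        col = dos[:, j]
        miss = np.isnan(col)
        if miss.all():
            keep[j] = False
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        if np.ptp(col) == 0:  # monomorphic after imputation
            keep[j] = False

    if not keep.any():
        raise EmptyPanelError("qc_filter: all SNPs removed by QC")

    idx = np.flatnonzero(keep)
    return GenotypePanel(
        sample_ids=list(panel.sample_ids),
        snps=[panel.snps[i] for i in idx],
        dosages=dos[:, idx],
    )


def cis_snps(
    panel: GenotypePanel, gene: GeneInfo, window_bp: int = 1_000_000
) -> GenotypePanel:
    """Restrict the panel to the gene's cis window.

    Keeps SNPs on ``gene.chrom`` with ``tss - window_bp <= pos <= tes +
    window_bp`` (both bounds inclusive).  An absent chromosome yields an
    empty panel with a warning rather than an error.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    lo = gene.tss - window_bp
    hi = gene.tes + window_bp
    idx = [
        j
        for j, s in enumerate(panel.snps)
        if s.chrom == gene.chrom and lo <= s.pos <= hi
    ]
    if not any(s.chrom == gene.chrom for s in panel.snps):
        warnings.warn(
            f"cis_snps: chromosome {gene.chrom} absent from panel "
            f"for gene {gene.gene_id}",
            stacklevel=2,
        )
    return panel.subset_snps(idx)


def mask_annotations(
    raw_values: np.ndarray,
    signal_pvalues: np.ndarray,
    alpha: float = 1e-2,
    track_names: list[str] | None = None,
) -> AnnotationMatrix:
    """Zero out annotation entries whose underlying signal is not significant.

    Entries with signal p-value >= ``alpha`` are set to 0 and flagged in the
    ``masked`` indicator; significant entries carry their raw continuous
    values (fold enrichments / methylation fractions) unchanged.
    """
    raw = np.atleast_2d(np.asarray(raw_values, dtype=float))
    pv = np.atleast_2d(np.asarray(signal_pvalues, dtype=float))
    if raw.shape != pv.shape:
        raise ValueError(f"value shape {raw.shape} != p-value shape {pv.shape}")
    if np.any(raw < 0):
        raise ValueError("annotation values must be non-negative")
    masked = pv >= alpha
    values = np.where(masked, 0.0, raw)
    if track_names is None:
        track_names = [f"track{j}" for j in range(raw.shape[1])]
    return AnnotationMatrix(track_names=track_names, values=values, masked=masked)


def annotate_snps(
    panel: GenotypePanel,
    intervals: pd.DataFrame,
    alpha: float = 1e-2,
    standardize: bool = False,
) -> AnnotationMatrix:
    """Project BED-like interval annotations onto the panel's SNPs.

    ``intervals`` has columns chrom/start/end/track/value/pvalue with
    0-based half-open coordinates; a SNP at 1-based position ``pos``
    overlaps an interval iff ``start < pos <= end``.  When several
    intervals of one track overlap a SNP the maximum value (and that
    interval's p-value) is taken.  Significance masking at ``alpha`` is
    applied afterwards; ``standardize`` optionally rescales each track to
    unit standard deviation across SNPs (a pure scaling, so masked zeros
    stay zero and values stay non-negative).
    """
    required = {"chrom", "start", "end", "track", "value", "pvalue"}
    if not required.issubset(intervals.columns):
        raise ValueError(f"interval table must have columns {sorted(required)}")
    if (intervals["value"] < 0).any():
        raise ValueError("annotation values must be non-negative")

    tracks = sorted(intervals["track"].unique())
    p, m = panel.n_snps, len(tracks)
    raw = np.zeros((p, m))
    pv = np.ones((p, m))
    pos = np.array([s.pos for s in panel.snps])
    chrom = np.array([s.chrom for s in panel.snps])
    for tj, track in enumerate(tracks):
        sub = intervals[intervals["track"] == track]
        for row in sub.itertuples(index=False):
            hit = (chrom == str(row.chrom)) & (pos > row.start) & (pos <= row.end)
            better = hit & (row.value > raw[:, tj])
            raw[better, tj] = row.value
            pv[better, tj] = row.pvalue
    ann = mask_annotations(raw, pv, alpha=alpha, track_names=tracks)
    if standardize:
        sd = ann.values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        ann = dataclasses.replace(ann, values=ann.values / sd)
    return ann
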