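"""Readers and writers for the pipeline's on-disk formats.

Formats (all gzip-transparent where text-based):

* genotype panels — VCF 4.x (read via cyvcf2, written as plain text with a
  DS FORMAT field so fractional mean-imputed dosages round-trip) and
  PLINK1 bed/bim/fam (minimal built-in codec, SNP-major 2-bit encoding;
  fractional dosages are rounded on write);
* expression matrices — TSV, genes x samples;
* annotation tracks — BED-like TSV (chrom, start, end, track, value,
  pvalue) with 0-based half-open intervals;
* GWAS summary statistics — TSV with mandatory header SNP/A1/A2/Z/N;
* model stores — one pair of TSVs per tissue: a per-SNP weights table
  (gene, snp, chrom, pos, ref, alt, maf, train_mean, beta, pps) and a
  per-gene sidecar (gene, tissue, method, cv_r2, cv_pvalue, omega).

Readers validate shapes and report malformed rows with line numbers.
"""

from __future__ import annotations

import gzip

import numpy as np
import pandas as pd

from .types import (
    ExpressionVector,
    GenotypePanel,
    GwasSummary,
    ImputationModel,
    SnpRecord,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_plink",
    "write_plink",
    "read_expression",
    "write_expression",
    "expression_vector",
    "read_annotation_bed",
    "write_annotation_bed",
    "read_gwas",
    "write_gwas",
    "read_model_store",
    "write_model_store",
]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _maf_from_dosage(col: np.ndarray) -> float:
    ok = col[~np.isnan(col)]
    if len(ok) == 0:
        return 0.0
    f = float(ok.mean() / 2.0)
    return min(f, 1.0 - f)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path) -> GenotypePanel:
    """Read a VCF into a dosage panel.

    Uses the DS (dosage) FORMAT field when present, otherwise alt-allele
    counts from GT; missing genotypes become NaN (imputed later by QC).
    Multi-allelic records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snps, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise FormatError(
                f"{path}: multi-allelic record at {var.CHROM}:{var.POS}"
            )
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).ravel()
            col[col < -0.5] = np.nan  # cyvcf2 encodes missing as negative fill
        else:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            gt = var.gt_types.astype(float)
            col = np.where(gt == 3, 2.0, gt)
            col[gt == 2] = np.nan
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                allele_ref=var.REF,
                allele_alt=var.ALT[0],
                maf=_maf_from_dosage(col),
            )
        )
        cols.append(col)
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.zeros((len(sample_ids), 0))
    return GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a panel as VCF with GT (rounded) and DS (exact) fields."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt dosage">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in enumerate(panel.snps):
            fields = [
                snp.chrom, str(snp.pos), snp.snp_id, snp.allele_ref,
                snp.allele_alt, ".", "PASS", ".", "GT:DS",
            ]
            for d in panel.dosages[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major


def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write PLINK1 bed/bim/fam.  A1 = alt, A2 = ref; dosages are rounded
    to the nearest genotype (the format stores hard calls only)."""
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for sid in panel.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for s in panel.snps:
            fh.write(
                f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\t{s.allele_alt}\t{s.allele_ref}\n"
            )
    n = panel.n_samples
    # 2-bit codes per sample: 00 hom A1(alt, dosage 2), 01 missing,
    # 10 het, 11 hom A2(ref, dosage 0)
    code_of = {2: 0b00, 1: 0b10, 0: 0b11}
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(panel.n_snps):
            col = panel.dosages[:, j]
            byte = 0
            out = bytearray()
            for i in range(n):
                d = col[i]
                code = 0b01 if np.isnan(d) else code_of[int(round(d))]
                byte |= code << ((i % 4) * 2)
                if i % 4 == 3:
                    out.append(byte)
                    byte = 0
            if n % 4 != 0:
                out.append(byte)
            fh.write(bytes(out))


def read_plink(prefix) -> GenotypePanel:
    """Read PLINK1 bed/bim/fam into a dosage panel (alt = A1 counts)."""
    prefix = str(prefix)
    sample_ids = []
    with open(prefix + ".fam") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{prefix}.fam line {ln}: expected >= 2 fields")
            sample_ids.append(parts[1])
    bim_rows = []
    with open(prefix + ".bim") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{prefix}.bim line {ln}: expected 6 fields")
            bim_rows.append(parts)
    n, p = len(sample_ids), len(bim_rows)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic {magic!r} (need SNP-major v1)")
        data = fh.read()
    bytes_per_snp = (n + 3) // 4
    if len(data) != bytes_per_snp * p:
        raise FormatError(
            f"{prefix}.bed: {len(data)} data bytes, expected {bytes_per_snp * p}"
        )
    decode = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
    dosages = np.empty((n, p))
    for j in range(p):
        chunk = data[j * bytes_per_snp : (j + 1) * bytes_per_snp]
        for i in range(n):
            b = chunk[i // 4]
            dosages[i, j] = decode[(b >> ((i % 4) * 2)) & 0b11]
    snps = []
    for j, (chrom, sid, _cm, pos, a1, a2) in enumerate(bim_rows):
        snps.append(
            SnpRecord(
                snp_id=sid,
                chrom=chrom,
                pos=int(pos),
                allele_ref=a2,
                allele_alt=a1,
                maf=_maf_from_dosage(dosages[:, j]),
            )
        )
    return GenotypePanel(sample_ids=sample_ids, snps=snps, dosages=dosages)


# ---------------------------------------------------------------------------
# expression TSV (genes x samples)
# ---------------------------------------------------------------------------


def read_expression(path) -> pd.DataFrame:
    """Genes-by-samples expression table; first column is gene_id."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id '{dup}'")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index_label="gene_id")


def expression_vector(df: pd.DataFrame, gene_id: str) -> ExpressionVector:
    if gene_id not in df.index:
        raise KeyError(f"gene '{gene_id}' not in expression table")
    row = df.loc[gene_id]
    return ExpressionVector(
        gene_id=gene_id,
        sample_ids=[str(c) for c in df.columns],
        values=row.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# annotation BED-like TSV
# ---------------------------------------------------------------------------

_BED_COLS = ["chrom", "start", "end", "track", "value", "pvalue"]


def read_annotation_bed(path) -> pd.DataFrame:
    """BED-like track intervals: chrom, start, end (0-based half-open),
    track, value, pvalue."""
    rows = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _BED_COLS:
            raise FormatError(
                f"{path}: header must be {_BED_COLS}, got {header}"
            )
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path} line {ln}: expected 6 fields")
            try:
                rows.append(
                    {
                        "chrom": parts[0],
                        "start": int(parts[1]),
                        "end": int(parts[2]),
                        "track": parts[3],
                        "value": float(parts[4]),
                        "pvalue": float(parts[5]),
                    }
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {ln}: {exc}") from exc
    return pd.DataFrame(rows, columns=_BED_COLS)


def write_annotation_bed(df: pd.DataFrame, path) -> None:
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, columns=_BED_COLS)


# ---------------------------------------------------------------------------
# GWAS summary TSV
# ---------------------------------------------------------------------------

_GWAS_COLS = ["SNP", "A1", "A2", "Z", "N"]


def read_gwas(path) -> GwasSummary:
    """GWAS summary TSV with mandatory header SNP/A1/A2/Z/N.

    Optional CHR/POS columns populate the positional fallback index used
    during harmonization.  Z is the association z-score for the A2 allele.
    """
    records: dict[str, tuple[str, str, float]] = {}
    positions: dict[str, tuple[str, int]] = {}
    n_gwas = None
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _GWAS_COLS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory columns {missing}")
        idx = {c: header.index(c) for c in header}
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path} line {ln}: {len(parts)} fields, expected {len(header)}"
                )
            try:
                snp = parts[idx["SNP"]]
                z = float(parts[idx["Z"]])
                n = int(float(parts[idx["N"]]))
                records[snp] = (parts[idx["A1"]], parts[idx["A2"]], z)
                if "CHR" in idx and "POS" in idx:
                    positions[snp] = (parts[idx["CHR"]], int(parts[idx["POS"]]))
            except ValueError as exc:
                raise FormatError(f"{path} line {ln}: {exc}") from exc
            n_gwas = n if n_gwas is None else max(n_gwas, n)
    if n_gwas is None:
        raise FormatError(f"{path}: no data rows")
    return GwasSummary(records=records, n_gwas=n_gwas, positions=positions)


def write_gwas(gwas: GwasSummary, path) -> None:
    with _open_text(path, "wt") as fh:
        has_pos = bool(gwas.positions)
        cols = _GWAS_COLS + (["CHR", "POS"] if has_pos else [])
        fh.write("\t".join(cols) + "\n")
        for snp, (a1, a2, z) in gwas.records.items():
            row = [snp, a1, a2, f"{z:.10g}", str(gwas.n_gwas)]
            if has_pos:
                chrom, pos = gwas.positions.get(snp, (".", 0))
                row += [chrom, str(pos)]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# model store (per-tissue TSV pair)
# ---------------------------------------------------------------------------

_WEIGHT_COLS = [
    "gene", "snp", "chrom", "pos", "ref", "alt", "maf", "train_mean",
    "beta", "pps",
]
_GENE_COLS = ["gene", "tissue", "method", "cv_r2", "cv_pvalue", "omega"]


def write_model_store(models: list[ImputationModel], prefix) -> None:
    """Write a tissue's models as <prefix>.weights.tsv + <prefix>.genes.tsv."""
    prefix = str(prefix)
    with _open_text(prefix + ".weights.tsv", "wt") as fh:
        fh.write("\t".join(_WEIGHT_COLS) + "\n")
        for m in models:
            for k, s in enumerate(m.snps):
                fh.write(
                    "\t".join(
                        [
                            m.gene_id, s.snp_id, s.chrom, str(s.pos),
                            s.allele_ref, s.allele_alt, f"{s.maf:.10g}",
                            f"{m.train_mean[k]:.10g}", f"{m.beta_hat[k]:.10g}",
                            f"{m.pps[k]:.10g}",
                        ]
                    )
                    + "\n"
                )
    with _open_text(prefix + ".genes.tsv", "wt") as fh:
        fh.write("\t".join(_GENE_COLS) + "\n")
        for m in models:
            omega = ";".join(f"{v:.10g}" for v in m.omega_hat)
            fh.write(
                "\t".join(
                    [
                        m.gene_id, m.tissue, m.method_tag, f"{m.cv_r2:.10g}",
                        f"{m.cv_pvalue:.10g}", omega,
                    ]
                )
                + "\n"
            )


def read_model_store(prefix) -> list[ImputationModel]:
    prefix = str(prefix)
    with _open_text(prefix + ".genes.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _GENE_COLS:
            raise FormatError(f"{prefix}.genes.tsv: bad header {header}")
        gene_rows = {}
        order = []
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_GENE_COLS):
                raise FormatError(f"{prefix}.genes.tsv line {ln}: bad field count")
            gene_rows[parts[0]] = parts
            order.append(parts[0])
    per_gene: dict[str, list] = {g: [] for g in gene_rows}
    with _open_text(prefix + ".weights.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _WEIGHT_COLS:
            raise FormatError(f"{prefix}.weights.tsv: bad header {header}")
        for ln, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_WEIGHT_COLS):
                raise FormatError(
                    f"{prefix}.weights.tsv line {ln}: bad field count"
                )
            gene = parts[0]
            if gene not in per_gene:
                raise FormatError(
                    f"{prefix}.weights.tsv line {ln}: gene '{gene}' not in sidecar"
                )
            try:
                per_gene[gene].append(
                    (
                        SnpRecord(
                            snp_id=parts[1], chrom=parts[2], pos=int(parts[3]),
                            allele_ref=parts[4], allele_alt=parts[5],
                            maf=float(parts[6]),
                        ),
                        float(parts[7]), float(parts[8]), float(parts[9]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{prefix}.weights.tsv line {ln}: {exc}") from exc
    models = []
    for gene in order:
        _, tissue, method, cv_r2, cv_p, omega = gene_rows[gene]
        rows = per_gene[gene]
        models.append(
            ImputationModel(
                gene_id=gene,
                tissue=tissue,
                snps=[r[0] for r in rows],
                train_mean=np.array([r[1] for r in rows]),
                beta_hat=np.array([r[2] for r in rows]),
                pps=np.array([r[3] for r in rows]),
                omega_hat=np.array([float(v) for v in omega.split(";")]),
                method_tag=method,
                cv_r2=float(cv_r2),
                cv_pvalue=float(cv_p),
            )
        )
    return models
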