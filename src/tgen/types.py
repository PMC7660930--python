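"""Domain containers shared across the pipeline.

The objects here are thin, validated dataclasses around numpy arrays:
a genotype dosage panel, per-gene expression, the SNP-by-track epigenetic
annotation matrix, GWAS summary statistics, and the fitted per-gene
imputation model.  All heavier machinery (file formats, inference) lives
in sibling modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnpRecord",
    "GenotypePanel",
    "GeneInfo",
    "ExpressionVector",
    "AnnotationMatrix",
    "GwasSummary",
    "PriorConfig",
    "VariationalState",
    "GridFit",
    "ImputationModel",
    "CvReport",
    "AlignedModelGwas",
    "AssociationResult",
]

#: complementary base pairs whose strand cannot be resolved from alleles alone
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_ambiguous(ref: str, alt: str) -> bool:
    """True for strand-ambiguous SNPs (A/T or C/G); indels are never ambiguous."""
    return (ref.upper(), alt.upper()) in AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class SnpRecord:
    """Identity and metadata of one biallelic variant."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    allele_ref: str
    allele_alt: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 <= self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in [0, 0.5], got {self.maf}")
        if not self.allele_ref or not self.allele_alt:
            raise ValueError(f"{self.snp_id}: alleles must be non-empty")
        if self.allele_ref == self.allele_alt:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")

    @property
    def ambiguous(self) -> bool:
        return is_ambiguous(self.allele_ref, self.allele_alt)


@dataclass
class GenotypePanel:
    """Sample-by-SNP dosage matrix (alt-allele counts in [0, 2]).

    ``dosages`` may contain NaN before QC; :func:`tgen.preprocess.qc_filter`
    mean-imputes them.  Row order is the sample order shared with any paired
    :class:`ExpressionVector`.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2.0 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def subset_snps(self, idx: np.ndarray | list[int]) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx].copy(),
        )

    def subset_samples(self, idx: np.ndarray | list[int]) -> "GenotypePanel":
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in idx],
            snps=list(self.snps),
            dosages=self.dosages[idx, :].copy(),
        )


@dataclass(frozen=True)
class GeneInfo:
    """Gene coordinates defining the cis window (genomic, 1-based, tss <= tes)."""

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: tss ({self.tss}) > tes ({self.tes})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class ExpressionVector:
    """Covariate-adjusted residual expression for one gene, sample-aligned."""

    gene_id: str
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != len(self.sample_ids):
            raise ValueError(
                f"{self.gene_id}: {len(self.values)} values for "
                f"{len(self.sample_ids)} samples"
            )


@dataclass
class AnnotationMatrix:
    """SNP-by-track continuous epigenetic values after significance masking.

    Values are non-negative (fold enrichments over background for
    histone-mark / DNase signal, methylated-read fractions for DNA
    methylation).  ``masked`` flags entries zeroed because the underlying
    signal was not significant; masked entries are exactly 0.
    """

    track_names: list[str]
    values: np.ndarray
    masked: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.track_names):
            raise ValueError(
                f"{self.values.shape[1]} value columns for "
                f"{len(self.track_names)} tracks"
            )
        if np.any(self.values < 0):
            raise ValueError("annotation values must be non-negative")
        if self.masked is None:
            self.masked = np.zeros_like(self.values, dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)
            if self.masked.shape != self.values.shape:
                raise ValueError("masked indicator shape mismatch")
            if np.any(self.values[self.masked] != 0):
                raise ValueError("masked entries must be exactly 0")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_tracks(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, idx: np.ndarray | list[int]) -> "AnnotationMatrix":
        idx = np.asarray(idx, dtype=int)
        return AnnotationMatrix(
            track_names=list(self.track_names),
            values=self.values[idx, :].copy(),
            masked=self.masked[idx, :].copy(),
        )

    @staticmethod
    def empty(n_snps: int) -> "AnnotationMatrix":
        """Annotation-free design (zero tracks): the vb-baseline reduction."""
        return AnnotationMatrix(track_names=[], values=np.zeros((n_snps, 0)))


@dataclass
class GwasSummary:
    """Per-SNP GWAS summary statistics.

    ``records`` maps snp_id -> (allele1, allele2, z) where z is the
    association z-score for the allele2 dosage (allele1 is the other
    allele).  ``n_gwas`` is the GWAS sample size.
    """

    records: dict[str, tuple[str, str, float]]
    n_gwas: int
    positions: dict[str, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_gwas < 1:
            raise ValueError("n_gwas must be positive")
        for snp_id, (a1, a2, z) in self.records.items():
            if a1 == a2:
                raise ValueError(f"{snp_id}: GWAS alleles must be distinct")
            if not np.isfinite(z):
                raise ValueError(f"{snp_id}: non-finite z")


# ---------------------------------------------------------------------------
# inference-side containers
# ---------------------------------------------------------------------------


@dataclass
class PriorConfig:
    """Hyper-priors and the hyperparameter grid for the variational fit.

    ``a, b`` parameterize the inverse-gamma prior on the noise variance
    sigma2; ``c, d`` the inverse-gamma prior on the (relative) slab variance
    sigma_beta2; ``a0, b0`` the gamma prior on the annotation-coefficient
    precision eta.  ``theta_grid`` is either an explicit list of
    (sigma2, sigma_beta2, eta) triples or "auto", which expands to
    sigma_beta2 in {0.001, 0.01, 0.1, 1} x eta in {1, 10} with sigma2
    profiled at its coordinate-wise optimum during the fit.
    """

    a: float = 0.01
    b: float = 0.01
    c: float = 0.01
    d: float = 0.01
    a0: float = 1.0
    b0: float = 1.0
    theta_grid: list[tuple[float, float, float]] | str = "auto"
    tol: float = 1e-4
    max_iter: int = 500

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d", "a0", "b0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PriorConfig.{name} must be positive")

    def resolve_grid(self, var_y: float) -> tuple[list[tuple[float, float, float]], bool]:
        """Return (grid, profile_sigma2).

        For the auto grid, sigma2 entries start at var(Y) and are profiled
        during the fit; explicit grids hold sigma2 fixed.
        """
        if isinstance(self.theta_grid, str):
            if self.theta_grid != "auto":
                raise ValueError(f"unknown theta_grid '{self.theta_grid}'")
            s2 = max(var_y, 1e-8)
            grid = [
                (s2, sb2, eta)
                for sb2 in (0.001, 0.01, 0.1, 1.0)
                for eta in (1.0, 10.0)
            ]
            return grid, True
        grid = [tuple(float(v) for v in t) for t in self.theta_grid]
        if not grid:
            raise ValueError("theta_grid must be non-empty")
        for t in grid:
            if len(t) != 3 or any(v <= 0 for v in t):
                raise ValueError(f"invalid grid point {t}")
        return grid, False


@dataclass
class VariationalState:
    """Converged (or flagged) variational solution at one grid point.

    ``alpha[k]`` approximates P(gamma_k = 1 | X, Y, theta); ``mu``/``s2``
    are the conditional posterior mean/variance of beta_k given inclusion;
    ``omega_mean``/``omega_cov`` the Gaussian posterior of the annotation
    coefficients (intercept first); ``xi`` the local parameters of the
    quadratic logistic bound.
    """

    alpha: np.ndarray
    mu: np.ndarray
    s2: np.ndarray
    omega_mean: np.ndarray
    omega_cov: np.ndarray
    xi: np.ndarray
    elbo_trace: list[float]
    sigma2: float
    sigma_beta2: float
    eta: float
    converged: bool
    n_iter: int

    @property
    def elbo(self) -> float:
        return self.elbo_trace[-1]


@dataclass
class GridFit:
    """Per-grid-point states and their normalized posterior weights."""

    states: list[VariationalState]
    log_weights: np.ndarray

    def __post_init__(self) -> None:
        self.log_weights = np.asarray(self.log_weights, dtype=float)
        total = np.exp(self.log_weights).sum()
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"grid weights sum to {total}, expected 1")

    @property
    def weights(self) -> np.ndarray:
        return np.exp(self.log_weights)


@dataclass
class ImputationModel:
    """Fitted per-gene, per-tissue expression imputation model.

    ``beta_hat`` is the grid-averaged posterior-mean effect (sum over theta
    of weight * alpha * mu), the weights of the prediction rule
    Yhat = X_centered beta_hat; ``pps`` the grid-averaged inclusion
    probability per SNP; ``train_mean`` the training-panel dosage means
    used for centering at prediction time.
    """

    gene_id: str
    tissue: str
    snps: list[SnpRecord]
    beta_hat: np.ndarray
    pps: np.ndarray
    train_mean: np.ndarray
    omega_hat: np.ndarray
    method_tag: str = "tgen"
    cv_r2: float = float("nan")
    cv_pvalue: float = float("nan")

    VALID_TAGS = ("tgen", "vb", "vb.annot", "elnt", "elnt.annot")

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float).ravel()
        self.pps = np.asarray(self.pps, dtype=float).ravel()
        self.train_mean = np.asarray(self.train_mean, dtype=float).ravel()
        self.omega_hat = np.asarray(self.omega_hat, dtype=float).ravel()
        p = len(self.snps)
        if not (len(self.beta_hat) == len(self.pps) == len(self.train_mean) == p):
            raise ValueError(
                f"{self.gene_id}: beta/pps/train_mean lengths must equal "
                f"{p} SNPs"
            )
        if self.method_tag not in self.VALID_TAGS:
            raise ValueError(f"unknown method_tag '{self.method_tag}'")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass
class CvReport:
    """K-fold cross-validation diagnostics for one gene model."""

    gene_id: str
    folds: list[np.ndarray]
    r2: float
    pvalue: float
    per_fold_r2: list[float]
    method_tag: str = "tgen"

    def __post_init__(self) -> None:
        n = sum(len(f) for f in self.folds)
        all_idx = np.sort(np.concatenate(self.folds))
        if not np.array_equal(all_idx, np.arange(n)):
            raise ValueError("folds must partition the samples")
        if not np.isfinite(self.r2):
            raise ValueError("r2 must be finite")


@dataclass
class AlignedModelGwas:
    """Model SNPs harmonized to GWAS z-scores plus reference-panel scalings.

    ``lambda_diag`` holds the per-SNP ratio sd(dosage) / sd(imputed
    expression) on the reference panel — the diagonal of the Lambda matrix
    converting SNP-level GWAS z-scores into the gene-level z.
    """

    snp_ids: list[str]
    z: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    kept_idx: np.ndarray | None = None  # model-row indices of kept SNPs
    snp_sd: np.ndarray | None = None
    pred_sd: float | None = None
    lambda_diag: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float).ravel()
        if len(self.z) != len(self.snp_ids):
            raise ValueError("z length must match snp_ids")
        if self.lambda_diag is not None:
            self.lambda_diag = np.asarray(self.lambda_diag, dtype=float)
            if np.any(self.lambda_diag <= 0):
                raise ValueError("lambda_diag must be positive")


@dataclass
class AssociationResult:
    """Gene-tissue association z-score against one trait."""

    gene_id: str
    tissue: str
    z: float
    pvalue: float
    n_snps_used: int
    significant: bool = False
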