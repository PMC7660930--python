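"""Synthetic genotype / annotation / expression / GWAS generator.

Emulates the statistical structure the imputation model assumes, so every
pipeline stage is testable without external cohorts:

* dosages are Binomial(2, maf) draws coupled through a latent Gaussian
  AR(1) copula, inducing the adjacent-SNP linkage disequilibrium that a
  real cis window shows;
* epigenetic annotations are sparse non-negative marks (most SNPs carry an
  exact zero, standing in for non-significant signal after masking; the
  rest draw Exponential fold-enrichment-like values);
* eQTL status follows gamma_k ~ Bernoulli(pi_k) with
  logit(pi_k) = omega_0 + A_k omega_slopes, and effects
  beta_k | gamma_k=1 ~ N(0, sigma_beta2 * sigma2);
* expression is Y = X_c beta + N(0, sigma2);
* the trait in an independent GWAS cohort is mediated through expression,
  T = kappa (X_c beta) + noise, scaled to unit trait variance, and per-SNP
  GWAS z-scores come from actual marginal regressions (t-statistics), with
  a further independent cohort serving as the LD/SD reference panel.

All generators are pure functions of (config, seed); ground truth (which
SNPs are causal, their effects and prior probabilities, realized
heritability) is exported for recovery tests.

What this generator does NOT emulate: recombination-map LD beyond AR(1),
population structure, trans effects, and non-Gaussian expression noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import (
    AnnotationMatrix,
    ExpressionVector,
    GenotypePanel,
    GwasSummary,
    SnpRecord,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimDataset",
    "simulate_panel",
    "simulate_annotated_effects",
    "simulate_expression",
    "simulate_gwas",
    "simulate_gwas_cohort",
    "simulate_dataset",
]


@dataclass
class SimConfig:
    """Study conditions for one simulated gene.

    Defaults describe a realistic single-gene cis region: 200 candidate
    SNPs in a 2 Mb window with moderate adjacent-SNP LD (rho = 0.3), one
    informative epigenetic track with 80% of SNPs carrying no significant
    signal, a logit prior of -2 (baseline inclusion ~0.12) with slope +2,
    and a relative slab variance giving cis heritability around 0.3.
    """

    n_train: int = 500
    n_gwas: int = 5000
    n_ref: int = 500
    p: int = 200
    m: int = 1
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.3
    omega_true: tuple[float, ...] = (-2.0, 2.0)
    annot_sparsity: float = 0.8
    annot_scale: float = 1.0
    sigma_beta2: float = 0.03
    sigma2: float = 1.0
    kappa: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_gwas, self.n_ref, self.p, self.m + 1) <= 0:
            raise ValueError("all sizes must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if len(self.omega_true) != self.m + 1:
            raise ValueError(
                f"omega_true must have length m+1 = {self.m + 1}"
            )
        if min(self.sigma_beta2, self.sigma2) <= 0:
            raise ValueError("variances must be positive")


@dataclass
class SimTruth:
    """Generator-side ground truth for recovery tests."""

    gamma_true: np.ndarray
    beta_true: np.ndarray
    pi_true: np.ndarray
    heritability_realized: float = float("nan")

    def __post_init__(self) -> None:
        if np.any(self.beta_true[~self.gamma_true.astype(bool)] != 0):
            raise ValueError("beta_true must be zero where gamma_true is false")

    def to_json(self) -> str:
        return json.dumps(
            {
                "gamma_true": self.gamma_true.astype(int).tolist(),
                "beta_true": self.beta_true.tolist(),
                "pi_true": self.pi_true.tolist(),
                "heritability_realized": self.heritability_realized,
            }
        )

    @staticmethod
    def from_json(text: str) -> "SimTruth":
        d = json.loads(text)
        return SimTruth(
            gamma_true=np.array(d["gamma_true"], dtype=bool),
            beta_true=np.array(d["beta_true"]),
            pi_true=np.array(d["pi_true"]),
            heritability_realized=d["heritability_realized"],
        )


_BASES = ("A", "C", "G", "T")


def _draw_dosages(rng, n, mafs, ld_rho) -> np.ndarray:
    """Binomial(2, maf) dosages with an AR(1) Gaussian copula across SNPs."""
    p = len(mafs)
    z = np.empty((n, p))
    z[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov = rng.standard_normal((n, p - 1))
        scale = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, p):
            z[:, j] = ld_rho * z[:, j - 1] + scale * innov[:, j - 1]
    u = stats.norm.cdf(z)
    # two latent uniforms per diplotype, correlated through the shared copula
    z2 = np.empty((n, p))
    z2[:, 0] = rng.standard_normal(n)
    if p > 1:
        innov2 = rng.standard_normal((n, p - 1))
        scale = np.sqrt(1.0 - ld_rho**2)
        for j in range(1, p):
            z2[:, j] = ld_rho * z2[:, j - 1] + scale * innov2[:, j - 1]
    u2 = stats.norm.cdf(z2)
    dos = (u < mafs).astype(float) + (u2 < mafs).astype(float)
    return dos


def simulate_panel(config: SimConfig, seed: int | None = None) -> GenotypePanel:
    """Dosage panel with AR(1)-copula LD inside a synthetic 2 Mb cis window."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*config.maf_range, size=config.p)
    dos = _draw_dosages(rng, config.n_train, mafs, config.ld_rho)
    positions = np.sort(
        rng.choice(np.arange(1_000_000, 3_000_000), size=config.p, replace=False)
    )
    snps = []
    for j in range(config.p):
        ref, alt = rng.choice(4, size=2, replace=False)
        # avoid strand-ambiguous pairs so QC keeps every simulated SNP
        while (_BASES[ref], _BASES[alt]) in {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}:
            ref, alt = rng.choice(4, size=2, replace=False)
        emp = dos[:, j].mean() / 2.0
        snps.append(
            SnpRecord(
                snp_id=f"rs{j:05d}",
                chrom="1",
                pos=int(positions[j]),
                allele_ref=_BASES[ref],
                allele_alt=_BASES[alt],
                maf=float(min(emp, 1.0 - emp)),
            )
        )
    return GenotypePanel(
        sample_ids=[f"S{i:05d}" for i in range(config.n_train)],
        snps=snps,
        dosages=dos,
    )


def simulate_annotated_effects(
    panel: GenotypePanel, config: SimConfig, seed: int | None = None
) -> tuple[AnnotationMatrix, SimTruth]:
    """Sparse annotations, annotation-dependent eQTL status, and effects."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    p, m = panel.n_snps, config.m
    present = rng.random((p, m)) >= config.annot_sparsity
    values = np.where(present, rng.exponential(config.annot_scale, (p, m)), 0.0)
    ann = AnnotationMatrix(
        track_names=[f"mark{t}" for t in range(m)],
        values=values,
        masked=~present,
    )
    omega = np.asarray(config.omega_true)
    pi_true = 1.0 / (1.0 + np.exp(-(omega[0] + values @ omega[1:])))
    gamma = rng.random(p) < pi_true
    beta = np.zeros(p)
    beta[gamma] = rng.normal(
        0.0, np.sqrt(config.sigma_beta2 * config.sigma2), gamma.sum()
    )
    return ann, SimTruth(gamma_true=gamma, beta_true=beta, pi_true=pi_true)


def simulate_expression(
    panel: GenotypePanel,
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
) -> ExpressionVector:
    """Y = X_centered beta_true + N(0, sigma2); realized h2 recorded."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 2)
    Xc = panel.dosages - panel.dosages.mean(axis=0)
    genetic = Xc @ truth.beta_true
    noise = rng.normal(0.0, np.sqrt(config.sigma2), panel.n_samples)
    y = genetic + noise
    var_y = float(np.var(y))
    truth.heritability_realized = float(np.var(genetic) / var_y) if var_y > 0 else 0.0
    return ExpressionVector(
        gene_id="gene_sim", sample_ids=list(panel.sample_ids), values=y
    )


def _marginal_z(dosages: np.ndarray, trait: np.ndarray) -> np.ndarray:
    """Per-SNP marginal-regression t-statistics (the GWAS z-scores)."""
    n = len(trait)
    xc = dosages - dosages.mean(axis=0)
    tc = trait - trait.mean()
    sxx = np.sum(xc**2, axis=0)
    sxy = xc.T @ tc
    bhat = sxy / sxx
    rss = np.sum(tc**2) - bhat * sxy
    se = np.sqrt(np.maximum(rss, 1e-300) / (n - 2) / sxx)
    return bhat / se


def simulate_gwas_cohort(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    panel_template: GenotypePanel | None = None,
) -> tuple[GenotypePanel, np.ndarray, GwasSummary]:
    """Individual-level GWAS cohort: genotypes, trait, and its summary stats.

    The trait is T = kappa * (X_c beta_true) + noise with the noise scaled
    so that Var(T) = 1; per-SNP z-scores are marginal-regression
    t-statistics on the cohort (summary records use A1 = ref, A2 = alt, so
    z is the alt-dosage association).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 3)
    if panel_template is None:
        panel_template = simulate_panel(config, seed=seed)
    mafs = np.clip([min(s.maf, 0.5) for s in panel_template.snps], 0.01, 0.5)
    dos = _draw_dosages(rng, config.n_gwas, mafs, config.ld_rho)
    Xc = dos - dos.mean(axis=0)
    genetic = config.kappa * (Xc @ truth.beta_true)
    var_g = float(np.var(genetic))
    if var_g >= 1.0:
        raise ValueError(f"kappa too large: mediated variance {var_g:.3f} >= 1")
    trait = genetic + rng.normal(0.0, np.sqrt(1.0 - var_g), config.n_gwas)
    z = _marginal_z(dos, trait)
    records = {
        s.snp_id: (s.allele_ref, s.allele_alt, float(z[j]))
        for j, s in enumerate(panel_template.snps)
    }
    positions = {s.snp_id: (s.chrom, s.pos) for s in panel_template.snps}
    gwas = GwasSummary(records=records, n_gwas=config.n_gwas, positions=positions)
    cohort = GenotypePanel(
        sample_ids=[f"G{i:06d}" for i in range(config.n_gwas)],
        snps=list(panel_template.snps),
        dosages=dos,
    )
    return cohort, trait, gwas


def simulate_gwas(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    panel_template: GenotypePanel | None = None,
) -> tuple[GwasSummary, GenotypePanel]:
    """GWAS summary statistics plus an independent n_ref reference panel."""
    seed = config.seed if seed is None else seed
    if panel_template is None:
        panel_template = simulate_panel(config, seed=seed)
    _, _, gwas = simulate_gwas_cohort(
        truth, config, seed=seed, panel_template=panel_template
    )
    rng = np.random.default_rng(seed + 4)
    mafs = np.clip([min(s.maf, 0.5) for s in panel_template.snps], 0.01, 0.5)
    ref_dos = _draw_dosages(rng, config.n_ref, mafs, config.ld_rho)
    reference = GenotypePanel(
        sample_ids=[f"R{i:05d}" for i in range(config.n_ref)],
        snps=list(panel_template.snps),
        dosages=ref_dos,
    )
    return gwas, reference


@dataclass
class SimDataset:
    """One fully linked simulated study."""

    panel: GenotypePanel
    annotations: AnnotationMatrix
    expression: ExpressionVector
    truth: SimTruth
    gwas: GwasSummary
    reference: GenotypePanel
    config: SimConfig | None = field(repr=False, default=None)


def simulate_dataset(config: SimConfig, seed: int | None = None) -> SimDataset:
    """Generate the full linked set: panel, annotations, expression, GWAS."""
    seed = config.seed if seed is None else seed
    panel = simulate_panel(config, seed=seed)
    ann, truth = simulate_annotated_effects(panel, config, seed=seed)
    expr = simulate_expression(panel, truth, config, seed=seed)
    gwas, reference = simulate_gwas(truth, config, seed=seed, panel_template=panel)
    return SimDataset(
        panel=panel,
        annotations=ann,
        expression=expr,
        truth=truth,
        gwas=gwas,
        reference=reference,
        config=config,
    )
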