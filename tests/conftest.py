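import numpy as np
import pytest

from tgen.synthetic import SimConfig, simulate_dataset, simulate_panel
from tgen.types import GenotypePanel, SnpRecord


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_panel(dosages, positions=None, chrom="1", alleles=None, ids=None):
    """Small hand-built panel for unit tests."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    snps = []
    for j in range(p):
        col = dosages[:, j]
        ok = col[~np.isnan(col)]
        f = ok.mean() / 2.0 if len(ok) else 0.0
        ref, alt = alleles[j] if alleles else ("A", "G")
        snps.append(
            SnpRecord(
                snp_id=(ids[j] if ids else f"s{j}"),
                chrom=chrom,
                pos=(positions[j] if positions else 100 + j),
                allele_ref=ref,
                allele_alt=alt,
                maf=float(min(f, 1 - f)),
            )
        )
    return GenotypePanel(
        sample_ids=[f"i{i}" for i in range(n)], snps=snps, dosages=dosages
    )


@pytest.fixture()
def tiny_panel(rng):
    dos = rng.integers(0, 3, size=(30, 5)).astype(float)
    dos[:, 2] = np.clip(dos[:, 2] + rng.integers(0, 2, 30), 0, 2)
    return make_panel(dos)


@pytest.fixture(scope="session")
def small_dataset():
    """One linked simulated study reused across read-only tests."""
    cfg = SimConfig(n_train=200, n_gwas=800, n_ref=200, p=30, seed=7)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_panel():
    return simulate_panel(SimConfig(n_train=120, p=12, seed=3))
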