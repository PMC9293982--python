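import numpy as np
import pytest

from desertsweep.genotype_io import GenotypeMatrix, HaplotypeMatrix, SnpRecord
from desertsweep.simulate import (
    SimConfig,
    haplotypes_to_genotypes,
    simulate_haplotypes,
)


def make_snps(n, chrom="1", spacing=1000, start=1000):
    return [
        SnpRecord(chrom=chrom, pos=start + i * spacing, id=f"snp{i}",
                  ref_allele="A", alt_allele="G")
        for i in range(n)
    ]


def make_gm(calls, pops=None, **kwargs):
    calls = np.asarray(calls, dtype=np.int16)
    n, m = calls.shape
    return GenotypeMatrix(
        snps=make_snps(m),
        samples=[f"s{i}" for i in range(n)],
        pops=pops or ["p0"] * n,
        calls=calls,
        **kwargs,
    )


def make_haps(haps, pops=None, positions=None):
    haps = np.asarray(haps, dtype=np.uint8)
    n, m = haps.shape
    if positions is not None:
        snps = [
            SnpRecord(chrom="1", pos=int(p), id=f"snp{i}",
                      ref_allele="A", alt_allele="G")
            for i, p in enumerate(positions)
        ]
    else:
        snps = make_snps(m)
    return HaplotypeMatrix(
        snps=snps,
        haplotypes=haps,
        sample_of_haplotype=[f"s{i // 2}" for i in range(n)],
        pops=pops or ["p0"] * n,
    )


@pytest.fixture(scope="session")
def sim_pair():
    """Two simulated populations (no sweeps) plus merged genotypes."""
    cfg = SimConfig(seed=42, n_pops=2, n_samples_per_pop=25, n_snps=600,
                    chrom_length_bp=3_000_000, drift_fst_target=0.05)
    haps, truth = simulate_haplotypes(cfg)
    return cfg, haps, haplotypes_to_genotypes(haps)


@pytest.fixture(scope="session")
def sim_sweep():
    """One population with an implanted hard sweep in the middle."""
    cfg = SimConfig(seed=7, n_pops=2, n_samples_per_pop=30, n_snps=1200,
                    chrom_length_bp=4_000_000, drift_fst_target=0.05,
                    sweep_specs=((0, 2_000_000, 0.7),))
    haps, truth = simulate_haplotypes(cfg)
    return cfg, haps, truth
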