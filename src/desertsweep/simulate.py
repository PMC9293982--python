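"""Synthetic inputs with known ground truth.

Generates every input the pipeline needs: phased multi-population
haplotypes with distance-decaying background LD and implanted hard sweeps,
diploid genotypes with planted QC violations, a toy tiled gene annotation
and a stage-structured expression matrix.  All generators are pure
functions of (config, seed): a fixed seed gives byte-identical outputs.

Haplotypes are built as recombinant mosaics of population founder
haplotypes (segment lengths geometric in bp), not from a coalescent model:
the target properties are decaying LD and tunable between-population
differentiation, not demographic realism.  Hard sweeps are implanted by
overwriting a fraction of one population's haplotypes with a single donor
haplotype over a window around the sweep position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression import ExpressionMatrix, fpkm_from_counts
from .genotype_io import (
    MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    HaplotypeMatrix,
    SnpRecord,
    write_gff,
    write_plink,
    write_vcf,
)


@dataclass(frozen=True)
class ExpressionSimConfig:
    n_genes: int = 500
    stages: tuple[str, ...] = ("FP", "LP", "P30", "P45")
    reps_per_stage: int = 3
    n_de_per_stage: int = 10
    effect_fold: float = 4.0
    noise_cv: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_pops: int = 2
    n_samples_per_pop: int = 50
    n_snps: int = 2000
    chrom_length_bp: int = 10_000_000
    chrom: str = "1"
    mosaic_segment_len_bp: int = 50_000
    n_founders: int = 60
    drift_fst_target: float = 0.05
    # (population index, position bp, carrier_fraction)
    sweep_specs: tuple[tuple[int, int, float], ...] = ()
    sweep_window_bp: int = 400_000
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)

    def __post_init__(self) -> None:
        for pop, pos, frac in self.sweep_specs:
            if not (0 <= pop < self.n_pops):
                raise ValueError(f"sweep population {pop} out of range")
            if not (1 <= pos <= self.chrom_length_bp):
                raise ValueError(f"sweep position {pos} outside the chromosome")
            if not (0 < frac <= 1):
                raise ValueError("carrier_fraction must be in (0,1]")


@dataclass
class GroundTruth:
    sweep_snps: dict[int, list[int]] = field(default_factory=dict)  # pop -> SNP idx
    qc_violations: dict[str, list[int]] = field(default_factory=dict)
    de_genes: dict[str, list[str]] = field(default_factory=dict)    # stage -> ids

    def to_dict(self) -> dict:
        return {
            "sweep_snps": {str(k): v for k, v in self.sweep_snps.items()},
            "qc_violations": self.qc_violations,
            "de_genes": self.de_genes,
        }


def _positions(rng: np.random.Generator, n_snps: int, length: int) -> np.ndarray:
    """Roughly even spacing with jitter; strictly increasing, within range."""
    base = np.linspace(1, length, n_snps + 2)[1:-1]
    gap = base[1] - base[0] if n_snps > 1 else length / 2
    pos = base + rng.uniform(-0.4, 0.4, size=n_snps) * gap
    pos = np.sort(np.round(pos).astype(np.int64))
    pos = np.maximum.accumulate(pos + np.arange(n_snps))  # enforce strict order
    return np.clip(pos, 1, length + n_snps)


def _snp_records(config: SimConfig, pos: np.ndarray) -> list[SnpRecord]:
    return [
        SnpRecord(
            chrom=config.chrom,
            pos=int(p),
            id=f"snp{j}",
            ref_allele="A",
            alt_allele="G",
            anc_allele="ref",
        )
        for j, p in enumerate(pos)
    ]


def simulate_haplotypes(
    config: SimConfig,
) -> tuple[list[HaplotypeMatrix], GroundTruth]:
    """Per-population phased haplotype matrices plus ground truth.

    Allele 0 is ancestral by construction.  Founder allele frequencies are
    drawn from a U-shaped distribution; per-population frequencies drift
    via a Balding–Nichols beta with F = ``drift_fst_target``.
    """
    rng = np.random.default_rng(config.seed)
    pos = _positions(rng, config.n_snps, config.chrom_length_bp)
    snps = _snp_records(config, pos)

    anc_freq = np.clip(rng.beta(0.8, 0.8, size=config.n_snps), 0.05, 0.95)
    F = config.drift_fst_target
    truth = GroundTruth()
    out: list[HaplotypeMatrix] = []
    for pop in range(config.n_pops):
        if F > 0:
            shape = (1 - F) / F
            pop_freq = rng.beta(anc_freq * shape, (1 - anc_freq) * shape)
            pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
        else:
            pop_freq = anc_freq
        founders = (
            rng.random((config.n_founders, config.n_snps)) < pop_freq
        ).astype(np.uint8)

        n_hap = 2 * config.n_samples_per_pop
        haps = np.empty((n_hap, config.n_snps), dtype=np.uint8)
        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-gaps / config.mosaic_segment_len_bp)
        cols = np.arange(config.n_snps)
        for h in range(n_hap):
            switches = rng.random(config.n_snps - 1) < p_switch
            seg = np.concatenate([[0], np.cumsum(switches)])
            donors = rng.integers(config.n_founders, size=int(seg[-1]) + 1)
            haps[h, :] = founders[donors[seg], cols]

        for spec_pop, sweep_pos, frac in config.sweep_specs:
            if spec_pop != pop:
                continue
            lo = int(np.searchsorted(pos, sweep_pos - config.sweep_window_bp // 2))
            hi = int(np.searchsorted(pos, sweep_pos + config.sweep_window_bp // 2,
                                     side="right"))
            core = int(np.argmin(np.abs(pos - sweep_pos)))
            donor_hap = haps[0, lo:hi].copy()
            donor_hap[core - lo] = 1  # derived allele rides the sweep
            n_carriers = int(np.ceil(frac * n_hap))
            carriers = rng.choice(n_hap, size=n_carriers, replace=False)
            haps[np.ix_(carriers, np.arange(lo, hi))] = donor_hap
            truth.sweep_snps.setdefault(pop, []).append(core)

        samples = [f"pop{pop}_s{i}" for i in range(config.n_samples_per_pop)]
        out.append(
            HaplotypeMatrix(
                snps=list(snps),
                haplotypes=haps,
                sample_of_haplotype=[s for s in samples for _ in range(2)],
                pops=[f"pop{pop}"] * n_hap,
            )
        )
    return out, truth


def haplotypes_to_genotypes(haps_list: Sequence[HaplotypeMatrix]) -> GenotypeMatrix:
    """Pair consecutive haplotypes into phased diploid samples and merge
    populations into one matrix."""
    snps = list(haps_list[0].snps)
    samples: list[str] = []
    pops: list[str] = []
    a0_rows, a1_rows = [], []
    for haps in haps_list:
        if [s.id for s in haps.snps] != [s.id for s in snps]:
            raise ValueError("populations must share one SNP panel")
        for i in range(0, haps.n_haplotypes, 2):
            samples.append(haps.sample_of_haplotype[i])
            pops.append(haps.pops[i])
            a0_rows.append(haps.haplotypes[i, :])
            a1_rows.append(haps.haplotypes[i + 1, :])
    a0 = np.array(a0_rows, dtype=np.int16)
    a1 = np.array(a1_rows, dtype=np.int16)
    return GenotypeMatrix(
        snps=snps,
        samples=samples,
        pops=pops,
        calls=(a0 + a1).astype(np.int16),
        allele0=a0,
        allele1=a1,
        phased=np.ones(a0.shape, dtype=bool),
    )


def simulate_genotypes_for_qc(
    config: SimConfig,
    n_fail_callrate: int = 10,
    n_fail_maf: int = 10,
    n_fail_hwe: int = 5,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Diploid genotypes with disjoint planted QC violations.

    Clean SNPs: full call rate, allele frequency in [0.2, 0.8],
    Hardy–Weinberg genotype proportions.  Call-rate violators get ~20%
    missing calls; MAF violators a 0.01 allele frequency; HWE violators an
    extreme heterozygote deficit (all homozygotes at 50/50 frequency).
    """
    n_planted = n_fail_callrate + n_fail_maf + n_fail_hwe
    if n_planted > config.n_snps:
        raise ValueError("more planted violations than SNPs")
    rng = np.random.default_rng(config.seed)
    n = config.n_pops * config.n_samples_per_pop
    pos = _positions(rng, config.n_snps, config.chrom_length_bp)
    snps = _snp_records(config, pos)

    freqs = rng.uniform(0.2, 0.8, size=config.n_snps)
    calls = (
        (rng.random((n, config.n_snps)) < freqs).astype(np.int16)
        + (rng.random((n, config.n_snps)) < freqs).astype(np.int16)
    )

    planted = rng.choice(config.n_snps, size=n_planted, replace=False)
    cr_idx = planted[:n_fail_callrate]
    maf_idx = planted[n_fail_callrate : n_fail_callrate + n_fail_maf]
    hwe_idx = planted[n_fail_callrate + n_fail_maf :]

    for j in cr_idx:  # >10% missing, margin above the 0.90 threshold
        n_miss = max(int(np.ceil(0.20 * n)), int(np.floor(0.10 * n)) + 2)
        rows = rng.choice(n, size=n_miss, replace=False)
        calls[rows, j] = MISSING
    for j in maf_idx:  # rare but polymorphic
        col = np.zeros(n, dtype=np.int16)
        n_het = max(1, int(np.floor(2 * n * 0.01)))
        col[rng.choice(n, size=n_het, replace=False)] = 1
        calls[:, j] = col
    for j in hwe_idx:  # all homozygotes at p = 0.5: extreme het deficit
        col = np.full(n, 2, dtype=np.int16)
        col[rng.choice(n, size=n // 2, replace=False)] = 0
        calls[:, j] = col

    truth = GroundTruth(
        qc_violations={
            "callrate": sorted(int(j) for j in cr_idx),
            "maf": sorted(int(j) for j in maf_idx),
            "hwe": sorted(int(j) for j in hwe_idx),
        }
    )
    samples = [f"s{i}" for i in range(n)]
    pops = [f"pop{i % config.n_pops}" for i in range(n)]
    return GenotypeMatrix(snps=snps, samples=samples, pops=pops, calls=calls), truth


def simulate_expression(
    config: SimConfig,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray, GroundTruth]:
    """Stage-structured FPKM matrix with planted stage-specific genes.

    Returns (matrix, counts, gene_lengths, truth).  Integer fragment counts
    are derived so that FPKM recomputed from them reproduces the matrix
    exactly (the matrix IS the count-derived FPKM).
    """
    e = config.expression
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes = [f"g{i}" for i in range(e.n_genes)]
    sample_ids = [
        f"{stage}_r{r}" for stage in e.stages for r in range(e.reps_per_stage)
    ]
    stage_of_sample = [stage for stage in e.stages for _ in range(e.reps_per_stage)]
    n_samples = len(sample_ids)

    base = rng.lognormal(mean=3.0, sigma=1.0, size=e.n_genes)
    target = np.tile(base[:, None], (1, n_samples))

    truth = GroundTruth()
    pool = rng.permutation(e.n_genes)
    for si, stage in enumerate(e.stages):
        de = pool[si * e.n_de_per_stage : (si + 1) * e.n_de_per_stage]
        cols = [k for k, s in enumerate(stage_of_sample) if s == stage]
        target[np.ix_(de, cols)] *= e.effect_fold
        truth.de_genes[stage] = [genes[i] for i in sorted(de)]

    if e.noise_cv > 0:
        sigma = np.sqrt(np.log1p(e.noise_cv**2))
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                              size=target.shape)
        target = target * noise

    lengths = rng.integers(500, 5000, size=e.n_genes).astype(float)
    total = 1_000_000.0  # same depth per sample so cv=0 => identical reps
    counts = np.rint(target * total * lengths[:, None] / 1e9)
    values = fpkm_from_counts(counts, lengths, totals=[total] * n_samples)
    matrix = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=sample_ids,
        stage_of_sample=stage_of_sample,
        values=values,
    )
    return matrix, counts, lengths, truth


def tiled_annotation(config: SimConfig, gene_len: int = 10_000,
                     spacing: int = 20_000) -> GeneAnnotation:
    """Evenly tiled toy genes across the simulated chromosome: one gene per
    ``spacing`` bp, so the count is chrom_length_bp // spacing."""
    genes = []
    n_genes = config.chrom_length_bp // spacing
    for k in range(n_genes):
        start = k * spacing + 1
        genes.append((f"gene{k}", config.chrom, start, start + gene_len - 1))
    return GeneAnnotation(genes=genes)


def emit_fixture_bundle(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete text fixture bundle; byte-stable under a fixed seed.

    Emits a merged phased VCF + population map, a PLINK pair, a GFF3
    annotation, expression TSVs (FPKM, counts, lengths, stage map) and the
    ground-truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    haps_list, truth = simulate_haplotypes(config)
    g = haplotypes_to_genotypes(haps_list)

    paths = {
        "vcf": out / "genotypes.vcf",
        "pop_map": out / "pop_map.tsv",
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "gff": out / "genes.gff3",
        "fpkm": out / "expression_fpkm.tsv",
        "counts": out / "expression_counts.tsv",
        "lengths": out / "gene_lengths.tsv",
        "stages": out / "sample_stages.tsv",
        "truth": out / "ground_truth.json",
    }
    write_vcf(g, paths["vcf"])
    with open(paths["pop_map"], "w") as fh:
        for s, p in zip(g.samples, g.pops):
            fh.write(f"{s}\t{p}\n")
    write_plink(g, paths["ped"], paths["map"])
    write_gff(tiled_annotation(config), paths["gff"])

    expr, counts, lengths, etruth = simulate_expression(config)
    truth.de_genes = etruth.de_genes
    _write_matrix_tsv(paths["fpkm"], expr.gene_ids, expr.sample_ids, expr.values)
    _write_matrix_tsv(paths["counts"], expr.gene_ids, expr.sample_ids, counts)
    with open(paths["lengths"], "w") as fh:
        fh.write("gene_id\tlength\n")
        for gid, L in zip(expr.gene_ids, lengths):
            fh.write(f"{gid}\t{int(L)}\n")
    with open(paths["stages"], "w") as fh:
        fh.write("sample_id\tstage\n")
        for s, st in zip(expr.sample_ids, expr.stage_of_sample):
            fh.write(f"{s}\t{st}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _write_matrix_tsv(path: Path, gene_ids, sample_ids, values) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
        for gid, row in zip(gene_ids, np.asarray(values)):
            fh.write(gid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
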