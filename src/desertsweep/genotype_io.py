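"""Readers/writers for the standard formats the pipeline touches.

Builds validated in-memory genotype, haplotype and annotation objects from
VCF, PLINK text (.ped/.map), GFF3 and TSV score tables, and serializes them
back.  Coordinates are 1-based inclusive throughout, matching VCF/GFF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing diploid call in ``GenotypeMatrix.calls``
MISSING = -1

ANC_POLICIES = ("major_allele", "alt_is_derived", "from_info_tag")


@dataclass(frozen=True)
class SnpRecord:
    """A single biallelic SNP with 1-based physical coordinates."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    anc_allele: str = "unknown"  # one of {"ref", "alt", "unknown"}

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: ref and alt alleles are identical")
        if self.anc_allele not in ("ref", "alt", "unknown"):
            raise ValueError(f"SNP {self.id}: bad anc_allele {self.anc_allele!r}")


def _check_sorted(snps: Sequence[SnpRecord]) -> None:
    """Positions must be strictly increasing within each chromosome."""
    prev: dict[str, int] = {}
    seen_order: list[str] = []
    for s in snps:
        if s.chrom in prev:
            if seen_order and seen_order[-1] != s.chrom:
                raise ValueError(f"chromosome {s.chrom} appears in non-contiguous blocks")
            if s.pos <= prev[s.chrom]:
                raise ValueError(
                    f"SNPs on {s.chrom} not strictly increasing at pos {s.pos}"
                )
        else:
            seen_order.append(s.chrom)
        prev[s.chrom] = s.pos


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosage calls (0/1/2, ``MISSING`` = -1).

    ``allele0``/``allele1``/``phased`` are optional per-call phase arrays
    carried along when the source was a phased VCF (or the simulator); they
    are required by :func:`to_haplotypes`.
    """

    snps: list[SnpRecord]
    samples: list[str]
    pops: list[str]
    calls: np.ndarray  # (n_samples, n_snps) int8/int16
    allele0: np.ndarray | None = None
    allele1: np.ndarray | None = None
    phased: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if len(self.pops) != len(self.samples):
            raise ValueError("pops and samples must have the same length")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,-1}")
        _check_sorted(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    def sample_indices(self, pop: str | Iterable[str]) -> np.ndarray:
        """Row indices of samples belonging to ``pop`` (a label or labels)."""
        pops = {pop} if isinstance(pop, str) else set(pop)
        idx = [i for i, p in enumerate(self.pops) if p in pops]
        if not idx:
            raise KeyError(f"no samples with population label(s) {sorted(pops)}")
        return np.array(idx, dtype=np.intp)

    def subset_snps(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=np.intp)
        return GenotypeMatrix(
            snps=[self.snps[i] for i in keep],
            samples=list(self.samples),
            pops=list(self.pops),
            calls=self.calls[:, keep],
            allele0=None if self.allele0 is None else self.allele0[:, keep],
            allele1=None if self.allele1 is None else self.allele1[:, keep],
            phased=None if self.phased is None else self.phased[:, keep],
        )

    def subset_samples(self, keep: Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep, dtype=np.intp)
        return GenotypeMatrix(
            snps=list(self.snps),
            samples=[self.samples[i] for i in keep],
            pops=[self.pops[i] for i in keep],
            calls=self.calls[keep, :],
            allele0=None if self.allele0 is None else self.allele0[keep, :],
            allele1=None if self.allele1 is None else self.allele1[keep, :],
            phased=None if self.phased is None else self.phased[keep, :],
        )


@dataclass
class HaplotypeMatrix:
    """Phased, polarized haplotypes: 0 = ancestral, 1 = derived, no missing."""

    snps: list[SnpRecord]
    haplotypes: np.ndarray  # (n_haplotypes, n_snps) uint8
    sample_of_haplotype: list[str]
    pops: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (len(self.sample_of_haplotype), len(self.snps)):
            raise ValueError("haplotype matrix shape mismatch")
        if len(self.pops) != len(self.sample_of_haplotype):
            raise ValueError("pops length mismatch")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotypes must be strictly 0/1 (no missing data)")
        _check_sorted(self.snps)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps], dtype=np.int64)

    def subset_pops(self, pop: str | Iterable[str]) -> "HaplotypeMatrix":
        pops = {pop} if isinstance(pop, str) else set(pop)
        idx = [i for i, p in enumerate(self.pops) if p in pops]
        if not idx:
            raise KeyError(f"no haplotypes with population label(s) {sorted(pops)}")
        return HaplotypeMatrix(
            snps=list(self.snps),
            haplotypes=self.haplotypes[idx, :],
            sample_of_haplotype=[self.sample_of_haplotype[i] for i in idx],
            pops=[self.pops[i] for i in idx],
        )


@dataclass
class GeneAnnotation:
    """Gene spans with 1-based inclusive coordinates."""

    genes: list[tuple[str, str, int, int]]  # (gene_id, chrom, start, end)

    def __post_init__(self) -> None:
        seen = set()
        for gid, chrom, start, end in self.genes:
            if start > end:
                raise ValueError(f"gene {gid}: start {start} > end {end}")
            if gid in seen:
                raise ValueError(f"duplicate gene id {gid}")
            seen.add(gid)


# ---------------------------------------------------------------------------
# population maps
# ---------------------------------------------------------------------------

def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column whitespace/tab table: sample_id  population."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{line_no}: expected 2 columns")
            mapping[parts[0]] = parts[1]
    return mapping


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, pop_map: Mapping[str, str]) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multiallelic or non-SNP records are skipped (the count is logged).
    ``./.`` genotypes become missing.  Every sample in the VCF must appear
    in ``pop_map``.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in pop_map]
    if missing_pop:
        raise ValueError(
            "samples absent from population map: " + ", ".join(missing_pop)
        )

    snps: list[SnpRecord] = []
    rows_a0: list[np.ndarray] = []
    rows_a1: list[np.ndarray] = []
    rows_ph: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        anc = "unknown"
        aa = dict(var.INFO).get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa == var.REF.upper():
                anc = "ref"
            elif aa == var.ALT[0].upper():
                anc = "alt"
        snps.append(
            SnpRecord(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or f"{var.CHROM}:{var.POS}",
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                anc_allele=anc,
            )
        )
        gts = var.genotypes  # [[a0, a1, phased], ...]
        arr = np.array(gts, dtype=np.int16)
        rows_a0.append(arr[:, 0])
        rows_a1.append(arr[:, 1])
        rows_ph.append(arr[:, 2].astype(bool))
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNP/multiallelic records", path, skipped)

    n_snps = len(snps)
    n_samples = len(samples)
    a0 = np.stack(rows_a0, axis=1) if n_snps else np.zeros((n_samples, 0), np.int16)
    a1 = np.stack(rows_a1, axis=1) if n_snps else np.zeros((n_samples, 0), np.int16)
    ph = np.stack(rows_ph, axis=1) if n_snps else np.zeros((n_samples, 0), bool)
    miss = (a0 < 0) | (a1 < 0)
    calls = np.where(miss, MISSING, a0 + a1).astype(np.int16)
    return GenotypeMatrix(
        snps=snps,
        samples=samples,
        pops=[pop_map[s] for s in samples],
        calls=calls,
        allele0=a0,
        allele1=a1,
        phased=ph,
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2.  Phase separators follow ``g.phased``."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in g.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        have_phase = g.allele0 is not None and g.allele1 is not None
        for j, s in enumerate(g.snps):
            info = "."
            if s.anc_allele == "ref":
                info = f"AA={s.ref_allele}"
            elif s.anc_allele == "alt":
                info = f"AA={s.alt_allele}"
            fields = [s.chrom, str(s.pos), s.id, s.ref_allele, s.alt_allele,
                      ".", "PASS", info, "GT"]
            for i in range(g.n_samples):
                c = g.calls[i, j]
                if c == MISSING:
                    fields.append("./.")
                elif have_phase:
                    sep = "|" if (g.phased is not None and g.phased[i, j]) else "/"
                    fields.append(f"{g.allele0[i, j]}{sep}{g.allele1[i, j]}")
                else:
                    fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(c)])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK text
# ---------------------------------------------------------------------------

def read_plink(
    ped_path: str | Path,
    map_path: str | Path,
    ref_alleles: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read a whitespace-delimited PLINK .ped/.map pair.

    The family-ID column is used as the population label; ``0`` alleles make
    the whole genotype missing.  Calls count the non-reference allele, where
    the per-SNP reference allele is taken from ``ref_alleles`` (snp id →
    allele) when given, otherwise the first non-missing allele seen for the
    SNP in file order.
    """
    snp_meta: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}:{line_no}: expected >=4 columns")
            snp_meta.append((parts[0], parts[1], int(parts[3])))
    n_snps = len(snp_meta)

    samples: list[str] = []
    pops: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{line_no}: {len(parts) - 6} allele columns "
                    f"for {n_snps} .map SNPs"
                )
            pops.append(parts[0])
            samples.append(parts[1])
            allele_rows.append(parts[6:])

    # resolve the per-SNP reference allele
    a_ref: list[str | None] = [None] * n_snps
    a_alt: list[str | None] = [None] * n_snps
    for j in range(n_snps):
        sid = snp_meta[j][1]
        if ref_alleles and sid in ref_alleles:
            a_ref[j] = ref_alleles[sid]
        for row in allele_rows:
            for a in (row[2 * j], row[2 * j + 1]):
                if a == "0":
                    continue
                if a_ref[j] is None:
                    a_ref[j] = a
                elif a != a_ref[j] and a_alt[j] is None:
                    a_alt[j] = a
        if a_ref[j] is None:
            a_ref[j] = "A"  # fully missing column
        if a_alt[j] is None:
            a_alt[j] = "T" if a_ref[j] != "T" else "A"

    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int16)
    for i, row in enumerate(allele_rows):
        for j in range(n_snps):
            x, y = row[2 * j], row[2 * j + 1]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x != a_ref[j]) + (y != a_ref[j])

    snps = [
        SnpRecord(chrom=c, pos=p, id=sid, ref_allele=a_ref[j], alt_allele=a_alt[j])
        for j, (c, sid, p) in enumerate(snp_meta)
    ]
    return GenotypeMatrix(snps=snps, samples=samples, pops=pops, calls=calls)


def write_plink(g: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    with open(map_path, "w") as fh:
        for s in g.snps:
            fh.write(f"{s.chrom}\t{s.id}\t0\t{s.pos}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(g.samples):
            fields = [g.pops[i], sample, "0", "0", "0", "-9"]
            for j, s in enumerate(g.snps):
                c = g.calls[i, j]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [s.ref_allele, s.ref_allele]
                elif c == 1:
                    fields += [s.ref_allele, s.alt_allele]
                else:
                    fields += [s.alt_allele, s.alt_allele]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def to_haplotypes(g: GenotypeMatrix, anc_policy: str = "major_allele") -> HaplotypeMatrix:
    """Split phased diploid calls into a 0=ancestral / 1=derived matrix.

    Requires per-call phase arrays (present when ``g`` came from
    :func:`read_vcf` on a phased VCF or from the simulator).  Under
    ``major_allele`` the genome-wide major allele, pooled over all
    populations, is treated as ancestral (ties broken toward the reference
    allele); ``alt_is_derived`` keeps the 0/1 coding; ``from_info_tag`` uses
    each record's ``anc_allele`` field and errors where it is unknown.
    """
    if anc_policy not in ANC_POLICIES:
        raise ValueError(f"anc_policy must be one of {ANC_POLICIES}")
    if g.allele0 is None or g.allele1 is None or g.phased is None:
        raise ValueError("genotype matrix carries no phase information")
    for j in range(g.n_snps):
        for i in range(g.n_samples):
            if g.calls[i, j] == MISSING:
                raise ValueError(
                    f"missing genotype at sample {g.samples[i]}, SNP {g.snps[j].id}"
                )
            if not g.phased[i, j]:
                raise ValueError(
                    f"unphased genotype at sample {g.samples[i]}, SNP {g.snps[j].id}"
                )

    n_hap = 2 * g.n_samples
    haps = np.empty((n_hap, g.n_snps), dtype=np.uint8)
    haps[0::2, :] = g.allele0
    haps[1::2, :] = g.allele1

    anc_is_alt = np.zeros(g.n_snps, dtype=bool)  # flip column when True
    if anc_policy == "major_allele":
        alt_freq = haps.mean(axis=0)
        anc_is_alt = alt_freq > 0.5  # tie (==0.5) keeps ref as ancestral
    elif anc_policy == "from_info_tag":
        for j, s in enumerate(g.snps):
            if s.anc_allele == "unknown":
                raise ValueError(f"SNP {s.id}: no ancestral-allele annotation")
            anc_is_alt[j] = s.anc_allele == "alt"
    haps[:, anc_is_alt] = 1 - haps[:, anc_is_alt]

    snps = [
        SnpRecord(
            chrom=s.chrom, pos=s.pos, id=s.id,
            ref_allele=s.ref_allele, alt_allele=s.alt_allele,
            anc_allele="alt" if flip else "ref",
        )
        for s, flip in zip(g.snps, anc_is_alt)
    ]
    sample_of_hap = [s for s in g.samples for _ in range(2)]
    pops = [p for p in g.pops for _ in range(2)]
    return HaplotypeMatrix(
        snps=snps, haplotypes=haps, sample_of_haplotype=sample_of_hap, pops=pops
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> GeneAnnotation:
    """Extract ``gene`` features from a GFF3 file."""
    genes: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{line_no}: expected 9 tab-separated columns")
            chrom, _src, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            if ftype != "gene":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{line_no}: bad coordinates") from exc
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id") or f"gene_{line_no}"
            genes.append((gid, chrom, start_i, end_i))
    return GeneAnnotation(genes=genes)


def write_gff(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid, chrom, start, end in ann.genes:
            fh.write(f"{chrom}\tdesertsweep\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialize a tree (duck-typed ``.name`` / ``.children`` of
    ``(child, branch_length)`` pairs) to Newick with 6-decimal lengths."""

    def render(node) -> str:
        if not node.children:
            return node.name or ""
        inner = ",".join(
            f"{render(child)}:{length:.6f}" for child, length in node.children
        )
        return f"({inner}){node.name or ''}"

    text = render(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["chrom", "pos", "id", "stat", "raw", "std", "sig_1pct", "sig_5pct"]


def write_score_table(table, path: str | Path) -> None:
    """TSV with the fixed column header used by every scan statistic."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in table.snps],
            "pos": [s.pos for s in table.snps],
            "id": [s.id for s in table.snps],
            "stat": table.stat,
            "raw": table.raw,
            "std": table.std,
            "sig_1pct": table.sig_1pct.astype(int),
            "sig_5pct": table.sig_5pct.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing score columns {missing}")
    return df
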