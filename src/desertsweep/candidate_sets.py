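"""Candidate regions and gene sets from score tables: top-percentile SNP
selection, gene annotation with flanks, and multi-test set intersections."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genotype_io import GeneAnnotation
from .sweep_stats import ScoreTable


@dataclass
class GeneSet:
    name: str
    gene_ids: set[str]
    provenance: tuple[str, str, str]  # (statistic, comparison, threshold)


@dataclass
class UpsetMatrix:
    """Exclusive-region sizes of every non-empty membership combination."""

    set_names: list[str]
    sizes: dict[tuple[bool, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.sizes.values())


def select_top(
    scores: ScoreTable, fraction: float, tail: str = "two_sided"
) -> set[int]:
    """Indices of the ⌈fraction·n_valid⌉ most extreme standardized scores.

    ``tail``: ``upper`` (largest), ``lower`` (smallest) or ``two_sided``
    (largest |z|).  Ties at the boundary are all included.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0,1)")
    if tail not in ("upper", "lower", "two_sided"):
        raise ValueError(f"unknown tail {tail!r}")
    valid = scores.valid & np.isfinite(scores.std)
    idx = np.where(valid)[0]
    if idx.size == 0:
        raise ValueError("no valid scores")
    z = scores.std[idx]
    if tail == "upper":
        key = z
    elif tail == "lower":
        key = -z
    else:
        key = np.abs(z)
    # guard against float noise in fraction*n (e.g. 0.07*100 = 7.0000…01)
    k = max(1, math.ceil(fraction * idx.size - 1e-9))
    threshold = np.sort(key)[::-1][k - 1]
    return {int(i) for i, v in zip(idx, key) if v >= threshold}


def flag_significant(
    scores: ScoreTable, tail: str = "two_sided"
) -> ScoreTable:
    """Fill the 1%/5% significance columns of a score table in place."""
    for frac, attr in ((0.01, "sig_1pct"), (0.05, "sig_5pct")):
        sel = select_top(scores, frac, tail)
        arr = np.zeros(len(scores.snps), dtype=bool)
        arr[list(sel)] = True
        setattr(scores, attr, arr)
    return scores


def annotate_genes(
    snp_set: Sequence[int],
    scores: ScoreTable,
    annotation: GeneAnnotation,
    flank_bp: int = 50_000,
    name: str = "candidates",
    provenance: tuple[str, str, str] | None = None,
) -> GeneSet:
    """Genes whose [start−flank, end+flank] interval (inclusive) contains a
    selected SNP.  Positions are binary-searched per chromosome."""
    by_chrom: dict[str, list[int]] = {}
    for i in snp_set:
        by_chrom.setdefault(scores.snps[i].chrom, []).append(scores.snps[i].pos)
    pos_sorted = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}

    gene_chroms = {chrom for _, chrom, _, _ in annotation.genes}
    unmatched = set(by_chrom) - gene_chroms
    if unmatched and gene_chroms:
        warnings.warn(
            f"{len(unmatched)} SNP chromosome(s) absent from the annotation: "
            f"{sorted(unmatched)}",
            stacklevel=2,
        )

    hits: set[str] = set()
    for gid, chrom, start, end in annotation.genes:
        pos = pos_sorted.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, start - flank_bp, side="left")
        hi = np.searchsorted(pos, end + flank_bp, side="right")
        if hi > lo:
            hits.add(gid)
    prov = provenance or (scores.stat, "", "custom")
    return GeneSet(name=name, gene_ids=hits, provenance=prov)


def intersect_sets(sets: Sequence[GeneSet]) -> UpsetMatrix:
    """Exact exclusive-region set algebra over the given gene sets."""
    if not sets:
        raise ValueError("need at least one gene set")
    union: set[str] = set().union(*(s.gene_ids for s in sets))
    sizes: dict[tuple[bool, ...], int] = {}
    for gene in union:
        combo = tuple(gene in s.gene_ids for s in sets)
        sizes[combo] = sizes.get(combo, 0) + 1
    return UpsetMatrix(set_names=[s.name for s in sets], sizes=sizes)


def cgs(sets: Sequence[GeneSet], rule: str = "union", name: str = "CGS") -> GeneSet:
    """Candidate gene set over the per-test gene sets: ``union`` (default,
    the 1%-threshold construction) or ``intersection`` (the overlapping-
    genes-at-5% construction)."""
    if not sets:
        raise ValueError("need at least one gene set")
    if rule == "union":
        genes: set[str] = set().union(*(s.gene_ids for s in sets))
    elif rule == "intersection":
        genes = set(sets[0].gene_ids)
        for s in sets[1:]:
            genes &= s.gene_ids
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return GeneSet(name=name, gene_ids=genes, provenance=("cgs", rule, "combined"))
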