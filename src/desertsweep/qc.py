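"""Marker-level quality control: call rate, minor-allele frequency and an
exact Hardy–Weinberg test, with strict "less than" removal semantics."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QcThresholds:
    min_call_rate: float = 0.90
    min_maf: float = 0.05
    min_hwe_p: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class QcReport:
    n_input: int
    n_fail_callrate: int
    n_fail_maf: int
    n_fail_hwe: int
    n_retained: int
    fail_reasons: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_fail_callrate": self.n_fail_callrate,
            "n_fail_maf": self.n_fail_maf,
            "n_fail_hwe": self.n_fail_hwe,
            "n_retained": self.n_retained,
            "fail_reasons": self.fail_reasons,
        }


def call_rate(g: GenotypeMatrix, snp_index: int) -> float:
    """Fraction of samples with a non-missing call at the SNP."""
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    col = g.calls[:, snp_index]
    return float(np.count_nonzero(col != MISSING) / g.n_samples)


def maf(g: GenotypeMatrix, snp_index: int) -> float:
    """Minor-allele frequency among non-missing calls."""
    col = g.calls[:, snp_index]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError(f"SNP index {snp_index}: all calls missing")
    p = float(obs.sum() / (2 * obs.size))
    return min(p, 1.0 - p)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration (same parity, same allele counts) whose
    conditional probability does not exceed that of the observed table.
    Computed with exact integer weights — configuration weight
    ``n! / (nAA! nAa! naa!) * 2**nAa`` — so ties are handled exactly.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("zero total samples")
    n_a = 2 * n_aa + n_Aa
    n_minor = min(n_a, 2 * n - n_a)

    f = math.factorial
    weights: dict[int, int] = {}
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_rare = (n_minor - het) // 2
        hom_common = n - het - hom_rare
        weights[het] = f(n) // (f(hom_common) * f(het) * f(hom_rare)) * 2**het
    w_obs = weights[n_Aa]
    num = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(num, sum(weights.values())))


def _genotype_counts(g: GenotypeMatrix, snp_index: int) -> tuple[int, int, int]:
    col = g.calls[:, snp_index]
    obs = col[col != MISSING]
    return (
        int(np.count_nonzero(obs == 0)),
        int(np.count_nonzero(obs == 1)),
        int(np.count_nonzero(obs == 2)),
    )


def apply_qc(
    g: GenotypeMatrix, thresholds: QcThresholds = QcThresholds()
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing any of the three filters, evaluated on the full
    pooled sample set.  A SNP is removed when call rate < ``min_call_rate``,
    MAF < ``min_maf`` or HWE exact p < ``min_hwe_p`` (strict inequalities).
    """
    fail_reasons: dict[str, list[str]] = {}
    n_cr = n_maf = n_hwe = 0
    keep: list[int] = []
    for j in range(g.n_snps):
        reasons = []
        cr = call_rate(g, j)
        if cr < thresholds.min_call_rate:
            reasons.append("callrate")
            n_cr += 1
        has_obs = bool((g.calls[:, j] != MISSING).any())
        if has_obs:
            if maf(g, j) < thresholds.min_maf:
                reasons.append("maf")
                n_maf += 1
            if hwe_exact_p(*_genotype_counts(g, j)) < thresholds.min_hwe_p:
                reasons.append("hwe")
                n_hwe += 1
        if reasons:
            fail_reasons[g.snps[j].id] = reasons
        else:
            keep.append(j)
    report = QcReport(
        n_input=g.n_snps,
        n_fail_callrate=n_cr,
        n_fail_maf=n_maf,
        n_fail_hwe=n_hwe,
        n_retained=len(keep),
        fail_reasons=fail_reasons,
    )
    return g.subset_snps(keep), report
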