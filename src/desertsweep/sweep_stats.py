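"""Selection-sweep statistics built from scratch.

Four complementary scans over a SNP panel:

* per-SNP Weir–Cockerham FST (variance components a, b, c) with a
  ratio-of-sums genome average,
* EHH → iHH → iHS within a population,
* site-EHH (EHHS) → iES → xp-EHH and Rsb between two populations.

All integrals are over physical distance (bp); units cancel in every
ln-ratio.  Standardization: iHS within derived-allele-frequency bins,
cross-population scores genome-wide (z-score by default, median-centered
variant available for Rsb).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix, SnpRecord

FLAG_OK = "ok"
FLAG_MAF = "maf_fail"
FLAG_EDGE = "edge_truncated"
FLAG_ZERO = "zero_ihh"


@dataclass(frozen=True)
class SweepConfig:
    ehh_cutoff: float = 0.05
    core_maf_min: float = 0.05
    freq_bins: int = 20
    min_bin_count: int = 10
    edge_policy: str = "discard"       # or "truncate"
    standardize: str = "zscore"        # Rsb alternative: "median"

    def __post_init__(self) -> None:
        if not (0 < self.ehh_cutoff < 1):
            raise ValueError("ehh_cutoff must be in (0,1)")
        if self.freq_bins < 2:
            raise ValueError("freq_bins must be >= 2")
        if self.edge_policy not in ("discard", "truncate"):
            raise ValueError("edge_policy must be 'discard' or 'truncate'")


@dataclass
class EhhCurve:
    core_index: int
    side: str                        # "left", "right" or "both"
    points: list[tuple[int, float]]  # (pos bp, ehh), sorted by position
    allele_partition: str            # "ancestral", "derived" or "site"


@dataclass
class ScoreTable:
    snps: list[SnpRecord]
    stat: str
    raw: np.ndarray    # nan where invalid
    std: np.ndarray    # nan where invalid
    freq: np.ndarray   # derived-allele (or alt) frequency per SNP
    flag: np.ndarray   # str flags, FLAG_OK where valid
    sig_1pct: np.ndarray = field(default=None)
    sig_5pct: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.snps)
        if self.sig_1pct is None:
            self.sig_1pct = np.zeros(n, dtype=bool)
        if self.sig_5pct is None:
            self.sig_5pct = np.zeros(n, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        return self.flag == FLAG_OK


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def _side_ehh(
    H: np.ndarray, core: int, direction: int, cutoff: float
) -> list[tuple[int, float]]:
    """Haplotype-homozygosity decay on one side of the core.

    ``H`` holds only the rows whose homozygosity is tracked (the carriers of
    one core allele, or all haplotypes for EHHS).  Extends one SNP at a
    time, refining haplotype classes, until the value drops below
    ``cutoff`` (that first point is included), hits zero, or the chromosome
    ends.  Returns (snp_index, value) pairs.
    """
    nc = H.shape[0]
    denom = nc * (nc - 1)
    group = np.zeros(nc, dtype=np.int64)
    out: list[tuple[int, float]] = []
    j = core
    n_snps = H.shape[1]
    while True:
        j += direction
        if j < 0 or j >= n_snps:
            break
        key = group * 2 + H[:, j]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        e = float((counts * (counts - 1)).sum() / denom)
        out.append((j, e))
        if e < cutoff or e == 0.0:
            break
    return out


def ehh(
    haps: HaplotypeMatrix, core: int, allele: int, cutoff: float = 0.05
) -> EhhCurve:
    """Extended haplotype homozygosity around a core SNP for one allele.

    EHH at a flanking SNP s is the probability that two random carriers of
    ``allele`` at the core are identical over [core..s]:
    Σ_k n_k(n_k−1) / (n_c(n_c−1)) over distinct extended haplotypes.
    EHH(core) = 1 by definition.  Both sides are extended until the value
    falls below ``cutoff`` (use 0 < cutoff to truncate, tiny cutoff for a
    full curve).
    """
    carriers = haps.haplotypes[:, core] == allele
    nc = int(carriers.sum())
    if nc < 2:
        raise ValueError(f"core {core}: fewer than 2 carriers of allele {allele}")
    H = haps.haplotypes[carriers, :]
    pos = haps.positions
    left = _side_ehh(H, core, -1, cutoff)
    right = _side_ehh(H, core, +1, cutoff)
    points = (
        [(int(pos[j]), e) for j, e in reversed(left)]
        + [(int(pos[core]), 1.0)]
        + [(int(pos[j]), e) for j, e in right]
    )
    partition = "derived" if allele == 1 else "ancestral"
    return EhhCurve(core_index=core, side="both", points=points,
                    allele_partition=partition)


def ehhs(haps: HaplotypeMatrix, core: int, cutoff: float = 0.05) -> EhhCurve:
    """Site-specific EHH over all haplotypes, normalized to 1 at the core."""
    H = haps.haplotypes
    n = H.shape[0]
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    counts = np.bincount(H[:, core])
    h_core = float((counts * (counts - 1)).sum() / (n * (n - 1)))
    if h_core == 0.0:
        raise ValueError(f"core {core}: zero haplotype homozygosity at the core")
    pos = haps.positions
    scaled_cutoff = cutoff * h_core
    left = _side_ehh_site(H, core, -1, scaled_cutoff, h_core)
    right = _side_ehh_site(H, core, +1, scaled_cutoff, h_core)
    points = (
        [(int(pos[j]), e) for j, e in reversed(left)]
        + [(int(pos[core]), 1.0)]
        + [(int(pos[j]), e) for j, e in right]
    )
    return EhhCurve(core_index=core, side="both", points=points,
                    allele_partition="site")


def _side_ehh_site(
    H: np.ndarray, core: int, direction: int, scaled_cutoff: float, h_core: float
) -> list[tuple[int, float]]:
    # classes start split by the core allele, values normalized by h_core
    n = H.shape[0]
    denom = n * (n - 1)
    _, group = np.unique(H[:, core], return_inverse=True)
    out: list[tuple[int, float]] = []
    j = core
    n_snps = H.shape[1]
    while True:
        j += direction
        if j < 0 or j >= n_snps:
            break
        key = group * 2 + H[:, j]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        h = float((counts * (counts - 1)).sum() / denom)
        out.append((j, h / h_core))
        if h < scaled_cutoff or h == 0.0:
            break
    return out


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _integrate_side(
    core_pos: int, pts: Sequence[tuple[int, float]], cutoff: float
) -> tuple[float, bool]:
    """Trapezoidal area from the core out along one side, truncated at the
    first crossing of ``cutoff`` (linearly interpolated).  Returns
    (area, reached_cutoff)."""
    area = 0.0
    prev_pos, prev_e = core_pos, 1.0
    for p, e in pts:
        d = abs(p - prev_pos)
        if e < cutoff:
            if prev_e > cutoff:
                frac = (prev_e - cutoff) / (prev_e - e)
                area += d * frac * (prev_e + cutoff) / 2.0
            return area, True
        area += d * (prev_e + e) / 2.0
        prev_pos, prev_e = p, e
    return area, False


def _curve_sides(curve: EhhCurve, core_pos: int):
    left = [(p, e) for p, e in curve.points if p < core_pos]
    right = [(p, e) for p, e in curve.points if p > core_pos]
    return list(reversed(left)), right


def ihh_detail(curve: EhhCurve, core_pos: int, cutoff: float) -> tuple[float, bool]:
    """Two-sided integral of an EHH curve; bool = cutoff reached on both
    sides before the chromosome edge."""
    left, right = _curve_sides(curve, core_pos)
    a_l, ok_l = _integrate_side(core_pos, left, cutoff)
    a_r, ok_r = _integrate_side(core_pos, right, cutoff)
    return a_l + a_r, ok_l and ok_r


def ihh(
    haps: HaplotypeMatrix,
    core: int,
    allele: int,
    config: SweepConfig = SweepConfig(),
) -> float:
    """Integrated EHH (area under the two-sided decay curve, bp units)."""
    curve = ehh(haps, core, allele, cutoff=config.ehh_cutoff)
    area, _ = ihh_detail(curve, int(haps.positions[core]), config.ehh_cutoff)
    return area


def ies(
    haps: HaplotypeMatrix, core: int, config: SweepConfig = SweepConfig()
) -> float:
    """Integrated EHHS (site homozygosity decay area, bp units)."""
    curve = ehhs(haps, core, cutoff=config.ehh_cutoff)
    area, _ = ihh_detail(curve, int(haps.positions[core]), config.ehh_cutoff)
    return area


# ---------------------------------------------------------------------------
# standardization helpers
# ---------------------------------------------------------------------------

def _zscore(raw: np.ndarray, valid: np.ndarray, center: str = "mean") -> np.ndarray:
    std = np.full(raw.shape, np.nan)
    v = raw[valid]
    if v.size == 0:
        return std
    mu = float(np.mean(v)) if center == "mean" else float(np.median(v))
    sd = float(np.std(v))
    if sd > 0:
        std[valid] = (raw[valid] - mu) / sd
    return std


def standardization_groups(
    freq: np.ndarray, valid: np.ndarray, n_bins: int, min_count: int
) -> np.ndarray:
    """Realized standardization group label per SNP: equal-width derived-
    frequency bins, under-filled bins merged with their neighbors."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(freq, edges[1:-1]), 0, n_bins - 1)

    # merge under-filled bins (left to right, into the next bin; trailing
    # small bin merges backwards)
    bin_ids = sorted(set(which[valid]))
    merge_to = {b: b for b in bin_ids}
    counts = {b: int(np.sum(valid & (which == b))) for b in bin_ids}
    i = 0
    while i < len(bin_ids) - 1:
        b = bin_ids[i]
        if counts[b] < min_count:
            nxt = bin_ids[i + 1]
            counts[nxt] += counts[b]
            for k, v in merge_to.items():
                if v == b:
                    merge_to[k] = nxt
            counts[b] = 0
        i += 1
    if len(bin_ids) >= 2:
        # after the forward pass only the last bin can be under-filled
        last = bin_ids[-1]
        if 0 < counts[last] < min_count:
            earlier = [b for b in bin_ids if b != last and counts[b] > 0]
            if earlier:
                prev = earlier[-1]
                counts[prev] += counts[last]
                for k, v in merge_to.items():
                    if v == last:
                        merge_to[k] = prev
                counts[last] = 0

    return np.array([merge_to.get(b, b) for b in which])


def _bin_standardize(
    raw: np.ndarray, freq: np.ndarray, valid: np.ndarray,
    n_bins: int, min_count: int,
) -> np.ndarray:
    """Z-score within merged derived-frequency bins (population sd)."""
    std = np.full(raw.shape, np.nan)
    if not valid.any():
        return std
    groups = standardization_groups(freq, valid, n_bins, min_count)
    for b in set(groups[valid]):
        sel = valid & (groups == b)
        v = raw[sel]
        sd = float(np.std(v))
        if sd > 0:
            std[sel] = (v - float(np.mean(v))) / sd
        else:
            std[sel] = 0.0
    return std


# ---------------------------------------------------------------------------
# iHS
# ---------------------------------------------------------------------------

def ihs(haps: HaplotypeMatrix, config: SweepConfig = SweepConfig()) -> ScoreTable:
    """Per-SNP iHS = ln(iHH_ancestral / iHH_derived), standardized within
    derived-allele-frequency bins."""
    n_snps = haps.n_snps
    pos = haps.positions
    raw = np.full(n_snps, np.nan)
    freq = haps.haplotypes.mean(axis=0)
    flags = np.array([FLAG_OK] * n_snps, dtype=object)

    for j in range(n_snps):
        f = freq[j]
        if min(f, 1 - f) < config.core_maf_min:
            flags[j] = FLAG_MAF
            continue
        n_der = int(haps.haplotypes[:, j].sum())
        if n_der < 2 or haps.n_haplotypes - n_der < 2:
            flags[j] = FLAG_MAF
            continue
        c_anc = ehh(haps, j, 0, cutoff=config.ehh_cutoff)
        c_der = ehh(haps, j, 1, cutoff=config.ehh_cutoff)
        a_anc, ok_a = ihh_detail(c_anc, int(pos[j]), config.ehh_cutoff)
        a_der, ok_d = ihh_detail(c_der, int(pos[j]), config.ehh_cutoff)
        if config.edge_policy == "discard" and not (ok_a and ok_d):
            flags[j] = FLAG_EDGE
            continue
        if a_anc <= 0 or a_der <= 0:
            flags[j] = FLAG_ZERO
            continue
        raw[j] = math.log(a_anc / a_der)

    valid = flags == FLAG_OK
    std = _bin_standardize(raw, freq, valid, config.freq_bins, config.min_bin_count)
    # a valid raw score can still miss standardization (e.g. zero-sd bin)
    flags[valid & np.isnan(std)] = FLAG_ZERO
    return ScoreTable(snps=list(haps.snps), stat="ihs", raw=raw, std=std,
                      freq=freq, flag=np.asarray(flags))


# ---------------------------------------------------------------------------
# cross-population scans
# ---------------------------------------------------------------------------

def ies_scan(
    haps: HaplotypeMatrix, config: SweepConfig = SweepConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """iES at every SNP; returns (areas, cutoff_reached).  Areas are nan
    where the core site homozygosity is degenerate."""
    n_snps = haps.n_snps
    pos = haps.positions
    areas = np.full(n_snps, np.nan)
    reached = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        try:
            curve = ehhs(haps, j, cutoff=config.ehh_cutoff)
        except ValueError:
            continue
        areas[j], reached[j] = ihh_detail(curve, int(pos[j]), config.ehh_cutoff)
    return areas, reached


def _cross_pop_table(
    haps_a: HaplotypeMatrix,
    haps_b: HaplotypeMatrix,
    config: SweepConfig,
    stat: str,
    center: str,
    ies_a: np.ndarray | None = None,
    reached_a: np.ndarray | None = None,
    ies_b: np.ndarray | None = None,
    reached_b: np.ndarray | None = None,
) -> ScoreTable:
    if [s.id for s in haps_a.snps] != [s.id for s in haps_b.snps]:
        raise ValueError("populations must share the same SNP panel")
    if ies_a is None:
        ies_a, reached_a = ies_scan(haps_a, config)
    if ies_b is None:
        ies_b, reached_b = ies_scan(haps_b, config)
    n_snps = haps_a.n_snps
    pooled = np.concatenate([haps_a.haplotypes, haps_b.haplotypes], axis=0)
    freq = pooled.mean(axis=0)
    flags = np.array([FLAG_OK] * n_snps, dtype=object)
    raw = np.full(n_snps, np.nan)

    maf_bad = np.minimum(freq, 1 - freq) < config.core_maf_min
    flags[maf_bad] = FLAG_MAF
    for j in range(n_snps):
        if flags[j] != FLAG_OK:
            continue
        a, b = ies_a[j], ies_b[j]
        if np.isnan(a) or np.isnan(b):
            flags[j] = FLAG_ZERO
            continue
        if config.edge_policy == "discard" and not (reached_a[j] and reached_b[j]):
            flags[j] = FLAG_EDGE
            continue
        if a <= 0 or b <= 0:
            flags[j] = FLAG_ZERO
            continue
        raw[j] = math.log(a / b)

    valid = flags == FLAG_OK
    std = _zscore(raw, valid, center=center)
    flags[valid & np.isnan(std)] = FLAG_ZERO
    return ScoreTable(snps=list(haps_a.snps), stat=stat, raw=raw, std=std,
                      freq=freq, flag=np.asarray(flags))


def xpehh(
    haps_a: HaplotypeMatrix,
    haps_b: HaplotypeMatrix,
    config: SweepConfig = SweepConfig(),
    **precomputed,
) -> ScoreTable:
    """xp-EHH: ln of the ratio of the two populations' haplotype-
    homozygosity integrals at each SNP, z-scored genome-wide.  Positive
    standardized values mean longer haplotypes (a sweep) in population A.

    Precomputed ``ies_a``/``reached_a``/``ies_b``/``reached_b`` arrays from
    :func:`ies_scan` may be passed to avoid recomputation.
    """
    return _cross_pop_table(haps_a, haps_b, config, "xpehh", "mean", **precomputed)


def rsb(
    haps_a: HaplotypeMatrix,
    haps_b: HaplotypeMatrix,
    config: SweepConfig = SweepConfig(),
    **precomputed,
) -> ScoreTable:
    """Rsb: ln(iES_A / iES_B) per SNP, standardized genome-wide
    (``config.standardize`` = ``"zscore"`` or ``"median"`` centering)."""
    center = "median" if config.standardize == "median" else "mean"
    return _cross_pop_table(haps_a, haps_b, config, "rsb", center, **precomputed)


# ---------------------------------------------------------------------------
# Weir–Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components(
    g: GenotypeMatrix, pop_a: Sequence[int], pop_b: Sequence[int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir–Cockerham variance components (a, b, c) for two
    populations, plus a validity mask (both pops ≥2 genotyped samples and
    the SNP polymorphic overall)."""
    r = 2
    comps = []
    for rows in (pop_a, pop_b):
        calls = g.calls[np.asarray(rows, dtype=np.intp), :]
        obs = calls != MISSING
        n_i = obs.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i = np.where(obs, calls, 0).sum(axis=0) / (2 * n_i)
            h_i = np.where(obs, calls == 1, False).sum(axis=0) / n_i
        comps.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    valid = (n1 >= 2) & (n2 >= 2)
    n_bar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - s2 * (r - 1) / r
            - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
    valid &= (p_bar > 0) & (p_bar < 1)
    return (
        np.where(valid, a, np.nan),
        np.where(valid, b, np.nan),
        np.where(valid, c, np.nan),
        valid,
    )


def wc_fst(
    g: GenotypeMatrix, pop_a: Sequence[int] | str, pop_b: Sequence[int] | str
) -> ScoreTable:
    """Per-SNP Weir–Cockerham θ̂ = a/(a+b+c) between two sample sets, with a
    genome-wide z-scored column.  Populations may be given as row indices
    or as population labels."""
    rows_a = g.sample_indices(pop_a) if isinstance(pop_a, str) else np.asarray(pop_a)
    rows_b = g.sample_indices(pop_b) if isinstance(pop_b, str) else np.asarray(pop_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ValueError("each population needs at least 2 samples")
    a, b, c, valid = _wc_components(g, rows_a, rows_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(valid & (denom != 0), a / denom, np.nan)
    flags = np.where(np.isnan(theta), FLAG_ZERO, FLAG_OK).astype(object)
    ok = flags == FLAG_OK
    std = _zscore(theta, ok)
    p_all = _snp_alt_freq(g)
    return ScoreTable(snps=list(g.snps), stat="fst", raw=theta, std=std,
                      freq=p_all, flag=np.asarray(flags))


def mean_fst(
    g: GenotypeMatrix, pop_a: Sequence[int] | str, pop_b: Sequence[int] | str
) -> float:
    """Genome-average Weir–Cockerham FST as the ratio of summed variance
    components Σa / Σ(a+b+c) over valid SNPs."""
    rows_a = g.sample_indices(pop_a) if isinstance(pop_a, str) else np.asarray(pop_a)
    rows_b = g.sample_indices(pop_b) if isinstance(pop_b, str) else np.asarray(pop_b)
    a, b, c, valid = _wc_components(g, rows_a, rows_b)
    denom = a + b + c
    use = valid & np.isfinite(denom) & (denom != 0)
    if not use.any():
        raise ValueError("no valid SNPs for mean FST")
    return float(np.nansum(a[use]) / np.nansum(denom[use]))


def _snp_alt_freq(g: GenotypeMatrix) -> np.ndarray:
    X = g.calls.astype(float)
    X[g.calls == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        return np.nanmean(X, axis=0) / 2.0
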