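"""Expression arm: FPKM, the least-squares stage t-statistic, top-fraction
stage-specific gene sets (SEGS), the CGS∩SEGS association and ΔΔCt.

The t-statistic implements the printed closed form verbatim:
t = β̂[0] / sqrt(MSE·(XᵀX)⁻¹[0,0]) with β̂ = (XᵀX)⁻¹XᵀY and
MSE = ‖Y − Xβ̂‖²/N (note: divides by N, not N−2).  X has the focal-stage
indicator in column 0 and an intercept in column 1, so β̂[0] is the
focal-versus-rest mean difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .candidate_sets import GeneSet


@dataclass
class ExpressionMatrix:
    gene_ids: list[str]
    sample_ids: list[str]
    stage_of_sample: list[str]
    values: np.ndarray  # (genes, samples), FPKM

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if len(self.stage_of_sample) != len(self.sample_ids):
            raise ValueError("stage labels length mismatch")
        if (self.values < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.stage_of_sample))

    def stage_mask(self, stage: str) -> np.ndarray:
        m = np.array([s == stage for s in self.stage_of_sample], dtype=bool)
        if not m.any():
            raise KeyError(f"no samples in stage {stage!r}")
        return m


@dataclass
class SegsResult:
    stages: list[str]
    gene_ids: list[str]
    tstat: dict[str, np.ndarray]       # stage -> per-gene t
    rank: dict[str, np.ndarray]        # stage -> 0-based descending-t rank
    members: dict[str, set[str]]       # stage -> SEGS gene ids
    segs_fraction: float = 0.07


def fpkm(C: float, N: float, L: float) -> float:
    """FPKM = 10⁶·C / (N·L/10³): C fragments for the gene, N total mapped
    fragments, L coding-region length in bp."""
    if N <= 0 or L <= 0:
        raise ValueError("N and L must be positive")
    if C < 0:
        raise ValueError("C must be non-negative")
    return 1e6 * C / (N * L / 1e3)


def fpkm_from_counts(
    counts: np.ndarray, lengths: Sequence[float], totals: Sequence[float] | None = None
) -> np.ndarray:
    """Vectorized FPKM for a (genes × samples) fragment-count table.
    ``totals`` defaults to per-sample column sums."""
    counts = np.asarray(counts, dtype=float)
    L = np.asarray(lengths, dtype=float)[:, None]
    N = (
        counts.sum(axis=0, keepdims=True)
        if totals is None
        else np.asarray(totals, dtype=float)[None, :]
    )
    if (N <= 0).any() or (L <= 0).any():
        raise ValueError("totals and lengths must be positive")
    return 1e6 * counts / (N * L / 1e3)


def _tstat(y: np.ndarray, focal: np.ndarray) -> float:
    """The printed least-squares t for one response vector.

    Returns nan when both the effect and the residual variance vanish
    (degenerate) and ±inf when the fit is exact with a non-zero effect.
    """
    N = y.size
    n1 = int(focal.sum())
    n2 = N - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("focal stage must be a strict, non-empty subset of samples")
    # closed form of (XᵀX)⁻¹XᵀY for X = [indicator, intercept]:
    # β̂[0] = focal mean − rest mean; (XᵀX)⁻¹[0,0] = 1/n1 + 1/n2
    mean1 = float(y[focal].mean())
    mean2 = float(y[~focal].mean())
    effect = mean1 - mean2
    rss = float(((y[focal] - mean1) ** 2).sum() + ((y[~focal] - mean2) ** 2).sum())
    mse = rss / N
    se2 = mse * (1.0 / n1 + 1.0 / n2)
    if se2 <= 0:
        if effect == 0:
            return math.nan
        return math.copysign(math.inf, effect)
    return float(effect / math.sqrt(se2))


def stage_tstat(expr: ExpressionMatrix, gene: str | int, focal_stage: str) -> float:
    """t-statistic of one gene's focal-stage differential expression."""
    gi = gene if isinstance(gene, int) else expr.gene_ids.index(gene)
    return _tstat(expr.values[gi, :], expr.stage_mask(focal_stage))


def build_segs(expr: ExpressionMatrix, segs_fraction: float = 0.07) -> SegsResult:
    """Per-stage SEGS: genes sorted by descending t (focal up-regulation
    first); the top ⌈fraction·n_genes⌉ form the stage's set, boundary ties
    included.  Degenerate (nan) t values sort last."""
    if not (0 < segs_fraction < 1):
        raise ValueError("segs_fraction must be in (0,1)")
    n_genes = len(expr.gene_ids)
    # guard against float noise in fraction*n (e.g. 0.07*100 = 7.0000…01)
    k = max(1, math.ceil(segs_fraction * n_genes - 1e-9))
    tstat: dict[str, np.ndarray] = {}
    rank: dict[str, np.ndarray] = {}
    members: dict[str, set[str]] = {}
    for stage in expr.stages:
        focal = expr.stage_mask(stage)
        if focal.all():
            raise ValueError(f"stage {stage!r} contains every sample")
        t = np.array([_tstat(expr.values[i, :], focal) for i in range(n_genes)])
        key = np.where(np.isnan(t), -np.inf, t)
        order = np.argsort(-key, kind="stable")
        r = np.empty(n_genes, dtype=np.int64)
        r[order] = np.arange(n_genes)
        threshold = key[order[k - 1]]
        sel = key >= threshold if np.isfinite(threshold) else r < k
        tstat[stage] = t
        rank[stage] = r
        members[stage] = {expr.gene_ids[i] for i in np.where(sel)[0]}
    return SegsResult(
        stages=expr.stages,
        gene_ids=list(expr.gene_ids),
        tstat=tstat,
        rank=rank,
        members=members,
        segs_fraction=segs_fraction,
    )


def associate(
    cgs: GeneSet, segs: SegsResult
) -> tuple[dict[str, list[str]], dict[str, float]]:
    """CGS ∩ SEGS per stage, plus each stage's contribution fraction
    |intersection_stage| / |union over stages of intersections| (0 when the
    union is empty)."""
    if not cgs.gene_ids:
        raise ValueError("empty candidate gene set")
    inter = {
        stage: sorted(cgs.gene_ids & segs.members[stage]) for stage in segs.stages
    }
    union: set[str] = set().union(*(set(v) for v in inter.values()))
    total = len(union)
    contrib = {
        stage: (len(v) / total if total else 0.0) for stage, v in inter.items()
    }
    return inter, contrib


def ddct(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression 2^−ΔΔCt."""
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_val = (ct_target - ct_reference) - (
        ct_target_calibrator - ct_reference_calibrator
    )
    return 2.0 ** (-ddct_val)
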