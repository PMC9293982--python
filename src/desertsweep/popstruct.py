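"""Population structure: PCA, p-distance, neighbor joining, and linkage
disequilibrium (pairwise r², sliding-window pruning, decay curves)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, HaplotypeMatrix


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    coords: np.ndarray       # (n_samples, n_components)
    eigenvalues: np.ndarray  # variance per component, non-increasing
    varexp: np.ndarray       # fractions of total variance


def pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """PCA of the genotype matrix under the Patterson scaling.

    Missing calls are mean-imputed per SNP; each SNP column is centered by
    2p̂ and scaled by sqrt(2p̂(1−p̂)).  Monomorphic SNPs are rejected.
    """
    n, m = g.n_samples, g.n_snps
    if n_components > min(n - 1, m):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples-1, snps)="
            f"{min(n - 1, m)}"
        )
    X = g.calls.astype(float)
    X[g.calls == MISSING] = np.nan
    p_hat = np.nanmean(X, axis=0) / 2.0
    if np.any((p_hat <= 0) | (p_hat >= 1)):
        bad = np.where((p_hat <= 0) | (p_hat >= 1))[0]
        raise ValueError(f"monomorphic SNPs present (first index {bad[0]})")
    col_mean = 2.0 * p_hat
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = (X - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))

    # thin SVD; sample covariance eigenvalues = s^2 / (n - 1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (n - 1)
    total_var = float(np.sum(X**2)) / (n - 1)
    k = n_components
    return PcaResult(
        coords=U[:, :k] * s[:k],
        eigenvalues=eig[:k],
        varexp=eig[:k] / total_var if total_var > 0 else np.zeros(k),
    )


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def p_distance(g: GenotypeMatrix, i: int, j: int) -> float:
    """Mean per-SNP allele difference |calls_i − calls_j| / 2 over SNPs
    where both samples are genotyped (pairwise deletion)."""
    a = g.calls[i, :]
    b = g.calls[j, :]
    usable = (a != MISSING) & (b != MISSING)
    if not usable.any():
        raise ValueError(f"samples {i} and {j} share no co-observed SNP")
    return float(np.abs(a[usable] - b[usable]).mean() / 2.0)


def p_distance_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    n = g.n_samples
    X = g.calls.astype(float)
    X[g.calls == MISSING] = np.nan
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X - X[i, :]) / 2.0  # nan where either missing
        with np.errstate(invalid="ignore"):
            row = np.nanmean(diff, axis=1)
        if np.isnan(row).any():
            k = int(np.where(np.isnan(row))[0][0])
            raise ValueError(f"samples {i} and {k} share no co-observed SNP")
        d[i, :] = row
        d[i, i] = 0.0
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(labels=list(g.samples), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Iteratively joins the pair minimizing Q(i,j) = (n−2)d(i,j) − R_i − R_j.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  Returns an unrooted tree as a trifurcating root
    (a single edge for 2 taxa).
    """
    n = len(dm.labels)
    if n < 3:
        if n == 2:
            root = TreeNode()
            root.children = [
                (TreeNode(name=dm.labels[0]), dm.d[0, 1] / 2.0),
                (TreeNode(name=dm.labels[1]), dm.d[0, 1] / 2.0),
            ]
            return root
        raise ValueError("need at least 3 taxa")

    d = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]

        li = sub[ai, aj] / 2.0 + (R[ai] - R[aj]) / (2.0 * (m - 2))
        lj = sub[ai, aj] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        # distances from the new node to the remaining taxa
        new_d = np.zeros(d.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_d[k] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_d[:-1]
        d[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    lengths = [la, lb, lc]
    order = [a, b, c]
    # clamp negatives, spreading the deficit over the siblings
    for idx in range(3):
        if lengths[idx] < 0:
            deficit = lengths[idx]
            lengths[idx] = 0.0
            others = [k for k in range(3) if k != idx]
            for k in others:
                lengths[k] += deficit / 2.0
    root = TreeNode(children=[(nodes[order[k]], lengths[k]) for k in range(3)])
    return root


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(data, snp_a: int, snp_b: int, mode: str = "haplotype") -> float:
    """Pairwise r² between two SNPs.

    ``haplotype`` mode (requires a :class:`HaplotypeMatrix`): r² = D² /
    (pA pa pB pb) from phased haplotype frequencies.  ``composite`` mode
    (requires a :class:`GenotypeMatrix`): squared Pearson correlation of
    genotype dosages over pairwise-complete samples.
    """
    if mode == "haplotype":
        if not isinstance(data, HaplotypeMatrix):
            raise TypeError("haplotype mode requires a HaplotypeMatrix")
        a = data.haplotypes[:, snp_a].astype(float)
        b = data.haplotypes[:, snp_b].astype(float)
        pA, pB = a.mean(), b.mean()
        if pA in (0.0, 1.0) or pB in (0.0, 1.0):
            raise ValueError("monomorphic SNP in r² computation")
        pAB = (a * b).mean()
        D = pAB - pA * pB
        return float(D * D / (pA * (1 - pA) * pB * (1 - pB)))
    if mode == "composite":
        if not isinstance(data, GenotypeMatrix):
            raise TypeError("composite mode requires a GenotypeMatrix")
        a = data.calls[:, snp_a].astype(float)
        b = data.calls[:, snp_b].astype(float)
        ok = (data.calls[:, snp_a] != MISSING) & (data.calls[:, snp_b] != MISSING)
        a, b = a[ok], b[ok]
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("monomorphic SNP in r² computation")
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)
    raise ValueError(f"unknown mode {mode!r}")


def _dosage_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """Pairwise squared dosage correlation; missing values mean-imputed."""
    X = calls.astype(float)
    X[calls == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.nan
    X = X / sd
    r = (X.T @ X) / X.shape[0]
    return r * r


def _snp_mafs(calls: np.ndarray) -> np.ndarray:
    X = calls.astype(float)
    X[calls == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def ld_prune(
    g: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> list[int]:
    """Sliding-window LD pruning (PLINK --indep-pairwise style).

    Within each window, while any retained pair has r² > ``r2_max``, the
    lower-MAF SNP of the worst pair is removed (equal MAFs: the
    later-positioned one).  Windows advance by ``step_snps`` over the
    original SNP index grid, per chromosome.  Returns retained indices.
    """
    removed = np.zeros(g.n_snps, dtype=bool)
    mafs = _snp_mafs(g.calls)
    chroms = g.chroms
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        start = 0
        while True:
            win = idx[start : start + window_snps]
            if len(win) >= 2:
                _prune_window(g.calls, win, removed, mafs, r2_max)
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return [int(i) for i in np.where(~removed)[0]]


def _prune_window(
    calls: np.ndarray,
    win: np.ndarray,
    removed: np.ndarray,
    mafs: np.ndarray,
    r2_max: float,
) -> None:
    live = win[~removed[win]]
    if len(live) < 2:
        return
    r2 = _dosage_r2_matrix(calls[:, live])
    np.fill_diagonal(r2, 0.0)
    r2 = np.nan_to_num(r2, nan=0.0)
    alive = np.ones(len(live), dtype=bool)
    while True:
        masked = np.where(np.outer(alive, alive), r2, 0.0)
        worst = float(masked.max())
        if worst <= r2_max:
            break
        ai, aj = np.unravel_index(np.argmax(masked), masked.shape)
        gi, gj = live[ai], live[aj]
        if mafs[gi] > mafs[gj]:
            drop = aj
        elif mafs[gj] > mafs[gi]:
            drop = ai
        else:  # equal MAF: drop the later-positioned SNP
            drop = aj if gj > gi else ai
        alive[drop] = False
    removed[live[~alive]] = True


@dataclass
class LdDecayCurve:
    bin_edges: np.ndarray                 # len n_bins + 1, bp
    mean_r2: dict[str, np.ndarray]        # population -> per-bin mean r²
    pair_counts: dict[str, np.ndarray]    # population -> per-bin pair count


def ld_decay(
    data: GenotypeMatrix | HaplotypeMatrix,
    max_dist_bp: int = 500_000,
    bin_width_bp: int = 1_000,
    pops: Iterable[str] | None = None,
) -> LdDecayCurve:
    """Mean r² versus physical distance, per population.

    All intra-chromosome SNP pairs with distance ≤ ``max_dist_bp`` are
    binned by distance.  Haplotype r² is used for a HaplotypeMatrix,
    composite (dosage) r² for a GenotypeMatrix.  Pairs where either SNP is
    monomorphic within the population are skipped.
    """
    edges = np.arange(0, max_dist_bp + bin_width_bp, bin_width_bp)
    n_bins = len(edges) - 1
    all_pops = list(dict.fromkeys(data.pops))
    use_pops = all_pops if pops is None else list(pops)

    positions = data.positions
    chroms = np.array([s.chrom for s in data.snps])
    mean_r2: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for pop in use_pops:
        if isinstance(data, HaplotypeMatrix):
            sub = data.subset_pops(pop)
            M = sub.haplotypes.astype(float)
        else:
            rows = data.sample_indices(pop)
            M = data.calls[rows, :].astype(float)
            M[data.calls[rows, :] == MISSING] = np.nan
        sums = np.zeros(n_bins)
        nums = np.zeros(n_bins, dtype=np.int64)
        for chrom in dict.fromkeys(chroms):
            cidx = np.where(chroms == chrom)[0]
            if len(cidx) < 2:
                continue
            _accumulate_decay(
                M[:, cidx], positions[cidx], max_dist_bp, edges, sums, nums
            )
        with np.errstate(invalid="ignore"):
            mean_r2[pop] = np.where(nums > 0, sums / np.maximum(nums, 1), np.nan)
        counts[pop] = nums
    return LdDecayCurve(bin_edges=edges, mean_r2=mean_r2, pair_counts=counts)


def _accumulate_decay(
    M: np.ndarray,
    pos: np.ndarray,
    max_dist: int,
    edges: np.ndarray,
    sums: np.ndarray,
    nums: np.ndarray,
) -> None:
    # standardize columns; monomorphic / all-missing columns become nan
    mu = np.nanmean(M, axis=0)
    inds = np.where(np.isnan(M))
    M = M.copy()
    M[inds] = np.take(mu, inds[1])
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = M / sd
    n_snps = M.shape[1]
    for a in range(n_snps - 1):
        hi = int(np.searchsorted(pos, pos[a] + max_dist, side="right"))
        if hi <= a + 1:
            continue
        if not np.isfinite(Z[:, a]).all():
            continue
        block = Z[:, a + 1 : hi]
        ok = np.isfinite(block).all(axis=0)
        if not ok.any():
            continue
        r = (Z[:, a] @ block[:, ok]) / M.shape[0]
        d = pos[a + 1 : hi][ok] - pos[a]
        b = np.minimum(np.searchsorted(edges, d, side="right") - 1, len(sums) - 1)
        np.add.at(sums, b, r * r)
        np.add.at(nums, b, 1)
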