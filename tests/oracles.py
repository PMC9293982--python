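"""Independent brute-force / textbook oracles used by the test suite.

Deliberately written without reference to the package internals: different
parameterizations, plain loops, exact rational arithmetic where possible.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_enumeration_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p by full enumeration of the conditional distribution,
    using the complete hypergeometric-style probability formula with
    Fraction arithmetic."""
    n = n_AA + n_Aa + n_aa
    nA = 2 * n_AA + n_Aa
    na = 2 * n - nA
    f = math.factorial

    def prob(het: int) -> Fraction:
        # full conditional probability, not the reduced integer weights
        hom_A = (nA - het) // 2
        hom_a = (na - het) // 2
        return Fraction(
            f(n) * 2**het * f(nA) * f(na),
            f(hom_A) * f(het) * f(hom_a) * f(2 * n),
        )

    lo = min(nA, na)
    hets = list(range(lo % 2, lo + 1, 2))
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_Aa]
    total = sum(probs.values())
    acc = sum(p for p in probs.values() if p <= p_obs)
    return float(acc / total)


def wc_theta(counts_per_pop: list[tuple[int, int, int]]) -> float:
    """Textbook Weir–Cockerham theta-hat from per-population genotype count
    triples (hom_ref, het, hom_alt), written with explicit scalar loops."""
    r = len(counts_per_pop)
    ns, ps, hs = [], [], []
    for n0, n1, n2 in counts_per_pop:
        n_i = n0 + n1 + n2
        ns.append(n_i)
        ps.append((2 * n2 + n1) / (2 * n_i))
        hs.append(n1 / n_i)
    n_bar = sum(ns) / r
    n_c = (r * n_bar - sum(n * n for n in ns) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)

    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def ehh_pair_counting(haps: np.ndarray, core: int, allele: int, upto: int) -> float:
    """EHH at flanking index ``upto`` by brute-force enumeration of ordered
    carrier pairs identical over the closed interval [core..upto]."""
    carriers = [h for h in haps if h[core] == allele]
    nc = len(carriers)
    lo, hi = min(core, upto), max(core, upto)
    same = 0
    for i in range(nc):
        for j in range(nc):
            if i != j and np.array_equal(carriers[i][lo:hi + 1],
                                         carriers[j][lo:hi + 1]):
                same += 1
    return same / (nc * (nc - 1))


def ehhs_pair_counting(haps: np.ndarray, core: int, upto: int) -> float:
    """Site EHH (all haplotypes, split by core allele, normalized to 1 at
    the core) by ordered-pair counting."""
    n = len(haps)
    lo, hi = min(core, upto), max(core, upto)

    def homozygosity(span_lo, span_hi):
        same = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.array_equal(haps[i][span_lo:span_hi + 1],
                                             haps[j][span_lo:span_hi + 1]):
                    same += 1
        return same / (n * (n - 1))

    return homozygosity(lo, hi) / homozygosity(core, core)


def pooled_two_sample_t(y1: np.ndarray, y2: np.ndarray) -> float:
    """Classic equal-variance two-sample t (group1 minus group2)."""
    n1, n2 = len(y1), len(y2)
    s2 = (
        ((y1 - y1.mean()) ** 2).sum() + ((y2 - y2.mean()) ** 2).sum()
    ) / (n1 + n2 - 2)
    return (y1.mean() - y2.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))


def riemann_area(pts: list[tuple[float, float]], cutoff: float,
                 n_grid: int = 200_001) -> float:
    """Fine-grid Riemann sum of a piecewise-linear curve truncated at the
    first crossing of ``cutoff`` moving away from the first point."""
    xs = np.array([p for p, _ in pts], dtype=float)
    ys = np.array([e for _, e in pts], dtype=float)
    grid = np.linspace(xs[0], xs[-1], n_grid)
    vals = np.interp(grid, xs, ys)
    below = np.where(vals < cutoff)[0]
    end = below[0] if below.size else n_grid
    dx = grid[1] - grid[0]
    use = np.clip(vals[:end], cutoff, None)
    return float(np.sum(use) * dx)


def additive_distances(tree_edges, leaves):
    """Path-length matrix of a tree given as {node: [(child, length)]}."""
    import collections

    adj = collections.defaultdict(list)
    for parent, children in tree_edges.items():
        for child, length in children:
            adj[parent].append((child, length))
            adj[child].append((parent, length))
    n = len(leaves)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            d[i, j] = dist[dst]
    return d
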