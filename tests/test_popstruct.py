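import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from desertsweep.genotype_io import MISSING, write_newick
from desertsweep.popstruct import (
    DistanceMatrix,
    TreeNode,
    ld_decay,
    ld_prune,
    ld_r2,
    neighbor_joining,
    p_distance,
    p_distance_matrix,
    pca,
)
from desertsweep.simulate import SimConfig, haplotypes_to_genotypes, simulate_haplotypes

from .conftest import make_gm, make_haps
from .oracles import additive_distances


def drop_monomorphic(g):
    p = g.calls.mean(axis=0) / 2.0
    return g.subset_snps(np.where((p > 0) & (p < 1))[0])


class TestPca:
    def test_two_identical_clusters(self):
        row_a = [0, 2, 0, 2, 1, 1]
        row_b = [2, 0, 2, 0, 1, 2]
        calls = np.array([row_a] * 5 + [row_b] * 5)
        res = pca(make_gm(calls), n_components=2)
        pc1 = res.coords[:, 0]
        assert np.ptp(pc1[:5]) < 1e-9
        assert np.ptp(pc1[5:]) < 1e-9
        assert abs(pc1[0] - pc1[5]) > 1.0

    def test_scores_covariance_equals_eigenvalues(self, sim_pair):
        _, _, g = sim_pair
        res = pca(drop_monomorphic(g), n_components=5)
        cov = np.cov(res.coords, rowvar=False)
        assert np.allclose(cov, np.diag(res.eigenvalues), atol=1e-8)

    def test_three_population_separation(self):
        cfg = SimConfig(seed=21, n_pops=3, n_samples_per_pop=20, n_snps=800,
                        chrom_length_bp=4_000_000, drift_fst_target=0.15)
        haps, _ = simulate_haplotypes(cfg)
        g = drop_monomorphic(haplotypes_to_genotypes(haps))
        res = pca(g, n_components=2)
        labels = [p for p in g.pops]
        assert silhouette_score(res.coords[:, :2], labels) > 0.5

    def test_varexp_monotone_nonneg(self, sim_pair):
        _, _, g = sim_pair
        res = pca(drop_monomorphic(g), n_components=8)
        assert np.all(res.varexp >= 0)
        assert np.all(np.diff(res.varexp) <= 1e-12)
        assert res.varexp.sum() <= 1.0 + 1e-9

    def test_too_many_components(self):
        g = make_gm(np.array([[0, 1, 2], [1, 2, 0], [2, 1, 0]]))
        with pytest.raises(ValueError):
            pca(g, n_components=3)

    def test_monomorphic_rejected(self):
        g = make_gm(np.zeros((4, 2)))
        with pytest.raises(ValueError, match="monomorphic"):
            pca(g, n_components=1)


class TestPDistance:
    def test_identical_samples(self):
        g = make_gm(np.array([[0, 1, 2], [0, 1, 2]]))
        assert p_distance(g, 0, 1) == 0.0

    def test_arithmetic(self):
        g = make_gm(np.array([[0, 2], [2, 2]]))
        assert p_distance(g, 0, 1) == pytest.approx(0.5)

    def test_bounded(self, sim_pair):
        _, _, g = sim_pair
        dm = p_distance_matrix(g)
        assert np.all(dm.d >= 0) and np.all(dm.d <= 1)

    def test_matrix_matches_pairwise(self, sim_pair):
        _, _, g = sim_pair
        dm = p_distance_matrix(g)
        for i, j in [(0, 1), (3, 17), (10, 40)]:
            assert dm.d[i, j] == pytest.approx(p_distance(g, i, j))

    def test_no_coobserved_errors(self):
        calls = np.array([[0, MISSING], [MISSING, 1]])
        g = make_gm(calls)
        with pytest.raises(ValueError, match="co-observed"):
            p_distance(g, 0, 1)

    def test_pairwise_deletion(self):
        g = make_gm(np.array([[0, 2, MISSING], [2, 2, 0]]))
        assert p_distance(g, 0, 1) == pytest.approx(0.5)


def random_additive_tree(rng, n_taxa):
    """Random binary tree topology with positive branch lengths, as an
    edge dict for the oracle."""
    nodes = [f"t{i}" for i in range(n_taxa)]
    edges = {}
    next_id = 0
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = f"internal{next_id}"
        next_id += 1
        edges[parent] = [(a, rng.uniform(0.1, 2.0)), (b, rng.uniform(0.1, 2.0))]
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return edges


def tree_splits(node, all_leaves, parent_len=None, splits=None):
    """Map each branch to the leaf set below it (as a frozenset)."""
    if splits is None:
        splits = {}
    below = frozenset(node.leaves())
    if parent_len is not None:
        key = min(below, frozenset(all_leaves) - below, key=sorted)
        splits[key] = splits.get(key, 0.0) + parent_len
    for child, length in node.children:
        tree_splits(child, all_leaves, length, splits)
    return splits


def oracle_splits(edges, leaves):
    import collections

    adj = collections.defaultdict(list)
    for parent, children in edges.items():
        for child, length in children:
            adj[parent].append((child, length))
            adj[child].append((parent, length))
    root = next(iter(edges))
    while True:  # find the top-most node
        parents = [p for p, ch in edges.items() for c, _ in ch if c == root]
        if not parents:
            break
        root = parents[0]

    splits = {}

    def walk(u, seen):
        below = set()
        if u in leaves:
            below.add(u)
        for v, w in adj[u]:
            if v in seen:
                continue
            sub = walk(v, seen | {u})
            key = min(frozenset(sub), frozenset(leaves) - frozenset(sub),
                      key=sorted)
            splits[key] = splits.get(key, 0.0) + w
            below |= sub
        return below

    walk(root, set())
    return splits


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        dm = DistanceMatrix(labels=["A", "B", "C"], d=d)
        tree = neighbor_joining(dm)
        lengths = {child.name: ln for child, ln in tree.children}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    @pytest.mark.parametrize("n_taxa", [4, 5, 7])
    def test_additive_recovery(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        for _ in range(10):
            edges = random_additive_tree(rng, n_taxa)
            leaves = [f"t{i}" for i in range(n_taxa)]
            d = additive_distances(edges, leaves)
            tree = neighbor_joining(DistanceMatrix(labels=leaves, d=d))
            got = tree_splits(tree, leaves)
            want = oracle_splits(edges, set(leaves))
            # drop zero-length root artifacts before comparing
            want = {k: v for k, v in want.items() if 0 < len(k) < n_taxa}
            got = {k: v for k, v in got.items() if 0 < len(k) < n_taxa}
            assert set(got) == set(want)
            for k in want:
                assert got[k] == pytest.approx(want[k], abs=1e-9)

    def test_ultrametric_matches_single_linkage(self):
        # ((A:1,B:1):2,(C:1.5,D:1.5):1.5): ultrametric heights
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 3], [6, 6, 3, 0]],
            dtype=float,
        )
        tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
        splits = {k for k in tree_splits(tree, labels) if len(k) == 2}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["A", "B"], d=np.array([[0, 1], [2, 0]]))

    def test_newick_serializes(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=["A", "B", "C"], d=d))
        text = write_newick(tree)
        assert text.endswith(";") and "A" in text


class TestLdR2:
    def test_perfect_ld(self):
        h = make_haps([[0, 0], [0, 0], [1, 1], [1, 1]])
        assert ld_r2(h, 0, 1, mode="haplotype") == pytest.approx(1.0)

    def test_counts_example(self):
        # AB=4, Ab=0, aB=0, ab=4 -> D=0.25, r2=1
        h = make_haps([[0, 0]] * 4 + [[1, 1]] * 4)
        assert ld_r2(h, 0, 1, mode="haplotype") == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(3)
        h = make_haps(rng.integers(0, 2, size=(2000, 2)))
        assert ld_r2(h, 0, 1, mode="haplotype") < 0.01

    def test_monomorphic_errors(self):
        h = make_haps([[0, 0], [0, 1]])
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(h, 0, 1, mode="haplotype")

    def test_composite_mode(self):
        g = make_gm(np.array([[0, 0], [1, 1], [2, 2], [0, 0]]))
        assert ld_r2(g, 0, 1, mode="composite") == pytest.approx(1.0)

    def test_composite_requires_genotypes(self):
        h = make_haps([[0, 1], [1, 0]])
        with pytest.raises(TypeError):
            ld_r2(h, 0, 1, mode="composite")


def window_pairs_ok(g, retained, window_snps, step_snps, r2_max):
    """Exhaustive post-check over the same windows the pruner visits."""
    retained = set(retained)
    chroms = g.chroms
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        start = 0
        while True:
            win = [i for i in idx[start:start + window_snps] if i in retained]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    try:
                        r2 = ld_r2(g, win[a], win[b], mode="composite")
                    except ValueError:
                        continue
                    if r2 > r2_max + 1e-9:
                        return False
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return True


class TestLdPrune:
    def test_uncorrelated_nothing_removed(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(200, 20)).astype(np.int16)
        g = make_gm(calls)
        if window_pairs_ok(g, range(20), 50, 10, 0.1):
            retained = ld_prune(g)
            assert len(retained) == 20

    def test_duplicated_snp_lower_maf_removed(self):
        rng = np.random.default_rng(10)
        base = (rng.random(100) < 0.4).astype(np.int16) + (
            rng.random(100) < 0.4
        ).astype(np.int16)
        weaker = base.copy()
        weaker[base == 1] = 0  # same signal, lower MAF, still r2 > 0.1
        calls = np.column_stack([base, weaker])
        g = make_gm(calls)
        retained = ld_prune(g, window_snps=2, step_snps=1, r2_max=0.1)
        assert retained == [0]

    def test_postcheck_on_simulated_chromosome(self, sim_pair):
        _, _, g = sim_pair
        retained = ld_prune(g, 50, 10, 0.1)
        assert window_pairs_ok(g, retained, 50, 10, 0.1)
        assert 0 < len(retained) < g.n_snps

    def test_sample_duplication_invariance(self, sim_pair):
        _, _, g = sim_pair
        doubled = make_gm(np.vstack([g.calls, g.calls]))
        doubled.snps = g.snps
        assert ld_prune(g) == ld_prune(doubled)


class TestLdDecay:
    def test_single_snp_chromosome_no_pairs(self):
        g = make_gm(np.array([[0], [1], [2], [1]]))
        curve = ld_decay(g, max_dist_bp=10_000, bin_width_bp=1000)
        assert all(c.sum() == 0 for c in curve.pair_counts.values())

    def test_counts_and_range(self, sim_pair):
        _, haps, _ = sim_pair
        curve = ld_decay(haps[0], max_dist_bp=100_000, bin_width_bp=10_000)
        counts = curve.pair_counts["pop0"]
        means = curve.mean_r2["pop0"]
        ok = counts > 0
        assert np.all(means[ok] >= 0) and np.all(means[ok] <= 1 + 1e-9)
        # conservation: total equals a direct pair count
        pos = haps[0].positions
        expected = sum(
            int(np.searchsorted(pos, p + 100_000, side="right") - k - 1)
            for k, p in enumerate(pos)
        )
        assert counts.sum() <= expected  # monomorphic pairs are skipped
        assert counts.sum() > 0

    def test_decay_is_monotone_in_rank(self, sim_pair):
        _, haps, _ = sim_pair
        curve = ld_decay(haps[0], max_dist_bp=300_000, bin_width_bp=30_000)
        means = curve.mean_r2["pop0"]
        ok = curve.pair_counts["pop0"] > 0
        rho, _ = spearmanr(np.arange(len(means))[ok], means[ok])
        assert rho < 0
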