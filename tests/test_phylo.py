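"""SNP distances, neighbor joining, and bootstrap support."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from leafscreen.phylo import (
    PhyloError,
    bipartitions,
    bootstrap_support,
    genotype_matrix,
    neighbor_joining,
    snp_distance_matrix,
)


def gmat(rows, names=None):
    rows = np.asarray(rows, dtype=np.int8)
    names = names or [f"t{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=names,
                        columns=[f"s{j}" for j in range(rows.shape[1])])


def brute_force_distance(g, normalized=True):
    m = g.to_numpy()
    n = len(m)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            comp = [(a, b) for a, b in zip(m[i], m[j]) if a != -1 and b != -1]
            diff = sum(a != b for a, b in comp)
            d[i, j] = diff / len(comp) if normalized else diff
    return d


class TestDistances:
    def test_identical_rows_distance_zero(self):
        g = gmat([[0, 1, 1], [0, 1, 1]])
        assert snp_distance_matrix(g).iloc[0, 1] == 0

    def test_definition_three_of_ten(self):
        a = [0] * 10
        b = [1, 1, 1] + [0] * 7
        assert snp_distance_matrix(gmat([a, b])).iloc[0, 1] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("with_missing", [False, True])
    def test_matches_double_loop_oracle(self, seed, with_missing):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(6, 40)).astype(np.int8)
        if with_missing:
            mask = rng.random((6, 40)) < 0.15
            m[mask] = -1
            m[:, 0] = 0  # keep every pair comparable somewhere
        g = gmat(m)
        got = snp_distance_matrix(g).to_numpy()
        np.testing.assert_allclose(got, brute_force_distance(g), atol=1e-12)

    def test_zero_comparable_sites_raises(self):
        g = gmat([[0, -1], [-1, 0]], names=["x", "y"])
        with pytest.raises(PhyloError, match="x.*y"):
            snp_distance_matrix(g)

    def test_raw_counts_by_flag(self):
        a, b = [0] * 10, [1, 1, 1] + [0] * 7
        assert snp_distance_matrix(gmat([a, b]), normalized=False).iloc[0, 1] == 3


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)  # 2
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)  # 3
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)  # 7

    def test_additive_four_taxon_round_trip(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): pairwise path lengths are additive
        d = pd.DataFrame(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(d)
        td = tree.tip_tip_distances()
        for i, a in enumerate("ABCD"):
            for b in "ABCD"[i + 1:]:
                assert td[a, b] == pytest.approx(d.loc[a, b])
        assert bipartitions(tree) == {
            frozenset((frozenset("AB"), frozenset("CD")))
        }

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_exact_on_random_additive_matrices(self, seed):
        """NJ reproduces the path-length metric of random trees exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        d = _random_additive_matrix(n, rng)
        tree = neighbor_joining(d)
        td = tree.tip_tip_distances()
        for a in d.index:
            for b in d.index:
                if a != b:
                    assert td[a, b] == pytest.approx(d.loc[a, b], abs=1e-9)

    def test_cross_check_against_reference_nj(self):
        """Same topology as the scikit-bio NJ implementation."""
        rng = np.random.default_rng(5)
        d = _random_additive_matrix(7, rng)
        ours = bipartitions(neighbor_joining(d))
        ref_tree = skbio_nj(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        assert bipartitions(ref_tree) == ours

    def test_identical_taxa_joined_with_zero_branches(self):
        d = pd.DataFrame(
            [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == 0 and lengths["B"] == 0

    def test_rejects_asymmetric_matrix(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        with pytest.raises(PhyloError):
            neighbor_joining(d)


def _random_additive_matrix(n, rng):
    """Path-length metric of a random binary tree with positive branch lengths."""
    import itertools

    # build a random tree by sequential attachment; track leaf paths
    edges = {}  # node -> (parent, length)
    next_id = [0]

    def new_node():
        next_id[0] += 1
        return f"n{next_id[0]}"

    leaves = [f"L{i}" for i in range(n)]
    root = new_node()
    edges[leaves[0]] = (root, float(rng.uniform(0.5, 2)))
    edges[leaves[1]] = (root, float(rng.uniform(0.5, 2)))
    attachable = [leaves[0], leaves[1]]
    for leaf in leaves[2:]:
        target = attachable[int(rng.integers(0, len(attachable)))]
        parent, plen = edges[target]
        mid = new_node()
        cut = float(rng.uniform(0.2, 0.8)) * plen
        edges[mid] = (parent, plen - cut)
        edges[target] = (mid, cut)
        edges[leaf] = (mid, float(rng.uniform(0.5, 2)))
        attachable.append(leaf)

    def path_to_root(x):
        out = {}
        total = 0.0
        while x in edges:
            parent, ln = edges[x]
            total += ln
            out[parent] = total
            x = parent
        return out

    d = pd.DataFrame(0.0, index=leaves, columns=leaves)
    paths = {l: path_to_root(l) for l in leaves}
    for a, b in itertools.combinations(leaves, 2):
        shared = set(paths[a]) & set(paths[b])
        dist = min(paths[a][s] + paths[b][s] for s in shared)
        d.loc[a, b] = d.loc[b, a] = dist
    return d


class TestBootstrap:
    def test_clean_blocks_get_full_support(self):
        # two perfectly separated four-taxon blocks
        block = np.zeros((8, 40), dtype=np.int8)
        block[:4, :20] = 1
        block[4:, 20:] = 1
        g = gmat(block)
        tree = bootstrap_support(g, n_reps=50, seed=1)
        supports = [n.support for n in tree.non_tips() if hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_binary(self):
        rng = np.random.default_rng(2)
        g = gmat(rng.integers(0, 2, size=(5, 30)).astype(np.int8))
        tree = bootstrap_support(g, n_reps=1, seed=3)
        for n in tree.non_tips():
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(4)
        g = gmat(rng.integers(0, 2, size=(6, 50)).astype(np.int8))
        t1 = bootstrap_support(g, n_reps=30, seed=42)
        t2 = bootstrap_support(g, n_reps=30, seed=42)
        s1 = sorted(n.support for n in t1.non_tips() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips() if hasattr(n, "support"))
        assert s1 == s2

    def test_implanted_clades_recovered_with_high_support(self, study):
        """The two mutant-line clades come back with support > 95; the
        divergent outlier sits far from everything else."""
        g = genotype_matrix(study.variants)
        tree = bootstrap_support(g, n_reps=200, seed=11)
        taxa = frozenset(t.name for t in tree.tips())
        support_by_side = {}
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if hasattr(node, "support"):
                support_by_side[side] = node.support
                support_by_side[taxa - side] = node.support
        for clade in (frozenset({"D052", "D056", "D120"}),
                      frozenset({"D122", "D131", "D128"})):
            assert support_by_side.get(clade, 0) > 95
        d = snp_distance_matrix(g)
        others = [a for a in d.index if a != "Hwangdo"]
        assert d.loc["Hwangdo", others].min() > 2 * d.loc[others, others].max().max()


def test_genotype_matrix_codes_alt_presence(study):
    g = genotype_matrix(study.variants)
    assert set(np.unique(g.to_numpy())) <= {0, 1}
    acc = study.accessions[0]
    n_snps = sum(1 for v in study.variants[acc] if v.is_snp)
    assert g.loc[acc].sum() == n_snps
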