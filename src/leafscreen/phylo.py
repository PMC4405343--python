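"""SNP-distance matrices and neighbor-joining trees with bootstrap support.

The genotype matrix codes each accession x site entry as 0 (reference
allele), 1 (alternative allele), or -1 (missing).  Pairwise distance is the
fraction of sites, among those non-missing in both accessions, where the two
calls differ (pairwise deletion; raw counts available by flag).  Trees are
built with the Saitou-Nei neighbor-joining agglomeration, which is exact on
additive distance matrices; bootstrap support is the percentage of
site-resampled replicate trees containing each internal bipartition.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

MISSING = -1


class PhyloError(ValueError):
    pass


def genotype_matrix(
    variants_by_accession: dict[str, list],
    snps_only: bool = True,
) -> pd.DataFrame:
    """Accessions x sites genotype matrix from per-accession variant calls.

    A site is any (chrom, pos) carrying a call in at least one accession; an
    accession is coded 1 there if it carries an alternative allele, else 0.
    """
    sites = sorted(
        {
            (v.chrom, v.pos)
            for calls in variants_by_accession.values()
            for v in calls
            if v.is_snp or not snps_only
        }
    )
    site_idx = {s: j for j, s in enumerate(sites)}
    accs = list(variants_by_accession)
    m = np.zeros((len(accs), len(sites)), dtype=np.int8)
    for i, acc in enumerate(accs):
        for v in variants_by_accession[acc]:
            if snps_only and not v.is_snp:
                continue
            m[i, site_idx[(v.chrom, v.pos)]] = 1
    return pd.DataFrame(m, index=accs, columns=[f"{c}:{p}" for c, p in sites])


def snp_distance_matrix(g: pd.DataFrame, normalized: bool = True) -> pd.DataFrame:
    """Pairwise SNP distance under pairwise deletion of missing entries.

    d(i,j) = (# comparable sites where calls differ) / (# comparable sites),
    or the raw mismatch count with ``normalized=False``.  Raises if any pair
    shares no comparable site.
    """
    if len(g) < 2:
        raise PhyloError("need at least 2 accessions")
    m = g.to_numpy()
    present = m != MISSING
    n = len(g)
    if present.all():
        # no missing data: mismatch counts via dot products
        x = (m == 1).astype(np.float64)
        diff = x @ (1.0 - x).T + (1.0 - x) @ x.T
        n_sites = g.shape[1]
        if n_sites == 0:
            raise PhyloError("no sites in genotype matrix")
        d = diff / n_sites if normalized else diff
        np.fill_diagonal(d, 0.0)
        return pd.DataFrame(d, index=g.index, columns=g.index)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                raise PhyloError(
                    f"no comparable sites between {g.index[i]} and {g.index[j]}"
                )
            diff = int((m[i, both] != m[j, both]).sum())
            d[i, j] = d[j, i] = diff / n_comp if normalized else diff
    return pd.DataFrame(d, index=g.index, columns=g.index)


def neighbor_joining(d: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree represented with a degree-3 central node; all
    other internal nodes also have degree 3.  Negative branch-length
    estimates are clamped to 0 (deficit logged).  Ties in the Q-matrix
    minimisation are broken toward the lowest index pair, making runs
    reproducible.  Exact on additive matrices.
    """
    D = np.asarray(d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise PhyloError("distance matrix must be square and symmetric")
    if np.abs(np.diag(D)).max() > 1e-12:
        raise PhyloError("distance matrix must have zero diagonal")
    if len(D) < 3:
        raise PhyloError("need at least 3 taxa")
    nodes = [TreeNode(name=str(name)) for name in d.index]
    D = D.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index (i, j) among the minima; Q may lose exact symmetry to
        # floating-point error after agglomeration, so normalise pair order
        qmin = Q.min()
        i, j = min(
            (min(int(a), int(b)), max(int(a), int(b)))
            for a, b in zip(*np.nonzero(Q == qmin))
        )
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (n - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining ones
        rest = [k for k in range(n) if k not in (i, j)]
        dn = 0.5 * (D[i, rest] + D[j, rest] - dij)
        D2 = np.empty((n - 1, n - 1))
        D2[: n - 2, : n - 2] = D[np.ix_(rest, rest)]
        D2[n - 2, : n - 2] = dn
        D2[: n - 2, n - 2] = dn
        D2[n - 2, n - 2] = 0.0
        D = D2
        nodes = [nodes[k] for k in rest] + [new]

    # resolve the final three nodes around a central degree-3 vertex
    (d01, d02, d12) = (D[0, 1], D[0, 2], D[1, 2])
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, length in zip(nodes, lengths):
        node.length = _clamp(length)
    return TreeNode(children=list(nodes))


def _clamp(length: float) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.4g clamped to 0", length)
        return 0.0
    return float(length)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical keys of the internal bipartitions of an unrooted tree.

    Each internal edge splits the taxa in two; the key is the frozenset of
    the two sides, so it is invariant to rooting and node order.  Trivial
    (single-tip) splits are excluded.
    """
    taxa = frozenset(t.name for t in tree.tips())
    keys = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            keys.add(frozenset((side, taxa - side)))
    return keys


def bootstrap_support(
    g: pd.DataFrame,
    n_reps: int = 1000,
    seed: int | None = None,
    normalized: bool = True,
) -> TreeNode:
    """NJ tree with per-node bootstrap supports from site resampling.

    Site columns are resampled with replacement ``n_reps`` times; the support
    of each internal bipartition of the original tree is the percentage of
    replicate trees containing it.  Supports are stored on internal nodes as
    ``node.support``, which the newick writer emits as internal node labels.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(snp_distance_matrix(g, normalized=normalized))
    taxa = frozenset(t.name for t in tree.tips())
    counts: dict[frozenset, int] = {}
    n_sites = g.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        rep = g.iloc[:, cols]
        rep_tree = neighbor_joining(snp_distance_matrix(rep, normalized=normalized))
        for key in bipartitions(rep_tree):
            counts[key] = counts.get(key, 0) + 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = frozenset((side, taxa - side))
            node.support = 100.0 * counts.get(key, 0) / n_reps
    return tree


def write_phylip_distances(d: pd.DataFrame, path: str) -> None:
    """Write a distance matrix in relaxed PHYLIP square format."""
    with open(path, "w") as fh:
        fh.write(f"{len(d)}\n")
        for name, row in d.iterrows():
            fh.write(str(name) + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
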