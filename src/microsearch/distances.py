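"""Distance kernels.

The central kernel is the sparse Earth-Mover-Distance formulation of
weighted UniFrac: abundance differences ("earth") are placed at the
leaves carrying a non-zero difference and propagated bottom-up, level by
level, each node contributing |unbalanced mass| x (branch length to its
parent).  Because community profiles are sparse, only the union of the
ancestor paths of differing leaves is ever touched — typically a tiny
fraction of the phylogeny.

Two independent formulations serve as oracles: a dense variant that
walks every node, and the direct branch-sum identity
``sum_b l_b * |A_b - B_b|`` over subtree mass fractions.  Bray-Curtis
dissimilarity (non-phylogenetic, not a metric) supports the coarse
search path.
"""

from __future__ import annotations

from dataclasses import dataclass

from microsearch.errors import NotNormalizedError, ProfileValueError, UnknownLeafError
from microsearch.phylo import PhyloTree
from microsearch.profiles import AbundanceProfile

__all__ = [
    "DistanceResult",
    "emd_unifrac_sparse",
    "emd_unifrac_dense",
    "wuf_branch_sum",
    "bray_curtis",
]

#: residual masses below this are treated as balanced and not propagated
BALANCE_EPS = 1e-12
#: tolerance on "relative abundances sum to 1"
NORM_TOL = 1e-9


@dataclass
class DistanceResult:
    """A distance value plus traversal instrumentation."""

    value: float
    visited_nodes: int

    def __float__(self) -> float:
        return self.value


def _check_inputs(tree: PhyloTree, p: AbundanceProfile, q: AbundanceProfile) -> None:
    unknown = [o for o in p.counts if o not in tree.leaf_index]
    unknown += [o for o in q.counts if o not in tree.leaf_index]
    if unknown:
        raise UnknownLeafError(set(unknown))
    for prof in (p, q):
        if abs(prof.depth - 1.0) > NORM_TOL:
            raise NotNormalizedError(
                f"sample {prof.sample_id!r} sums to {prof.depth}, expected 1 "
                "(call to_relative first)"
            )


def emd_unifrac_sparse(
    tree: PhyloTree, p: AbundanceProfile, q: AbundanceProfile
) -> DistanceResult:
    """Weighted UniFrac via sparse bottom-up mass propagation.

    Per-level dictionaries hold the unbalanced mass received from the
    children processed so far.  Levels are processed deepest first, so a
    node is finalized only after all of its touched children; it then
    adds ``|mass| * branch_length`` to the distance and forwards the
    signed mass to its parent iff it is non-zero.  Only ancestors of
    leaves with a non-zero abundance difference are ever visited.
    """
    _check_inputs(tree, p, q)
    level_mass: list[dict[int, float]] = [dict() for _ in range(tree.n_levels)]
    for otu in set(p.counts) | set(q.counts):
        diff = p.counts.get(otu, 0.0) - q.counts.get(otu, 0.0)
        if diff != 0.0:
            nid = tree.leaf_index[otu]
            level_mass[tree.level_of[nid]][nid] = diff

    dist = 0.0
    visited = 0
    for level in range(tree.n_levels - 1, -1, -1):
        for nid, mass in level_mass[level].items():
            visited += 1
            node = tree.nodes[nid]
            if node.parent is None:
                continue  # root: no parent branch
            dist += abs(mass) * node.length
            if abs(mass) >= BALANCE_EPS:
                parent_level = level_mass[level - 1]
                parent_level[node.parent] = parent_level.get(node.parent, 0.0) + mass
    return DistanceResult(dist, visited)


def emd_unifrac_dense(
    tree: PhyloTree, p: AbundanceProfile, q: AbundanceProfile
) -> DistanceResult:
    """Dense oracle: same propagation, visiting every node of the tree."""
    _check_inputs(tree, p, q)
    mass = [0.0] * len(tree)
    for otu, v in p.counts.items():
        mass[tree.leaf_index[otu]] += v
    for otu, v in q.counts.items():
        mass[tree.leaf_index[otu]] -= v

    dist = 0.0
    visited = 0
    for level in range(tree.n_levels - 1, -1, -1):
        for nid in tree.levels[level]:
            visited += 1
            node = tree.nodes[nid]
            if node.parent is None:
                continue
            dist += abs(mass[nid]) * node.length
            mass[node.parent] += mass[nid]
    return DistanceResult(dist, visited)


def wuf_branch_sum(
    tree: PhyloTree, p: AbundanceProfile, q: AbundanceProfile
) -> float:
    """Second oracle: the branch-sum identity for weighted UniFrac.

    ``sum over non-root branches of length * |mass of p below - mass of
    q below|``, with subtree masses accumulated in post-order.
    """
    _check_inputs(tree, p, q)
    below_p = [0.0] * len(tree)
    below_q = [0.0] * len(tree)
    for otu, v in p.counts.items():
        below_p[tree.leaf_index[otu]] = v
    for otu, v in q.counts.items():
        below_q[tree.leaf_index[otu]] = v
    for level in range(tree.n_levels - 1, 0, -1):
        for nid in tree.levels[level]:
            parent = tree.nodes[nid].parent
            below_p[parent] += below_p[nid]
            below_q[parent] += below_q[nid]
    total = 0.0
    for node in tree.nodes:
        if node.parent is not None:
            total += node.length * abs(below_p[node.id] - below_q[node.id])
    return total


def bray_curtis(p: AbundanceProfile, q: AbundanceProfile) -> float:
    """Bray-Curtis dissimilarity on counts: ``1 - 2*sum(min)/(dp+dq)``.

    Bounded in [0, 1]; 0 iff the count vectors are identical; 1 for
    disjoint support.  Computed on (optionally rarefied) counts, not
    relative abundances.
    """
    if p.depth <= 0 or q.depth <= 0:
        raise ProfileValueError("Bray-Curtis undefined for empty profiles")
    shared = set(p.counts) & set(q.counts)
    overlap = sum(min(p.counts[o], q.counts[o]) for o in shared)
    return 1.0 - 2.0 * overlap / (p.depth + q.depth)
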